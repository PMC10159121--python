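"""Core containers for RT-qPCR Cp data.

A Cp (crossing point) is the PCR cycle at which the amplification signal
crosses the detection threshold; it is approximately a negative log2 of the
template quantity, so differences in Cp are log2 fold changes under the
usual efficiency-2 assumption.

The central container, :class:`CpMatrix`, holds a targets x samples matrix
of Cp values together with an explicit missingness mask, a role label per
target (miRNA, endogenous candidate, spike-in, interplate calibrator,
U6-snRNA reference, blank) and a plate/panel label per sample.  Masked
cells are stored as NaN so that no downstream computation can silently
consume an undetected value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: Recognised target roles.
ROLES = frozenset(
    {
        "mirna",
        "endo_candidate",
        "spikein_isolation",
        "spikein_cdna",
        "ipc",
        "reference_u6",
        "blank",
    }
)

#: Roles that are technical controls: never classified, imputed or ranked.
CONTROL_ROLES = frozenset({"spikein_isolation", "spikein_cdna", "ipc", "blank"})

#: Roles eligible for stability / missingness / survival analysis.
ANALYTE_ROLES = frozenset({"mirna", "endo_candidate", "reference_u6"})


class CpMatrixError(ValueError):
    """Raised when a CpMatrix violates its structural invariants."""


@dataclass
class CpMatrix:
    """Targets x samples Cp matrix with explicit missingness.

    Parameters
    ----------
    values
        Float DataFrame indexed by target id (rows) and sample id
        (columns).  Cells that are masked must be NaN.
    mask
        Boolean DataFrame with the same index/columns; ``True`` marks a
        missing / undetected cell.
    roles
        Mapping target id -> role (see :data:`ROLES`).  Targets absent
        from the mapping default to ``"mirna"``.
    plate
        Mapping sample id -> plate / panel label.  Every sample must have
        a plate label.
    meta
        Free-form provenance notes (e.g. which IPC assay was consumed by
        interplate calibration).
    """

    values: pd.DataFrame
    mask: pd.DataFrame
    roles: dict = field(default_factory=dict)
    plate: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        self.mask = self.mask.astype(bool)
        self.roles = {t: self.roles.get(t, "mirna") for t in self.values.index}
        self.validate()
        # enforce "masked cells carry no numeric meaning"
        self.values = self.values.where(~self.mask, np.nan)

    # -- validation ----------------------------------------------------

    def validate(self) -> None:
        v, m = self.values, self.mask
        if not v.index.equals(m.index) or not v.columns.equals(m.columns):
            raise CpMatrixError("values and mask must share index and columns")
        if v.index.has_duplicates:
            dupes = v.index[v.index.duplicated()].unique().tolist()
            raise CpMatrixError(f"duplicate target ids: {dupes}")
        if v.columns.has_duplicates:
            dupes = v.columns[v.columns.duplicated()].unique().tolist()
            raise CpMatrixError(f"duplicate sample ids: {dupes}")
        bad_roles = {r for r in self.roles.values() if r not in ROLES}
        if bad_roles:
            raise CpMatrixError(f"unknown roles: {sorted(bad_roles)}")
        missing_plate = [s for s in v.columns if s not in self.plate]
        if missing_plate:
            raise CpMatrixError(
                f"samples without a plate label: {missing_plate}"
            )
        # any unmasked NaN is a contract violation
        stray = v.isna() & ~m
        if stray.to_numpy().any():
            t, s = np.argwhere(stray.to_numpy())[0]
            raise CpMatrixError(
                f"unmasked NaN at ({v.index[t]}, {v.columns[s]})"
            )

    # -- basic accessors -----------------------------------------------

    @property
    def targets(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def n_targets(self) -> int:
        return len(self.values.index)

    @property
    def n_samples(self) -> int:
        return len(self.values.columns)

    def role_of(self, target: str) -> str:
        return self.roles[target]

    def targets_with_role(self, *roles: str) -> list:
        want = set(roles)
        return [t for t in self.targets if self.roles[t] in want]

    def observed(self, target: str) -> pd.Series:
        """Observed (unmasked) Cp values of one target."""
        row = self.values.loc[target]
        return row[~self.mask.loc[target]]

    # -- subsetting ----------------------------------------------------

    def select_targets(self, targets: Iterable[str]) -> "CpMatrix":
        targets = list(targets)
        return CpMatrix(
            self.values.loc[targets].copy(),
            self.mask.loc[targets].copy(),
            {t: self.roles[t] for t in targets},
            dict(self.plate),
            dict(self.meta),
        )

    def select_samples(self, samples: Iterable[str]) -> "CpMatrix":
        samples = list(samples)
        return CpMatrix(
            self.values[samples].copy(),
            self.mask[samples].copy(),
            dict(self.roles),
            {s: self.plate[s] for s in samples},
            dict(self.meta),
        )

    def drop_targets(self, targets: Iterable[str]) -> "CpMatrix":
        drop = set(targets)
        return self.select_targets([t for t in self.targets if t not in drop])

    def copy(self) -> "CpMatrix":
        return CpMatrix(
            self.values.copy(),
            self.mask.copy(),
            dict(self.roles),
            dict(self.plate),
            dict(self.meta),
        )

    def equals(self, other: "CpMatrix") -> bool:
        return (
            self.values.round(10).fillna(-1).equals(other.values.round(10).fillna(-1))
            and self.mask.equals(other.mask)
            and self.roles == other.roles
            and {s: self.plate[s] for s in self.samples}
            == {s: other.plate[s] for s in other.samples}
        )


#: Mandatory sample-annotation columns.
ANNOTATION_COLUMNS = ("sample_id", "os_months", "event", "age", "histology", "panel")


def validate_annotation(ann: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample-annotation table.

    Requires columns ``sample_id, os_months, event, age, histology,
    panel``; overall survival must be a non-negative number of months and
    the event indicator must be 0 (censored) or 1 (death).
    """
    missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise ValueError(f"annotation missing mandatory columns: {missing}")
    if ann["sample_id"].duplicated().any():
        dupes = ann.loc[ann["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids in annotation: {dupes}")
    out = ann.copy()
    out["os_months"] = pd.to_numeric(out["os_months"], errors="coerce")
    out["event"] = pd.to_numeric(out["event"], errors="coerce")
    out["age"] = pd.to_numeric(out["age"], errors="coerce")
    bad_rows = []
    for i, row in out.iterrows():
        if not np.isfinite(row["os_months"]) or row["os_months"] < 0:
            bad_rows.append((i, "os_months"))
        if row["event"] not in (0.0, 1.0):
            bad_rows.append((i, "event"))
    if bad_rows:
        detail = ", ".join(f"row {i} ({col})" for i, col in bad_rows)
        raise ValueError(f"malformed annotation rows: {detail}")
    out["event"] = out["event"].astype(int)
    return out.set_index("sample_id", drop=False)


def align_annotation(m: CpMatrix, ann: pd.DataFrame) -> pd.DataFrame:
    """Return the annotation rows for the samples of ``m``, in order.

    Raises if a sample has no annotation or if a panel label disagrees
    with the matrix's plate assignment.
    """
    missing = [s for s in m.samples if s not in ann.index]
    if missing:
        raise ValueError(f"samples without annotation: {missing}")
    sub = ann.loc[list(m.samples)]
    clash = [
        s
        for s in m.samples
        if pd.notna(sub.loc[s, "panel"]) and str(sub.loc[s, "panel"]) != str(m.plate[s])
    ]
    if clash:
        raise ValueError(f"panel label disagrees with plate map for: {clash}")
    return sub
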