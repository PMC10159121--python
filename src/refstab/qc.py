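"""Interplate calibration and spike-in based sample quality control.

Calibration removes between-run Cp offsets using the interplate
calibrator (IPC) assay that is run on every plate: each plate's offset is
its mean IPC Cp minus the grand mean of the per-plate IPC means, and the
offset is subtracted from every observed Cp on that plate.  Offsets
therefore sum to zero across plates and all within-plate Cp differences
are preserved exactly.

Sample QC uses the RNA-isolation spike-ins.  UniSp2 is spiked at a
concentration 100-fold above UniSp4, so under efficiency-2 amplification
the expected Cp gap is log2(100) ~ 6.64 cycles.  A sample fails when its
UniSp2 Cp exceeds 30, when the UniSp4 - UniSp2 difference falls outside
the (inclusive) 5-8 cycle window, or when either spike-in is undetected.
The additional controls (UniSp5, UniSp6, cel-miR-39-3p) are reported but
trigger no exclusion: the low-concentration UniSp5 in particular is not
always detectable and no exclusion rule is defined for it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import CONTROL_ROLES, CpMatrix

#: Expected Cp step per 100-fold dilution under efficiency-2 amplification.
DILUTION_STEP_100X = float(np.log2(100.0))

RULE_UNISP2_GT_MAX = "unisp2_gt_max"
RULE_DELTA42_OUT_OF_RANGE = "delta42_out_of_range"
RULE_SPIKEIN_MISSING = "spikein_missing"


@dataclass
class QCReport:
    """Per-sample spike-in QC outcome plus per-plate calibration offsets.

    ``samples`` has one row per sample with columns ``unisp2_cp``,
    ``unisp4_cp``, ``delta42`` (= UniSp4 - UniSp2, cycles), ``pass`` and
    ``reasons`` (semicolon-joined rule ids, empty iff passing), plus the
    informational spike-ins when present.  ``ipc_offsets`` maps plate ->
    offset in cycles (empty if calibration was not run).
    """

    samples: pd.DataFrame
    ipc_offsets: dict = field(default_factory=dict)

    @property
    def passing(self) -> list:
        return self.samples.index[self.samples["pass"]].tolist()

    @property
    def failing(self) -> list:
        return self.samples.index[~self.samples["pass"]].tolist()


def interplate_calibrate(
    m: CpMatrix, ipc_target: str | None = None, reference: str = "grand_mean"
) -> tuple[CpMatrix, dict]:
    """Remove per-plate run offsets using the interplate calibrator.

    Parameters
    ----------
    m
        Raw Cp matrix; the IPC assay must be observed at least once on
        every plate.
    ipc_target
        Target id of the IPC assay; defaults to the unique target with
        role ``ipc``.
    reference
        ``"grand_mean"`` (default; offsets sum to zero and the result is
        invariant to plate ordering) or ``"first_plate"`` (offsets are
        relative to the first plate in sample order).

    Returns
    -------
    (calibrated matrix, plate -> offset in cycles).  The IPC rows are
    retained but flagged as consumed in ``meta["ipc_consumed"]``.
    """
    if ipc_target is None:
        ipc = m.targets_with_role("ipc")
        if len(ipc) != 1:
            raise ValueError(f"expected exactly one ipc-role target, found {ipc}")
        ipc_target = ipc[0]
    if m.roles.get(ipc_target) != "ipc":
        raise ValueError(f"{ipc_target!r} does not have role 'ipc'")

    plates: dict[str, list] = {}
    for s in m.samples:
        plates.setdefault(m.plate[s], []).append(s)

    ipc_row = m.values.loc[ipc_target]
    ipc_mask = m.mask.loc[ipc_target]
    plate_means = {}
    for p, samples in plates.items():
        obs = [s for s in samples if not ipc_mask[s]]
        if not obs:
            raise ValueError(f"plate {p!r} has no observed IPC value")
        plate_means[p] = float(ipc_row[obs].mean())

    if reference == "grand_mean":
        ref = float(np.mean(list(plate_means.values())))
    elif reference == "first_plate":
        ref = plate_means[m.plate[m.samples[0]]]
    else:
        raise ValueError(f"unknown reference {reference!r}")
    offsets = {p: mean - ref for p, mean in plate_means.items()}

    out = m.values.copy()
    for p, samples in plates.items():
        out[samples] = out[samples] - offsets[p]
    calibrated = CpMatrix(
        out,
        m.mask.copy(),
        dict(m.roles),
        dict(m.plate),
        {**m.meta, "ipc_consumed": ipc_target, "calibrated": True},
    )
    return calibrated, offsets


def spikein_qc(
    m: CpMatrix,
    unisp2_id: str = "UniSp2",
    unisp4_id: str = "UniSp4",
    unisp2_max: float = 30.0,
    delta42_range: tuple[float, float] = (5.0, 8.0),
    ipc_offsets: dict | None = None,
    extra_controls: tuple = ("UniSp5", "UniSp6", "cel-miR-39-3p"),
) -> tuple[QCReport, CpMatrix]:
    """Exclude samples with failed RNA-isolation spike-in controls.

    A sample fails iff UniSp2 Cp > ``unisp2_max``, or the UniSp4 - UniSp2
    difference lies outside the inclusive ``delta42_range`` window, or
    either spike-in is missing.  Returns the QC report and the matrix
    restricted to passing samples with all control rows (spike-ins, IPC,
    blanks) dropped.
    """
    for t in (unisp2_id, unisp4_id):
        if t not in m.targets:
            raise ValueError(f"spike-in assay {t!r} absent from matrix")
        if m.roles[t] not in CONTROL_ROLES:
            raise ValueError(f"{t!r} does not carry a spike-in role")
    lo, hi = delta42_range

    rows = []
    for s in m.samples:
        u2 = m.values.at[unisp2_id, s] if not m.mask.at[unisp2_id, s] else np.nan
        u4 = m.values.at[unisp4_id, s] if not m.mask.at[unisp4_id, s] else np.nan
        reasons = []
        delta = np.nan
        if np.isnan(u2) or np.isnan(u4):
            reasons.append(RULE_SPIKEIN_MISSING)
            if not np.isnan(u2) and u2 > unisp2_max:
                reasons.append(RULE_UNISP2_GT_MAX)
        else:
            delta = u4 - u2
            if u2 > unisp2_max:
                reasons.append(RULE_UNISP2_GT_MAX)
            if not (lo <= delta <= hi):
                reasons.append(RULE_DELTA42_OUT_OF_RANGE)
        row = {
            "unisp2_cp": u2,
            "unisp4_cp": u4,
            "delta42": delta,
            "pass": not reasons,
            "reasons": ";".join(reasons),
            "plate": m.plate[s],
        }
        for t in extra_controls:
            if t in m.targets:
                row[t] = (
                    m.values.at[t, s] if not m.mask.at[t, s] else np.nan
                )
        rows.append(row)
    report = QCReport(
        pd.DataFrame(rows, index=pd.Index(m.samples, name="sample_id")),
        dict(ipc_offsets or {}),
    )

    keep_targets = [t for t in m.targets if m.roles[t] not in CONTROL_ROLES]
    cleaned = m.select_targets(keep_targets).select_samples(report.passing)
    return report, cleaned
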