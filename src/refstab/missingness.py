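"""Detection-limit masking and missingness profiling.

qPCR signals crossing the threshold very late are not reliable
quantifications: Cp values at or above the limit of detection (default
35 cycles) are marked missing.  Targets are then partitioned by their
fraction of missing cells (ratio NA): ``complete`` (no missing cells,
usable for stability analysis), ``imputable`` (ratio strictly below the
threshold, default 20%, eligible for imputation) and ``excluded``
(too sparse to impute credibly).

Whether missingness is associated with clinical or technical covariates
is probed with per-target univariate tests: samples are split by the
target's missing indicator and each covariate is compared between the
two groups — Kruskal-Wallis for continuous covariates, Pearson
chi-squared (no continuity correction) for discrete ones.  The tests are
reported for inspection only; they never gate imputation, and no
multiplicity correction is applied since each is read as a separate
univariate screen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import ANALYTE_ROLES, CpMatrix

DEFAULT_LOD = 35.0
DEFAULT_NA_THRESHOLD = 0.20


@dataclass
class MissingnessProfile:
    """Per-target missingness classes and covariate-association tests.

    ``classes``: DataFrame indexed by target with columns ``ratio_na``
    (fraction in [0, 1]) and ``class`` in {complete, imputable,
    excluded}.  Control assays are never classified.  ``tests``: one row
    per (target, covariate) with the test name, statistic and p-value,
    or a skip reason.
    """

    classes: pd.DataFrame
    tests: pd.DataFrame = field(default_factory=pd.DataFrame)

    def targets_in_class(self, cls: str) -> list:
        return self.classes.index[self.classes["class"] == cls].tolist()

    @property
    def complete(self) -> list:
        return self.targets_in_class("complete")

    @property
    def imputable(self) -> list:
        return self.targets_in_class("imputable")

    @property
    def excluded(self) -> list:
        return self.targets_in_class("excluded")


def mark_missing(m: CpMatrix, lod: float = DEFAULT_LOD) -> CpMatrix:
    """Mask every Cp at or above the limit of detection.

    Idempotent, and monotone in ``lod``: lowering the limit can only add
    masked cells, never recover one.
    """
    new_mask = m.mask | (m.values >= lod).fillna(False)
    return CpMatrix(
        m.values.where(~new_mask),
        new_mask,
        dict(m.roles),
        dict(m.plate),
        {**m.meta, "lod": lod},
    )


def partition_targets(
    m: CpMatrix, threshold: float = DEFAULT_NA_THRESHOLD
) -> MissingnessProfile:
    """Classify analyte targets by their missing-value ratio.

    ratio NA = (# masked cells) / (# samples).  ``complete`` iff the
    ratio is 0; ``imputable`` iff 0 < ratio < ``threshold`` (strict, so
    e.g. 18.8% is imputable at the 20% default while 29.2% is excluded);
    ``excluded`` otherwise.  Spike-ins, IPC and blanks are not
    classified.
    """
    if m.n_samples == 0:
        raise ValueError("cannot partition targets with zero samples")
    analytes = [t for t in m.targets if m.roles[t] in ANALYTE_ROLES]
    ratio = m.mask.loc[analytes].sum(axis=1) / m.n_samples
    cls = pd.Series("excluded", index=ratio.index, dtype=object)
    cls[ratio == 0] = "complete"
    cls[(ratio > 0) & (ratio < threshold)] = "imputable"
    classes = pd.DataFrame({"ratio_na": ratio, "class": cls})
    classes.index.name = "target"
    return MissingnessProfile(classes)


def missingness_association(
    m: CpMatrix,
    ann: pd.DataFrame,
    covariates: dict,
    targets: list | None = None,
) -> pd.DataFrame:
    """Test each target's missing indicator against each covariate.

    Parameters
    ----------
    covariates
        Mapping covariate column -> ``"continuous"`` or ``"discrete"``.
    targets
        Targets to test; defaults to analyte targets having at least one
        missing and one observed cell.

    Returns a DataFrame with columns ``target, covariate, test,
    statistic, p_value, skipped_reason``.
    """
    ann = ann.loc[list(m.samples)]
    if targets is None:
        n_missing = m.mask.sum(axis=1)
        targets = [
            t
            for t in m.targets
            if m.roles[t] in ANALYTE_ROLES and 0 < n_missing[t] < m.n_samples
        ]
    rows = []
    for t in targets:
        miss = m.mask.loc[t].to_numpy()
        for cov, kind in covariates.items():
            if kind not in {"continuous", "discrete"}:
                raise ValueError(f"covariate {cov!r} must be continuous or discrete")
            x = ann[cov]
            row = {"target": t, "covariate": cov, "statistic": np.nan,
                   "p_value": np.nan, "skipped_reason": ""}
            if x.nunique(dropna=True) <= 1:
                row["test"] = "kruskal_wallis" if kind == "continuous" else "chi_squared"
                row["skipped_reason"] = "covariate_constant"
                rows.append(row)
                continue
            if kind == "continuous":
                row["test"] = "kruskal_wallis"
                g_miss = pd.to_numeric(x[miss]).dropna()
                g_obs = pd.to_numeric(x[~miss]).dropna()
                pooled = pd.concat([g_miss, g_obs])
                if pooled.nunique() <= 1:
                    # all values identical within both groups: no evidence
                    row["statistic"], row["p_value"] = 0.0, 1.0
                else:
                    h, p = stats.kruskal(g_miss, g_obs)
                    row["statistic"], row["p_value"] = float(h), float(p)
            else:
                row["test"] = "chi_squared"
                table = pd.crosstab(miss, x.astype(str))
                if table.shape[0] < 2:
                    row["skipped_reason"] = "missing_indicator_constant"
                else:
                    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
                    row["statistic"], row["p_value"] = float(chi2), float(p)
            rows.append(row)
    return pd.DataFrame(
        rows,
        columns=["target", "covariate", "test", "statistic", "p_value", "skipped_reason"],
    )


def profile_missingness(
    m: CpMatrix,
    ann: pd.DataFrame | None = None,
    covariates: dict | None = None,
    threshold: float = DEFAULT_NA_THRESHOLD,
) -> MissingnessProfile:
    """Partition targets and (optionally) run the association tests."""
    profile = partition_targets(m, threshold=threshold)
    if ann is not None and covariates:
        profile.tests = missingness_association(
            m, ann, covariates, targets=profile.imputable
        )
    return profile
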