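"""Univariate Cox proportional-hazards screening over workflow grids.

Each miRNA's normalized delta-Cp enters a univariate Cox model of
overall survival, h_i(t) = h0(t) * exp(beta * x_i), fitted by partial
likelihood with Efron tie handling (lifelines).  Reported per miRNA:
the Wald p-value, the score-test p-value (the continuous-covariate
generalisation of the log-rank test, computed at beta = 0 with Efron
tie handling), the hazard ratio exp(beta) per 1 delta-Cp unit and its
95% Wald CI.

``run_workflow_grid`` reproduces the full study design: the 5 x 3 grid
of missing-data handling {complete_cases, imp_missF, imp_VIM,
imp_max_one, imp_na_35} crossed with normalization {ENDO, U6-snRNA,
GMean}.  The complete-cases arm restricts to targets with no missing
values; the imputation arms use complete plus imputable targets.  No
multiple-testing correction is applied by default: the screen mirrors a
per-miRNA P < 0.05 univariate read-out (Benjamini-Hochberg available).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy import stats

from .core import CpMatrix, align_annotation
from .imputation import impute
from .missingness import MissingnessProfile, partition_targets
from .normalization import (
    NormalizedMatrix,
    default_gmean_include,
    normalize_endo,
    normalize_global_mean,
    normalize_reference,
)
from .stability import select_complete_cases, stability_report

IMPUTATION_ARMS = ("complete_cases", "imp_missF", "imp_VIM", "imp_max_one", "imp_na_35")
SCHEME_LABELS = {"ENDO": "ENDO", "U6": "U6-snRNA", "GMEAN": "GMean"}

RESULT_COLUMNS = [
    "target",
    "wald_p",
    "logrank_p",
    "hr",
    "hr_lower",
    "hr_upper",
    "coef",
    "se",
    "n",
    "n_events",
    "estimable",
    "workflow",
]


def cox_score_test(
    x: np.ndarray, time: np.ndarray, event: np.ndarray
) -> tuple[float, float]:
    """Score test of beta = 0 in a univariate Cox model, Efron ties.

    For a continuous covariate this is the generalisation of the
    log-rank test; for a binary covariate it coincides with it.
    Returns (chi-squared statistic on 1 df, p-value).
    """
    x = np.asarray(x, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    U = 0.0
    I = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        dead = (time == t) & (event == 1)
        d = int(dead.sum())
        nR = int(at_risk.sum())
        sx, sx2 = x[at_risk].sum(), (x[at_risk] ** 2).sum()
        dx, dx2 = x[dead].sum(), (x[dead] ** 2).sum()
        U += dx
        for l in range(d):
            denom = nR - l
            mean_l = (sx - (l / d) * dx) / denom
            U -= mean_l
            I += (sx2 - (l / d) * dx2) / denom - mean_l**2
    if I <= 0:
        return 0.0, 1.0
    chi2 = U**2 / I
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def cox_univariate(
    x: pd.Series,
    ann: pd.DataFrame,
    target: str = "",
    workflow: str = "",
) -> dict:
    """Fit one univariate Cox model of overall survival on ``x``.

    ``x`` is indexed by sample id; ``ann`` must carry ``os_months`` and
    ``event`` for those samples.  Returns one result row; degenerate
    inputs (no events, constant covariate) yield a row flagged
    non-estimable rather than an exception.
    """
    sub = ann.loc[x.index]
    row = {
        "target": target or x.name,
        "wald_p": np.nan,
        "logrank_p": np.nan,
        "hr": np.nan,
        "hr_lower": np.nan,
        "hr_upper": np.nan,
        "coef": np.nan,
        "se": np.nan,
        "n": len(x),
        "n_events": int(sub["event"].sum()),
        "estimable": False,
        "workflow": workflow,
    }
    if not np.isfinite(x.to_numpy()).all():
        raise ValueError(f"non-finite covariate for {row['target']!r}")
    if row["n_events"] < 2 or np.ptp(x.to_numpy()) == 0:
        return row
    df = pd.DataFrame(
        {"time": sub["os_months"].to_numpy(), "event": sub["event"].to_numpy(),
         "x": x.to_numpy()}
    )
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
    except Exception:
        return row
    summ = cph.summary.loc["x"]
    _, logrank_p = cox_score_test(df["x"], df["time"], df["event"])
    row.update(
        wald_p=float(summ["p"]),
        logrank_p=logrank_p,
        hr=float(summ["exp(coef)"]),
        hr_lower=float(summ["exp(coef) lower 95%"]),
        hr_upper=float(summ["exp(coef) upper 95%"]),
        coef=float(summ["coef"]),
        se=float(summ["se(coef)"]),
        estimable=True,
    )
    return row


def scan_normalized(
    norm: NormalizedMatrix,
    ann: pd.DataFrame,
    targets: list,
    workflow: str,
) -> pd.DataFrame:
    """Cox-scan every listed target of one normalized dataset."""
    rows = [
        cox_univariate(norm.values.loc[t], ann, target=t, workflow=workflow)
        for t in targets
    ]
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


@dataclass
class WorkflowGridResult:
    """All Cox rows over the imputation x normalization grid."""

    results: pd.DataFrame
    endo_ids: list
    u6_id: str
    alpha: float = 0.05
    failures: dict = field(default_factory=dict)

    @property
    def hits(self) -> pd.DataFrame:
        r = self.results
        return r[(r["estimable"]) & (r["wald_p"] < self.alpha)]

    @property
    def workflows(self) -> list:
        return sorted(self.results["workflow"].unique())


def run_workflow_grid(
    m: CpMatrix,
    ann: pd.DataFrame,
    endo_ids: list | None = None,
    u6_id: str | None = None,
    profile: MissingnessProfile | None = None,
    alpha: float = 0.05,
    seed: int = 0,
    rf_trees: int = 100,
    knn_k: int = 5,
) -> WorkflowGridResult:
    """Cox-scan the full 5 x 3 imputation-by-normalization grid.

    ``m`` must already be QC-passed, calibrated and LOD-masked.  The
    endogenous reference set defaults to the top-2 consensus-stable
    targets of the complete-case stability ranking; the U6 reference
    defaults to the unique ``reference_u6``-role target.  A failing grid
    cell is recorded in ``failures`` rather than aborting the scan.
    """
    ann = align_annotation(m, ann)
    if profile is None:
        profile = partition_targets(m)
    if u6_id is None:
        u6 = m.targets_with_role("reference_u6")
        if len(u6) != 1:
            raise ValueError(f"expected one reference_u6 target, found {u6}")
        u6_id = u6[0]

    complete = select_complete_cases(m)
    if endo_ids is None:
        ranking = stability_report(complete)
        endo_ids = ranking.top_k(2)

    retained = [t for t in m.targets if t in profile.complete + profile.imputable]
    imputable_matrix = m.select_targets(retained)

    results = []
    failures: dict[str, str] = {}
    for arm in IMPUTATION_ARMS:
        if arm == "complete_cases":
            data, source = complete, "complete_cases"
        else:
            try:
                imp = impute(
                    imputable_matrix,
                    arm,
                    seed=seed,
                    **({"n_trees": rf_trees} if arm == "imp_missF" else {}),
                    **({"k": knn_k} if arm == "imp_VIM" else {}),
                )
            except Exception as exc:  # a failed arm is reported, not fatal
                failures[arm] = str(exc)
                continue
            data, source = imp.matrix, arm
        scan_targets = [t for t in data.targets if data.roles[t] != "reference_u6"]
        for scheme in ("ENDO", "U6", "GMEAN"):
            workflow = f"{arm}_{SCHEME_LABELS[scheme]}"
            try:
                if scheme == "ENDO":
                    norm = normalize_endo(data, endo_ids, source=source)
                elif scheme == "U6":
                    norm = normalize_reference(data, u6_id, source=source)
                else:
                    norm = normalize_global_mean(
                        data, default_gmean_include(data), source=source
                    )
                results.append(scan_normalized(norm, ann, scan_targets, workflow))
            except Exception as exc:
                failures[workflow] = str(exc)
    all_rows = (
        pd.concat(results, ignore_index=True)
        if results
        else pd.DataFrame(columns=RESULT_COLUMNS)
    )
    return WorkflowGridResult(all_rows, list(endo_ids), u6_id, alpha, failures)


def benjamini_hochberg(p: pd.Series) -> pd.Series:
    """BH-adjusted p-values (available but off by default in the screen)."""
    from statsmodels.stats.multitest import multipletests

    adj = np.full(len(p), np.nan)
    ok = np.isfinite(p.to_numpy())
    if ok.any():
        adj[ok] = multipletests(p.to_numpy()[ok], method="fdr_bh")[1]
    return pd.Series(adj, index=p.index, name="p_bh")
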