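"""Delta-Cp normalization schemes and the coefficient-of-variation summary.

All three schemes subtract a per-sample reference level from every Cp in
that sample, so within-sample differences between targets are preserved
exactly:

ENDO
    reference = geometric mean of the chosen stable endogenous miRNAs'
    Cp values in the sample (with a single reference gene this reduces
    to plain subtraction).
U6
    reference = the U6-snRNA Cp of the sample.
GMEAN
    reference = arithmetic mean Cp over all retained miRNAs in the
    sample (post-imputation, so every included cell is present); the
    per-sample mean of normalized values is 0 by construction.

The geometric mean in ENDO is taken over Cp values themselves, the
arithmetic-mean-of-Cp alternative (equivalent to a geometric mean on the
linear-quantity scale) is available by flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .core import CpMatrix

SCHEMES = ("ENDO", "U6", "GMEAN")


@dataclass
class NormalizedMatrix:
    """Delta-Cp values (targets x samples, cycles) plus provenance."""

    values: pd.DataFrame
    scheme: str
    reference_spec: str
    source: str = "complete_cases"


def _check_reference_observed(m: CpMatrix, ids: Iterable[str]) -> None:
    for t in ids:
        if t not in m.targets:
            raise ValueError(f"reference target {t!r} absent from matrix")
        masked = m.mask.loc[t]
        if masked.any():
            s = masked[masked].index[0]
            raise ValueError(f"reference {t!r} is missing in sample {s!r}")


def normalize_endo(
    m: CpMatrix,
    endo_ids: Iterable[str],
    mean: str = "geometric",
    source: str = "complete_cases",
) -> NormalizedMatrix:
    """Subtract the (geometric) mean of stable endogenous controls."""
    endo_ids = list(endo_ids)
    if not endo_ids:
        raise ValueError("endo_ids must be non-empty")
    _check_reference_observed(m, endo_ids)
    ref_rows = m.values.loc[endo_ids]
    if mean == "geometric":
        if (ref_rows.to_numpy() <= 0).any():
            raise ValueError("geometric mean undefined for Cp <= 0")
        ref = np.exp(np.log(ref_rows).mean(axis=0))
    elif mean == "arithmetic":
        ref = ref_rows.mean(axis=0)
    else:
        raise ValueError(f"unknown mean {mean!r}")
    return NormalizedMatrix(
        m.values.sub(ref, axis=1),
        "ENDO",
        f"{mean} mean of {{{', '.join(endo_ids)}}}",
        source,
    )


def normalize_reference(
    m: CpMatrix, ref_id: str, source: str = "complete_cases"
) -> NormalizedMatrix:
    """Subtract a single reference assay (classically U6-snRNA)."""
    _check_reference_observed(m, [ref_id])
    return NormalizedMatrix(
        m.values.sub(m.values.loc[ref_id], axis=1),
        "U6",
        ref_id,
        source,
    )


def default_gmean_include(m: CpMatrix) -> list:
    """Targets entering the global mean: retained miRNAs, not U6/controls."""
    return m.targets_with_role("mirna", "endo_candidate")


def normalize_global_mean(
    m: CpMatrix,
    include: Iterable[str] | None = None,
    source: str = "complete_cases",
) -> NormalizedMatrix:
    """Subtract the per-sample arithmetic mean Cp over ``include``.

    ``include`` defaults to all miRNA-role targets (U6-snRNA and control
    assays excluded).  Every included cell must be observed, i.e. the
    matrix is post-imputation or complete-case.
    """
    include = list(include) if include is not None else default_gmean_include(m)
    if not include:
        raise ValueError("global-mean include set is empty")
    _check_reference_observed(m, include)
    ref = m.values.loc[include].mean(axis=0)
    return NormalizedMatrix(
        m.values.sub(ref, axis=1),
        "GMEAN",
        f"per-sample mean over {len(include)} targets",
        source,
    )


def coefficient_of_variation(m: CpMatrix | pd.DataFrame) -> pd.Series:
    """Per-target CoV in percent: 100 * SD / mean of Cp across samples.

    On a masked CpMatrix only observed cells enter; on an imputed or
    plain DataFrame every cell counts.  Requires at least 2 observed
    values and a nonzero mean per target.
    """
    v = m.values.where(~m.mask) if isinstance(m, CpMatrix) else pd.DataFrame(m)
    n_obs = v.notna().sum(axis=1)
    if (n_obs < 2).any():
        bad = n_obs.index[n_obs < 2].tolist()
        raise ValueError(f"CoV needs >= 2 observed values; offending targets: {bad}")
    mean = v.mean(axis=1)
    if (mean == 0).any():
        raise ValueError("CoV undefined for zero-mean target")
    return (100.0 * v.std(axis=1, ddof=1) / mean).rename("cov_pct")
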