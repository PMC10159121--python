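"""Missing-Cp imputation strategies.

Four strategies are provided, spanning the single/multiple imputation
contrast the workflow is designed to expose:

``imp_na_35``
    Replace every missing cell with a constant (Cp = 35, the detection
    limit).  Treats missingness as "below detection".
``imp_max_one``
    Replace missing cells of a target with that target's highest
    observed Cp plus one cycle — a per-target "just past the worst
    observed" constant.
``imp_missF``
    Iterative random-forest imputation (the missForest algorithm):
    initialise missing cells with per-target means, then sweep over
    targets in order of ascending missingness, regressing each target on
    all others with a random forest and refreshing its imputed cells,
    until the normalised squared change between sweeps first increases.
``imp_VIM``
    k-nearest-neighbour imputation: donors are ranked by Gower distance
    (per-target absolute difference scaled by the target's observed
    range, averaged over targets observed in both samples) and the
    missing cell takes the median (default) of the k nearest donors'
    observed values.

All methods leave observed cells bit-identical and record which cells
were imputed.  The random-forest path is fully reproducible from its
seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .core import CpMatrix

METHODS = ("imp_na_35", "imp_max_one", "imp_missF", "imp_VIM")


@dataclass
class ImputedDataset:
    """A fully observed CpMatrix plus imputation provenance.

    ``provenance`` is the set of (target, sample) cells that were filled
    in, i.e. exactly the pre-imputation mask of the retained targets.
    """

    matrix: CpMatrix
    method: str
    provenance: set = field(default_factory=set)
    seed: int | None = None
    iterations: int = 0
    converged: bool = True

    def __post_init__(self) -> None:
        if self.matrix.mask.to_numpy().any():
            raise ValueError("imputed dataset still contains masked cells")


def _finish(m: CpMatrix, filled: pd.DataFrame, method: str, **kw) -> ImputedDataset:
    ti, si = np.nonzero(m.mask.to_numpy())
    prov = {(m.targets[i], m.samples[j]) for i, j in zip(ti, si)}
    out = CpMatrix(
        filled,
        pd.DataFrame(False, index=m.targets, columns=m.samples),
        dict(m.roles),
        dict(m.plate),
        {**m.meta, "imputation": method},
    )
    return ImputedDataset(out, method, prov, **kw)


def impute_constant(m: CpMatrix, value: float = 35.0) -> ImputedDataset:
    """``imp_na_35``: every missing cell becomes ``value``."""
    filled = m.values.where(~m.mask, value)
    return _finish(m, filled, "imp_na_35")


def impute_max_plus_one(m: CpMatrix) -> ImputedDataset:
    """``imp_max_one``: missing cells take the target's observed max + 1."""
    filled = m.values.copy()
    for t in m.targets:
        miss = m.mask.loc[t]
        if not miss.any():
            continue
        obs = m.observed(t)
        if obs.empty:
            raise ValueError(f"target {t!r} has no observed value to anchor max+1")
        filled.loc[t, miss[miss].index] = float(obs.max()) + 1.0
    return _finish(m, filled, "imp_max_one")


def impute_random_forest(
    m: CpMatrix,
    n_trees: int = 100,
    max_iter: int = 10,
    seed: int = 0,
) -> ImputedDataset:
    """``imp_missF``: iterative random-forest (missForest) imputation.

    Samples are the observations, targets the variables.  Missing cells
    are initialised with the per-target mean of observed values; each
    sweep visits targets in ascending order of missingness, fits a
    random forest of ``n_trees`` trees (mtry = floor(sqrt(p))) of the
    target's observed entries on all other targets, and overwrites the
    target's imputed cells with the forest's predictions.  Sweeping
    stops the first time the normalised squared change in imputed values
    increases (the previous sweep's values are returned) or after
    ``max_iter`` sweeps (flagged non-converged).
    """
    if m.n_targets < 2:
        raise ValueError("random-forest imputation needs at least 2 targets")
    rng = np.random.RandomState(seed)
    X = m.values.T.copy()  # samples x targets
    miss = m.mask.T.copy()
    if not miss.to_numpy().any():
        return _finish(m, m.values.copy(), "imp_missF", seed=seed, iterations=0)

    # mean initialisation
    for t in X.columns:
        if miss[t].any():
            obs = X.loc[~miss[t], t]
            if obs.empty:
                raise ValueError(f"target {t!r} fully missing; cannot impute")
            X.loc[miss[t], t] = float(obs.mean())

    order = miss.sum(axis=0).sort_values(kind="stable").index
    order = [t for t in order if miss[t].any()]
    mtry = max(1, int(np.floor(np.sqrt(m.n_targets - 1))))

    prev = X.copy()
    prev_delta = np.inf
    iterations = 0
    converged = False
    for sweep in range(1, max_iter + 1):
        for t in order:
            predictors = [c for c in X.columns if c != t]
            rf = RandomForestRegressor(
                n_estimators=n_trees,
                max_features=min(mtry, len(predictors)),
                random_state=rng.randint(0, 2**31 - 1),
            )
            obs_rows = ~miss[t]
            rf.fit(X.loc[obs_rows, predictors], X.loc[obs_rows, t])
            X.loc[miss[t], t] = rf.predict(X.loc[miss[t], predictors])
        imp_cells = miss.to_numpy()
        num = float(((X.to_numpy() - prev.to_numpy()) ** 2)[imp_cells].sum())
        den = float((X.to_numpy() ** 2)[imp_cells].sum())
        delta = num / den if den > 0 else 0.0
        iterations = sweep
        if delta >= prev_delta:
            X = prev  # the previous sweep's values were the best
            converged = True
            break
        prev = X.copy()
        prev_delta = delta
    else:
        warnings.warn("missForest sweep limit reached without convergence")
    return _finish(
        m, X.T, "imp_missF", seed=seed, iterations=iterations, converged=converged
    )


def _gower_distances(m: CpMatrix, sample: str) -> pd.Series:
    """Gower distance from ``sample`` to every other sample.

    Per-target contributions are |difference| / observed range of that
    target (0 when the range is 0), averaged over targets observed in
    both samples; samples sharing no observed target get distance inf.
    """
    v = m.values
    obs = ~m.mask
    ranges = (v.max(axis=1) - v.min(axis=1)).replace(0.0, np.nan)
    diff = (v.sub(v[sample], axis=0)).abs().div(ranges, axis=0)
    diff = diff.where(ranges.notna(), 0.0)  # zero-range targets contribute 0
    shared = pd.DataFrame(
        obs.to_numpy() & obs[sample].to_numpy()[:, None], index=v.index, columns=v.columns
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        d = diff.where(shared).mean(axis=0)
    d[shared.sum(axis=0) == 0] = np.inf
    return d.drop(sample)


def impute_knn(
    m: CpMatrix, k: int = 5, aggregate: str = "median"
) -> ImputedDataset:
    """``imp_VIM``: k-nearest-neighbour imputation with Gower distance.

    For each missing cell (t, s) the k nearest donor samples that have t
    observed supply their values of t, aggregated by ``median`` (default)
    or ``mean``.  Donors lacking t are skipped and the next nearest
    promoted; if fewer than k usable donors exist, all available are
    used with a warning.
    """
    if aggregate not in {"median", "mean"}:
        raise ValueError("aggregate must be 'median' or 'mean'")
    if m.n_samples < 2:
        raise ValueError("kNN imputation needs at least 2 samples")
    agg = np.median if aggregate == "median" else np.mean
    filled = m.values.copy()
    for s in m.samples:
        miss_targets = m.mask.index[m.mask[s]]
        if len(miss_targets) == 0:
            continue
        d = _gower_distances(m, s).sort_values(kind="stable")
        for t in miss_targets:
            donors = [o for o in d.index if not m.mask.at[t, o] and np.isfinite(d[o])]
            if not donors:
                raise ValueError(f"no usable donor for cell ({t!r}, {s!r})")
            if len(donors) < k:
                warnings.warn(
                    f"only {len(donors)} donors (< k={k}) for ({t!r}, {s!r})"
                )
            use = donors[:k]
            filled.at[t, s] = float(agg(m.values.loc[t, use].to_numpy()))
    return _finish(m, filled, "imp_VIM")


def impute(m: CpMatrix, method: str, seed: int = 0, **kwargs) -> ImputedDataset:
    """Dispatch to one of the four named strategies."""
    if method == "imp_na_35":
        return impute_constant(m, **kwargs)
    if method == "imp_max_one":
        return impute_max_plus_one(m, **kwargs)
    if method == "imp_missF":
        return impute_random_forest(m, seed=seed, **kwargs)
    if method == "imp_VIM":
        return impute_knn(m, **kwargs)
    raise ValueError(f"unknown imputation method {method!r}; choose from {METHODS}")
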