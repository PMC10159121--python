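"""Reference-gene stability algorithms and consensus ranking.

Four classic stability measures are computed on a complete-case Cp
matrix (targets with no missing cells), all on the Cp scale directly —
Cp is already a log2-quantity, so pairwise Cp differences are log2
expression ratios under the efficiency-2 assumption.  Lower values mean
more stable in every algorithm, but the values are not comparable
between algorithms; only the ranks are aggregated.

comparative delta-Ct
    value(j) = mean over all other genes k of the sample SD of the
    pairwise difference Cp_j - Cp_k.  A gene that co-varies with the
    panel has small pairwise SDs.

BestKeeper
    Dispersion of a gene's Cp about its own central value: by default
    the mean absolute deviation about the geometric mean of Cp (the
    BestKeeper "SD [+/- Cp]" descriptor); a plain arithmetic SD variant
    is available by flag.  Unlike the other three measures this one is
    not invariant to adding a per-sample constant, because it never
    compares genes within a sample.

NormFinder (ungrouped)
    Model-based: Cp_ig = alpha_g + beta_i + eps_ig with gene-specific
    error variance sigma_g^2.  Centering each sample by its mean over
    genes gives d_ig whose per-gene variance u_g mixes sigma_g^2 with
    the average panel variance; the moment estimator below unmixes them
    and reports sigma_hat_g (0 when the moment estimate goes negative).
    A grouped variant (intra- plus inter-group variation) is available
    when a sample grouping is supplied.

geNorm
    M_j = mean pairwise-difference SD against the genes still in the
    candidate set (identical to delta-Ct on the first iteration); the
    least stable gene (largest M) is removed and M recomputed until two
    genes remain, which share the final M and jointly rank 1.

The consensus (RefFinder-style) ranking is the geometric mean of the
four per-algorithm competition ranks, ranked ascending.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ANALYTE_ROLES, CpMatrix

ALGORITHMS = ("deltact", "bestkeeper", "normfinder", "genorm")


def select_complete_cases(m: CpMatrix, min_targets: int = 3) -> CpMatrix:
    """Keep analyte targets (miRNA / endogenous candidate / U6) with no
    missing cells.

    Stability analysis is undefined below ``min_targets`` surviving
    targets.
    """
    keep = [
        t
        for t in m.targets
        if m.roles[t] in ANALYTE_ROLES and not m.mask.loc[t].any()
    ]
    if len(keep) < min_targets:
        raise ValueError(
            f"only {len(keep)} complete-case targets; "
            f"stability needs at least {min_targets}"
        )
    return m.select_targets(keep)


def _require_complete(m: CpMatrix) -> pd.DataFrame:
    if m.mask.to_numpy().any():
        raise ValueError("stability algorithms require a complete-case matrix")
    return m.values


def _pairwise_sd_means(v: pd.DataFrame) -> pd.Series:
    """Mean over partners of SD(Cp_j - Cp_k); shared by delta-Ct and geNorm."""
    x = v.to_numpy(dtype=float)
    G = x.shape[0]
    diffs = x[:, None, :] - x[None, :, :]  # G x G x n
    sds = diffs.std(axis=2, ddof=1)
    np.fill_diagonal(sds, np.nan)
    return pd.Series(np.nanmean(sds, axis=1), index=v.index)


def stability_delta_ct(m: CpMatrix) -> pd.Series:
    """Comparative delta-Ct stability values (lower = stabler)."""
    v = _require_complete(m)
    if v.shape[0] < 3:
        raise ValueError("delta-Ct needs at least 3 targets")
    if v.shape[1] < 2:
        raise ValueError("delta-Ct needs at least 2 samples")
    return _pairwise_sd_means(v).rename("value_deltact")


def stability_bestkeeper(m: CpMatrix, variant: str = "mad_geomean") -> pd.Series:
    """BestKeeper dispersion of each gene's Cp (lower = stabler).

    ``variant="mad_geomean"`` (default): mean absolute deviation about
    the geometric mean of Cp; ``variant="sd"``: arithmetic sample SD.
    """
    v = _require_complete(m)
    if variant == "mad_geomean":
        if (v.to_numpy() <= 0).any():
            raise ValueError("geometric mean undefined for Cp <= 0")
        gm = np.exp(np.log(v).mean(axis=1))
        out = (v.sub(gm, axis=0)).abs().mean(axis=1)
    elif variant == "sd":
        out = v.std(axis=1, ddof=1)
    else:
        raise ValueError(f"unknown BestKeeper variant {variant!r}")
    return out.rename("value_bestkeeper")


def stability_normfinder(
    m: CpMatrix, groups: pd.Series | None = None
) -> pd.Series:
    """NormFinder model-based stability (lower = stabler).

    Without ``groups``: moment estimator of the gene-specific error SD
    in the additive two-way model.  With ``groups`` (sample -> label): a
    grouped variant combining the intra-group error SD with the
    between-group spread of the gene's centred level.
    """
    v = _require_complete(m)
    G = v.shape[0]
    if G < 3:
        raise ValueError("NormFinder needs at least 3 genes")
    if groups is None:
        return _normfinder_ungrouped(v).rename("value_normfinder")
    groups = pd.Series(groups).loc[v.columns]
    per_group_sd = []
    group_level = []
    for _, cols in groups.groupby(groups).groups.items():
        sub = v[list(cols)]
        d = sub.sub(sub.mean(axis=0), axis=1)
        group_level.append(d.mean(axis=1))
        if sub.shape[1] >= 3:
            per_group_sd.append(_normfinder_ungrouped(sub))
    intra = (
        pd.concat(per_group_sd, axis=1).mean(axis=1)
        if per_group_sd
        else pd.Series(0.0, index=v.index)
    )
    inter = pd.concat(group_level, axis=1).std(axis=1, ddof=1).fillna(0.0)
    return np.sqrt(intra**2 + inter**2).rename("value_normfinder")


def _normfinder_ungrouped(v: pd.DataFrame) -> pd.Series:
    G = v.shape[0]
    d = v.sub(v.mean(axis=0), axis=1)  # centre each sample by its gene mean
    u = d.var(axis=1, ddof=1)
    total = (G / (G - 1)) * u.sum()
    sigma2 = np.maximum(0.0, (u - total / G**2) * G / (G - 2))
    return np.sqrt(sigma2)


def stability_genorm(m: CpMatrix) -> tuple[pd.Series, list]:
    """geNorm M values via stepwise exclusion.

    Returns (per-gene value, exclusion order least-stable-first).  Each
    excluded gene's value is its M at removal; the final two genes share
    the final M.  Ties in the removal step are broken by lexicographic
    target id (first removed).
    """
    v = _require_complete(m)
    if v.shape[0] < 3:
        raise ValueError("geNorm needs at least 3 genes")
    current = v.copy()
    values: dict[str, float] = {}
    exclusion_order: list[str] = []
    while current.shape[0] > 2:
        M = _pairwise_sd_means(current)
        worst_val = M.max()
        tied = sorted(M.index[np.isclose(M, worst_val)])
        worst = tied[0]
        values[worst] = float(M[worst])
        exclusion_order.append(worst)
        current = current.drop(index=worst)
    final_M = _pairwise_sd_means(current)
    for g in current.index:
        values[g] = float(final_M[g])
    out = pd.Series({t: values[t] for t in v.index}, name="value_genorm")
    return out, exclusion_order


def genorm_ranks(m: CpMatrix) -> pd.Series:
    """geNorm competition ranks from the exclusion order.

    The final pair jointly ranks 1, the next rank is 3, and earlier
    removals follow in reverse removal order.
    """
    values, order = stability_genorm(m)
    ranks = pd.Series(0, index=values.index, dtype=int)
    final_pair = [t for t in values.index if t not in order]
    for t in final_pair:
        ranks[t] = 1
    for pos, t in enumerate(reversed(order)):
        ranks[t] = 3 + pos
    return ranks.rename("rank_genorm")


def rank_targets(values: pd.Series, ascending: bool = True) -> pd.Series:
    """Competition (min) ranks: ties share the lowest rank, next skips."""
    if not np.isfinite(values).all():
        raise ValueError("cannot rank non-finite stability values")
    return values.rank(method="min", ascending=ascending).astype(int)


def reffinder_aggregate(ranks: pd.DataFrame) -> pd.DataFrame:
    """Geometric-mean consensus of four per-algorithm rank vectors.

    ``ranks`` columns are the four algorithms' competition ranks on an
    aligned target index.  Returns columns ``geomean`` (the geometric
    mean of the four ranks) and ``rank_overall`` (its competition rank,
    ascending).
    """
    if ranks.isna().any().any():
        raise ValueError("rank vectors must cover identical target sets")
    if ranks.shape[1] != 4:
        raise ValueError("expected exactly four rank vectors")
    geo = np.exp(np.log(ranks.astype(float)).mean(axis=1))
    return pd.DataFrame(
        {"geomean": geo, "rank_overall": rank_targets(geo)}
    )


@dataclass
class StabilityTable:
    """Per-target stability values, ranks, and the consensus ranking."""

    table: pd.DataFrame
    genorm_exclusion_order: list

    @property
    def top(self) -> list:
        return self.table.index.tolist()

    def top_k(self, k: int) -> list:
        return self.table.index[:k].tolist()


def stability_report(
    m: CpMatrix,
    bestkeeper_variant: str = "mad_geomean",
    groups: pd.Series | None = None,
) -> StabilityTable:
    """Run all four algorithms, rank each, and aggregate.

    The result is sorted by the consensus (geometric-mean) rank; row
    order is invariant to the input's target order apart from ties.
    """
    dct = stability_delta_ct(m)
    bk = stability_bestkeeper(m, variant=bestkeeper_variant)
    nf = stability_normfinder(m, groups=groups)
    gn_values, gn_order = stability_genorm(m)
    gn_rank = genorm_ranks(m)
    ranks = pd.DataFrame(
        {
            "rank_deltact": rank_targets(dct),
            "rank_bestkeeper": rank_targets(bk),
            "rank_normfinder": rank_targets(nf),
            "rank_genorm": gn_rank,
        }
    )
    agg = reffinder_aggregate(ranks)
    table = pd.concat(
        [
            dct.rename("value_deltact"),
            ranks["rank_deltact"],
            bk.rename("value_bestkeeper"),
            ranks["rank_bestkeeper"],
            nf.rename("value_normfinder"),
            ranks["rank_normfinder"],
            gn_values.rename("value_genorm"),
            ranks["rank_genorm"],
            agg,
        ],
        axis=1,
    )
    table = table.sort_values(["rank_overall", "geomean"], kind="stable")
    table.index.name = "target"
    return StabilityTable(table, gn_order)
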