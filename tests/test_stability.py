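"""Stability algorithms: brute-force oracles, invariances, consensus."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from refstab.simulate import SimConfig, TargetSpec, generate_dataset
from refstab.stability import (
    genorm_ranks,
    rank_targets,
    reffinder_aggregate,
    select_complete_cases,
    stability_bestkeeper,
    stability_delta_ct,
    stability_genorm,
    stability_normfinder,
    stability_report,
)

from conftest import make_cp


def random_matrix(seed, g=6, n=8, lo=18.0, hi=33.0):
    rng = np.random.default_rng(seed)
    return make_cp(rng.uniform(lo, hi, (g, n)))


class TestSelectCompleteCases:
    def test_only_masked_target_dropped(self):
        m = make_cp([[20.0, np.nan], [21.0, 22.0], [23.0, 24.0], [25.0, 26.0]])
        cc = select_complete_cases(m)
        assert list(cc.targets) == ["t2", "t3", "t4"]

    def test_no_missingness_is_identity(self):
        m = random_matrix(0)
        assert list(select_complete_cases(m).targets) == list(m.targets)

    def test_controls_never_selected(self):
        m = make_cp(
            [[20.0] * 3, [21.0, 21.5, 22.0], [23.0] * 3, [24.0, 25.0, 26.0]],
            targets=["UniSp2", "a", "b", "c"],
            roles={"UniSp2": "spikein_isolation"},
        )
        assert "UniSp2" not in select_complete_cases(m).targets

    def test_too_few_survivors_is_an_error(self):
        m = make_cp([[20.0, np.nan], [21.0, 22.0], [23.0, 24.0]])
        with pytest.raises(ValueError, match="complete-case"):
            select_complete_cases(m)


class TestDeltaCt:
    def test_matches_brute_force_pairwise_enumeration(self):
        m = random_matrix(3, g=5, n=7)
        got = stability_delta_ct(m)
        v = m.values
        for j in m.targets:
            sds = [
                np.std(v.loc[j] - v.loc[k], ddof=1) for k in m.targets if k != j
            ]
            assert got[j] == pytest.approx(np.mean(sds))

    def test_constant_offset_pair(self):
        # t2 = t1 + 2 exactly; their mutual pairwise SD is 0
        rng = np.random.default_rng(1)
        noise = rng.normal(26, 1.5, 6)
        m = make_cp([noise - 5, noise - 3, rng.normal(28, 1.0, 6)])
        got = stability_delta_ct(m)
        sd_vs_noise = np.std(m.values.loc["t1"] - m.values.loc["t3"], ddof=1)
        assert got["t1"] == pytest.approx(sd_vs_noise / 2)

    def test_sample_shift_invariance(self):
        m = random_matrix(4)
        shifted = make_cp(
            m.values.add(np.arange(m.n_samples) * 0.9, axis=1).to_numpy()
        )
        assert np.allclose(stability_delta_ct(m), stability_delta_ct(shifted))


class TestBestKeeper:
    def test_constant_target_scores_zero(self):
        m = make_cp([[24.0] * 4, [20.0, 21.0, 22.0, 23.0], [30.0, 29.0, 28.0, 27.0]])
        assert stability_bestkeeper(m)["t1"] == pytest.approx(0.0, abs=1e-12)

    def test_two_sample_hand_case(self):
        m = make_cp([[20.0, 22.0], [25.0, 26.0], [28.0, 29.0]])
        gm = np.sqrt(20.0 * 22.0)
        expected = ((gm - 20.0) + (22.0 - gm)) / 2
        assert stability_bestkeeper(m)["t1"] == pytest.approx(expected)
        assert stability_bestkeeper(m)["t1"] == pytest.approx(1.0, abs=5e-4)

    def test_not_sample_shift_invariant(self):
        # the one algorithm that must NOT be invariant to per-sample shifts
        m = random_matrix(5)
        shifted = make_cp(
            m.values.add(np.arange(m.n_samples) * 1.1, axis=1).to_numpy()
        )
        assert not np.allclose(stability_bestkeeper(m), stability_bestkeeper(shifted))

    def test_sd_variant(self):
        m = random_matrix(6)
        got = stability_bestkeeper(m, variant="sd")
        assert np.allclose(got, m.values.std(axis=1, ddof=1))

    def test_nonpositive_cp_rejected(self):
        m = make_cp([[0.0, 1.0], [2.0, 3.0], [4.0, 5.0]])
        with pytest.raises(ValueError, match="geometric"):
            stability_bestkeeper(m)


class TestNormFinder:
    def test_symmetric_design_gives_equal_values(self):
        rng = np.random.default_rng(7)
        g, n, sigma = 6, 4000, 0.5
        x = 25.0 + rng.normal(0, 1.0, n) + rng.normal(0, sigma, (g, n))
        vals = stability_normfinder(make_cp(x))
        assert vals.max() - vals.min() < 0.06

    def test_recovers_generating_sigmas(self):
        rng = np.random.default_rng(8)
        sigmas = np.array([0.1, 0.1, 0.1, 0.5, 0.5, 0.5, 1.0, 1.0, 1.0, 0.3])
        est = []
        for _ in range(100):
            beta = rng.normal(0, 1.0, 200)
            x = 25.0 + beta + rng.normal(0, 1, (10, 200)) * sigmas[:, None]
            est.append(stability_normfinder(make_cp(x)).to_numpy())
        mean_est = np.mean(est, axis=0)
        assert np.all(np.abs(mean_est - sigmas) / sigmas < 0.10)

    def test_sample_shift_invariance(self):
        m = random_matrix(9)
        shifted = make_cp(
            m.values.add(np.arange(m.n_samples) * 0.8, axis=1).to_numpy()
        )
        assert np.allclose(stability_normfinder(m), stability_normfinder(shifted))

    def test_grouped_variant_penalises_group_shift(self):
        rng = np.random.default_rng(10)
        n = 60
        groups = pd.Series(
            ["a"] * (n // 2) + ["b"] * (n // 2),
            index=[f"s{j + 1}" for j in range(n)],
        )
        base = 25.0 + rng.normal(0, 1.0, n) + rng.normal(0, 0.3, (5, n))
        shifty = base.copy()
        shifty[0, n // 2:] += 2.0  # gene 1 jumps between groups
        plain = stability_normfinder(make_cp(base), groups=groups)
        shifted = stability_normfinder(make_cp(shifty), groups=groups)
        assert shifted["t1"] > plain["t1"] + 0.5


class TestGeNorm:
    def test_final_pair_shares_value_and_rank(self):
        m = random_matrix(11, g=7)
        values, order = stability_genorm(m)
        final = [t for t in m.targets if t not in order]
        assert len(final) == 2
        assert values[final[0]] == pytest.approx(values[final[1]])
        ranks = genorm_ranks(m)
        assert ranks[final[0]] == ranks[final[1]] == 1
        assert sorted(ranks) == [1, 1] + list(range(3, m.n_targets + 1))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        hnp.arrays(
            float,
            st.tuples(st.integers(3, 8), st.integers(3, 10)),
            elements=st.floats(15.0, 35.0, allow_nan=False),
        )
    )
    def test_first_iteration_M_equals_delta_ct(self, arr):
        # algebraic identity: both are mean_k SD(Cp_j - Cp_k)
        if np.any(np.ptp(arr, axis=1) == 0):
            arr = arr + np.random.default_rng(0).normal(0, 0.01, arr.shape)
        from refstab.stability import _pairwise_sd_means

        m = make_cp(arr)
        np.testing.assert_allclose(
            _pairwise_sd_means(m.values).to_numpy(),
            stability_delta_ct(m).to_numpy(),
            rtol=0,
            atol=1e-12,
        )

    def test_exclusion_order_removes_noisiest_first(self):
        rng = np.random.default_rng(12)
        common = rng.normal(25, 1.2, 40)
        quiet = [common + rng.normal(0, 0.1, 40) for _ in range(3)]
        loud = [common + rng.normal(0, 3.0, 40)]
        m = make_cp(quiet + loud)
        _, order = stability_genorm(m)
        assert order[0] == "t4"


class TestRanking:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ((0.855, 0.855, 0.886), [1, 1, 3]),
            ((3.0, 1.0, 2.0), [3, 1, 2]),
            ((5.0, 5.0, 5.0), [1, 1, 1]),
        ],
    )
    def test_competition_ranks(self, values, expected):
        s = pd.Series(values)
        assert rank_targets(s).tolist() == expected

    def test_aggregate_identity_ranks(self):
        ranks = pd.DataFrame({"a": [1], "b": [1], "c": [1], "d": [1]})
        agg = reffinder_aggregate(ranks)
        assert agg["geomean"].iloc[0] == pytest.approx(1.0)

    def test_geomean_between_min_and_max_rank(self):
        rng = np.random.default_rng(13)
        ranks = pd.DataFrame(rng.integers(1, 20, (10, 4)))
        agg = reffinder_aggregate(ranks)
        assert (agg["geomean"] >= ranks.min(axis=1) - 1e-12).all()
        assert (agg["geomean"] <= ranks.max(axis=1) + 1e-12).all()


class TestStabilityReport:
    def test_table_invariant_to_target_order(self):
        m = random_matrix(14, g=6)
        rev = m.select_targets(list(m.targets)[::-1])
        a = stability_report(m).table.sort_index()
        b = stability_report(rev).table.sort_index()
        pd.testing.assert_frame_equal(a, b)

    def test_designed_stable_genes_recovered(self):
        # two ultra-stable genes among noisier ones land in the top 3
        hits = 0
        for seed in range(20):
            cfg = SimConfig(
                seed=seed,
                n_samples=48,
                mcar_rate=0.0,
                targets=[
                    TargetSpec("stable-a", 24.0, 0.2),
                    TargetSpec("stable-b", 26.0, 0.2),
                ]
                + [
                    TargetSpec(f"g{i}", 22.0 + 0.4 * i, 0.8 + 0.06 * i)
                    for i in range(18)
                ],
                spikeins=[],
                include_blank=False,
                prognostic_target="g0",
            )
            m, _, truth = generate_dataset(cfg)
            table = stability_report(select_complete_cases(m)).table
            top3 = table.index[:3]
            hits += set(truth.stable_set) <= set(top3)
        assert hits >= 19

    def test_values_nonnegative_and_sample_order_invariant(self):
        m = random_matrix(15)
        rev = m.select_samples(list(m.samples)[::-1])
        a = stability_report(m).table
        b = stability_report(rev).table
        for col in ("value_deltact", "value_bestkeeper", "value_normfinder", "value_genorm"):
            assert (a[col] >= 0).all()
            assert np.allclose(a[col].sort_index(), b[col].sort_index())
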