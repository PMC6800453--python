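"""Differential-methylation statistics against independent oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methagesig.data_model import ValidationError
from methagesig.diffmeth import (
    bh_fdr,
    contrast,
    glm_covariate_check,
    rank_sum_test,
    run_signature_pipeline,
    subtract_common,
    subtype_balance_test,
)
from methagesig.synthetic_data import SimulationConfig, simulate_methylation


def exact_rank_sum_p(a, b):
    """Oracle: enumerate every assignment of ranks to group A."""
    pooled = np.concatenate([a, b])
    ranks = np.argsort(np.argsort(pooled)) + 1.0
    n_a = len(a)
    w_obs = ranks[:n_a].sum()
    mu = n_a * (len(pooled) + 1) / 2.0
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n_a):
        w = ranks[list(combo)].sum()
        total += 1
        if abs(w - mu) >= abs(w_obs - mu) - 1e-9:
            count += 1
    return count / total


class TestRankSum:
    def test_no_separation_gives_p_one(self):
        a = np.full(5, 0.4)
        _, p = rank_sum_test(a, a)
        assert p == 1.0

    def test_most_extreme_three_vs_three(self):
        _, p = rank_sum_test([0.1, 0.2, 0.3], [0.7, 0.8, 0.9])
        assert p == pytest.approx(0.1)  # 2 of C(6,3)=20 arrangements

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        a, b = rng.random(6), rng.random(7)
        assert rank_sum_test(a, b)[1] == pytest.approx(rank_sum_test(b, a)[1])

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n_a, n_b = rng.integers(2, 9, size=2)
        a, b = rng.random(n_a), rng.random(n_b)
        _, p = rank_sum_test(a, b)
        assert p == pytest.approx(exact_rank_sum_p(a, b))

    def test_too_few_values_raise(self):
        with pytest.raises(ValidationError):
            rank_sum_test([0.1], [0.2, 0.3])

    def test_missing_values_dropped(self):
        a = [0.1, np.nan, 0.2, 0.3]
        _, p = rank_sum_test(a, [0.7, 0.8, 0.9])
        assert p == pytest.approx(0.1)


def step_up_oracle(p):
    """Direct BH step-up: q_i = min_{p_(j) ≥ p_(i)} p_(j)·m/rank(j), capped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        running = min(running, p[idx] * m / rank)
        q[idx] = running
    return q


class TestBH:
    def test_single_p_is_identity(self):
        assert bh_fdr([0.37])[0] == pytest.approx(0.37)

    def test_textbook_vector(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_all_equal(self):
        q = bh_fdr([0.2, 0.2, 0.2])
        assert np.allclose(q, 0.2)

    @pytest.mark.parametrize("m", [3, 17, 200, 1000])
    def test_matches_step_up_oracle(self, m):
        rng = np.random.default_rng(m)
        p = rng.uniform(1e-6, 1.0, size=m)
        assert np.allclose(bh_fdr(p), step_up_oracle(p))

    def test_out_of_range_raises(self):
        with pytest.raises(ValidationError):
            bh_fdr([0.5, 0.0])
        with pytest.raises(ValidationError):
            bh_fdr([0.5, 1.2])

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=1, max_size=60))
    def test_q_never_below_p_and_order_monotone(self, p):
        q = bh_fdr(p)
        assert (q >= np.asarray(p) - 1e-12).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()


class TestContrast:
    def test_unknown_group_raises(self, sim):
        _, bm, sheet, _, _ = sim
        with pytest.raises(ValidationError):
            contrast(bm, sheet, "BCVZ", "BCO")

    def test_significance_call_matches_thresholds(self, sim):
        _, bm, sheet, _, _ = sim
        res = contrast(bm, sheet, "BCVY", "BCO")
        expected = (res["q_value"] <= 0.05) & (res["delta_beta"].abs() >= 0.1)
        assert (res["significant"] == expected).all()
        # both failure modes occur in the cohort: small effect and large q
        assert ((res["q_value"] <= 0.05) & ~res["significant"]).any()

    def test_direction_matches_delta_sign(self, sim):
        _, bm, sheet, _, _ = sim
        res = contrast(bm, sheet, "BCVY", "BCO")
        assert (res.loc[res["delta_beta"] > 0, "direction"] == "hyper_in_A").all()
        assert (res.loc[res["delta_beta"] < 0, "direction"] == "hypo_in_A").all()

    def test_invariant_to_sample_order(self, sim):
        _, bm, sheet, _, _ = sim
        rng = np.random.default_rng(0)
        shuffled = bm.subset_samples(list(rng.permutation(bm.sample_ids)))
        a = contrast(bm, sheet, "BCVY", "BCO")
        b = contrast(shuffled, sheet, "BCVY", "BCO")
        pd.testing.assert_frame_equal(a, b)

    def test_missing_values_handled_pairwise(self, sim):
        _, bm, sheet, _, _ = sim
        data = bm.data.iloc[:50].copy()
        data.iloc[0, 0] = np.nan
        from methagesig.data_model import BetaMatrix

        res = contrast(BetaMatrix(data), sheet, "BCVY", "BCO")
        assert np.isfinite(res["p_value"]).all()


class TestSubtract:
    def test_set_difference_size_identity(self):
        rng = np.random.default_rng(5)
        a = set(rng.choice(10_000, size=800, replace=False))
        b = set(rng.choice(10_000, size=700, replace=False))
        out = subtract_common(a, b)
        assert len(out) == len(a) - len(a & b)

    def test_disjoint_identity(self):
        assert subtract_common({"x", "y"}, {"z"}) == {"x", "y"}

    def test_equal_sets_annihilate(self):
        assert subtract_common({"x", "y"}, {"y", "x"}) == set()


class TestSignaturePipeline:
    def test_distinctive_subset_of_pool(self, sig_result):
        assert sig_result.distinctive_signature.probe_ids <= sig_result.specific_pool.probe_ids

    def test_counts_identities(self, sig_result):
        c = sig_result.counts
        assert c["n_specific_pool"] == c["n_sig_bcvy_vs_normal"] - c["n_common"]
        assert len(sig_result.global_signature) == c["n_global_signature"]

    def test_planted_recovery(self, sim, sig_result):
        _, _, _, _, truth = sim
        td = set(truth.index[truth["truth_class"] == "distinctive"])
        tg = set(truth.index[truth["truth_class"] == "global"])
        d = sig_result.distinctive_signature.probe_ids
        g = sig_result.global_signature.probe_ids
        assert len(d & td) / len(td) >= 0.9
        assert len(d - td) / max(len(d), 1) <= 0.1
        assert len(g & (tg | td)) / len(tg | td) >= 0.9

    def test_null_simulation_near_empty(self):
        cfg = SimulationConfig(
            n_probes=1500, n_planted_global=0, n_planted_distinct=0,
            n_clock_cpgs=10, effect_size=0.0, seed=21,
        )
        bm, sheet, _, _ = simulate_methylation(cfg)
        res = run_signature_pipeline(bm, sheet)
        assert len(res.global_signature) <= 5
        assert len(res.distinctive_signature) <= 5

    def test_empty_group_raises(self, sim):
        _, bm, sheet, _, _ = sim
        sub = sheet.data[sheet.data["group"] != "NVY"].copy()
        from methagesig.data_model import SampleSheet

        with pytest.raises(ValidationError, match="NVY"):
            run_signature_pipeline(bm, SampleSheet(sub))

    def test_exclusion_list_removes_probes_before_testing(self, sim):
        _, bm, sheet, _, truth = sim
        clock_probes = set(truth.index[truth["truth_class"] == "clock"])
        res = run_signature_pipeline(bm, sheet, exclude_probes=clock_probes)
        assert res.counts["n_probes_tested"] == bm.shape[0] - len(clock_probes)


class TestGLM:
    def test_age_driven_probes_stay_age_significant(self, sim, sig_result):
        _, bm, sheet, _, _ = sim
        probes = sorted(sig_result.distinctive_signature.probe_ids)
        table = glm_covariate_check(bm, sheet, probes)
        assert table.attrs["frac_age_significant"] >= 0.9

    def test_subtype_p_roughly_uniform_on_null_probes(self, sim):
        _, bm, sheet, _, truth = sim
        nulls = list(truth.index[truth["truth_class"] == "null"][:150])
        table = glm_covariate_check(bm, sheet, nulls)
        # no subtype signal was planted: p should not pile up near zero
        assert (table["p_subtype"] < 0.05).mean() < 0.15
        assert table["p_subtype"].mean() > 0.3

    def test_constant_probe_flagged_degenerate(self, tiny_sheet):
        from methagesig.data_model import BetaMatrix

        data = pd.DataFrame(
            [[0.5, 0.5, 0.5, 0.5]], index=["cg1"], columns=["s1", "s2", "s3", "s4"]
        )
        table = glm_covariate_check(BetaMatrix(data), tiny_sheet, ["cg1"],
                                    covariates=("er_status",))
        assert table.loc["cg1", "degenerate"]
        assert table.loc["cg1", "p_age_group"] == 1.0


class TestSubtypeBalance:
    def test_identical_tables_are_homogeneous(self, ):
        from methagesig.data_model import SampleSheet, assign_groups

        rows = []
        for group_age, tissue in ((30, "tumour"), (60, "tumour")):
            for i, subtype in enumerate(["TN"] * 10 + ["LuminalA"] * 10):
                rows.append(
                    {
                        "sample_id": f"s{group_age}_{i}",
                        "age": group_age,
                        "tissue": tissue,
                        "subtype": subtype,
                        "er_status": "NA",
                        "relapse": "NA",
                    }
                )
        sheet = assign_groups(SampleSheet(pd.DataFrame(rows)))
        chi2, p = subtype_balance_test(sheet)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_table(self):
        # ((12,3),(5,10)): E = [[8.5,6.5],[8.5,6.5]], χ² = Σ(O−E)²/E = 6.652
        from methagesig.data_model import SampleSheet, assign_groups

        rows = []
        layout = {(30, "TN"): 12, (30, "LuminalA"): 3, (60, "TN"): 5, (60, "LuminalA"): 10}
        i = 0
        for (age, subtype), n in layout.items():
            for _ in range(n):
                rows.append(
                    {
                        "sample_id": f"s{i}",
                        "age": age,
                        "tissue": "tumour",
                        "subtype": subtype,
                        "er_status": "NA",
                        "relapse": "NA",
                    }
                )
                i += 1
        sheet = assign_groups(SampleSheet(pd.DataFrame(rows)))
        chi2, _ = subtype_balance_test(sheet)
        expected = sum(
            (o - e) ** 2 / e for o, e in zip((12, 3, 5, 10), (8.5, 6.5, 8.5, 6.5))
        )
        assert chi2 == pytest.approx(expected)
        assert chi2 == pytest.approx(6.652, abs=5e-4)
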