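import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from methagesig.data_model import ExpressionMatrix, SampleSheet, ValidationError, assign_groups
from methagesig.diffmeth import rank_sum_test
from methagesig.expression_integration import (
    balanced_permutation_test,
    combine_p,
    ddct_fold_change,
    integrate,
)
from methagesig.synthetic_data import simulate_expression


def _sheet(n_young=6, n_old=6, subtypes=("TN",)):
    rows = []
    for group, n, age in (("y", n_young, 30.0), ("o", n_old, 65.0)):
        for i in range(n):
            rows.append(
                {
                    "sample_id": f"{group}{i}",
                    "age": age,
                    "tissue": "tumour",
                    "subtype": subtypes[i % len(subtypes)],
                    "er_status": "NA",
                    "relapse": "NA",
                }
            )
    return assign_groups(SampleSheet(pd.DataFrame(rows)))


def _em(sheet, n_genes=5, effect=0.0, seed=0):
    rng = np.random.default_rng(seed)
    ids = sheet.data["sample_id"]
    young = sheet.data["group"].to_numpy() == "BCVY"
    vals = rng.normal(5.0, 1.0, size=(n_genes, len(ids)))
    vals[:, young] += effect
    return ExpressionMatrix(
        pd.DataFrame(vals, index=[f"g{i}" for i in range(n_genes)], columns=ids)
    )


class TestBalancedPermutation:
    def test_whole_cohort_reduces_to_plain_rank_sum(self):
        sheet = _sheet(6, 6)
        em = _em(sheet, n_genes=3, effect=1.0, seed=1)
        p = balanced_permutation_test(em, sheet, k=1, seed=0)
        young = [s for s in em.sample_ids if s.startswith("y")]
        old = [s for s in em.sample_ids if s.startswith("o")]
        for gene in em.gene_ids:
            _, expected = rank_sum_test(
                em.data.loc[gene, young].to_numpy(), em.data.loc[gene, old].to_numpy()
            )
            assert p.loc[0, gene] == pytest.approx(expected)

    def test_draws_are_balanced_per_subtype(self):
        sheet = _sheet(9, 15, subtypes=("TN", "LuminalA", "Her2"))
        em = _em(sheet, n_genes=2)
        p = balanced_permutation_test(em, sheet, k=5, seed=3)
        for draw in p.attrs["draws"]:
            for subtype, (young_ids, old_ids) in draw.items():
                assert len(young_ids) == len(old_ids)
                assert len(set(young_ids)) == len(young_ids)  # without replacement

    def test_subtype_absent_from_one_group_dropped(self, caplog):
        sheet = _sheet(8, 8, subtypes=("TN", "LuminalA"))
        # retype old samples so LuminalA only exists in the young group
        sheet.data.loc[sheet.data["group"] == "BCO", "subtype"] = "TN"
        em = _em(sheet, n_genes=2)
        p = balanced_permutation_test(em, sheet, k=2, seed=0)
        assert p.attrs["balanced_subtypes"] == ["TN"]

    def test_identical_seed_identical_matrix(self):
        sheet = _sheet(6, 8)
        em = _em(sheet, n_genes=4, seed=2)
        a = balanced_permutation_test(em, sheet, k=10, seed=42)
        b = balanced_permutation_test(em, sheet, k=10, seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_null_p_values_roughly_uniform(self):
        sheet = _sheet(10, 14)
        em = _em(sheet, n_genes=300, effect=0.0, seed=5)
        p = balanced_permutation_test(em, sheet, k=1, seed=9)
        ks = stats.kstest(p.iloc[0].to_numpy(), "uniform")
        assert ks.pvalue > 0.01


class TestCombineP:
    def test_all_ones_give_one(self):
        assert combine_p([1.0, 1.0, 1.0]) == pytest.approx(1.0)

    def test_two_moderate_p_fisher_oracle(self):
        x = -2 * (np.log(0.05) + np.log(0.05))
        assert x == pytest.approx(11.983, abs=1e-3)
        assert combine_p([0.05, 0.05]) == pytest.approx(stats.chi2.sf(x, 4))
        assert combine_p([0.05, 0.05]) == pytest.approx(0.0175, abs=2e-4)

    def test_single_p_is_identity(self):
        assert combine_p([0.3]) == pytest.approx(0.3)

    def test_stouffer_reduces_to_identity_at_k_one(self):
        assert combine_p([0.3], method="stouffer") == pytest.approx(0.3)

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            combine_p([])
        with pytest.raises(ValidationError):
            combine_p([0.5, 1.5])
        with pytest.raises(ValidationError):
            combine_p([0.5], method="tippett")

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=1, max_size=20),
        st.integers(min_value=0, max_value=19),
    )
    def test_monotone_in_each_component(self, p_vec, idx):
        idx = idx % len(p_vec)
        smaller = list(p_vec)
        smaller[idx] = smaller[idx] / 2
        assert combine_p(smaller) <= combine_p(p_vec) + 1e-12


class TestIntegrate:
    def _inputs(self, expr_effect, delta_beta):
        sheet = _sheet(8, 8)
        rng = np.random.default_rng(0)
        ids = sheet.data["sample_id"]
        young = sheet.data["group"].to_numpy() == "BCVY"
        vals = rng.normal(5.0, 0.05, size=(1, len(ids)))
        vals[:, young] += expr_effect
        em = ExpressionMatrix(pd.DataFrame(vals, index=["g0"], columns=ids))
        meth = pd.DataFrame({"delta_beta": [delta_beta]}, index=pd.Index(["cg0"]))
        gmap = pd.DataFrame({"gene_id": ["g0"], "probe_id": ["cg0"]})
        return meth, em, sheet, gmap

    def test_hypo_probe_with_overexpression_retained(self):
        meth, em, sheet, gmap = self._inputs(expr_effect=0.5, delta_beta=-0.2)
        out = integrate(meth, em, sheet, gmap, permutations=10, seed=1)
        assert out.loc["g0", "meth_direction"] == "hypo"
        assert bool(out.loc["g0", "retained"])

    def test_hypo_probe_with_underexpression_rejected(self):
        meth, em, sheet, gmap = self._inputs(expr_effect=-0.5, delta_beta=-0.2)
        out = integrate(meth, em, sheet, gmap, permutations=10, seed=1)
        assert not bool(out.loc["g0", "consistent"])
        assert not bool(out.loc["g0", "retained"])

    def test_retained_implies_all_three_conditions(self, sim, sig_result):
        _, bm, sheet, _, truth = sim
        em, gmap = simulate_expression(bm, truth, coupling=-0.8, seed=4)
        meth = sig_result.contrasts["bcvy_vs_bco_global"]
        out = integrate(meth, em, sheet, gmap[["gene_id", "probe_id"]],
                        permutations=15, seed=4)
        retained = out[out["retained"]]
        assert (retained["q_value"] < 0.01).all()
        assert (retained["expr_delta"].abs() >= 0.1).all()
        assert retained["consistent"].all()

    def test_absent_gene_skipped(self):
        meth, em, sheet, gmap = self._inputs(expr_effect=0.5, delta_beta=-0.2)
        gmap = pd.concat(
            [gmap, pd.DataFrame({"gene_id": ["ghost"], "probe_id": ["cg0"]})]
        )
        out = integrate(meth, em, sheet, gmap, permutations=5, seed=0)
        assert list(out.index) == ["g0"]


class TestDdct:
    def _table(self, target, reference, groups):
        return pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(len(target))],
                "group": groups,
                "target_ct": target,
                "reference_ct": reference,
            }
        )

    def test_equal_cts_give_unit_fold_change(self):
        ct = self._table([20.0] * 6, [20.0] * 6, ["young"] * 3 + ["old"] * 3)
        out, _ = ddct_fold_change(ct)
        assert np.allclose(out["fold_change"], 1.0)

    @pytest.mark.parametrize("ddct,expected", [(-1.0, 2.0), (2.0, 0.25)])
    def test_fold_change_closed_form(self, ddct, expected):
        # calibrator mean ΔCt = 5; young samples sit at 5 + ddct
        ct = self._table(
            [25.0 + ddct] * 3 + [25.0] * 3,
            [20.0] * 6,
            ["young"] * 3 + ["old"] * 3,
        )
        out, _ = ddct_fold_change(ct)
        young_fc = out.loc[out["group"] == "young", "fold_change"]
        assert np.allclose(young_fc, expected)

    def test_missing_reference_dropped(self):
        ct = self._table([21.0] * 4, [20.0, np.nan, 20.0, 20.0],
                         ["young", "young", "old", "old"])
        out, _ = ddct_fold_change(ct)
        assert len(out) == 3

    def test_group_comparison_detects_shift(self):
        rng = np.random.default_rng(0)
        target = np.concatenate([rng.normal(22, 0.2, 8), rng.normal(25, 0.2, 8)])
        ct = self._table(target, [20.0] * 16, ["young"] * 8 + ["old"] * 8)
        _, comp = ddct_fold_change(ct)
        assert comp["rank_sum_p"] < 0.01
        assert comp["group_mean_fold_change"]["young"] > comp["group_mean_fold_change"]["old"]
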