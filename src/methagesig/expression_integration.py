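"""Methylation–expression integration and qRT-PCR fold-change analytics.

Differential expression between the young and old tumour groups is
assessed by repeated subtype-balanced subsampling: each of ``k``
permutations draws, per molecular subtype, an equal number of samples
from both age groups, and a two-sided rank-sum test is run per gene
within the draw.  The k p-values per gene are combined (Fisher's method
by default, Stouffer optional), BH-adjusted over the tested genes, and a
gene is retained when it passes the FDR cut-off, shows an absolute
log-expression group difference of at least ``expr_delta_min``, and its
direction is consistent with the methylation change of its linked probes
(hypomethylated → overexpressed in the young group, hypermethylated →
repressed).
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import ExpressionMatrix, SampleSheet, ValidationError
from .diffmeth import bh_fdr

logger = logging.getLogger(__name__)

__all__ = [
    "balanced_permutation_test",
    "combine_p",
    "integrate",
    "ddct_fold_change",
]


def balanced_permutation_test(
    em: ExpressionMatrix,
    sheet: SampleSheet,
    genes: Sequence[str] | None = None,
    k: int = 50,
    seed: int = 0,
    group_young: str = "BCVY",
    group_old: str = "BCO",
) -> pd.DataFrame:
    """k × genes matrix of per-draw rank-sum p-values.

    Each permutation draws, for every subtype present with ≥ 2 samples in
    both age groups, min(n_young, n_old) samples from each group without
    replacement; a subtype failing that requirement is dropped from the
    balancing (logged).  The seed fixes all draws.
    """
    info = sheet.data.set_index("sample_id")
    info = info[info.index.isin(em.sample_ids)]
    young = info[info["group"] == group_young]
    old = info[info["group"] == group_old]
    if genes is None:
        genes = list(em.gene_ids)
    else:
        genes = [g for g in genes if g in em.gene_ids]
    if not genes:
        raise ValidationError("no requested genes present in the expression matrix")

    draws_young, draws_old = {}, {}
    for subtype in sorted(set(young["subtype"]) | set(old["subtype"])):
        y_ids = young.index[young["subtype"] == subtype].to_numpy()
        o_ids = old.index[old["subtype"] == subtype].to_numpy()
        if len(y_ids) < 2 or len(o_ids) < 2:
            logger.warning(
                "balanced_permutation_test: subtype %r dropped (needs ≥2 per group)",
                subtype,
            )
            continue
        draws_young[subtype], draws_old[subtype] = y_ids, o_ids
    if not draws_young:
        raise ValidationError("no subtype has ≥ 2 samples in both age groups")

    rng = np.random.default_rng(seed)
    values = em.data.loc[genes]
    p_rows = []
    all_draws = []
    for _ in range(k):
        y_sel, o_sel = [], []
        draw_record = {}
        for subtype in draws_young:
            m = min(len(draws_young[subtype]), len(draws_old[subtype]))
            y_sub = rng.choice(draws_young[subtype], size=m, replace=False)
            o_sub = rng.choice(draws_old[subtype], size=m, replace=False)
            y_sel.extend(y_sub)
            o_sel.extend(o_sub)
            draw_record[subtype] = (list(y_sub), list(o_sub))
        all_draws.append(draw_record)
        A = values[y_sel].to_numpy()
        B = values[o_sel].to_numpy()
        if len(y_sel) <= 8 and len(o_sel) <= 8:  # same policy as rank_sum_test
            from .diffmeth import rank_sum_test

            pvals = np.array([rank_sum_test(A[i], B[i])[1] for i in range(A.shape[0])])
        else:
            res = stats.mannwhitneyu(
                A, B, alternative="two-sided", method="asymptotic",
                use_continuity=True, axis=1,
            )
            pvals = res.pvalue
        p_rows.append(np.clip(pvals, np.finfo(float).tiny, 1.0))
    out = pd.DataFrame(
        np.vstack(p_rows), columns=genes, index=pd.RangeIndex(k, name="permutation")
    )
    out.attrs["balanced_subtypes"] = sorted(draws_young)
    out.attrs["draws"] = all_draws  # per permutation: subtype -> (young ids, old ids)
    return out


def combine_p(p_vec, method: str = "fisher") -> float:
    """Combine k p-values into one.

    Fisher: X = −2 Σ ln pᵢ referred to χ² with 2k degrees of freedom.
    Stouffer: mean of the normal quantiles, referred to N(0, 1).  Zero
    p-values are clamped to the smallest positive float (logged).
    """
    p = np.asarray(p_vec, dtype=float)
    if p.size == 0:
        raise ValidationError("cannot combine an empty p-value vector")
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in (0, 1]")
    if np.any(p == 0):
        logger.warning("combine_p: clamping %d zero p-values", int((p == 0).sum()))
        p = np.clip(p, np.finfo(float).tiny, 1.0)
    if method == "fisher":
        x = -2.0 * np.sum(np.log(p))
        return float(stats.chi2.sf(x, df=2 * p.size))
    if method == "stouffer":
        z = np.sum(stats.norm.isf(p)) / np.sqrt(p.size)
        return float(stats.norm.sf(z))
    raise ValidationError(f"unknown combination method {method!r}")


def integrate(
    meth_results: pd.DataFrame,
    em: ExpressionMatrix,
    sheet: SampleSheet,
    gene_probe_map: pd.DataFrame,
    q_max: float = 0.01,
    expr_delta_min: float = 0.1,
    permutations: int = 50,
    seed: int = 0,
    combine: str = "fisher",
    group_young: str = "BCVY",
    group_old: str = "BCO",
) -> pd.DataFrame:
    """Per-gene methylation–expression integration.

    ``meth_results`` is a contrast table (young vs old) indexed by
    probe_id; ``gene_probe_map`` links each gene to its regulatory
    probe(s).  A gene's methylation direction is the sign of the mean Δβ
    over its linked probes.  Expression differences are group means over
    the full cohort; q-values are BH over the tested genes.  The retained
    set satisfies ``q < q_max``, ``|Δexpr| ≥ expr_delta_min`` and
    direction consistency.
    """
    gmap = gene_probe_map.groupby("gene_id")["probe_id"].apply(list)
    genes = [g for g in gmap.index if g in set(em.gene_ids)]
    skipped = set(gmap.index) - set(genes)
    if skipped:
        logger.warning("integrate: %d mapped genes absent from expression", len(skipped))
    if not genes:
        raise ValidationError("no mapped genes present in the expression matrix")

    p_matrix = balanced_permutation_test(
        em, sheet, genes, k=permutations, seed=seed,
        group_young=group_young, group_old=group_old,
    )
    info = sheet.data.set_index("sample_id")
    info = info[info.index.isin(em.sample_ids)]
    young_ids = info.index[info["group"] == group_young]
    old_ids = info.index[info["group"] == group_old]

    rows = []
    for gene in genes:
        probes = [p for p in gmap[gene] if p in meth_results.index]
        if not probes:
            logger.warning("integrate: gene %s has no probes in the contrast, skipped", gene)
            continue
        mean_delta = float(meth_results.loc[probes, "delta_beta"].mean())
        meth_direction = "hypo" if mean_delta < 0 else "hyper"
        expr = em.data.loc[gene]
        expr_delta = float(expr[young_ids].mean() - expr[old_ids].mean())
        consistent = (meth_direction == "hypo" and expr_delta > 0) or (
            meth_direction == "hyper" and expr_delta < 0
        )
        rows.append(
            {
                "gene_id": gene,
                "probe_ids": ";".join(probes),
                "combined_p": combine_p(p_matrix[gene].to_numpy(), method=combine),
                "expr_delta": expr_delta,
                "meth_direction": meth_direction,
                "consistent": consistent,
            }
        )
    out = pd.DataFrame(rows).set_index("gene_id")
    out["q_value"] = bh_fdr(out["combined_p"].to_numpy())
    out["retained"] = (
        (out["q_value"] < q_max)
        & (out["expr_delta"].abs() >= expr_delta_min)
        & out["consistent"]
    )
    out.attrs.update({"q_max": q_max, "expr_delta_min": expr_delta_min,
                      "permutations": permutations, "combine": combine, "seed": seed})
    return out


def ddct_fold_change(
    ct: pd.DataFrame, calibrator_group: str = "old"
) -> tuple[pd.DataFrame, dict]:
    """Comparative-Ct (ΔΔCt) relative expression with rank-sum group comparison.

    ``ct`` needs columns sample_id, group ({young, old}), target_ct and
    reference_ct (housekeeping gene, e.g. GAPDH).  Per sample,
    ΔCt = target − reference; ΔΔCt = ΔCt − mean ΔCt of the calibrator
    group; fold change = 2^(−ΔΔCt).  Samples missing the reference Ct are
    dropped (logged).
    """
    from .diffmeth import rank_sum_test

    df = ct.copy()
    required = {"sample_id", "group", "target_ct", "reference_ct"}
    if not required <= set(df.columns):
        raise ValidationError(f"Ct table requires columns {sorted(required)}")
    missing_ref = df["reference_ct"].isna()
    if missing_ref.any():
        logger.warning("ddct_fold_change: dropping %d samples without reference Ct",
                       int(missing_ref.sum()))
        df = df[~missing_ref]
    if (df[["target_ct", "reference_ct"]] <= 0).any().any():
        raise ValidationError("Ct values must be positive")
    if calibrator_group not in set(df["group"]):
        raise ValidationError(f"calibrator group {calibrator_group!r} absent from table")

    df["delta_ct"] = df["target_ct"] - df["reference_ct"]
    calib = df.loc[df["group"] == calibrator_group, "delta_ct"].mean()
    df["delta_delta_ct"] = df["delta_ct"] - calib
    df["fold_change"] = 2.0 ** (-df["delta_delta_ct"])

    comparison: dict = {
        "group_mean_fold_change": df.groupby("group")["fold_change"].mean().to_dict()
    }
    young = df.loc[df["group"] == "young", "fold_change"].to_numpy()
    old = df.loc[df["group"] == "old", "fold_change"].to_numpy()
    if len(young) >= 2 and len(old) >= 2:
        _, p = rank_sum_test(young, old)
        comparison["rank_sum_p"] = float(p)
    return df, comparison
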