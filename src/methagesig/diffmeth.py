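"""Per-probe differential methylation and the contrast-and-subtract
signature procedure.

The signature extraction runs in three stages on the four-group design
(BCVY / BCO tumours, NVY / NO normals):

1. each tumour group is contrasted against the pooled normals at
   q ≤ 0.05 and |Δβ| ≥ 0.1;
2. probes significant in *both* tumour contrasts (the shared
   tumour-vs-normal changes) are subtracted, leaving the BCVY-specific
   pool;
3. the young-vs-old contrast is run (a) over all probes outside the
   shared set → the *global* age signature, and (b) within the
   BCVY-specific pool at the stricter q ≤ 0.01 → the *distinctive*
   signature, which is a subset of the pool by construction.

Sign convention: Δβ = mean β(group A) − mean β(group B) with A the
younger / experimental group, so Δβ > 0 means hypermethylated in A.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_model import BetaMatrix, SampleSheet, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "SignatureSet",
    "SignaturePipelineResult",
    "rank_sum_test",
    "bh_fdr",
    "contrast",
    "subtract_common",
    "run_signature_pipeline",
    "glm_covariate_check",
    "subtype_balance_test",
]


def rank_sum_test(a, b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test.

    Missing values are dropped; each vector needs ≥ 2 non-missing values.
    The exact null distribution is enumerated when both groups have ≤ 8
    observations and the pooled data are tie-free; otherwise the normal
    approximation with tie-corrected variance and continuity correction
    is used.  Returns ``(W, p)`` with W the rank-sum statistic of ``a``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("rank_sum_test needs ≥ 2 non-missing values per group")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):  # no separation at all: ranks carry no signal
        w = len(a) * (len(pooled) + 1) / 2.0
        return w, 1.0
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(a) <= 8 and len(b) <= 8 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    w = float(res.statistic) + len(a) * (len(a) + 1) / 2.0  # U → Wilcoxon W
    return w, float(res.pvalue)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values).

    Input order is preserved; every p must lie in (0, 1].  q never falls
    below the raw p and is monotone in the order statistics.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _group_columns(bm: BetaMatrix, sheet: SampleSheet, group) -> list[str]:
    samples = sheet.samples_in_group(group)
    cols = [s for s in samples if s in bm.sample_ids]
    if not cols:
        raise ValidationError(f"no samples of group {group!r} present in the matrix")
    return cols


def contrast(
    bm: BetaMatrix,
    sheet: SampleSheet,
    group_a: str | Sequence[str],
    group_b: str | Sequence[str],
    q_max: float = 0.05,
    delta_min: float = 0.1,
) -> pd.DataFrame:
    """Per-probe rank-sum contrast of group A vs group B.

    Returns a DataFrame indexed by probe_id with columns mean_a, mean_b,
    delta_beta, p_value, q_value (BH over all probes tested in this
    contrast), direction ({hyper_in_A, hypo_in_A, none}) and the boolean
    significance call ``q ≤ q_max and |Δβ| ≥ delta_min``.  Thresholds are
    recorded in ``DataFrame.attrs``.
    """
    cols_a = _group_columns(bm, sheet, group_a)
    cols_b = _group_columns(bm, sheet, group_b)
    A = bm.data[cols_a].to_numpy()
    B = bm.data[cols_b].to_numpy()

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_a = np.nanmean(A, axis=1)
        mean_b = np.nanmean(B, axis=1)
    delta = mean_a - mean_b

    p = np.empty(bm.shape[0])
    has_nan = np.isnan(A).any(axis=1) | np.isnan(B).any(axis=1)
    small = len(cols_a) <= 8 and len(cols_b) <= 8
    clean = ~has_nan
    if clean.any() and not small:
        with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = stats.mannwhitneyu(
                A[clean], B[clean], alternative="two-sided", method="asymptotic",
                use_continuity=True, axis=1,
            )
        p[clean] = res.pvalue
    elif clean.any():
        for i in np.flatnonzero(clean):
            _, p[i] = rank_sum_test(A[i], B[i])
    for i in np.flatnonzero(has_nan):
        _, p[i] = rank_sum_test(A[i], B[i])

    # constant probes: the normal approximation degenerates (zero variance)
    p = np.where(np.isnan(p), 1.0, np.clip(p, np.finfo(float).tiny, 1.0))
    q = bh_fdr(p)
    direction = np.select([delta > 0, delta < 0], ["hyper_in_A", "hypo_in_A"], "none")
    out = pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "delta_beta": delta,
            "p_value": p,
            "q_value": q,
            "direction": direction,
            "significant": (q <= q_max) & (np.abs(delta) >= delta_min),
        },
        index=bm.probe_ids.copy(),
    )
    out.attrs.update(
        {"group_a": group_a, "group_b": group_b, "q_max": q_max, "delta_min": delta_min}
    )
    return out


def subtract_common(sig_a: Iterable[str], sig_b: Iterable[str]) -> set[str]:
    """Remove from ``sig_a`` the probes also present in ``sig_b`` (set difference)."""
    return set(sig_a) - set(sig_b)


@dataclass
class SignatureSet:
    """A named probe set with the contrasts and thresholds that produced it."""

    name: str
    probe_ids: frozenset
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.probe_ids = frozenset(self.probe_ids)

    def __len__(self) -> int:
        return len(self.probe_ids)


@dataclass
class SignaturePipelineResult:
    global_signature: SignatureSet
    specific_pool: SignatureSet
    distinctive_signature: SignatureSet
    contrasts: dict  # stage name -> contrast DataFrame
    counts: dict


def run_signature_pipeline(
    bm: BetaMatrix,
    sheet: SampleSheet,
    q_max: float = 0.05,
    delta_min: float = 0.1,
    distinct_q: float = 0.01,
    distinct_use_raw_p: bool = False,
    exclude_probes: Iterable[str] | None = None,
) -> SignaturePipelineResult:
    """Three-stage contrast-and-subtract signature extraction (see module docs).

    ``exclude_probes`` removes known age-predictive CpGs before any
    testing, so age-related methylation drift cannot confound the tumour
    signatures.  ``distinct_use_raw_p`` switches the stage-3 0.01 cut-off
    from BH-adjusted q to the raw rank-sum p.
    """
    if exclude_probes:
        from .data_model import filter_probes

        bm = filter_probes(bm, exclude_probes)
    for group in ("BCVY", "BCO", "NVY", "NO"):
        if not sheet.samples_in_group(group):
            raise ValidationError(f"group {group} is empty; all four groups required")

    normals = ("NVY", "NO")
    c_bco = contrast(bm, sheet, "BCO", normals, q_max, delta_min)
    c_bcvy = contrast(bm, sheet, "BCVY", normals, q_max, delta_min)
    sig_bco = set(c_bco.index[c_bco["significant"]])
    sig_bcvy = set(c_bcvy.index[c_bcvy["significant"]])
    common = sig_bcvy & sig_bco
    pool = subtract_common(sig_bcvy, sig_bco)

    # stage 3a: young vs old over every probe outside the shared tumour set
    bm_global = bm.subset_probes(set(bm.probe_ids) - common)
    c_global = contrast(bm_global, sheet, "BCVY", "BCO", q_max, delta_min)
    global_sig = set(c_global.index[c_global["significant"]])

    # stage 3b: young vs old within the BCVY-specific pool, stricter cut-off
    if pool:
        bm_pool = bm.subset_probes(pool)
        c_distinct = contrast(bm_pool, sheet, "BCVY", "BCO", distinct_q, delta_min)
        if distinct_use_raw_p:
            sig_mask = (c_distinct["p_value"] <= distinct_q) & (
                c_distinct["delta_beta"].abs() >= delta_min
            )
            c_distinct["significant"] = sig_mask
        distinct_sig = set(c_distinct.index[c_distinct["significant"]])
    else:
        c_distinct = c_global.iloc[0:0]
        distinct_sig = set()

    thresholds = {"q_max": q_max, "delta_min": delta_min, "distinct_q": distinct_q,
                  "distinct_use_raw_p": distinct_use_raw_p}
    counts = {
        "n_probes_tested": int(bm.shape[0]),
        "n_sig_bco_vs_normal": len(sig_bco),
        "n_sig_bcvy_vs_normal": len(sig_bcvy),
        "n_common": len(common),
        "n_specific_pool": len(pool),
        "n_global_signature": len(global_sig),
        "n_distinctive_signature": len(distinct_sig),
    }
    assert counts["n_specific_pool"] == counts["n_sig_bcvy_vs_normal"] - counts["n_common"]
    result = SignaturePipelineResult(
        global_signature=SignatureSet(
            "global_signature", global_sig,
            {"contrast": "BCVY_vs_BCO", "universe": "all_minus_common", **thresholds},
        ),
        specific_pool=SignatureSet(
            "specific_pool", pool,
            {"contrast": "BCVY_vs_normals minus common", **thresholds},
        ),
        distinctive_signature=SignatureSet(
            "distinctive_signature", distinct_sig,
            {"contrast": "BCVY_vs_BCO", "universe": "specific_pool", **thresholds},
        ),
        contrasts={
            "bco_vs_normal": c_bco,
            "bcvy_vs_normal": c_bcvy,
            "bcvy_vs_bco_global": c_global,
            "bcvy_vs_bco_distinct": c_distinct,
        },
        counts=counts,
    )
    assert result.distinctive_signature.probe_ids <= result.specific_pool.probe_ids
    return result


def glm_covariate_check(
    bm: BetaMatrix,
    sheet: SampleSheet,
    probes: Iterable[str] | None = None,
    covariates: Sequence[str] = ("subtype", "er_status"),
    use_m_values: bool = False,
) -> pd.DataFrame:
    """Per-probe linear model β ~ age_group + covariates over tumour samples.

    Fits ordinary least squares per probe and reports the age-group
    coefficient p-value plus a Wald F-test p per covariate block, to
    check that young-vs-old methylation differences are not explained by
    molecular subtype or ER status.  ``use_m_values`` fits on
    log2(β/(1−β)) instead of β.  Rank-deficient designs skip the probe
    with a warning; the summary fraction of probes with age-group
    p < 0.05 is stored in ``DataFrame.attrs['frac_age_significant']``.
    """
    import statsmodels.api as sm

    mask = sheet.data["group"].isin(["BCVY", "BCO"])
    sub = sheet.data.loc[mask].set_index("sample_id")
    cols = [s for s in sub.index if s in bm.sample_ids]
    sub = sub.loc[cols]
    X = pd.DataFrame({"age_group": (sub["group"] == "BCVY").astype(float)}, index=cols)
    blocks = {"age_group": ["age_group"]}
    for cov in covariates:
        dummies = pd.get_dummies(sub[cov].astype(str), prefix=cov, drop_first=True)
        dummies = dummies.astype(float)
        X = pd.concat([X, dummies], axis=1)
        blocks[cov] = list(dummies.columns)
    X = sm.add_constant(X)

    probe_list = list(probes) if probes is not None else list(bm.probe_ids)
    rows = []
    for probe in probe_list:
        y = bm.data.loc[probe, cols].to_numpy(dtype=float)
        if use_m_values:
            y = np.log2(np.clip(y, 1e-3, 1 - 1e-3) / (1 - np.clip(y, 1e-3, 1 - 1e-3)))
        keep = ~np.isnan(y)
        if keep.sum() < X.shape[1] + 1:
            logger.warning("glm_covariate_check: %s skipped (too few samples)", probe)
            continue
        Xk = X.loc[np.array(cols)[keep]]
        if np.ptp(y[keep]) == 0:  # constant response: nothing to model
            row = {"probe_id": probe, "p_age_group": 1.0}
            row.update({f"p_{c}": 1.0 for c in covariates})
            row["degenerate"] = True
            rows.append(row)
            continue
        model = sm.OLS(y[keep], Xk)
        fit = model.fit()
        if np.linalg.matrix_rank(Xk.to_numpy()) < Xk.shape[1]:
            logger.warning("glm_covariate_check: %s skipped (rank-deficient design)", probe)
            continue
        row = {"probe_id": probe, "p_age_group": float(fit.pvalues["age_group"]),
               "degenerate": False}
        for cov in covariates:
            names = blocks[cov]
            if not names:
                row[f"p_{cov}"] = np.nan
                continue
            contrast_mat = np.zeros((len(names), Xk.shape[1]))
            for i, name in enumerate(names):
                contrast_mat[i, list(Xk.columns).index(name)] = 1.0
            row[f"p_{cov}"] = float(fit.f_test(contrast_mat).pvalue)
        rows.append(row)
    out = pd.DataFrame(rows).set_index("probe_id") if rows else pd.DataFrame()
    if len(out):
        out.attrs["frac_age_significant"] = float((out["p_age_group"] < 0.05).mean())
    return out


def subtype_balance_test(
    sheet: SampleSheet,
    among: Sequence[str] = ("BCVY", "BCO"),
    column: str = "subtype",
) -> tuple[float, float]:
    """Pearson chi-squared homogeneity test of a categorical covariate
    across age groups (no continuity correction).

    All-zero rows/columns are dropped with a warning; fewer than two
    remaining categories raises.
    """
    df = sheet.data[sheet.data["group"].isin(among)]
    table = pd.crosstab(df["group"], df[column].astype(str))
    table = table.loc[(table.sum(axis=1) > 0), (table.sum(axis=0) > 0)]
    dropped = set(pd.crosstab(df["group"], df[column].astype(str)).columns) - set(table.columns)
    if dropped:
        logger.warning("subtype_balance_test: dropped empty categories %s", sorted(dropped))
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValidationError("need ≥ 2 groups and ≥ 2 categories with nonzero totals")
    chi2, p, _, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
    return float(chi2), float(p)
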