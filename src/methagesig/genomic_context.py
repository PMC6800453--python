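"""Genomic and functional context of significant probes.

Signature probes are partitioned by CpG context (island / shores /
shelves / open sea), UCSC gene-region feature and regulatory element,
category-wise methylation differences are tested with Welch's t-test,
probes are split into EPIC-only vs 450K-shared platform membership, and
samples are clustered on a median-centred signature.

A probe carries exactly one CpG context but may carry several gene-region
or regulatory labels; such probes count once per label (multi-counting,
stated in output metadata).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from dataclasses import dataclass
from scipy import stats
from scipy.cluster import hierarchy
from sklearn.metrics import adjusted_rand_score

from .data_model import (
    CPG_CONTEXTS,
    GENE_REGIONS,
    REGULATORY,
    BetaMatrix,
    ProbeAnnotation,
    SampleSheet,
    ValidationError,
)
from .diffmeth import SignatureSet

__all__ = [
    "categorize",
    "platform_split",
    "cluster_samples",
    "fraction_percent",
    "ClusteringResult",
]

VOCABULARIES = {
    "cpg_context": CPG_CONTEXTS,
    "gene_region": GENE_REGIONS,
    "regulatory": REGULATORY,
}


def fraction_percent(n: int, total: int, ndigits: int = 2) -> float:
    """Percentage n/total rounded to ``ndigits`` decimals (as printed in reports)."""
    if total <= 0:
        raise ValidationError("total must be positive")
    return round(100.0 * n / total, ndigits)


def _probes_in_category(ann: ProbeAnnotation, vocabulary: str, category: str) -> pd.Index:
    if vocabulary == "cpg_context":
        return ann.data.index[ann.data["cpg_context"] == category]
    return ann.data.index[ann.data[vocabulary].map(lambda s: category in s)]


def categorize(
    sig: SignatureSet,
    ann: ProbeAnnotation,
    results: pd.DataFrame,
    p_threshold: float = 0.001,
) -> pd.DataFrame:
    """Category-wise methylation summary over the signature probes.

    For each category of each vocabulary, Welch's unequal-variance
    two-sample t-test compares the per-probe group-A means against the
    per-probe group-B means (``mean_a`` / ``mean_b`` columns of a
    contrast table).  Hyper/hypo fractions are computed over directional
    probes; categories with < 2 probes are reported with the test
    skipped.  Significance is called at p ≤ ``p_threshold``.
    """
    probes = pd.Index(sorted(sig.probe_ids))
    missing = probes.difference(ann.probe_ids)
    if len(missing):
        raise ValidationError(f"signature probes missing annotation: {missing.tolist()[:5]}")
    res = results.loc[probes.intersection(results.index)]
    rows = []
    for vocabulary, categories in VOCABULARIES.items():
        for category in categories:
            members = _probes_in_category(ann, vocabulary, category).intersection(res.index)
            sub = res.loc[members]
            n = len(sub)
            directional = sub[sub["delta_beta"] != 0]
            n_dir = len(directional)
            hyper = int((directional["delta_beta"] > 0).sum())
            row = {
                "vocabulary": vocabulary,
                "category": category,
                "n_probes": n,
                "hyper_fraction": hyper / n_dir if n_dir else np.nan,
                "hypo_fraction": (n_dir - hyper) / n_dir if n_dir else np.nan,
                "mean_delta": float(sub["delta_beta"].mean()) if n else np.nan,
            }
            if n >= 2:
                t, p = stats.ttest_ind(
                    sub["mean_a"], sub["mean_b"], equal_var=False
                )
                row.update(
                    t_statistic=float(t),
                    p_value=float(p),
                    significant=bool(p <= p_threshold),
                    tested=True,
                )
            else:
                row.update(t_statistic=np.nan, p_value=np.nan, significant=False, tested=False)
            rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["multi_counting"] = "probes count once per gene_region/regulatory label"
    out.attrs["p_threshold"] = p_threshold
    return out


def platform_split(
    sig: SignatureSet, ann: ProbeAnnotation, vocabulary: str = "cpg_context"
) -> pd.DataFrame:
    """EPIC-only vs 450K-shared counts per category plus an overall row.

    Percentages sum to 100 per category; the 'total' row counts every
    signature probe exactly once.
    """
    probes = pd.Index(sorted(sig.probe_ids))
    platform = ann.data.loc[probes, "platform"]
    rows = []
    categories = list(VOCABULARIES[vocabulary]) + ["total"]
    for category in categories:
        if category == "total":
            members = probes
        else:
            members = _probes_in_category(ann, vocabulary, category).intersection(probes)
        n = len(members)
        n_epic = int((platform.loc[members] == "epic_only").sum())
        n_shared = n - n_epic
        rows.append(
            {
                "category": category,
                "n_probes": n,
                "n_epic_only": n_epic,
                "n_shared_450k": n_shared,
                "pct_epic_only": fraction_percent(n_epic, n) if n else np.nan,
                "pct_shared_450k": fraction_percent(n_shared, n) if n else np.nan,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ClusteringResult:
    linkage_matrix: np.ndarray
    labels: pd.Series  # sample_id -> flat cluster id (1..k)
    crosstab: pd.DataFrame
    agreement: float  # adjusted Rand index vs BCVY-vs-rest
    newick: str


def _to_newick(Z: np.ndarray, leaf_names) -> str:
    tree = hierarchy.to_tree(Z)

    def rec(node, parent_dist):
        length = max(parent_dist - node.dist, 0.0)
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return rec(tree, tree.dist) + ";"


def cluster_samples(
    bm: BetaMatrix,
    sheet: SampleSheet,
    n_clusters: int = 2,
    linkage: str = "average",
    metric: str = "euclidean",
) -> ClusteringResult:
    """Supervised-signature clustering of samples.

    β-values are median-centred per probe across samples, samples are
    clustered by average-linkage hierarchical clustering on Euclidean
    distance (both configurable), and the flat ``n_clusters`` cut is
    compared against the BCVY-vs-rest labels by adjusted Rand index.
    """
    if bm.shape[1] < 2:
        raise ValidationError("clustering requires at least two samples")
    if bm.shape[0] < 1:
        raise ValidationError("clustering requires at least one probe")
    centred = bm.data.sub(bm.data.median(axis=1), axis=0)
    X = centred.to_numpy().T  # samples as observations
    from scipy.spatial.distance import pdist

    Z = hierarchy.linkage(pdist(X, metric=metric), method=linkage)
    flat = hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")
    labels = pd.Series(flat, index=bm.sample_ids, name="cluster")

    groups = sheet.data.set_index("sample_id").loc[bm.sample_ids, "group"]
    is_bcvy = (groups == "BCVY").astype(int)
    agreement = float(adjusted_rand_score(is_bcvy, flat))
    crosstab = pd.crosstab(groups, labels)
    return ClusteringResult(
        linkage_matrix=Z,
        labels=labels,
        crosstab=crosstab,
        agreement=agreement,
        newick=_to_newick(Z, list(bm.sample_ids)),
    )
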