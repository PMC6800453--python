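"""Core containers and delimited-text I/O for methylation analysis.

The universal input is a β-value matrix (probes × samples, methylation
fractions in [0, 1]), accompanied by a sample sheet carrying age, tissue
and clinical covariates, a probe annotation manifest (CpG context, gene
region, regulatory flags, array-platform membership) and, optionally, a
log-scale gene-expression matrix.  All containers are thin validated
wrappers around :class:`pandas.DataFrame` so downstream statistics can
work on plain arrays.

Missing β-values are represented as NaN; per-probe tests drop missing
samples pairwise rather than imputing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ValidationError",
    "BetaMatrix",
    "SampleSheet",
    "ProbeAnnotation",
    "ExpressionMatrix",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_probe_annotation",
    "write_probe_annotation",
    "read_blacklist",
    "read_gene_probe_map",
    "filter_probes",
    "assign_groups",
]

#: tumour groups are BCVY (breast cancer, very young) and BCO (older);
#: NVY / NO are the matched normal-tissue groups.
GROUPS = ("BCVY", "BCO", "NVY", "NO")

CPG_CONTEXTS = ("island", "n_shore", "s_shore", "n_shelf", "s_shelf", "open_sea")
GENE_REGIONS = ("TSS200", "TSS1500", "UTR5", "first_exon", "body", "UTR3")
REGULATORY = ("enhancer", "TFBS", "open_chromatin", "DNase")
PLATFORMS = ("epic_only", "shared_450k")

SAMPLE_SHEET_COLUMNS = ("sample_id", "age", "tissue", "subtype", "er_status", "relapse")


class ValidationError(ValueError):
    """Raised when an input container violates its invariants."""


def _delimiter(path: Path, dialect: str | None) -> str:
    if dialect is not None:
        if dialect not in ("tsv", "csv"):
            raise ValidationError(f"unknown dialect {dialect!r}; use 'tsv' or 'csv'")
        return "\t" if dialect == "tsv" else ","
    return "\t" if Path(path).suffix.lower() in (".tsv", ".txt") else ","


def _check_unique(ids: pd.Index, what: str) -> None:
    if ids.has_duplicates:
        dups = ids[ids.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}: {dups[:5]}")


@dataclass
class BetaMatrix:
    """Probes × samples matrix of methylation fractions.

    ``data`` is indexed by probe_id (rows) and sample_id (columns); every
    finite value must lie in [0, 1], NaN marks missing.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = self.data.astype(float)
        _check_unique(self.data.index, "probe_ids")
        _check_unique(self.data.columns, "sample_ids")
        vals = self.data.to_numpy()
        bad = (vals < 0) | (vals > 1)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"β-value {vals[i, j]:g} out of [0,1] at probe "
                f"{self.data.index[i]!r}, sample {self.data.columns[j]!r}"
            )

    @property
    def probe_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_probes(self, probes: Iterable[str]) -> "BetaMatrix":
        """Restrict to the given probes, keeping current row order."""
        keep = self.data.index.isin(set(probes))
        return BetaMatrix(self.data.loc[keep])

    def subset_samples(self, samples: Sequence[str]) -> "BetaMatrix":
        return BetaMatrix(self.data.loc[:, list(samples)])


@dataclass
class ExpressionMatrix:
    """Genes × samples matrix of log-scale expression values."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = self.data.astype(float)
        _check_unique(self.data.index, "gene_ids")
        _check_unique(self.data.columns, "sample_ids")

    @property
    def gene_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()


@dataclass
class SampleSheet:
    """Per-sample phenotype table.

    Required columns: sample_id, age (years), tissue ({tumour, normal}),
    subtype, er_status, relapse.  ``assign_groups`` derives the ``group``
    column ({BCVY, BCO, NVY, NO}) and an ``excluded`` flag for samples
    falling in the age gap between the two cut-offs.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValidationError(f"sample sheet missing columns {missing}")
        _check_unique(pd.Index(self.data["sample_id"]), "sample_ids")
        bad_tissue = set(self.data["tissue"]) - {"tumour", "normal"}
        if bad_tissue:
            raise ValidationError(f"unknown tissue values {sorted(bad_tissue)}")
        self.data = self.data.reset_index(drop=True)

    @property
    def sample_ids(self) -> pd.Index:
        return pd.Index(self.data["sample_id"])

    def samples_in_group(self, group: str | Sequence[str]) -> list[str]:
        if "group" not in self.data.columns:
            raise ValidationError("groups not assigned; call assign_groups first")
        groups = {group} if isinstance(group, str) else set(group)
        unknown = groups - set(GROUPS)
        if unknown:
            raise ValidationError(f"unknown group label(s) {sorted(unknown)}")
        mask = self.data["group"].isin(groups)
        if "excluded" in self.data.columns:
            mask &= ~self.data["excluded"].astype(bool)
        return self.data.loc[mask, "sample_id"].tolist()


@dataclass
class ProbeAnnotation:
    """Flat per-probe annotation manifest keyed by probe_id.

    ``cpg_context`` and ``platform`` are single-valued per probe;
    ``gene_region``, ``regulatory`` and ``gene_symbols`` hold frozensets /
    tuples (semicolon-delimited on disk, possibly empty).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.name != "probe_id":
            if "probe_id" not in self.data.columns:
                raise ValidationError("annotation requires a probe_id column")
            self.data = self.data.set_index("probe_id")
        _check_unique(self.data.index, "probe_ids")
        for col, vocab in (("cpg_context", CPG_CONTEXTS), ("platform", PLATFORMS)):
            if col not in self.data.columns:
                raise ValidationError(f"annotation missing column {col!r}")
            bad = set(self.data[col]) - set(vocab)
            if bad:
                raise ValidationError(f"unknown {col} values {sorted(bad)}")
        for col in ("gene_region", "regulatory", "gene_symbols"):
            if col not in self.data.columns:
                self.data[col] = [frozenset()] * len(self.data)
            elif self.data[col].map(lambda v: isinstance(v, str)).any():
                self.data[col] = self.data[col].map(_split_multi)

    @property
    def probe_ids(self) -> pd.Index:
        return self.data.index


def _split_multi(value) -> frozenset:
    if isinstance(value, frozenset):
        return value
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return frozenset()
    parts = [p for p in str(value).split(";") if p]
    return frozenset(parts)


# ---------------------------------------------------------------------------
# readers / writers


def read_beta_matrix(path: str | Path, dialect: str | None = None) -> BetaMatrix:
    """Read a probes × samples β matrix from delimited text.

    First column holds probe IDs, header row holds sample IDs; the
    delimiter is inferred from the extension (.tsv/.txt → tab) unless
    ``dialect`` forces it.  Out-of-range values raise
    :class:`ValidationError` naming the offending probe and sample.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_delimiter(path, dialect), index_col=0, comment="#")
    if df.shape[1] == 0:
        raise ValidationError(f"{path}: no sample columns found (malformed header?)")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return BetaMatrix(df)


def write_beta_matrix(bm: BetaMatrix, path: str | Path, dialect: str | None = None) -> None:
    bm.data.to_csv(path, sep=_delimiter(Path(path), dialect), index_label="probe_id")


def read_expression_matrix(path: str | Path, dialect: str | None = None) -> ExpressionMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep=_delimiter(path, dialect), index_col=0, comment="#")
    df.index = df.index.astype(str)
    return ExpressionMatrix(df)


def write_expression_matrix(em: ExpressionMatrix, path: str | Path, dialect: str | None = None) -> None:
    em.data.to_csv(path, sep=_delimiter(Path(path), dialect), index_label="gene_id")


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(path, comment="#")
    df["sample_id"] = df["sample_id"].astype(str)
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.data.to_csv(path, index=False)


def read_probe_annotation(path: str | Path) -> ProbeAnnotation:
    df = pd.read_csv(path, comment="#", keep_default_na=False)
    df["probe_id"] = df["probe_id"].astype(str)
    return ProbeAnnotation(df)


def write_probe_annotation(ann: ProbeAnnotation, path: str | Path) -> None:
    out = ann.data.copy()
    for col in ("gene_region", "regulatory", "gene_symbols"):
        out[col] = out[col].map(lambda s: ";".join(sorted(s)))
    out.to_csv(path, index_label="probe_id")


def read_blacklist(path: str | Path) -> set[str]:
    """One probe ID per line; blank lines and '#' comments ignored."""
    out = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line)
    return out


def read_gene_probe_map(path: str | Path) -> pd.DataFrame:
    """Two-column CSV (gene_id, probe_id) linking genes to regulatory probes."""
    df = pd.read_csv(path, comment="#", dtype=str)
    if not {"gene_id", "probe_id"} <= set(df.columns):
        raise ValidationError("gene-probe map requires gene_id and probe_id columns")
    return df[["gene_id", "probe_id"]]


# ---------------------------------------------------------------------------
# probe filtering and group assignment


def filter_probes(bm: BetaMatrix, blacklist: Iterable[str]) -> BetaMatrix:
    """Drop blacklisted probes (SNP-overlapping / cross-reactive), keeping order.

    Blacklisted IDs absent from the matrix are ignored (logged); an empty
    blacklist returns an equal matrix.  Idempotent.
    """
    blacklist = set(blacklist)
    absent = blacklist - set(bm.probe_ids)
    if absent:
        logger.info("filter_probes: %d blacklisted probes not in matrix", len(absent))
    keep = ~bm.probe_ids.isin(blacklist)
    return BetaMatrix(bm.data.loc[keep])


def assign_groups(
    sheet: SampleSheet, young_cut: float = 35.0, old_cut: float = 45.0
) -> SampleSheet:
    """Derive the four age/tissue groups from the sample sheet.

    Tumour samples aged ≤ ``young_cut`` become BCVY, aged ≥ ``old_cut``
    BCO; normal tissue likewise NVY / NO.  Samples in the open age gap
    between the cut-offs are flagged ``excluded`` (the study design uses
    no samples there).
    """
    df = sheet.data.copy()
    ages = pd.to_numeric(df["age"], errors="coerce")
    if ages.isna().any():
        bad = df.loc[ages.isna(), "sample_id"].tolist()
        raise ValidationError(f"missing or non-numeric age for samples {bad[:5]}")
    if (ages <= 0).any():
        bad = df.loc[ages <= 0, "sample_id"].tolist()
        raise ValidationError(f"non-positive age for samples {bad[:5]}")
    young = ages <= young_cut
    old = ages >= old_cut
    tumour = df["tissue"] == "tumour"
    group = np.select(
        [tumour & young, tumour & old, ~tumour & young, ~tumour & old],
        ["BCVY", "BCO", "NVY", "NO"],
        default="",
    )
    df["group"] = group
    df["excluded"] = group == ""
    return SampleSheet(df)
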