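"""Synthetic cohort generator with planted, recoverable structure.

Emulates an age-stratified breast-tumour methylation study: four sample
groups (BCVY = tumours from women ≤35 y, BCO = tumours ≥45 y, NVY / NO
the matched normal tissues), a bimodal β-value background, planted
differential-methylation effects, age-encoding clock CpGs with a planted
epigenetic age-acceleration in the young tumours, and methylation-coupled
gene expression.  Every probe's planted class and direction is recorded
in a truth table so downstream stages can be scored exactly.

Planted classes
---------------
``global``
    the old-tumour group is shifted by ±``effect_size`` relative to every
    other group, so the young-vs-old contrast sees the probe but the
    young-vs-normal contrast does not: these probes belong in the global
    age signature and stay out of the BCVY-specific pool.
``distinctive``
    the young-tumour group is shifted relative to tumours *and* normals —
    the profile the distinctive signature is designed to capture.  By
    default these are predominantly hypermethylated, mirroring the
    selective hypermethylation observed on top of global hypomethylation.
``clock``
    β is a deterministic linear encoding of (transformed) age plus noise;
    solving the clock model on these probes returns each sample's age,
    offset by ``age_accel_young`` years in BCVY.
``null``
    bimodal background only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .data_model import (
    CPG_CONTEXTS,
    BetaMatrix,
    ProbeAnnotation,
    SampleSheet,
    ValidationError,
    assign_groups,
)
from .epigenetic_age import ClockModel, age_transform

__all__ = [
    "SimulationConfig",
    "simulate_methylation",
    "simulate_clock",
    "simulate_expression",
    "clock_beta_matrix",
]

TRUTH_CLASSES = ("null", "global", "distinctive", "clock")

_CLOCK_TAG = 0xC10C
_METH_TAG = 0x0B07
_EXPR_TAG = 0x0E49

#: group mean ages (years) and SDs mirroring the discovery cohort
_AGE_PARAMS = {
    "BCVY": (32.5, 2.7, 25.0, 35.0),
    "BCO": (65.5, 8.5, 45.5, 85.0),
    "NVY": (32.5, 2.7, 25.0, 35.0),
    "NO": (65.5, 8.5, 45.5, 85.0),
}

_SUBTYPES = ("LuminalA", "LuminalB", "TN", "LuminalHer2", "Her2")
_SUBTYPE_PROPS = (0.12, 0.38, 0.27, 0.05, 0.18)
_ER_POSITIVE = {"LuminalA", "LuminalB", "LuminalHer2"}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults mirror the study structure: Δβ effects of magnitude 0.2
    (comfortably past the ±0.1 call threshold), 69 % of global effects
    hypomethylated in the young tumours, 16 % of distinctive effects
    hypomethylated (84 % hyper), β-scale noise SD 0.05, and a planted
    +15-year epigenetic age acceleration in BCVY.
    """

    n_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"BCVY": 20, "BCO": 20, "NVY": 5, "NO": 5}
    )
    n_probes: int = 20_000
    n_planted_global: int = 200
    n_planted_distinct: int = 50
    effect_size: float = 0.2
    hypo_fraction: float = 0.69
    hypo_fraction_distinct: float = 0.16
    noise_sd: float = 0.05
    n_clock_cpgs: int = 100
    age_accel_young: float = 15.0
    adult_age: float = 20.0
    seed: int = 0

    def validate(self) -> None:
        unknown = set(self.n_per_group) - set(_AGE_PARAMS)
        if unknown:
            raise ValidationError(f"unknown groups in n_per_group: {sorted(unknown)}")
        counts = (
            self.n_probes,
            self.n_planted_global,
            self.n_planted_distinct,
            self.n_clock_cpgs,
            *self.n_per_group.values(),
        )
        if any(c < 0 for c in counts):
            raise ValidationError("all counts must be non-negative")
        planted = self.n_planted_global + self.n_planted_distinct + self.n_clock_cpgs
        if planted > self.n_probes:
            raise ValidationError(
                f"planted probes ({planted}) exceed n_probes ({self.n_probes})"
            )
        if not 0.0 <= self.hypo_fraction <= 1.0:
            raise ValidationError("hypo_fraction must lie in [0,1]")
        if not 0.0 <= self.hypo_fraction_distinct <= 1.0:
            raise ValidationError("hypo_fraction_distinct must lie in [0,1]")
        if self.noise_sd < 0 or self.effect_size < 0:
            raise ValidationError("noise_sd and effect_size must be non-negative")


def _rng(cfg_seed: int, tag: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=[int(cfg_seed), tag]))


# ---------------------------------------------------------------------------
# clock construction


def _clock_parts(cfg: SimulationConfig):
    """Deterministic clock construction shared by the β and clock generators.

    Weights are drawn first; per-probe slopes/offsets are then solved so
    that the linear predictor ``intercept + Σ w_j β_j(t)`` equals the
    transformed age t exactly: slopes ``d = w / Σw²`` (least-norm solution
    of ``w·d = 1``) and offsets ``c = 0.5 − d·t_mid`` keep β centred near
    0.5 across the adult age range.
    """
    if cfg.n_clock_cpgs < 1:
        raise ValidationError("n_clock_cpgs must be ≥ 1")
    rng = _rng(cfg.seed, _CLOCK_TAG)
    k = cfg.n_clock_cpgs
    weights = rng.normal(0.0, 2.5 / np.sqrt(k), size=k)
    if np.allclose(weights @ weights, 0.0):  # pathological draw at tiny k
        weights = np.full(k, 2.5 / np.sqrt(k))
    slopes = weights / (weights @ weights)
    t_mid = age_transform(50.0, cfg.adult_age)
    offsets = 0.5 - slopes * t_mid
    intercept = -float(weights @ offsets)
    probe_ids = [f"cg_clk{i:05d}" for i in range(k)]
    return probe_ids, weights, slopes, offsets, intercept


def clock_beta_matrix(cfg: SimulationConfig, ages, sample_ids=None, noise_sd: float | None = None) -> BetaMatrix:
    """β matrix of the clock probes for arbitrary (effective) ages.

    Useful for testing clock recovery outside the four-group cohort:
    β_j(t) = c_j + d_j·F(age), plus Gaussian noise (``noise_sd`` defaults
    to the config value), clamped to [0, 1].
    """
    probe_ids, _, slopes, offsets, _ = _clock_parts(cfg)
    ages = np.asarray(ages, dtype=float)
    if sample_ids is None:
        sample_ids = [f"S{i + 1:03d}" for i in range(len(ages))]
    sd = cfg.noise_sd if noise_sd is None else noise_sd
    t = age_transform(ages, cfg.adult_age)
    rng = _rng(cfg.seed, _METH_TAG)
    vals = offsets[:, None] + slopes[:, None] * t[None, :]
    vals = np.clip(vals + rng.normal(0.0, sd, vals.shape), 0.0, 1.0)
    return BetaMatrix(
        pd.DataFrame(vals, index=pd.Index(probe_ids, name="probe_id"), columns=sample_ids)
    )


def simulate_clock(cfg: SimulationConfig) -> ClockModel:
    """Synthetic linear epigenetic clock consistent with ``simulate_methylation``.

    Stands in for a published multi-CpG clock coefficient table; the clock
    probes are disjoint from planted signature probes by construction.
    """
    probe_ids, weights, _, _, intercept = _clock_parts(cfg)
    return ClockModel(
        intercept=intercept,
        weights=pd.Series(weights, index=pd.Index(probe_ids, name="probe_id")),
        adult_age=cfg.adult_age,
    )


# ---------------------------------------------------------------------------
# methylation cohort


def _truncnorm(rng, mean, sd, lo, hi, size):
    out = rng.normal(mean, sd, size=size)
    for _ in range(100):
        bad = (out < lo) | (out > hi)
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    return np.clip(out, lo, hi)


def _allocate(n: int, props) -> np.ndarray:
    """Largest-remainder integer allocation of n items to proportions."""
    raw = np.asarray(props, dtype=float) * n
    base = np.floor(raw).astype(int)
    rem = n - base.sum()
    order = np.argsort(-(raw - base))
    base[order[:rem]] += 1
    return base


def _make_sheet(cfg: SimulationConfig, rng) -> SampleSheet:
    rows = []
    for group in ("BCVY", "BCO", "NVY", "NO"):
        n = int(cfg.n_per_group.get(group, 0))
        if n == 0:
            continue
        mean, sd, lo, hi = _AGE_PARAMS[group]
        ages = np.round(_truncnorm(rng, mean, sd, lo, hi, n), 1)
        tumour = group in ("BCVY", "BCO")
        if tumour:
            counts = _allocate(n, _SUBTYPE_PROPS)
            subtypes = rng.permutation(np.repeat(_SUBTYPES, counts))
        else:
            subtypes = np.array(["NA"] * n)
        for i in range(n):
            subtype = subtypes[i]
            if not tumour:
                er = "NA"
            else:
                # ER tracks subtype but not perfectly (receptor calls are noisy)
                er_pos = subtype in _ER_POSITIVE
                if rng.random() < 0.1:
                    er_pos = not er_pos
                er = "positive" if er_pos else "negative"
            relapse = (
                "NA"
                if not tumour
                else ("yes" if rng.random() < (0.2 if group == "BCVY" else 0.1) else "no")
            )
            rows.append(
                {
                    "sample_id": f"{group}_{i + 1:02d}",
                    "age": float(ages[i]),
                    "tissue": "tumour" if tumour else "normal",
                    "subtype": subtype,
                    "er_status": er,
                    "relapse": relapse,
                }
            )
    return assign_groups(SampleSheet(pd.DataFrame(rows)))


def _directions(n: int, hypo_fraction: float) -> np.ndarray:
    """Deterministic hypo/hyper split: exactly round(f·n) hypo probes."""
    n_hypo = int(round(hypo_fraction * n))
    return np.array(["hypo"] * n_hypo + ["hyper"] * (n - n_hypo))


def simulate_methylation(
    cfg: SimulationConfig,
) -> tuple[BetaMatrix, SampleSheet, ProbeAnnotation, pd.DataFrame]:
    """Generate the full synthetic cohort.

    Returns ``(beta, sheet, annotation, truth)`` where ``truth`` is a
    DataFrame indexed by probe_id with columns ``truth_class`` (one of
    null/global/distinctive/clock — a partition of all probes) and
    ``direction`` ('hypo'/'hyper' in BCVY relative to BCO, 'none'
    otherwise).  Identical configs (same seed) give bit-identical output.
    """
    cfg.validate()
    rng = _rng(cfg.seed, _METH_TAG)

    sheet = _make_sheet(cfg, rng)
    sample_ids = sheet.data["sample_id"].to_numpy()
    groups = sheet.data["group"].to_numpy()
    n_samples = len(sample_ids)
    is_bcvy = groups == "BCVY"
    is_bco = groups == "BCO"

    n_clock = cfg.n_clock_cpgs
    n_plain = cfg.n_probes - n_clock
    plain_ids = [f"cg{i:08d}" for i in range(n_plain)]
    clock_ids, _, slopes, offsets, _ = _clock_parts(cfg)

    # planted classes occupy random positions among the non-clock probes
    order = rng.permutation(n_plain)
    global_idx = order[: cfg.n_planted_global]
    distinct_idx = order[cfg.n_planted_global : cfg.n_planted_global + cfg.n_planted_distinct]

    truth_class = np.array(["null"] * n_plain, dtype=object)
    direction = np.array(["none"] * n_plain, dtype=object)
    if cfg.effect_size > 0:  # a zero effect plants nothing
        truth_class[global_idx] = "global"
        truth_class[distinct_idx] = "distinctive"
        direction[global_idx] = _directions(len(global_idx), cfg.hypo_fraction)
        direction[distinct_idx] = _directions(len(distinct_idx), cfg.hypo_fraction_distinct)

    # bimodal β background; planted probes draw their baseline from the
    # mode that leaves headroom for the shift (hypomethylation strikes
    # methylated sites, hypermethylation unmethylated ones)
    low = rng.beta(3.0, 17.0, size=n_plain)
    high = rng.beta(17.0, 3.0, size=n_plain)
    baseline = np.where(rng.random(n_plain) < 0.5, low, high)
    eff = cfg.effect_size
    is_hypo = direction == "hypo"
    is_hyper = direction == "hyper"
    is_global = truth_class == "global"
    is_distinct = truth_class == "distinctive"

    # per-probe, per-sample shift: 'hypo' means β(BCVY) sits below β(BCO)
    shift = np.zeros((n_plain, n_samples))
    sign = np.where(is_hypo, -1.0, 1.0)
    for row in global_idx:  # old tumours move opposite to the BCVY direction
        shift[row, is_bco] = -sign[row] * eff
    for row in distinct_idx:  # young tumours move away from everyone
        shift[row, is_bcvy] = sign[row] * eff

    # baselines leave headroom for the shifted group so clamping cannot
    # erode the planted effect: an upward shift starts from the
    # unmethylated mode, a downward shift from the methylated one
    shifts_up = (is_distinct & is_hyper) | (is_global & is_hypo)
    shifts_down = (is_distinct & is_hypo) | (is_global & is_hyper)
    baseline[shifts_up] = np.clip(low[shifts_up], 0.05, 0.95 - eff)
    baseline[shifts_down] = np.clip(high[shifts_down], 0.05 + eff, 0.95)

    values = baseline[:, None] + shift + rng.normal(0.0, cfg.noise_sd, (n_plain, n_samples))

    # clock probes encode transformed effective age (chronological age
    # plus the planted acceleration for young tumours)
    ages = sheet.data["age"].to_numpy(dtype=float)
    eff_age = ages + np.where(is_bcvy, cfg.age_accel_young, 0.0)
    t = age_transform(eff_age, cfg.adult_age)
    clock_vals = offsets[:, None] + slopes[:, None] * t[None, :]
    clock_vals = clock_vals + rng.normal(0.0, cfg.noise_sd, clock_vals.shape)

    all_ids = plain_ids + clock_ids
    data = pd.DataFrame(
        np.clip(np.vstack([values, clock_vals]), 0.0, 1.0),
        index=pd.Index(all_ids, name="probe_id"),
        columns=sample_ids,
    )
    bm = BetaMatrix(data)

    truth = pd.DataFrame(
        {
            "truth_class": np.concatenate([truth_class, ["clock"] * n_clock]),
            "direction": np.concatenate([direction, ["none"] * n_clock]),
        },
        index=pd.Index(all_ids, name="probe_id"),
    )

    ann = _make_annotation(rng, truth)
    return bm, sheet, ann, truth


def _make_annotation(rng, truth: pd.DataFrame) -> ProbeAnnotation:
    """Random context/region/regulatory labels, distinctive probes enriched
    for open-sea and open-sea probes enriched for EPIC-only membership."""
    n = len(truth)
    distinct = (truth["truth_class"] == "distinctive").to_numpy()
    base_probs = np.array([0.30, 0.10, 0.10, 0.05, 0.05, 0.40])
    distinct_probs = np.array([0.08, 0.04, 0.04, 0.02, 0.02, 0.80])
    ctx = np.where(
        distinct,
        rng.choice(CPG_CONTEXTS, size=n, p=distinct_probs),
        rng.choice(CPG_CONTEXTS, size=n, p=base_probs),
    )
    p_epic = np.where(ctx == "open_sea", 0.50, 0.15)
    platform = np.where(rng.random(n) < p_epic, "epic_only", "shared_450k")

    region_vocab = ("TSS200", "TSS1500", "UTR5", "first_exon", "body", "UTR3")
    region_probs = (0.10, 0.15, 0.10, 0.05, 0.50, 0.10)
    primary = rng.choice(region_vocab, size=n, p=region_probs)
    secondary = rng.choice(region_vocab, size=n)
    two = rng.random(n) < 0.15
    gene_region = [
        frozenset({primary[i], secondary[i]}) if two[i] else frozenset({primary[i]})
        for i in range(n)
    ]
    reg_flags = {"enhancer": 0.20, "TFBS": 0.15, "open_chromatin": 0.10, "DNase": 0.25}
    draws = {k: rng.random(n) < p for k, p in reg_flags.items()}
    regulatory = [
        frozenset(k for k in reg_flags if draws[k][i]) for i in range(n)
    ]
    df = pd.DataFrame(
        {
            "cpg_context": ctx,
            "platform": platform,
            "gene_region": gene_region,
            "regulatory": regulatory,
            "gene_symbols": [frozenset({f"G{i:06d}"}) for i in range(n)],
        },
        index=truth.index.copy(),
    )
    return ProbeAnnotation(df)


# ---------------------------------------------------------------------------
# expression


def simulate_expression(
    bm: BetaMatrix,
    truth: pd.DataFrame,
    coupling: float = -0.8,
    noise_sd: float = 0.1,
    n_null_genes: int | None = None,
    seed: int = 0,
) -> tuple["ExpressionMatrix", pd.DataFrame]:
    """Log-scale expression with one gene per planted probe.

    Coupled genes follow ``expr = baseline + coupling · β + noise`` with
    ``coupling`` in [−1, 0], so a probe hypomethylated in BCVY drives the
    linked gene's overexpression there.  An equal number of uncoupled
    genes (mapped to null probes) is added so false-retention can be
    scored.  Returns ``(em, gene_map)`` where gene_map has columns
    gene_id, probe_id, coupled.
    """
    if not -1.0 <= coupling <= 0.0:
        raise ValidationError("coupling must lie in [-1, 0]")
    from .data_model import ExpressionMatrix  # local to avoid cycle in type hints

    rng = _rng(seed, _EXPR_TAG)
    planted = truth.index[truth["truth_class"].isin(["global", "distinctive"])]
    nulls = truth.index[truth["truth_class"] == "null"]
    if n_null_genes is None:
        n_null_genes = len(planted)
    n_null_genes = min(n_null_genes, len(nulls))
    null_pick = pd.Index(rng.choice(nulls, size=n_null_genes, replace=False))

    records = []
    rows = []
    for probe, coupled in [(p, True) for p in planted] + [(p, False) for p in null_pick]:
        base = rng.uniform(2.0, 8.0)
        beta = bm.data.loc[probe].to_numpy()
        noise = rng.normal(0.0, noise_sd, size=len(beta))
        expr = base + (coupling * beta if coupled else 0.0) + noise
        gene = f"GENE_{probe}"
        records.append({"gene_id": gene, "probe_id": probe, "coupled": coupled})
        rows.append(pd.Series(expr, index=bm.sample_ids, name=gene))

    em = ExpressionMatrix(pd.DataFrame(rows))
    em.data.index.name = "gene_id"
    return em, pd.DataFrame(records)
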