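"""Synthetic multi-cohort data with planted TMM structure.

Generates everything the pipeline consumes — expression with signature-gene
shifts per planted group, group-linked censored survival, a small driver
mutation panel with group-specific rates, copy-number segments with
group-specific altered fractions, and stage labels — so every downstream
stage can be tested against known truth without external downloads.

Randomness: a single global seed is expanded into independent per-component
substreams via ``numpy.random.SeedSequence.spawn`` (PCG64 generators), so
regenerating one component reproduces it bit-identically regardless of the
others.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classifier import TMM_LABELS
from .io_formats import (
    ClinicalTable,
    CNVSegmentTable,
    ExpressionMatrix,
    GeneSetCollection,
    MutationTable,
)

__all__ = [
    "CohortConfig",
    "SyntheticCohort",
    "generate_expression",
    "generate_survival",
    "generate_mutations",
    "generate_cnv",
    "generate_cohort",
]

#: Substream indices (order is part of the determinism contract).
_STREAMS = ("labels", "expression", "survival", "mutations", "cnv", "stage")


@dataclass
class CohortConfig:
    """Knobs for the generator.

    mixing: proportions over (TEL+ALT, ALT, TEL, NDTMM); the default mirrors
    a large pan-cancer composition (0.47, 0.27, 0.09, 0.17).
    effect: mean log2 shift added to a signature's genes in samples where
    that mechanism is active.
    hazards: per-group exponential event rates; censor_rate: independent
    exponential censoring rate (0 disables censoring).
    mutation_rates: group -> {gene: per-sample mutation probability}.
    cnv_burden_mean: group -> mean fraction of genome altered (Beta around
    the mean with concentration cnv_burden_kappa).
    stage_probs: optional group -> probabilities over stages I-IV.
    """

    n_samples: int = 400
    mixing: tuple[float, float, float, float] = (0.47, 0.27, 0.09, 0.17)
    n_genes: int = 500
    n_signature_genes: int = 30
    effect: float = 3.0
    noise_sd: float = 0.5
    baseline_mean: float = 5.0
    n_cohorts: int = 2
    hazards: dict[str, float] = field(
        default_factory=lambda: {
            "TEL+ALT": 1.0, "ALT": 3.0, "TEL": 1.0, "NDTMM": 0.5,
        }
    )
    censor_rate: float = 0.3
    mutation_rates: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "TEL+ALT": {"KRAS": 0.05, "TP53": 0.10, "PTEN": 0.10},
            "ALT": {"KRAS": 0.60, "TP53": 0.10, "PTEN": 0.10},
            "TEL": {"KRAS": 0.05, "TP53": 0.10, "PTEN": 0.10},
            "NDTMM": {"KRAS": 0.05, "TP53": 0.50, "PTEN": 0.10},
        }
    )
    cnv_burden_mean: dict[str, float] = field(
        default_factory=lambda: {
            "TEL+ALT": 0.25, "ALT": 0.40, "TEL": 0.25, "NDTMM": 0.10,
        }
    )
    cnv_burden_kappa: float = 30.0
    n_segments: int = 50
    segment_length: int = 1_000_000
    stage_probs: dict[str, tuple[float, float, float, float]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be positive")
        mix = np.asarray(self.mixing, dtype=float)
        if mix.size != 4 or (mix < 0).any():
            raise ValueError("mixing must be 4 non-negative proportions")
        if abs(mix.sum() - 1.0) > 1e-9:
            raise ValueError(f"mixing must sum to 1, got {mix.sum()!r}")
        if self.effect < 0:
            raise ValueError("effect must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.n_genes < 2 * self.n_signature_genes:
            raise ValueError(
                "n_genes must be >= 2 * n_signature_genes "
                f"({self.n_genes} < {2 * self.n_signature_genes})"
            )
        for g, h in self.hazards.items():
            if h <= 0:
                raise ValueError(f"hazard for {g!r} must be > 0")
        if self.censor_rate < 0:
            raise ValueError("censor_rate must be >= 0")
        for g, rates in self.mutation_rates.items():
            for gene, p in rates.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(
                        f"mutation rate {gene!r}/{g!r} outside [0, 1]"
                    )
        for g, m in self.cnv_burden_mean.items():
            if not 0.0 <= m <= 1.0:
                raise ValueError(f"cnv_burden_mean for {g!r} outside [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticCohort:
    expression: ExpressionMatrix
    truth_labels: pd.DataFrame  # sample_id, label, cohort
    clinical: ClinicalTable
    mutations: MutationTable
    cnv: CNVSegmentTable
    gene_sets: GeneSetCollection
    config: CohortConfig


def _substreams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {
        name: np.random.default_rng(child)
        for name, child in zip(_STREAMS, children)
    }


def _draw_labels(
    rng: np.random.Generator, n: int, mixing: Sequence[float]
) -> np.ndarray:
    return rng.choice(TMM_LABELS, size=n, p=np.asarray(mixing, dtype=float))


def generate_expression(
    config: CohortConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame, GeneSetCollection]:
    """Expression matrix with planted signature shifts.

    Baseline expression is Normal(baseline_mean, noise_sd) per gene/sample;
    the TEL signature genes gain +effect in TEL and TEL+ALT samples and the
    ALT signature genes gain +effect in ALT and TEL+ALT samples.  Returns the
    matrix, a truth-label table and the two planted signature sets.
    """
    rngs = _substreams(config.seed)
    n, g = config.n_samples, config.n_genes
    labels = _draw_labels(rngs["labels"], n, config.mixing)
    sample_ids = [f"S{i:05d}" for i in range(n)]
    gene_ids = [f"G{i:05d}" for i in range(g)]
    k = config.n_signature_genes
    tel_genes = gene_ids[:k]
    alt_genes = gene_ids[k : 2 * k]

    x = rngs["expression"].normal(config.baseline_mean, config.noise_sd, (g, n))
    tel_active = np.isin(labels, ["TEL", "TEL+ALT"])
    alt_active = np.isin(labels, ["ALT", "TEL+ALT"])
    x[:k, tel_active] += config.effect
    x[k : 2 * k, alt_active] += config.effect

    cohorts = [f"C{i % config.n_cohorts + 1}" for i in range(n)]
    cohort_of = dict(zip(sample_ids, cohorts))
    em = ExpressionMatrix(
        pd.DataFrame(x, index=gene_ids, columns=sample_ids), cohort_of
    )
    truth = pd.DataFrame(
        {"sample_id": sample_ids, "label": labels, "cohort": cohorts}
    )
    sets = GeneSetCollection(
        {"TEL": list(tel_genes), "ALT": list(alt_genes)},
        {"TEL": "planted telomerase signature",
         "ALT": "planted ALT signature"},
    )
    return em, truth, sets


def generate_survival(
    truth_labels: pd.DataFrame,
    hazards: Mapping[str, float],
    censor_rate: float,
    seed: int | np.random.Generator = 0,
) -> ClinicalTable:
    """Exponential event times per group with independent exponential
    censoring: os_time = min(event, censor), os_event = event <= censor."""
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    labels = truth_labels["label"].to_numpy()
    missing = set(labels) - set(hazards)
    if missing:
        raise ValueError(f"no hazard for groups {sorted(missing)}")
    for g, h in hazards.items():
        if h <= 0:
            raise ValueError(f"hazard for {g!r} must be > 0")
    if censor_rate < 0:
        raise ValueError("censor_rate must be >= 0")
    n = len(labels)
    rates = np.array([hazards[l] for l in labels], dtype=float)
    event_t = rng.exponential(1.0 / rates)
    if censor_rate > 0:
        censor_t = rng.exponential(1.0 / censor_rate, size=n)
    else:
        censor_t = np.full(n, np.inf)
    os_time = np.minimum(event_t, censor_t)
    os_event = (event_t <= censor_t).astype(int)
    table = pd.DataFrame(
        {
            "sample_id": truth_labels["sample_id"],
            "os_time": os_time,
            "os_event": os_event,
            "stage": pd.NA,
            "cohort": truth_labels.get("cohort", "ALL"),
        }
    )
    return ClinicalTable(table)


def generate_mutations(
    truth_labels: pd.DataFrame,
    mutation_rates: Mapping[str, Mapping[str, float]],
    rng: np.random.Generator,
) -> MutationTable:
    """Bernoulli driver-panel mutations with per-group per-gene rates.

    Every planted mutation is recorded as a missense variant; a matching
    volume of silent passenger records (rate 0.05 per gene) exercises the
    nonsynonymous filter.
    """
    genes = sorted({g for rates in mutation_rates.values() for g in rates})
    rows = []
    for sample, label in zip(
        truth_labels["sample_id"], truth_labels["label"]
    ):
        rates = mutation_rates.get(str(label), {})
        for gene in genes:
            if rng.random() < rates.get(gene, 0.0):
                rows.append(
                    {
                        "sample_id": str(sample),
                        "gene_id": gene,
                        "variant_classification": "Missense_Mutation",
                    }
                )
            if rng.random() < 0.05:
                rows.append(
                    {
                        "sample_id": str(sample),
                        "gene_id": gene,
                        "variant_classification": "Silent",
                    }
                )
    table = pd.DataFrame(
        rows, columns=["sample_id", "gene_id", "variant_classification"]
    )
    return MutationTable(table)


def generate_cnv(
    truth_labels: pd.DataFrame,
    burden_mean: Mapping[str, float],
    kappa: float,
    n_segments: int,
    segment_length: int,
    rng: np.random.Generator,
) -> CNVSegmentTable:
    """Equal-length segments on one synthetic chromosome per sample; the
    altered fraction is Beta(mean * kappa, (1 - mean) * kappa) per sample and
    altered segments get |seg_mean| = 0.8 (others 0)."""
    rows = []
    for sample, label in zip(
        truth_labels["sample_id"], truth_labels["label"]
    ):
        m = float(burden_mean.get(str(label), 0.0))
        if 0.0 < m < 1.0:
            frac = rng.beta(m * kappa, (1.0 - m) * kappa)
        else:
            frac = m
        n_alt = int(round(frac * n_segments))
        altered = rng.choice(n_segments, size=n_alt, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_alt)
        seg_means = np.zeros(n_segments)
        seg_means[altered] = 0.8 * signs
        for i in range(n_segments):
            rows.append(
                {
                    "sample_id": str(sample),
                    "chromosome": "1",
                    "start": i * segment_length + 1,
                    "end": (i + 1) * segment_length,
                    "seg_mean": seg_means[i],
                }
            )
    return CNVSegmentTable(pd.DataFrame(rows))


_STAGES = ("I", "II", "III", "IV")


def _assign_stage(
    truth_labels: pd.DataFrame,
    stage_probs: Mapping[str, Sequence[float]] | None,
    rng: np.random.Generator,
) -> pd.Series:
    probs = stage_probs or {}
    out = []
    for label in truth_labels["label"]:
        p = np.asarray(probs.get(str(label), (0.25, 0.25, 0.25, 0.25)))
        out.append(rng.choice(_STAGES, p=p / p.sum()))
    return pd.Series(out, index=truth_labels.index)


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate the full joined cohort: expression, truth labels, clinical
    (with stage), mutations and copy-number segments, all deterministic under
    ``config.seed``."""
    rngs = _substreams(config.seed)
    expression, truth, sets = generate_expression(config)
    clinical = generate_survival(
        truth, config.hazards, config.censor_rate, rngs["survival"]
    )
    stage = _assign_stage(truth, config.stage_probs, rngs["stage"])
    clin_table = clinical.table.copy()
    clin_table["stage"] = stage.to_numpy()
    clinical = ClinicalTable(clin_table)
    mutations = generate_mutations(
        truth, config.mutation_rates, rngs["mutations"]
    )
    cnv = generate_cnv(
        truth,
        config.cnv_burden_mean,
        config.cnv_burden_kappa,
        config.n_segments,
        config.segment_length,
        rngs["cnv"],
    )
    return SyntheticCohort(
        expression=expression,
        truth_labels=truth,
        clinical=clinical,
        mutations=mutations,
        cnv=cnv,
        gene_sets=sets,
        config=config,
    )
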