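"""Configuration-driven orchestration of the full analysis.

A YAML run config either points at input files or embeds a ``simulate``
block; ``run_full`` executes score -> classify -> frequencies -> survival ->
DEG -> ORA -> burden -> contingency -> correlations, writing every stage's
result as a TSV/JSON artifact plus a manifest.  Outputs are deterministic
under a fixed seed (wall-clock timings go to the run log, never into
artifacts).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classifier import ClassifierParams, classify_cohorts, tmm_frequencies
from .enrichment import EnrichmentParams, cohort_zscore, score_matrix
from .group_stats import (
    bh_adjust,
    cnv_burden,
    contingency_chisq,
    correlation_matrix,
    hypergeom_ora,
    mannwhitney,
    moderated_t_deg,
    mutation_frequency_compare,
    tmb,
)
from .io_formats import (
    NONSYNONYMOUS_CLASSES,
    read_clinical,
    read_expression,
    read_gmt,
    read_maf_lite,
    read_seg,
    write_clinical,
    write_expression,
    write_gmt,
    write_maf_lite,
    write_seg,
)
from .survival import outcome_split, stratified_survival
from .synthetic_cohort import CohortConfig, SyntheticCohort, generate_cohort

logger = logging.getLogger(__name__)

__all__ = ["ConfigError", "StageError", "RunConfig", "validate_config",
           "run_full", "write_cohort"]


class ConfigError(ValueError):
    """Invalid or unparsable run configuration."""


class StageError(RuntimeError):
    """A pipeline stage failed; earlier stages' outputs remain on disk."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


_TOP_KEYS = {
    "seed", "output_dir", "simulate", "inputs", "enrichment", "classifier",
    "outcome_split", "thresholds", "correlations",
}
_INPUT_KEYS = {
    "expression", "expression_format", "log2", "gene_sets", "clinical",
    "mutations", "cnv",
}
_ENRICH_KEYS = {"alpha", "kcdf", "tie_rule", "B", "seed"}
_CLASSIFIER_KEYS = {"tau", "tel_set", "alt_set"}
_THRESHOLD_KEYS = {"fdr", "seg_mean", "nonsyn_classes"}
_CORR_KEYS = {"genes_a", "genes_b"}
_SIMULATE_KEYS = {
    "n_samples", "mixing", "n_genes", "n_signature_genes", "effect",
    "noise_sd", "baseline_mean", "n_cohorts", "hazards", "censor_rate",
    "mutation_rates", "cnv_burden_mean", "cnv_burden_kappa", "n_segments",
    "segment_length", "stage_probs", "seed",
}


def _reject_unknown(block: dict, allowed: set[str], where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) under {where}: {sorted(unknown)}")


def _expect(value: Any, types: tuple, where: str) -> Any:
    if not isinstance(value, types):
        names = "/".join(t.__name__ for t in types)
        raise ConfigError(f"{where}: expected {names}, got {value!r}")
    return value


@dataclass
class RunConfig:
    """Fully resolved, validated run configuration."""

    seed: int = 0
    output_dir: str = "tmm_out"
    simulate: CohortConfig | None = None
    inputs: dict[str, Any] = field(default_factory=dict)
    enrichment: EnrichmentParams = field(default_factory=EnrichmentParams)
    classifier: ClassifierParams = field(default_factory=ClassifierParams)
    tel_set: str = "TEL"
    alt_set: str = "ALT"
    outcome_split_strategy: str = "median_event"
    fdr: float = 0.05
    seg_mean_threshold: float = 0.2
    nonsyn_classes: tuple[str, ...] = tuple(sorted(NONSYNONYMOUS_CLASSES))
    correlations: dict[str, list[str]] = field(default_factory=dict)
    raw: dict = field(default_factory=dict)


def _build_config(doc: dict) -> RunConfig:
    if not isinstance(doc, dict):
        raise ConfigError("config root must be a mapping")
    _reject_unknown(doc, _TOP_KEYS, "the top level")
    cfg = RunConfig(raw=doc)
    cfg.seed = int(_expect(doc.get("seed", 0), (int,), "seed"))
    cfg.output_dir = str(doc.get("output_dir", "tmm_out"))

    if "simulate" in doc and "inputs" in doc:
        raise ConfigError("config may declare 'simulate' or 'inputs', not both")
    if "simulate" in doc:
        sim = _expect(doc["simulate"], (dict,), "simulate")
        _reject_unknown(sim, _SIMULATE_KEYS, "simulate")
        sim = dict(sim)
        sim.setdefault("seed", cfg.seed)
        if "mixing" in sim:
            sim["mixing"] = tuple(float(x) for x in sim["mixing"])
        try:
            cfg.simulate = CohortConfig(**sim)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"simulate: {exc}")
    elif "inputs" in doc:
        inp = _expect(doc["inputs"], (dict,), "inputs")
        _reject_unknown(inp, _INPUT_KEYS, "inputs")
        for key in ("expression", "gene_sets", "clinical"):
            if key not in inp:
                raise ConfigError(f"inputs: missing required key {key!r}")
        for key in ("expression", "gene_sets", "clinical", "mutations", "cnv"):
            if key in inp and not Path(inp[key]).exists():
                raise ConfigError(f"inputs.{key}: file not found: {inp[key]}")
        cfg.inputs = dict(inp)
    else:
        raise ConfigError("config needs a 'simulate' or 'inputs' block")

    enr = _expect(doc.get("enrichment", {}), (dict,), "enrichment")
    _reject_unknown(enr, _ENRICH_KEYS, "enrichment")
    try:
        cfg.enrichment = EnrichmentParams(
            alpha=float(_expect(enr.get("alpha", 0.25), (int, float),
                                "enrichment.alpha")),
            kcdf=bool(_expect(enr.get("kcdf", False), (bool,),
                              "enrichment.kcdf")),
            tie_rule=str(enr.get("tie_rule", "average")),
            B=int(_expect(enr.get("B", 1000), (int,), "enrichment.B")),
            seed=enr.get("seed", cfg.seed),
        )
    except ValueError as exc:
        raise ConfigError(f"enrichment: {exc}")

    cls = _expect(doc.get("classifier", {}), (dict,), "classifier")
    _reject_unknown(cls, _CLASSIFIER_KEYS, "classifier")
    tau = cls.get("tau", 0.0)
    if not isinstance(tau, (int, float)) or isinstance(tau, bool):
        raise ConfigError(f"classifier.tau: expected a number, got {tau!r}")
    try:
        cfg.classifier = ClassifierParams(tau=float(tau))
    except ValueError as exc:
        raise ConfigError(f"classifier: {exc}")
    cfg.tel_set = str(cls.get("tel_set", "TEL"))
    cfg.alt_set = str(cls.get("alt_set", "ALT"))

    strategy = str(doc.get("outcome_split", "median_event"))
    if strategy not in ("median_event", "event_status"):
        raise ConfigError(f"outcome_split: unknown strategy {strategy!r}")
    cfg.outcome_split_strategy = strategy

    thr = _expect(doc.get("thresholds", {}), (dict,), "thresholds")
    _reject_unknown(thr, _THRESHOLD_KEYS, "thresholds")
    cfg.fdr = float(_expect(thr.get("fdr", 0.05), (int, float),
                            "thresholds.fdr"))
    if not 0.0 < cfg.fdr <= 1.0:
        raise ConfigError(f"thresholds.fdr: outside (0, 1]: {cfg.fdr}")
    cfg.seg_mean_threshold = float(
        _expect(thr.get("seg_mean", 0.2), (int, float), "thresholds.seg_mean")
    )
    if cfg.seg_mean_threshold < 0:
        raise ConfigError("thresholds.seg_mean: must be >= 0")
    if "nonsyn_classes" in thr:
        cfg.nonsyn_classes = tuple(str(c) for c in thr["nonsyn_classes"])

    corr = _expect(doc.get("correlations", {}), (dict,), "correlations")
    _reject_unknown(corr, _CORR_KEYS, "correlations")
    cfg.correlations = {k: [str(g) for g in v] for k, v in corr.items()}
    return cfg


def validate_config(path: str | Path) -> RunConfig:
    """Load, default and validate a YAML run config; unknown keys rejected."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        doc = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}")
    return _build_config(doc if doc is not None else {})


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> dict[str, str]:
    """Write a synthetic cohort in the pipeline's on-disk dialects."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "gene_sets": outdir / "gene_sets.gmt",
        "clinical": outdir / "clinical.tsv",
        "mutations": outdir / "mutations.maf.tsv",
        "cnv": outdir / "cnv.seg.tsv",
        "truth_labels": outdir / "truth_labels.tsv",
    }
    write_expression(cohort.expression, paths["expression"])
    write_gmt(cohort.gene_sets, paths["gene_sets"])
    write_clinical(cohort.clinical, paths["clinical"])
    write_maf_lite(cohort.mutations, paths["mutations"])
    write_seg(cohort.cnv, paths["cnv"])
    cohort.truth_labels.to_csv(paths["truth_labels"], sep="\t", index=False)
    manifest = {
        "kind": "synthetic_cohort",
        "version": __version__,
        "config": cohort.config.to_dict(),
        "files": {k: p.name for k, p in paths.items()},
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return {k: str(p) for k, p in paths.items()}


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def run_full(config: RunConfig, force: bool = False) -> Path:
    """Execute every stage and write its artifact under config.output_dir.

    Stages communicate only via the returned in-memory tables and the on-disk
    artifacts; a stage failure raises :class:`StageError` and leaves earlier
    outputs intact.  Re-running with the same seed reproduces every artifact
    byte for byte.
    """
    outdir = Path(config.output_dir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise ConfigError(
            f"output directory {outdir} is not empty (use force to overwrite)"
        )
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("tmmkit")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "config": config.raw,
        "stages": {},
    }

    def stage(name: str):
        class _Stage:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                logger.info("stage %s: start", name)
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                dt = time.perf_counter() - self_inner.t0
                if exc is not None:
                    logger.error("stage %s: failed after %.2fs: %s",
                                 name, dt, exc)
                    root.removeHandler(handler)
                    raise StageError(name, exc) from exc
                logger.info("stage %s: done in %.2fs", name, dt)
                return False

        return _Stage()

    try:
        # ---- load or simulate inputs
        with stage("inputs"):
            if config.simulate is not None:
                cohort = generate_cohort(config.simulate)
                write_cohort(cohort, outdir / "inputs")
                expr = cohort.expression
                sets = cohort.gene_sets
                clinical = cohort.clinical
                mutations = cohort.mutations
                cnv = cohort.cnv
            else:
                inp = config.inputs
                expr = read_expression(
                    inp["expression"],
                    format=inp.get("expression_format", "tsv"),
                    log2=bool(inp.get("log2", False)),
                )
                sets = read_gmt(inp["gene_sets"])
                clinical = read_clinical(inp["clinical"])
                cohort_of = dict(
                    zip(
                        clinical.table["sample_id"].astype(str),
                        clinical.table["cohort"].astype(str),
                    )
                )
                expr = expr.with_cohorts(cohort_of)
                mutations = (
                    read_maf_lite(inp["mutations"])
                    if "mutations" in inp else None
                )
                cnv = read_seg(inp["cnv"]) if "cnv" in inp else None
            manifest["stages"]["inputs"] = {
                "n_genes": expr.shape[0],
                "n_samples": expr.shape[1],
                "n_sets": len(sets.names()),
            }

        # ---- enrichment scores
        with stage("score"):
            em_raw = score_matrix(expr, sets, config.enrichment)
            scores_out = em_raw.scores.copy()
            scores_out.insert(0, "set_name", scores_out.index)
            _write_tsv(scores_out, outdir / "scores.tsv")
            em = cohort_zscore(em_raw)
            manifest["stages"]["score"] = {
                "sets": em.set_names, "scale": em.scale,
            }

        # ---- classification + frequencies
        with stage("classify"):
            labels = classify_cohorts(
                em, config.tel_set, config.alt_set, config.classifier
            )
            _write_tsv(labels, outdir / "labels.tsv")
            freq = pd.concat(
                [tmm_frequencies(labels, "overall"),
                 tmm_frequencies(labels, "cohort")],
                ignore_index=True,
            )
            _write_tsv(freq, outdir / "frequencies.tsv")
            manifest["stages"]["classify"] = {
                "n_labeled": int(len(labels)),
                "counts": labels["label"].value_counts().to_dict(),
            }

        # ---- survival
        with stage("survival"):
            strata = stratified_survival(clinical, labels, by_cohort=False)
            km_rows = []
            logrank_json: dict[str, Any] = {}
            for stratum, res in strata.items():
                for label, curve in res["curves"].items():
                    df = curve.to_frame()
                    df.insert(0, "stratum", stratum)
                    df.insert(1, "label", label)
                    km_rows.append(df)
                lr = res["logrank"]
                logrank_json[stratum] = {
                    "statistic": lr.statistic,
                    "df": lr.df,
                    "p_value": lr.p_value,
                    "observed": lr.observed,
                    "expected": lr.expected,
                }
            _write_tsv(pd.concat(km_rows, ignore_index=True),
                       outdir / "km.tsv")
            (outdir / "logrank.json").write_text(
                json.dumps(logrank_json, indent=2, sort_keys=True) + "\n"
            )
            manifest["stages"]["survival"] = {
                "p_values": {k: v["p_value"] for k, v in logrank_json.items()}
            }

        # ---- differential expression
        with stage("deg"):
            deg_frames = []
            good, poor = outcome_split(clinical,
                                       config.outcome_split_strategy)
            good = [s for s in good if s in expr.sample_ids]
            poor = [s for s in poor if s in expr.sample_ids]
            if len(good) >= 2 and len(poor) >= 2:
                d = moderated_t_deg(expr, good, poor)
                d.insert(0, "comparison", "good_vs_poor")
                deg_frames.append(d)
            else:
                logger.warning("deg: outcome split too small, skipped")
            by_label = labels.groupby("label")["sample_id"].apply(list)
            ndtmm = by_label.get("NDTMM", [])
            alt = by_label.get("ALT", [])
            if len(ndtmm) >= 2 and len(alt) >= 2:
                d = moderated_t_deg(expr, ndtmm, alt)
                d.insert(0, "comparison", "NDTMM_vs_ALT")
                deg_frames.append(d)
            else:
                logger.warning("deg: NDTMM/ALT groups too small, skipped")
            if not deg_frames:
                raise ValueError("no DEG comparison had >= 2 samples per arm")
            deg = pd.concat(deg_frames, ignore_index=True)
            _write_tsv(deg, outdir / "deg.tsv")
            manifest["stages"]["deg"] = {
                "comparisons": sorted(set(deg["comparison"])),
                "n_significant": int((deg["q_value"] < config.fdr).sum()),
            }

        # ---- over-representation
        with stage("ora"):
            ora_frames = []
            for comparison, sub in deg.groupby("comparison"):
                hits = list(sub.loc[sub["q_value"] < config.fdr, "gene_id"])
                if not hits:
                    logger.info("ora: no hits for %s", comparison)
                    continue
                o = hypergeom_ora(hits, expr.gene_ids, sets)
                o.insert(0, "comparison", comparison)
                ora_frames.append(o)
            ora = (
                pd.concat(ora_frames, ignore_index=True)
                if ora_frames
                else pd.DataFrame(
                    columns=["comparison", "set_name", "overlap",
                             "set_size_in_universe", "query_size",
                             "universe_size", "p_value", "q_value"]
                )
            )
            _write_tsv(ora, outdir / "ora.tsv")
            manifest["stages"]["ora"] = {"n_rows": int(len(ora))}

        # ---- molecular burden
        with stage("burden"):
            if mutations is None and cnv is None:
                logger.info("burden: no mutation/CNV inputs, stage skipped")
                manifest["stages"]["burden"] = {"skipped": True}
            else:
                burden = labels[["sample_id", "label"]].copy()
                tests: dict[str, Any] = {}
                if mutations is not None:
                    counts = tmb(mutations, burden["sample_id"],
                                 config.nonsyn_classes)
                    burden["tmb"] = counts.to_numpy()
                    mf = mutation_frequency_compare(
                        mutations, labels, "ALT", "NDTMM"
                    )
                    _write_tsv(mf, outdir / "mutfreq.tsv")
                if cnv is not None:
                    fga = cnv_burden(cnv, config.seg_mean_threshold)
                    burden["fga"] = (
                        fga.reindex(burden["sample_id"]).fillna(0.0).to_numpy()
                    )
                for metric in ("tmb", "fga"):
                    if metric not in burden.columns:
                        continue
                    va = burden.loc[burden["label"] == "ALT", metric]
                    vb = burden.loc[burden["label"] == "NDTMM", metric]
                    if len(va) and len(vb):
                        u, p = mannwhitney(va, vb)
                        tests[metric] = {
                            "groups": ["ALT", "NDTMM"], "U": u, "p_value": p,
                        }
                _write_tsv(burden, outdir / "burden.tsv")
                (outdir / "burden_tests.json").write_text(
                    json.dumps(tests, indent=2, sort_keys=True) + "\n"
                )
                manifest["stages"]["burden"] = {
                    "n_samples": int(len(burden)),
                    "tests": {k: v["p_value"] for k, v in tests.items()},
                }

        # ---- stage/grade contingency
        with stage("contingency"):
            stage_col = clinical.table.set_index(
                clinical.table["sample_id"].astype(str)
            )["stage"]
            if stage_col.dropna().nunique() < 2:
                logger.info("contingency: <2 stage levels, stage skipped")
                manifest["stages"]["contingency"] = {"skipped": True}
            else:
                counts, props, chi2_stat, df_c, p, low = contingency_chisq(
                    labels, stage_col
                )
                tidy = (
                    counts.stack()
                    .rename("count")
                    .reset_index()
                    .rename(columns={"cat": "category"})
                )
                tidy["proportion"] = props.stack().to_numpy()
                tidy["chi2"] = chi2_stat
                tidy["df"] = df_c
                tidy["p_value"] = p
                tidy["low_expected_counts"] = low
                _write_tsv(tidy, outdir / "contingency.tsv")
                manifest["stages"]["contingency"] = {
                    "chi2": chi2_stat, "df": df_c, "p_value": p,
                }

        # ---- correlation matrices
        with stage("correlations"):
            genes_a = config.correlations.get("genes_a")
            genes_b = config.correlations.get("genes_b")
            if not genes_a:
                genes_a = [g for g in sets[config.tel_set]
                           if g in expr.values.index]
            if not genes_b:
                genes_b = [g for g in sets[config.alt_set]
                           if g in expr.values.index]
            res = correlation_matrix(expr, genes_a, genes_b)
            tidy = (
                res.r.stack(future_stack=True)
                .rename("pearson_r")
                .reset_index()
                .rename(columns={"level_0": "gene_a", "level_1": "gene_b"})
            )
            tidy["defined"] = res.defined.stack(future_stack=True).to_numpy()
            _write_tsv(tidy, outdir / "correlations.tsv")
            manifest["stages"]["correlations"] = {
                "shape": list(res.r.shape),
            }

        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n"
        )
    finally:
        root.removeHandler(handler)
        handler.close()
    return outdir
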