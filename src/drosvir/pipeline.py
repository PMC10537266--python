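"""End-to-end orchestration: simulate -> call -> epidemiology -> DE -> correlation.

A single :class:`PipelineConfig` drives every stage; each run writes its
tabular outputs plus a JSON manifest recording the parameters, thresholds,
seeds, stage timings, warnings and the SHA-256 of every file produced, so
a rerun with the same configuration and seed is fully reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import calling, correlate, de, epidemiology, io
from .simulate import (
    SimConfig,
    SyntheticTruth,
    simulate_experiment,
    config_from_dict,
    config_to_dict,
    virus_coef,
)

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("drosvir")


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run.

    Exactly one of ``sim`` (synthetic mode) or the three real-input paths
    (``meta_path``, ``virus_counts_path``, ``gene_counts_path``) must be
    provided.
    """

    outdir: str = "drosvir_run"
    sim: SimConfig | None = None
    meta_path: str | None = None
    virus_counts_path: str | None = None
    gene_counts_path: str | None = None
    rel_threshold: float = 0.01
    abs_threshold: float = 150.0
    tune_abs_threshold: bool = False
    coinfection_alpha: float = 0.01
    lfc_cut: float = 0.5
    de_alpha: float = 0.001
    correlation_alpha: float = 0.001
    correlation_method: str = "pearson"
    moderate: bool = True
    min_calls_for_de: int = 5
    stages: tuple[str, ...] = ("call", "prevalence", "coinfection", "de", "correlate")
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        real = all(
            p is not None
            for p in (self.meta_path, self.virus_counts_path, self.gene_counts_path)
        )
        if (self.sim is None) == (not real):
            raise ValueError(
                "provide exactly one of a synthetic SimConfig or the three real input paths"
            )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("sim", None)
        cfg = cls(**{k: v for k, v in raw.items() if k != "sim"})
        if sim is not None:
            cfg.sim = config_from_dict(sim)
        if "stages" in raw:
            cfg.stages = tuple(raw["stages"])
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every enabled stage in dependency order; return the manifest."""
    cfg.validate()
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    outdir = io.ensure_dir(cfg.outdir)
    manifest: dict = {
        "seed": cfg.seed,
        "parameters": {
            "rel_threshold": cfg.rel_threshold,
            "abs_threshold": cfg.abs_threshold,
            "tune_abs_threshold": cfg.tune_abs_threshold,
            "coinfection_alpha": cfg.coinfection_alpha,
            "lfc_cut": cfg.lfc_cut,
            "de_alpha": cfg.de_alpha,
            "correlation_alpha": cfg.correlation_alpha,
            "correlation_method": cfg.correlation_method,
            "moderate": cfg.moderate,
        },
        "stages": {},
        "outputs": {},
        "warnings": [],
    }

    def register(name: str, path: Path) -> None:
        manifest["outputs"][name] = {
            "path": str(path.relative_to(outdir)),
            "sha256": _sha256(path),
        }

    collected: list[str] = []

    def run_stage(name, fn):
        t0 = time.perf_counter()
        log.info("stage %s: starting", name)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            result = fn()
        for w in caught:
            collected.append(f"{name}: {w.message}")
        manifest["stages"][name] = {"seconds": round(time.perf_counter() - t0, 3)}
        log.info("stage %s: done (%.2fs)", name, time.perf_counter() - t0)
        return result

    truth: SyntheticTruth | None = None

    # ----- inputs -----------------------------------------------------
    if cfg.sim is not None:
        def _simulate():
            sim = cfg.sim
            meta, vc, gc, tr = simulate_experiment(sim)
            io.write_metadata(meta, outdir / "metadata.tsv")
            io.write_virus_counts(vc, outdir / "virus_counts.tsv")
            io.write_gene_counts(gc, outdir / "gene_counts.tsv")
            tr.to_json(outdir / "truth.json")
            for n, f in (("metadata", "metadata.tsv"), ("virus_counts", "virus_counts.tsv"),
                         ("gene_counts", "gene_counts.tsv"), ("truth", "truth.json")):
                register(n, outdir / f)
            manifest["sim_config"] = config_to_dict(sim)
            return meta, vc, gc, tr

        meta, virus_counts, gene_counts, truth = run_stage("simulate", _simulate)
    else:
        meta = io.read_metadata(cfg.meta_path)
        virus_counts = io.read_virus_counts(cfg.virus_counts_path)
        gene_counts = io.read_gene_counts(cfg.gene_counts_path)
        manifest["inputs"] = {
            "metadata": {"path": str(cfg.meta_path), "sha256": _sha256(Path(cfg.meta_path))},
            "virus_counts": {"path": str(cfg.virus_counts_path),
                             "sha256": _sha256(Path(cfg.virus_counts_path))},
            "gene_counts": {"path": str(cfg.gene_counts_path),
                            "sha256": _sha256(Path(cfg.gene_counts_path))},
        }

    virus_cols = [c for c in virus_counts.columns if c != "total_reads"]
    projects = meta["project"]

    # ----- calling ----------------------------------------------------
    calls = None
    if "call" in cfg.stages:
        def _call():
            if truth is not None:
                male_m, female_m = truth.male_markers, truth.female_markers
            else:
                male_m = list(calling.DEFAULT_MALE_MARKERS)
                female_m = list(calling.DEFAULT_FEMALE_MARKERS)
            try:
                sex = calling.verify_sex(gene_counts, male_m, female_m)
            except ValueError as err:
                log.warning("sex verification unavailable: %s", err)
                sex = pd.Series("ambiguous", index=gene_counts.columns)
            meta["sex_verified"] = sex.reindex(meta.index).fillna("ambiguous")
            try:
                switching = calling.estimate_switching_rate(
                    gene_counts, sex, male_m, female_m, lanes=meta.get("lane")
                )
                switching_payload = {
                    "rate": switching.rate, "n_wrong": switching.n_wrong,
                    "n_total": switching.n_total, "ci": list(switching.ci),
                    "undefined": switching.undefined,
                }
            except ValueError as err:
                switching_payload = {"error": str(err)}
            abs_threshold = cfg.abs_threshold
            tuning = None
            if cfg.tune_abs_threshold and (meta.get("duplicate_id", "") != "").any():
                abs_threshold, profile = calling.select_abs_threshold(
                    virus_counts, meta["duplicate_id"],
                    rel_threshold=cfg.rel_threshold, projects=projects,
                )
                tuning = profile.to_dict(orient="records")
            result = calling.call_infections(
                virus_counts, rel_threshold=cfg.rel_threshold,
                abs_threshold=abs_threshold, projects=projects,
            )
            try:
                clusters = calling.flag_contaminant_clusters(virus_counts)
            except ValueError:
                clusters = []
            io.write_calls(result.present, outdir / "calls.tsv")
            register("calls", outdir / "calls.tsv")
            report = {
                "rel_threshold": cfg.rel_threshold,
                "abs_threshold": abs_threshold,
                "threshold_tuning": tuning,
                "switching_rate": switching_payload,
                "contaminant_clusters": [sorted(c) for c in clusters],
                "per_virus_max": result.per_virus_max.to_dict(),
            }
            with open(outdir / "calling_report.json", "w") as fh:
                json.dump(report, fh, indent=2, default=float)
            register("calling_report", outdir / "calling_report.json")
            return result.present

        calls = run_stage("call", _call)

    # ----- epidemiology ----------------------------------------------
    if "prevalence" in cfg.stages:
        if calls is None:
            raise RuntimeError("prevalence stage requires the call stage output")

        def _prevalence():
            prev = epidemiology.estimate_prevalence(calls, projects)
            prev.to_csv(outdir / "prevalence.tsv", sep="\t", index=False)
            register("prevalence", outdir / "prevalence.tsv")
            return prev

        run_stage("prevalence", _prevalence)

    if "coinfection" in cfg.stages:
        if calls is None:
            raise RuntimeError("coinfection stage requires the call stage output")

        def _coinfection():
            scan = epidemiology.coinfection_scan(calls, projects, alpha=cfg.coinfection_alpha)
            scan.to_csv(outdir / "coinfection.tsv", sep="\t", index=False)
            register("coinfection", outdir / "coinfection.tsv")
            return scan

        run_stage("coinfection", _coinfection)

    # ----- differential expression ------------------------------------
    de_results: dict[str, de.VirusDEResults] = {}
    if "de" in cfg.stages:
        if calls is None:
            raise RuntimeError("de stage requires the call stage output")

        def _de():
            summaries = {}
            for virus in virus_cols:
                if calls[virus].sum() < cfg.min_calls_for_de:
                    log.info("skipping DE for %s: fewer than %d positive libraries",
                             virus, cfg.min_calls_for_de)
                    continue
                model = de.VirusDEModel(gene_counts, meta, calls, virus)
                res = model.fit(moderate=cfg.moderate)
                de_results[virus] = res
                path = outdir / f"de_{virus}.tsv"
                res.table.to_csv(path, sep="\t", index=False)
                register(f"de_{virus}", path)
                summaries[virus] = {
                    "libraries": len(res.spec.libraries),
                    "genes": int(res.table["gene"].nunique()),
                    "fixed_terms": res.spec.fixed_terms,
                    "random_group": res.spec.random_group,
                    "class_counts": res.class_counts().to_dict(orient="records"),
                }
            with open(outdir / "de_summary.json", "w") as fh:
                json.dump(summaries, fh, indent=2, default=float)
            register("de_summary", outdir / "de_summary.json")
            return summaries

        run_stage("de", _de)

    # ----- correlation -------------------------------------------------
    if "correlate" in cfg.stages and de_results:
        def _correlate():
            em = correlate.effect_matrix(de_results)
            report = correlate.correlate_effects(
                em, method=cfg.correlation_method, alpha=cfg.correlation_alpha
            )
            report.to_frame().to_csv(outdir / "correlation.tsv", sep="\t", index=False)
            register("correlation", outdir / "correlation.tsv")
            for virus, res in de_results.items():
                vt = correlate.volcano_table(res.table)
                path = outdir / f"volcano_{virus}.tsv"
                vt.to_csv(path, sep="\t", index=False)
                register(f"volcano_{virus}", path)
            return report

        run_stage("correlate", _correlate)

    # ----- recovery report (synthetic mode) ----------------------------
    if truth is not None and de_results:
        def _recovery():
            rec = {}
            for virus, res in de_results.items():
                coef = virus_coef(virus)
                est = res.coef_table(coef)["logFC"]
                true = truth.true_logfc[coef].reindex(est.index).fillna(0.0)
                affected = true != 0
                entry = {"n_genes": int(len(est)),
                         "n_affected_tested": int(affected.sum())}
                if affected.any():
                    err = (est[affected] - true[affected]).to_numpy()
                    entry["mae_virus_logfc"] = float(np.mean(np.abs(err)))
                    entry["bias_virus_logfc"] = float(np.mean(err))
                rec[virus] = entry
            with open(outdir / "recovery.json", "w") as fh:
                json.dump(rec, fh, indent=2)
            register("recovery", outdir / "recovery.json")
            return rec

        run_stage("recovery", _recovery)

    manifest["warnings"] = collected
    manifest["timestamp"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=float)
    return manifest
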