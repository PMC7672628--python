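"""End-to-end pipeline orchestration with a run manifest.

Stages run in dependency order: simulate (or load real inputs) ->
extract-utr -> scan-motifs -> normalize -> de -> classify. Every run
writes a ``manifest.json`` echoing the configuration, the seed, package
version, per-output row counts and the failing stage if any, so a run is
self-describing and byte-reproducible under a fixed seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .annotation import extract_utrs, read_genome_fasta, read_gff3, write_utr_fasta
from .de import run_consecutive_contrasts, write_de_table
from .motifs import builtin_motifs, compile_motif, scan_gene_set, write_motif_table
from .normalize import normalize_and_log, read_counts, stage_profile, tmm_factors
from .patterns import classify_all
from .simulate import SimulationConfig, simulate_bundle, write_bundle

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid pipeline configuration; message lists all problems."""


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Validated configuration of one pipeline run."""

    out_dir: Path
    seed: int = 0
    simulate: dict[str, Any] | None = None
    genome: Path | None = None
    gff: Path | None = None
    counts: Path | None = None
    samples: Path | None = None
    fdr: float = 0.05
    lfc: float = 1.0
    min_expr_log2: float = 1.0
    utr_mode: str = "span"
    motif_specs: tuple[str, ...] | None = None  # None: the six built-ins

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "PipelineConfig":
        problems = []
        known = {
            "out_dir", "seed", "simulate", "genome", "gff", "counts",
            "samples", "fdr", "lfc", "min_expr_log2", "utr_mode", "motif_specs",
        }
        for k in raw:
            if k not in known:
                problems.append(f"unknown key {k!r}")
        if "out_dir" not in raw:
            problems.append("out_dir is required")
        sim = raw.get("simulate")
        real = [raw.get(k) for k in ("genome", "gff", "counts", "samples")]
        if sim is None and not all(real):
            problems.append(
                "either a 'simulate' block or all of genome/gff/counts/samples"
            )
        if sim is not None and any(real):
            problems.append("'simulate' block and real input paths are exclusive")
        for k in ("fdr", "lfc", "min_expr_log2"):
            if k in raw and not raw[k] > 0:
                problems.append(f"{k} must be positive")
        if raw.get("utr_mode", "span") not in ("span", "spliced"):
            problems.append("utr_mode must be 'span' or 'spliced'")
        if problems:
            raise ConfigError("; ".join(problems))
        paths = {
            k: Path(raw[k]) if raw.get(k) else None
            for k in ("genome", "gff", "counts", "samples")
        }
        return cls(
            out_dir=Path(raw["out_dir"]),
            seed=int(raw.get("seed", 0)),
            simulate=sim,
            fdr=float(raw.get("fdr", 0.05)),
            lfc=float(raw.get("lfc", 1.0)),
            min_expr_log2=float(raw.get("min_expr_log2", 1.0)),
            utr_mode=raw.get("utr_mode", "span"),
            motif_specs=tuple(raw["motif_specs"]) if raw.get("motif_specs") else None,
            **paths,
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigError("config file must contain a mapping")
        return cls.from_dict(raw)


def _row_count(path: Path) -> int:
    with open(path) as fh:
        return max(0, sum(1 for _ in fh) - 1)  # minus header


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute the full pipeline; returns the manifest (also written to disk).

    The manifest is written even when a stage fails, recording the failing
    stage; the exception is then re-raised as :class:`StageError`.
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "fdr": config.fdr,
            "lfc": config.lfc,
            "min_expr_log2": config.min_expr_log2,
            "utr_mode": config.utr_mode,
            "motif_specs": list(config.motif_specs) if config.motif_specs else "builtin",
            "simulate": config.simulate,
        },
        "stages": {},
        "outputs": {},
        "status": "running",
    }
    stage = "setup"
    try:
        if config.simulate is not None:
            stage = "simulate"
            t0 = time.perf_counter()
            sim_cfg = SimulationConfig(seed=config.seed, **config.simulate)
            bundle = simulate_bundle(sim_cfg)
            write_bundle(bundle, out / "bundle")
            genome = bundle.genome
            genes = bundle.transcripts
            counts, sheet = bundle.counts, bundle.samples
            manifest["stages"]["simulate"] = {
                "seconds": round(time.perf_counter() - t0, 3),
                "n_genes": len(genes),
            }
        else:
            stage = "load"
            genome = read_genome_fasta(config.genome)
            counts, sheet = read_counts(config.counts, config.samples)
            genes = None

        stage = "extract-utr"
        t0 = time.perf_counter()
        if genes is None:
            genes = read_gff3(config.gff)
        utrs, skipped = extract_utrs(genome, genes, mode=config.utr_mode)
        write_utr_fasta(utrs, out / "utr.fa")
        skipped.to_csv(out / "skipped_genes.tsv", sep="\t", index=False)
        manifest["stages"]["extract-utr"] = {
            "seconds": round(time.perf_counter() - t0, 3),
            "n_utrs": len(utrs),
            "n_skipped": len(skipped),
        }

        stage = "scan-motifs"
        t0 = time.perf_counter()
        patterns = (
            [compile_motif(s) for s in config.motif_specs]
            if config.motif_specs
            else builtin_motifs()
        )
        motif_table = scan_gene_set(utrs, patterns)
        write_motif_table(motif_table, out / "motif_counts.tsv")
        manifest["stages"]["scan-motifs"] = {
            "seconds": round(time.perf_counter() - t0, 3),
            "n_genes": len(motif_table),
        }

        stage = "normalize"
        t0 = time.perf_counter()
        factors = tmm_factors(counts)
        norm = normalize_and_log(counts, factors)
        profiles = stage_profile(norm.log2, sheet)
        factors.to_frame().to_csv(out / "tmm_factors.tsv", sep="\t")
        norm.cpm.to_csv(out / "normalized_cpm.tsv", sep="\t")
        norm.log2.to_csv(out / "log2_cpm.tsv", sep="\t")
        profiles.to_csv(out / "stage_profiles.tsv", sep="\t")
        manifest["stages"]["normalize"] = {
            "seconds": round(time.perf_counter() - t0, 3),
        }

        stage = "de"
        t0 = time.perf_counter()
        de_table = run_consecutive_contrasts(counts, sheet, fdr=config.fdr, lfc=config.lfc)
        write_de_table(de_table, out / "de_results.tsv")
        for name, sub in de_table.groupby("contrast"):
            write_de_table(sub, out / f"de_{name}.tsv")
        manifest["stages"]["de"] = {
            "seconds": round(time.perf_counter() - t0, 3),
            "n_contrasts": de_table["contrast"].nunique(),
        }

        stage = "classify"
        t0 = time.perf_counter()
        labels = classify_all(de_table, profiles, min_expr_log2=config.min_expr_log2)
        labels.to_csv(out / "patterns.tsv", sep="\t")
        manifest["stages"]["classify"] = {
            "seconds": round(time.perf_counter() - t0, 3),
            "label_counts": labels["label"].value_counts().to_dict(),
        }

        for f in sorted(out.glob("*.tsv")):
            manifest["outputs"][f.name] = _row_count(f)
        manifest["status"] = "ok"
        return manifest
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        raise StageError(stage, exc) from exc
    finally:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
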