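"""Orchestration: simulate -> quantify/test -> enrich -> screen, one run.

Every stage writes a plain TSV before the next begins, so any stage can be
re-run standalone; the JSON manifest (written last) snapshots the config,
input checksums, per-stage row counts, tool version and seed, and fully
determines a rerun (outputs are bit-identical apart from the manifest
timestamp).
"""

from __future__ import annotations

import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path

import yaml

import dgepair
from dgepair import enrichment, io, screen, simulate, stats

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r}: {message}")


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def load_config(path) -> dict:
    with Path(path).open() as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ValueError(f"config {path} is not a mapping")
    return config


def _test_config(section: dict) -> stats.TestConfig:
    return stats.TestConfig(
        fdr_threshold=float(section.get("fdr", 0.001)),
        min_abs_log2=float(section.get("min_abs_log2", 1.0)),
        zero_substitute=float(section.get("zero_substitute", 0.01)),
    )


def run_pipeline(config, out_dir=None, seed: int | None = None) -> dict:
    """Execute the configured stages; returns the manifest dict.

    ``config`` is a mapping or a YAML path. Inputs come either from a
    ``simulate`` section (generated into the output directory) or from an
    ``inputs`` section naming existing files.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    out = Path(out_dir or config.get("out", "dgepair_run"))
    out.mkdir(parents=True, exist_ok=True)
    if seed is None:
        seed = int(config.get("seed", 0))

    manifest: dict = {
        "tool": "dgepair",
        "version": dgepair.__version__,
        "seed": seed,
        "config": config,
        "input_checksums": {},
        "counts": {},
        "outputs": [],
    }

    counts_path = annotations_path = hits_path = catalog_path = None
    inputs = config.get("inputs", {}) or {}

    # --- stage: simulate -------------------------------------------------
    if "simulate" in config:
        try:
            sim_section = dict(config["simulate"] or {})
            sim_section["seed"] = seed
            spec = simulate.SyntheticSpec(**sim_section)
            counts, libs, truth = simulate.generate_counts(spec)
            counts_path = out / "counts.tsv"
            io.write_counts(counts, libs, counts_path)
            planted = None
            if spec.n_terms or spec.planted_term_size:
                annotations, enr_truth = simulate.generate_annotations(
                    truth.gene_ids, spec, truth
                )
                annotations_path = out / "annotations.tsv"
                io.write_annotations(annotations, annotations_path)
                planted = enr_truth.planted_term_id
            if spec.hit_fraction or spec.n_catalog:
                hits, catalog = simulate.generate_hits_and_catalog(truth.gene_ids, spec)
                hits_path = out / "hits.tsv"
                io.write_hits(hits, hits_path)
                if catalog:
                    catalog_path = out / "catalog.tsv"
                    io.write_catalog(catalog, catalog_path)
            simulate.write_truth(truth, out / "truth.tsv", planted)
            manifest["counts"]["genes_simulated"] = len(counts)
            manifest["outputs"].append(str(counts_path))
        except StageError:
            raise
        except Exception as exc:
            raise StageError("simulate", str(exc)) from exc
    else:
        counts_path = inputs.get("counts")
        annotations_path = inputs.get("annotations")
        hits_path = inputs.get("hits")
        catalog_path = inputs.get("catalog")

    # --- stage: quantify + test -----------------------------------------
    test_section = config.get("test", {}) or {}
    try:
        if counts_path is None or not Path(counts_path).exists():
            raise FileNotFoundError(f"counts file {counts_path!r} not found")
        manifest["input_checksums"]["counts"] = _sha256(Path(counts_path))
        counts, libs = io.read_counts(
            counts_path,
            total_L=test_section.get("n1"),
            total_S=test_section.get("n2"),
        )
        config_obj = _test_config(test_section)
        logger.info(
            "testing %d genes with totals N1=%d N2=%d, FDR<=%g, |log2|>=%g",
            len(counts), libs.total_reads_L, libs.total_reads_S,
            config_obj.fdr_threshold, config_obj.min_abs_log2,
        )
        records = stats.call_degs(counts, libs, config_obj)
        results_path = out / "results.tsv"
        io.write_results(records, results_path)
        summary = stats.summarize_degs(records)
        manifest["counts"].update(summary)
        manifest["counts"]["genes_total"] = len(counts)
        manifest["outputs"].append(str(results_path))
    except StageError:
        raise
    except Exception as exc:
        raise StageError("quantify", str(exc)) from exc

    deg_ids = {r.gene_id for r in records if r.is_deg}

    # --- stage: enrich ---------------------------------------------------
    if annotations_path is not None:
        try:
            manifest["input_checksums"]["annotations"] = _sha256(Path(annotations_path))
            annotations = io.read_annotations(annotations_path)
            enrich_section = config.get("enrich", {}) or {}
            enriched = enrichment.enrich_terms(
                deg_ids,
                annotations,
                namespace=enrich_section.get("namespace"),
                correction=enrich_section.get("correction", "bh"),
                alpha=float(enrich_section.get("alpha", 0.05)),
            )
            enrichment_path = out / "enrichment.tsv"
            enrichment.write_enrichment(enriched, enrichment_path)
            manifest["counts"]["terms_tested"] = len(enriched)
            manifest["counts"]["enriched_terms"] = sum(1 for r in enriched if r.enriched)
            manifest["outputs"].append(str(enrichment_path))
        except StageError:
            raise
        except Exception as exc:
            raise StageError("enrich", str(exc)) from exc

    # --- stage: screen ---------------------------------------------------
    screen_section = config.get("screen", {}) or {}
    catalog = None
    if catalog_path is not None:
        manifest["input_checksums"]["catalog"] = _sha256(Path(catalog_path))
        catalog = io.read_catalog(catalog_path)
    if hits_path is not None:
        try:
            manifest["input_checksums"]["hits"] = _sha256(Path(hits_path))
            hits = io.read_hits(hits_path)
            candidates = screen.screen_flowering_related(
                records,
                hits,
                e_max=float(screen_section.get("e_max", 1e-5)),
                catalog=catalog,
            )
            candidates_path = out / "candidates.tsv"
            screen.write_candidates(candidates, candidates_path)
            manifest["counts"]["candidates"] = len(candidates)
            manifest["outputs"].append(str(candidates_path))
        except StageError:
            raise
        except Exception as exc:
            raise StageError("screen", str(exc)) from exc
    if catalog is not None:
        try:
            report = screen.flowering_time_report(
                catalog, counts, libs, _test_config(test_section)
            )
            report_path = out / "flowering_report.tsv"
            screen.write_report(report, report_path)
            manifest["counts"]["report_rows"] = len(report)
            manifest["outputs"].append(str(report_path))
        except StageError:
            raise
        except Exception as exc:
            raise StageError("screen", str(exc)) from exc

    manifest["timestamp"] = datetime.now(timezone.utc).isoformat()
    with (out / "manifest.json").open("w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
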