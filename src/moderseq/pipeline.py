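"""End-to-end orchestration: simulate/ingest -> quantify -> DE -> splicing.

A run is driven by a nested config (YAML on disk); unknown keys are
rejected before any computation.  All randomness flows from the single
config seed.  Every run writes a JSON manifest recording the package
version, the fully-resolved parameters, and SHA-256 checksums of inputs
and outputs, so identical config + inputs yield byte-identical results.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from . import de_moderated, exon_splicing, quantify, synthetic_data
from .io_formats import (ExpressionMatrix, read_alignment_table, read_design,
                         read_gene_models, write_design, write_matrix,
                         write_results_table)

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or unknown run configuration."""


class DataError(ValueError):
    """Inputs exist but are unusable."""


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "outdir": "moderseq_run",
    "log_level": "INFO",
    "simulate": {
        "n_genes": 2000,
        "design": [2, 2],
        "mean_log_expr": [8.0, 2.0],
        "dispersion_trend": [0.05, 2.0],
        "pi_de": 0.0015,
        "lfc_dist": [2.0, 0.5],
        "exons_per_gene": 4,
        "exon_depth": 300,
        "differential_exon_fraction": 0.02,
        "usage_shift": 0.3,
    },
    "inputs": {
        "models": None,
        "models_dialect": "gtf_lite",
        "alignments": None,
        "design": None,
    },
    "quantify": {
        "radius_kb": 20,
        "cluster_gap_bp": 500,
        "iterations": 1,
    },
    "de": {
        "mode": "auto",
        "span": 0.4,
        "pseudocount": 0.25,
        "reference": "normal",
        "fdr": 0.05,
        "fc": 2.0,
        "rpkm_floor": 0.1,
    },
    "splicing": {
        "min_total": 10,
        "method": "exon_vs_rest",
    },
    "report": {
        "top_k": 20,
    },
}


def resolve_config(user: dict | None) -> dict:
    """Merge a user config over the defaults, rejecting unknown keys."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)

    def merge(base: dict, over: dict, path: str) -> None:
        for key, val in over.items():
            if key not in base:
                raise ConfigError(f"unknown config key {path + key!r}")
            if isinstance(base[key], dict) and isinstance(val, dict):
                merge(base[key], val, path + key + ".")
            else:
                base[key] = val

    if user:
        merge(cfg, user, "")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _quantify_from_files(cfg: dict, outdir: Path) -> ExpressionMatrix:
    inp = cfg["inputs"]
    models = read_gene_models(inp["models"], dialect=inp["models_dialect"])
    design, totals = read_design(inp["design"])
    alignments = read_alignment_table(inp["alignments"])
    if not alignments:
        raise DataError("alignment table is empty")
    by_sample: dict[str, list] = {s: [] for s in design.index}
    for rec in alignments:
        sample = rec.read_id.rsplit(":", 1)[0] if ":" in rec.read_id else None
        if sample not in by_sample:
            raise DataError(f"read {rec.read_id!r} does not name a designed sample "
                            "(read_id convention is '<sample>:<read>')")
        by_sample[sample].append(rec)
    rpkm_cols, count_cols, total_list = {}, {}, {}
    for sample in design.index:
        total = None if totals is None else float(totals[sample])
        df = quantify.quantify_sample(
            by_sample[sample], models, total_mapped_reads=total,
            radius_bp=int(cfg["quantify"]["radius_kb"]) * 1000,
            cluster_gap_bp=cfg["quantify"]["cluster_gap_bp"],
            iterations=cfg["quantify"]["iterations"])
        rpkm_cols[sample] = df["final_rpkm"]
        count_cols[sample] = (df["unique_reads"] + df["splice_reads"]
                              + df["multiread_weight"] + df["region_reads"])
        total_list[sample] = df.attrs["total_mapped_reads"]
    rpkm = pd.DataFrame(rpkm_cols)
    counts = pd.DataFrame(count_cols)
    expr = ExpressionMatrix(rpkm, counts, design,
                            pd.Series(total_list)[design.index])
    write_matrix(rpkm, outdir / "rpkm.tsv")
    write_matrix(counts, outdir / "counts.tsv")
    return expr


def run_pipeline(config: dict | None, outdir: str | Path | None = None) -> dict:
    """Execute the full pipeline; returns the manifest dictionary.

    If file inputs are configured they are quantified; otherwise the
    synthetic-data module generates the experiment from the config seed.
    Stage failures abort with the failing stage named; partial outputs are
    quarantined under ``<outdir>/partial``.
    """
    cfg = resolve_config(config)
    out = Path(outdir) if outdir is not None else Path(cfg["outdir"])
    partial = out / "partial"
    partial.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    manifest: dict = {"version": __version__, "config": cfg, "seed": seed,
                      "inputs": {}, "outputs": {}, "stages": []}
    stage = "setup"
    try:
        use_files = cfg["inputs"]["alignments"] is not None
        if use_files:
            stage = "quantify"
            for key in ("models", "alignments", "design"):
                manifest["inputs"][key] = _sha256(Path(cfg["inputs"][key]))
            expr = _quantify_from_files(cfg, partial)
            truth = None
        else:
            stage = "simulate"
            sim = cfg["simulate"]
            ccfg = synthetic_data.CountSimConfig(
                n_genes=sim["n_genes"], design=tuple(sim["design"]),
                mean_log_expr_dist=tuple(sim["mean_log_expr"]),
                dispersion_trend=tuple(sim["dispersion_trend"]),
                pi_de=sim["pi_de"], lfc_dist=tuple(sim["lfc_dist"]), seed=seed)
            expr, truth = synthetic_data.simulate_counts(ccfg)
            write_matrix(expr.rpkm, partial / "rpkm.tsv")
            write_matrix(expr.counts, partial / "counts.tsv")
            write_design(expr.design, expr.total_mapped_reads, partial / "design.tsv")
            write_results_table(truth, partial / "truth.tsv")
        manifest["stages"].append(stage)

        stage = "de"
        de_cfg = cfg["de"]
        de = de_moderated.de_test(
            expr, mode=de_cfg["mode"], span=de_cfg["span"],
            pseudocount=de_cfg["pseudocount"], reference=de_cfg["reference"],
            fc_threshold=de_cfg["fc"], fdr_threshold=de_cfg["fdr"],
            rpkm_floor=de_cfg["rpkm_floor"])
        write_results_table(de, partial / "de.tsv")
        write_results_table(de_moderated.volcano_table(de), partial / "volcano.tsv")
        write_results_table(
            de_moderated.rank_top_expressed(expr, k=cfg["report"]["top_k"]),
            partial / "top_expressed.tsv")
        manifest["stages"].append(stage)

        stage = "splicing"
        sim = cfg["simulate"]
        if use_files:
            models = read_gene_models(cfg["inputs"]["models"],
                                      dialect=cfg["inputs"]["models_dialect"])
            alignments = read_alignment_table(cfg["inputs"]["alignments"])
            design, _ = read_design(cfg["inputs"]["design"])
            tables = exon_splicing.build_exon_tables(alignments, models, design)
        else:
            _, tables, _ = synthetic_data.simulate_exon_reads(
                n_genes=max(50, sim["n_genes"] // 10),
                exons_per_gene=sim["exons_per_gene"], depth=sim["exon_depth"],
                differential_exon_fraction=sim["differential_exon_fraction"],
                usage_shift=sim["usage_shift"], seed=seed,
                design=tuple(sim["design"]))
            design = pd.Series(["cond1"] * sim["design"][0] + ["cond2"] * sim["design"][1],
                               index=list(tables.columns))
        spl = exon_splicing.test_exon_usage(tables, design,
                                            min_total=cfg["splicing"]["min_total"],
                                            method=cfg["splicing"]["method"])
        write_results_table(spl, partial / "splicing.tsv")
        manifest["stages"].append(stage)

        stage = "report"
        report = make_report(de, spl)
        (partial / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
        manifest["stages"].append(stage)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # promote quarantined outputs only after every stage succeeded
    for f in sorted(partial.iterdir()):
        target = out / f.name
        if target.exists():
            target.unlink()
        f.rename(target)
    partial.rmdir()
    for f in sorted(out.glob("*.tsv")) + sorted(out.glob("*.json")):
        manifest["outputs"][f.name] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def make_report(de: pd.DataFrame, splicing: pd.DataFrame,
                mendelian: pd.DataFrame | None = None) -> dict:
    """Summary counts over the DE, splicing and (optional) cross tables."""
    calls = de["call"].value_counts() if len(de) else {}
    report = {
        "n_genes": int(len(de)),
        "n_up": int(calls.get("up", 0)),
        "n_down": int(calls.get("down", 0)),
        "n_tested_exons": int(len(splicing)),
        "n_splicing_q05": int((splicing["q"] < 0.05).sum()) if len(splicing) else 0,
    }
    if mendelian is not None:
        report["n_crosses"] = int(len(mendelian))
        report["min_cross_p"] = float(mendelian["p"].min()) if len(mendelian) else None
    return report
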