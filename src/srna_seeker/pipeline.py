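"""End-to-end orchestration: map -> coverage -> discover -> quantify -> DE ->
CA -> network, from a single validated config with one global seed.

Every stage writes its outputs under the run directory and never touches
another stage's files; each output declares the hash of the config that
produced it (inline comment for line formats, manifest entry otherwise).
Reruns with the same config and seed are bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coverage as cov
from . import discovery, io, network, quantdiff, synthdata
from .core import CONDITIONS, DetectionParams, sample_ids

logger = logging.getLogger(__name__)

SUMMARY_SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "run"
    paths: dict = field(default_factory=dict)  # genome, annotation, reads_dir, predictions, pathway_map, transcriptome
    detection: DetectionParams = field(default_factory=DetectionParams)
    de: dict = field(default_factory=lambda: {
        "fc_threshold": 1.5, "alpha": 0.05, "mode": "condition", "reference": "control",
    })
    network: dict = field(default_factory=lambda: {
        "max_rank": 100, "energy_cutoff": -10.0, "r_cut": 0.4,
        "corr_alpha": 0.05, "enrich_alpha": 0.05, "min_hits": 2,
    })
    normalization_target: float | None = None  # None -> demo's design-expected total
    demo: bool = True

    def canonical(self) -> dict:
        d = asdict(self)
        d["detection"] = asdict(self.detection)
        return d

    @property
    def config_hash(self) -> str:
        # outdir is where results land, not what they are: exclude it so the
        # same study in two directories hashes identically
        d = self.canonical()
        d.pop("outdir")
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


_DEFAULTS = PipelineConfig()
_KNOWN_KEYS = set(_DEFAULTS.canonical())


def validate_config(raw: dict | str | os.PathLike | None) -> PipelineConfig:
    """Normalize a YAML file or dict into a PipelineConfig.

    Unknown keys are rejected; numeric strings are coerced with a warning;
    all type mismatches and bound violations are collected and reported
    together, not just the first.
    """
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        with open(raw) as fh:
            raw = yaml.safe_load(fh) or {}
    errors: list[str] = []
    unknown = set(raw) - _KNOWN_KEYS
    for k in sorted(unknown):
        errors.append(f"unknown config key: {k!r}")

    def coerce_number(key, value, caster=float):
        if isinstance(value, str):
            try:
                out = caster(value)
                logger.warning("config key %s given as string %r; coerced", key, value)
                return out
            except ValueError:
                errors.append(f"{key}: cannot interpret {value!r} as a number")
                return None
        if isinstance(value, bool) or not isinstance(value, (int, float)):
            errors.append(f"{key}: expected a number, got {type(value).__name__}")
            return None
        return caster(value)

    cfg = PipelineConfig()
    if "seed" in raw:
        v = coerce_number("seed", raw["seed"], int)
        if v is not None:
            cfg.seed = v
    if "outdir" in raw:
        cfg.outdir = str(raw["outdir"])
    if "demo" in raw:
        cfg.demo = bool(raw["demo"])
    if "paths" in raw:
        if isinstance(raw["paths"], dict):
            cfg.paths = dict(raw["paths"])
        else:
            errors.append("paths: expected a mapping")
    if "normalization_target" in raw and raw["normalization_target"] is not None:
        v = coerce_number("normalization_target", raw["normalization_target"])
        if v is not None and v <= 0:
            errors.append("normalization_target: must be positive")
        else:
            cfg.normalization_target = v

    det_kwargs = {}
    for key, value in (raw.get("detection") or {}).items():
        if not hasattr(_DEFAULTS.detection, key):
            errors.append(f"detection.{key}: unknown key")
            continue
        caster = int if isinstance(getattr(_DEFAULTS.detection, key), int) else float
        v = coerce_number(f"detection.{key}", value, caster)
        if v is not None:
            if v <= 0:
                errors.append(f"detection.{key}: must be positive")
            else:
                det_kwargs[key] = v
    if not errors:
        cfg.detection = DetectionParams(**{**asdict(_DEFAULTS.detection), **det_kwargs})

    for section in ("de", "network"):
        for key, value in (raw.get(section) or {}).items():
            base = getattr(cfg, section)
            if key not in base:
                errors.append(f"{section}.{key}: unknown key")
                continue
            if isinstance(base[key], str):
                base[key] = str(value)
            else:
                v = coerce_number(f"{section}.{key}", value)
                if v is not None:
                    base[key] = v

    if errors:
        raise ValueError("invalid config:\n  " + "\n  ".join(errors))
    logger.info("effective thresholds: %s", json.dumps(cfg.canonical(), sort_keys=True))
    return cfg


def _stage_seed(base_seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{base_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def run_pipeline(config: PipelineConfig | dict | str | None = None) -> dict:
    """Run every stage in order and return the machine-readable summary.

    In demo mode (no input paths) the synthetic study supplies all inputs,
    including target-prediction / pathway / transcriptome tables with planted
    enrichment.  Missing declared inputs fail fast naming the file.
    """
    if not isinstance(config, PipelineConfig):
        config = validate_config(config)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash

    for key in ("genome", "annotation", "predictions", "pathway_map", "transcriptome"):
        p = config.paths.get(key)
        if p and not Path(p).exists():
            raise FileNotFoundError(f"configured input {key} does not exist: {p}")

    # ---- inputs: demo study or user files
    if config.demo and not config.paths.get("genome"):
        study = synthdata.synthetic_study(seed=_stage_seed(config.seed, "simulate"))
        genome, annotation = study.genome, study.annotation
        reads_by_sample = study.reads_by_sample
        norm_target = config.normalization_target or study.normalization_target
        io.write_fasta(genome, outdir / "genome.fasta")
        io.write_annotation_gff3(annotation, outdir / "annotation.gff3")
        io.write_tsv(study.truth, outdir / "ground_truth.tsv")
    else:
        genome = io.read_fasta(config.paths["genome"])
        annotation = io.read_annotation_gff3(config.paths["annotation"])
        reads_dir = Path(config.paths["reads_dir"])
        reads_by_sample = {}
        for sid in sample_ids():
            fq = reads_dir / f"{sid}.fastq"
            if not fq.exists():
                raise FileNotFoundError(f"missing reads file: {fq}")
            reads_by_sample[sid] = io.read_fastq(fq)
        study = None
        norm_target = config.normalization_target or 100_000_000.0

    # ---- map + coverage + normalize
    index = cov.GenomeIndex(genome)
    raw_tracks: dict[str, list] = {}
    norm_tracks: dict[str, list] = {}
    mapping_rows = []
    for sid, reads in reads_by_sample.items():
        mapped, summary = cov.map_reads_iterative(reads, index)
        tracks = cov.compute_coverage(mapped, genome, sample_id=sid)
        normalized, factor = cov.normalize_to_total(tracks, annotation, norm_target)
        raw_tracks[sid] = tracks
        norm_tracks[sid] = normalized
        mapping_rows.append({"sample": sid, **summary.as_dict(), "scale_factor": factor})
        io.write_bedgraph(tracks, outdir / f"coverage_raw_{sid}.bedgraph")
        io.write_bedgraph(normalized, outdir / f"coverage_norm_{sid}.bedgraph")
    _write_tsv_with_hash(pd.DataFrame(mapping_rows), outdir / "mapping_summary.tsv", chash)

    # ---- discover
    srnas = discovery.call_srnas(norm_tracks, annotation, genome, config.detection)
    io.write_srna_gff3(srnas, outdir / "srnas.gff3")
    io.write_srna_table(srnas, annotation, outdir / "srnas.tsv")

    # ---- quantify
    expr = quantdiff.expression_matrix(srnas, norm_tracks)
    _write_tsv_with_hash(expr.rename_axis("srna_id").reset_index(),
                         outdir / "expression.tsv", chash)

    # ---- DE (rounded normalized expression as the count-scale input)
    de_table = pd.DataFrame()
    de_counts_per_condition: dict[str, int] = {}
    if len(srnas) >= 2:
        counts = expr.round().astype(int)
        keep = (counts > 0).all(axis=1)
        if keep.any():
            de_table = quantdiff.de_conditions(
                counts[keep],
                reference=config.de["reference"],
                fc_threshold=config.de["fc_threshold"],
                alpha=config.de["alpha"],
                mode=config.de["mode"],
            )
    if not de_table.empty:
        _write_tsv_with_hash(de_table, outdir / "de_results.tsv", chash)
        sig = de_table[de_table["significant"]]
        de_counts_per_condition = sig.groupby("comparison").size().to_dict()

    # ---- CA
    ca_rows = 0
    if len(srnas) >= 3:
        ca = quantdiff.correspondence_analysis(expr[expr.sum(axis=1) > 0])
        coords = pd.concat([
            ca.row_coords.assign(kind="sRNA"),
            ca.col_coords.assign(kind="sample"),
        ]).rename_axis("name").reset_index()
        keep_cols = ["name"] + [c for c in ("dim1", "dim2") if c in coords.columns] + ["kind"]
        _write_tsv_with_hash(coords[keep_cols], outdir / "ca_coordinates.tsv", chash)
        ca_rows = len(ca.row_coords)

    # ---- network
    net_summary = {"n_srnas": 0, "n_pathways": 0, "n_edges": 0}
    net_inputs = _network_inputs(config, expr, outdir)
    if net_inputs is not None:
        predictions, pathway_map, transcriptome, srna_expr = net_inputs
        net, enrich, corr = network.build_network(
            predictions, srna_expr, transcriptome, pathway_map,
            max_rank=int(config.network["max_rank"]),
            energy_cutoff=config.network["energy_cutoff"],
            r_cut=config.network["r_cut"],
            corr_alpha=config.network["corr_alpha"],
            enrich_alpha=config.network["enrich_alpha"],
            min_hits=int(config.network["min_hits"]),
        )
        network.export_graph(net, outdir / "network.graphml", outdir / "network.sif")
        _write_tsv_with_hash(enrich, outdir / "enrichment.tsv", chash)
        net_summary = {
            "n_srnas": len(net.srnas), "n_pathways": len(net.pathways),
            "n_edges": net.n_edges,
        }

    category_counts = {cat: 0 for cat in ("ncRNA", "asRNA", "UTR")}
    for s in srnas:
        category_counts[s.category] += 1

    summary = {
        "schema_version": SUMMARY_SCHEMA_VERSION,
        "config_hash": chash,
        "seed": config.seed,
        "n_samples": len(reads_by_sample),
        "srna_counts": category_counts,
        "n_srnas_total": len(srnas),
        "n_repeat_flagged": sum(1 for s in srnas if s.repeat_flag),
        "de_significant_per_comparison": dict(sorted(de_counts_per_condition.items())),
        "ca_rows": ca_rows,
        "network": net_summary,
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


def _network_inputs(config: PipelineConfig, expr: pd.DataFrame, outdir: Path):
    paths = config.paths
    if paths.get("predictions"):
        predictions = io.read_tsv(paths["predictions"])
        pathway_map = io.read_tsv(paths["pathway_map"])
        transcriptome = io.read_tsv(paths["transcriptome"], index_col=0)
        return predictions, pathway_map, transcriptome, expr
    if not config.demo:
        return None
    # demo: planted enrichment over the discovered trans-encoded sRNAs
    nc_ids = [i for i in expr.index if i.startswith("nc")][:8]
    if len(nc_ids) < 2:
        return None
    genes, pathways = synthdata.default_pathways()
    pw_names = sorted(pathways)
    enriched = [(nc_ids[k], pw_names[k]) for k in range(min(3, len(nc_ids)))]
    truth = synthdata.simulate_network_truth(
        nc_ids, genes, pathways, enriched,
        seed=_stage_seed(config.seed, "network_truth"),
        samples=list(expr.columns),
    )
    io.write_tsv(truth.predictions, outdir / "target_predictions.tsv")
    io.write_tsv(truth.pathway_map, outdir / "pathway_map.tsv")
    _df = truth.transcriptome.rename_axis("gene_id").reset_index()
    io.write_tsv(_df, outdir / "transcriptome.tsv")
    io.write_tsv(pd.DataFrame(truth.true_edges, columns=["srna_id", "pathway_id"]),
                 outdir / "network_truth_edges.tsv")
    return truth.predictions, truth.pathway_map, truth.transcriptome, truth.srna_expression


def _write_tsv_with_hash(df: pd.DataFrame, path: Path, config_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, sep="\t", index=False)
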