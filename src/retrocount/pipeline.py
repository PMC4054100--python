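"""End-to-end orchestration: simulate/load -> assign -> methylation and
expression differentials -> integration -> TSV report bundle with a manifest.

All outputs are plain TSV with deterministic row order, so re-running with
an identical configuration reproduces identical files.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .annotation import (TagSet, distance_to_nearest_gene, filter_unique_reads,
                         parse_bed, parse_repeatmasker_out)
from .expression import (count_expression, differential_expression,
                         fold_change_density, readthrough_control)
from .integration import (conditional_summary, distance_summary, join_loci,
                          quadrant_counts)
from .methylation import class_differential, locus_differential
from .synthetic import SyntheticConfig, simulate_scene, write_scene

log = logging.getLogger(__name__)

STAGES = ("simulate", "assign", "help-diff", "rna-diff", "integrate", "report")

DEFAULT_THRESHOLDS = {
    "alpha": 0.05,
    "meth_log2fc": 1.0,
    "expr_log2fc": 5.0,
    "min_mspi": 2,
    "min_total": 5,
    "offset": 10_000,
    "min_mapq": 20,
}

_KNOWN_KEYS = {"annotation", "genes", "libraries", "thresholds",
               "stratify_levels", "seed", "outdir", "simulate"}
_LIBRARY_KEYS = {"hpaii_tester", "hpaii_driver", "mspi_tester", "mspi_driver",
                 "rna_tester", "rna_driver"}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Validated, defaults-filled pipeline configuration."""

    outdir: Path
    seed: int = 0
    annotation: Path | None = None
    genes: Path | None = None
    libraries: dict[str, Path] = field(default_factory=dict)
    thresholds: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    stratify_levels: tuple[str, ...] = ("class", "family", "name")
    simulate: bool = True
    #: SyntheticConfig field overrides for the simulate stage
    synthetic_overrides: dict = field(default_factory=dict)


def validate_config(raw: dict) -> PipelineConfig:
    """Normalise a parsed YAML/JSON config dict; unknown keys are rejected."""
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    thresholds = dict(DEFAULT_THRESHOLDS)
    for key, value in (raw.get("thresholds") or {}).items():
        if key not in DEFAULT_THRESHOLDS:
            raise ValueError(f"unknown threshold {key!r}")
        if value is None or value <= 0:
            raise ValueError(f"threshold {key!r} must be positive")
        thresholds[key] = value
    libraries = {k: Path(v) for k, v in (raw.get("libraries") or {}).items()}
    unknown_libs = set(libraries) - _LIBRARY_KEYS
    if unknown_libs:
        raise ValueError(f"unknown library label(s): {sorted(unknown_libs)}")
    sim_raw = raw.get("simulate", not libraries)
    if isinstance(sim_raw, dict):
        simulate, overrides = True, sim_raw
    else:
        simulate, overrides = bool(sim_raw), {}
    valid_fields = {f.name for f in dataclasses.fields(SyntheticConfig)}
    unknown_sim = set(overrides) - valid_fields
    if unknown_sim:
        raise ValueError(f"unknown simulate key(s): {sorted(unknown_sim)}")
    cfg = PipelineConfig(
        outdir=Path(raw.get("outdir", "retrocount_out")),
        seed=int(raw.get("seed", 0)),
        annotation=Path(raw["annotation"]) if raw.get("annotation") else None,
        genes=Path(raw["genes"]) if raw.get("genes") else None,
        libraries=libraries,
        thresholds=thresholds,
        stratify_levels=tuple(raw.get("stratify_levels", ("class", "family", "name"))),
        simulate=simulate,
        synthetic_overrides=overrides,
    )
    if not cfg.simulate:
        for key in ("annotation",):
            if getattr(cfg, key) is None:
                raise ValueError(f"config is missing {key!r}")
        missing = {"hpaii_tester", "hpaii_driver"} - set(cfg.libraries)
        if missing:
            raise ValueError(f"config is missing libraries {sorted(missing)}")
        for label, path in cfg.libraries.items():
            if not path.exists():
                raise ValueError(f"library {label!r}: {path} does not exist")
        if not cfg.annotation.exists():
            raise ValueError(f"annotation {cfg.annotation} does not exist")
    return cfg


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return validate_config(raw)


def _load_annotation(path: Path) -> pd.DataFrame:
    if path.suffix == ".out":
        return parse_repeatmasker_out(path)
    return parse_bed(path, kind="repeat")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns the manifest dict (also written to disk).

    Any stage failure raises :class:`PipelineError` carrying the stage name.
    """
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    thresholds = config.thresholds
    completed: list[str] = []
    inputs: dict[str, str] = {}

    # -- stage: simulate (or load) ------------------------------------------
    stage = "simulate"
    try:
        if config.simulate:
            overrides = {k: v for k, v in config.synthetic_overrides.items()
                         if k != "seed"}
            scene = simulate_scene(SyntheticConfig(**overrides, seed=config.seed))
            paths = write_scene(scene, outdir / "simulated")
            annotation, genes = scene.annotation, scene.genes
            tags = {
                "hpaii_tester": scene.tags["hpaii_mutant"],
                "hpaii_driver": scene.tags["hpaii_control"],
                "mspi_tester": scene.tags["mspi_mutant"],
                "mspi_driver": scene.tags["mspi_control"],
                "rna_tester": scene.tags["rna_mutant"],
                "rna_driver": scene.tags["rna_control"],
            }
            # RNA reads are counted by positional overlap, not by their
            # generating transcript (read-through reads lie upstream of it)
            for label in ("rna_tester", "rna_driver"):
                tags[label].records = tags[label].records.drop(columns=["locus_id"])
            inputs = {k: _sha256(p) for k, p in paths.items()}
        else:
            annotation = _load_annotation(config.annotation)
            genes = parse_bed(config.genes, kind="genes") if config.genes else None
            tags = {
                label: filter_unique_reads(
                    path, min_mapq=int(thresholds["min_mapq"]),
                    library_label=label)
                for label, path in config.libraries.items()
            }
            inputs = {"annotation": _sha256(config.annotation),
                      **{k: _sha256(v) for k, v in config.libraries.items()}}
        completed.append(stage)
    except Exception as exc:  # noqa: BLE001 - stage attribution
        raise PipelineError(stage, str(exc)) from exc

    # -- stage: assign -------------------------------------------------------
    stage = "assign"
    try:
        n_assigned = {}
        for label, tagset in tags.items():
            if "locus_id" in tagset.records.columns:
                assigned = tagset.records["locus_id"].notna().sum()
            else:
                from .annotation import assign_tags
                tagset.records["locus_id"] = assign_tags(tagset, annotation)
                assigned = tagset.records["locus_id"].notna().sum()
            n_assigned[label] = int(assigned)
            log.info("%s: %d/%d tags repeat-assigned", label, assigned,
                     tagset.total_count)
        completed.append(stage)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    # -- stage: help-diff ----------------------------------------------------
    stage = "help-diff"
    try:
        for level in config.stratify_levels:
            table = class_differential(
                tags["hpaii_tester"], tags["hpaii_driver"], annotation,
                stratify_by=level)
            _write_tsv(table, outdir / f"help_class_{level}.tsv")
        meth_loci = locus_differential(
            tags["hpaii_tester"], tags["hpaii_driver"], annotation,
            mspi_tester=tags.get("mspi_tester"),
            mspi_driver=tags.get("mspi_driver"),
            min_mspi=int(thresholds["min_mspi"]))
        _write_tsv(meth_loci, outdir / "help_loci.tsv")
        completed.append(stage)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    # -- stage: rna-diff -----------------------------------------------------
    stage = "rna-diff"
    expr = None
    try:
        if "rna_tester" in tags and "rna_driver" in tags:
            reads = {"control": tags["rna_driver"], "mutant": tags["rna_tester"]}
            counts = count_expression(reads, annotation, strand_mode="split")
            sizes = {c: t.total_count for c, t in reads.items()}
            expr = differential_expression(
                counts, sizes, min_total=int(thresholds["min_total"]))
            _write_tsv(expr, outdir / "rna_loci.tsv")
            informative = expr[expr["informative"]].merge(
                annotation[["locus_id", "rep_class", "rep_name"]], on="locus_id")
            for label, mask in (
                ("iap", informative["rep_name"].str.startswith("IAP")),
                ("non_iap_ltr", (informative["rep_class"] == "LTR")
                 & ~informative["rep_name"].str.startswith("IAP")),
                ("line", informative["rep_class"] == "LINE"),
            ):
                if mask.any():
                    dens = fold_change_density(informative, mask.to_numpy())
                    _write_tsv(
                        pd.DataFrame({"log2fc": dens.grid,
                                      "density": dens.density}),
                        outdir / f"density_{label}.tsv")
            rt = readthrough_control(
                reads, annotation, offset=int(thresholds["offset"]),
                alpha=thresholds["alpha"],
                min_total=int(thresholds["min_total"]))
            _write_tsv(rt, outdir / "readthrough.tsv")
        completed.append(stage)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    # -- stage: integrate ----------------------------------------------------
    stage = "integrate"
    try:
        if expr is not None:
            distances = (distance_to_nearest_gene(annotation, genes)
                         if genes is not None and len(genes) else None)
            joined = join_loci(
                meth_loci, expr,
                expr_thresh=thresholds["expr_log2fc"],
                meth_thresh=thresholds["meth_log2fc"],
                distances=distances)
            _write_tsv(joined, outdir / "joined_loci.tsv")
            _write_tsv(quadrant_counts(joined).rename("n").reset_index(),
                       outdir / "quadrant_counts.tsv")
            _write_tsv(conditional_summary(joined, "hypomethylated",
                                           alpha=thresholds["alpha"]),
                       outdir / "summary_hypomethylated.tsv")
            _write_tsv(conditional_summary(joined, "upregulated",
                                           alpha=thresholds["alpha"]),
                       outdir / "summary_upregulated.tsv")
            if distances is not None:
                _write_tsv(distance_summary(joined, distances,
                                            alpha=thresholds["alpha"]),
                           outdir / "distance_summary.tsv")
        completed.append(stage)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    # -- stage: report -------------------------------------------------------
    stage = "report"
    try:
        manifest = {
            "version": __version__,
            "seed": config.seed,
            "stages": completed + [stage],
            "thresholds": {k: float(v) for k, v in thresholds.items()},
            "inputs_sha256": inputs,
            "tags_assigned": n_assigned,
        }
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True))
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc
    return manifest
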