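"""Synthetic genomes, HpaII/MspI tag libraries and stranded RNA read sets
with recorded planted truth.

The generator emulates the statistical structure of an HpaII-representation
methylation assay on bulk DNA: CCGG sites are scattered through a toy repeat
annotation, each site carries a per-(class, genotype) methylation
probability (the fraction of cells methylated at that site), the HpaII
library samples a fixed tag budget over sites weighted by the *unmethylated*
fraction, and the MspI library samples the same budget uniformly over all
sites (the copy-number control).  RNA read sets draw per-locus Poisson counts
with planted log2 fold changes, placed uniformly on the locus strand; a
configurable fraction of expression-planted LTR loci instead transcribe from
a start 12 kb upstream, running through the shifted-window control region
into the locus (the read-through scenario).

Everything is driven by a single integer seed: a fixed seed gives
byte-identical outputs.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from bisect import bisect_left, insort
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .annotation import (GENE_COLUMNS, TAG_COLUMNS, TagSet, make_locus_id,
                         write_bed, write_repeatmasker_out)

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid synthetic-scene configuration."""


class PlacementError(RuntimeError):
    """Requested loci cannot be placed on the configured chromosomes."""


#: Fixed toy taxonomy: (class, family, name) plus the within-class weight
#: used to apportion the per-class locus budget among names.
TAXONOMY: tuple[tuple[str, str, str, float], ...] = (
    ("LINE", "L1", "L1Md_A", 1.0),
    ("LTR", "ERVK", "IAPEz-int", 0.4),
    ("LTR", "ERVK", "IAPLTR1", 0.3),
    ("LTR", "ERVL", "MERVL-int", 0.3),
    ("SINE", "B1", "B1_Mm", 1.0),
    ("Satellite", "major", "GSAT_MM", 1.0),
    ("tRNA", "tRNA", "tRNA-Lys", 1.0),
)

GENOTYPES = ("control", "mutant")


def _default_chrom_sizes() -> dict[str, int]:
    return {"chr1": 30_000_000, "chr2": 25_000_000,
            "chr3": 25_000_000, "chr4": 20_000_000}


def _default_n_loci() -> dict[str, int]:
    # Composition keeps the in-class/out-of-class contingency well behaved:
    # the planted LTR unmethylated-mass delta stays small relative to the
    # unmethylated mass of the remaining classes, so unplanted-class odds
    # ratios suffer only mild compositional shrinkage (closed form:
    # OR(X) = (W_d - w_X)/(W_t - w_X) ~= 0.85-0.92 for every unplanted X).
    return {"LINE": 350, "LTR": 60, "SINE": 450, "Satellite": 120, "tRNA": 150}


def _default_meth_prob() -> dict[str, dict[str, float]]:
    # Control values follow the broad wild-type ordering (satellites and
    # LTRs heavily methylated, SINEs intermediate, tRNA-adjacent repeats
    # largely unmethylated); the mutant loses methylation at LTR, LINE and
    # satellite compartments, the coupled scene of the study design.
    return {
        "LINE": {"control": 0.85, "mutant": 0.40},
        "LTR": {"control": 0.90, "mutant": 0.40},
        "SINE": {"control": 0.60, "mutant": 0.60},
        "Satellite": {"control": 0.90, "mutant": 0.60},
        "tRNA": {"control": 0.30, "mutant": 0.30},
    }


def _default_expr_log2fc() -> dict[str, float]:
    return {"IAPEz-int": 5.0, "IAPLTR1": 5.0}


def _default_library_depth() -> dict[str, int]:
    return {"hpaii": 100_000, "mspi": 100_000}


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic scene.

    The defaults encode the coupled scenario: LTR/LINE/satellite
    hypomethylation in the mutant with transcriptional activation planted
    only at IAP repeat names, LINEs hypomethylated but silent.
    """

    chrom_sizes: dict[str, int] = field(default_factory=_default_chrom_sizes)
    n_loci_per_class: dict[str, int] = field(default_factory=_default_n_loci)
    locus_length_range: tuple[int, int] = (500, 3000)
    #: expected CCGG sites per kb inside repeat loci
    ccgg_rate: float = 2.0
    #: expected CCGG sites per kb outside repeats
    ccgg_background_rate: float = 0.02
    meth_prob: dict[str, dict[str, float]] = field(default_factory=_default_meth_prob)
    background_meth_prob: dict[str, float] = field(
        default_factory=lambda: {"control": 0.75, "mutant": 0.75})
    expr_log2fc: dict[str, float] = field(default_factory=_default_expr_log2fc)
    #: mean RNA reads per locus in the control condition
    base_expression: float = 20.0
    #: mean RNA reads per gene in *both* conditions: the stable bulk of the
    #: transcriptome, which dominates library totals so that planted repeat
    #: activation only mildly perturbs depth normalisation (as in a real
    #: library, where repeat-derived reads are a small minority)
    gene_expression: float = 500.0
    #: fraction of expression-planted LTR loci transcribed from upstream
    readthrough_fraction: float = 0.1
    #: read-through transcripts start this far upstream of the locus, fully
    #: covering the 10 kb shifted control window
    readthrough_offset: int = 12_000
    library_depth: dict[str, int] = field(default_factory=_default_library_depth)
    rna_read_length: int = 50
    n_genes: int = 300
    gene_length: int = 2000
    #: when set, genes are placed at exactly this gap from a random repeat
    gene_offset_from_repeats: int | None = None
    seed: int = 0

    def validate(self) -> "SyntheticConfig":
        for chrom, size in self.chrom_sizes.items():
            if size <= 0:
                raise ConfigError(f"chromosome {chrom} has non-positive length")
        for cls, n in self.n_loci_per_class.items():
            if n < 0:
                raise ConfigError(f"negative locus count for class {cls}")
        lo, hi = self.locus_length_range
        if not 0 < lo <= hi:
            raise ConfigError("locus_length_range must be positive and ordered")
        for cls, probs in self.meth_prob.items():
            for gt, p in probs.items():
                if not 0 <= p <= 1:
                    raise ConfigError(f"meth_prob[{cls}][{gt}]={p} outside [0,1]")
        for gt, p in self.background_meth_prob.items():
            if not 0 <= p <= 1:
                raise ConfigError(f"background_meth_prob[{gt}] outside [0,1]")
        if not 0 <= self.readthrough_fraction <= 1:
            raise ConfigError("readthrough_fraction outside [0,1]")
        if min(self.ccgg_rate, self.ccgg_background_rate) < 0:
            raise ConfigError("CCGG rates must be non-negative")
        if self.base_expression < 0:
            raise ConfigError("base_expression must be non-negative")
        for label, depth in self.library_depth.items():
            if depth < 0:
                raise ConfigError(f"library_depth[{label}] must be non-negative")
        return self

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SyntheticTruth:
    """Planted ground truth recorded alongside a scene."""

    class_meth_delta: dict[str, tuple[float, float]]
    locus_expr_log2fc: dict[str, float]
    readthrough_loci: set[str]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "class_meth_delta": {k: list(v) for k, v in self.class_meth_delta.items()},
            "locus_expr_log2fc": self.locus_expr_log2fc,
            "readthrough_loci": sorted(self.readthrough_loci),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            class_meth_delta={k: tuple(v) for k, v in payload["class_meth_delta"].items()},
            locus_expr_log2fc=payload["locus_expr_log2fc"],
            readthrough_loci=set(payload["readthrough_loci"]),
        )


# ---------------------------------------------------------------------------
# scene constructors (named study conditions)

def default_config(seed: int = 0) -> SyntheticConfig:
    """Coupled scene: LTR+LINE+satellite hypomethylation, IAP activation."""
    return SyntheticConfig(seed=seed).validate()


def null_config(seed: int = 0) -> SyntheticConfig:
    """No planted methylation delta and no planted expression change."""
    cfg = SyntheticConfig(seed=seed)
    for cls in cfg.meth_prob:
        cfg.meth_prob[cls]["mutant"] = cfg.meth_prob[cls]["control"]
    cfg.expr_log2fc = {}
    cfg.readthrough_fraction = 0.0
    return cfg.validate()


def ltr_delta_config(seed: int = 0, control: float = 0.9,
                     mutant: float = 0.4) -> SyntheticConfig:
    """Single planted LTR-class methylation delta; all other classes null."""
    cfg = null_config(seed)
    cfg.meth_prob["LTR"] = {"control": control, "mutant": mutant}
    return cfg.validate()


def readthrough_config(seed: int = 0, fraction: float = 0.1) -> SyntheticConfig:
    """Coupled scene with a chosen read-through fraction."""
    cfg = SyntheticConfig(seed=seed)
    cfg.readthrough_fraction = fraction
    return cfg.validate()


# ---------------------------------------------------------------------------
# generation

def _name_budget(cls: str, n: int) -> list[tuple[str, str, int]]:
    """Apportion a class locus budget among its names (largest remainder)."""
    entries = [(fam, name, w) for c, fam, name, w in TAXONOMY if c == cls]
    if not entries:
        raise ConfigError(f"class {cls} not in the toy taxonomy")
    total_w = sum(w for _, _, w in entries)
    raw = [(fam, name, n * w / total_w) for fam, name, w in entries]
    counts = [int(x) for _, _, x in raw]
    remainders = sorted(
        range(len(raw)), key=lambda i: raw[i][2] - counts[i], reverse=True)
    for i in remainders[: n - sum(counts)]:
        counts[i] += 1
    return [(fam, name, k) for (fam, name, _), k in zip(raw, counts)]


def _place_interval(occupied: dict[str, list[tuple[int, int]]],
                    chroms: list[str], sizes: np.ndarray, probs: np.ndarray,
                    length: int, rng: np.random.Generator,
                    cls: str, max_tries: int = 200) -> tuple[str, int]:
    for _ in range(max_tries):
        ci = rng.choice(len(chroms), p=probs)
        chrom = chroms[ci]
        if sizes[ci] <= length:
            continue
        start = int(rng.integers(0, sizes[ci] - length))
        placed = occupied[chrom]
        i = bisect_left(placed, (start, start + length))
        if i > 0 and placed[i - 1][1] > start:
            continue
        if i < len(placed) and placed[i][0] < start + length:
            continue
        insort(placed, (start, start + length))
        return chrom, start
    raise PlacementError(
        f"could not place a {length} bp locus of class {cls}: "
        "chromosomes too small or too crowded")


def generate_annotation(config: SyntheticConfig,
                        rng: np.random.Generator | None = None,
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate non-overlapping repeat loci and a gene annotation.

    Raises :class:`PlacementError` naming the offending class when the
    requested loci cannot fit (checked up front by total length, then by
    bounded rejection sampling during placement).
    """
    config.validate()
    rng = rng or np.random.default_rng(config.seed)
    chroms = sorted(config.chrom_sizes)
    sizes = np.array([config.chrom_sizes[c] for c in chroms], dtype=float)
    probs = sizes / sizes.sum()
    genome = sizes.sum()

    lo, hi = config.locus_length_range
    mean_len = (lo + hi) / 2
    for cls in sorted(config.n_loci_per_class):
        if config.n_loci_per_class[cls] * lo > genome:
            raise PlacementError(
                f"class {cls}: total requested length exceeds the genome")
    if sum(config.n_loci_per_class.values()) * mean_len > 0.8 * genome:
        worst = max(config.n_loci_per_class, key=config.n_loci_per_class.get)
        raise PlacementError(
            f"requested loci cannot plausibly be placed (densest class: {worst})")

    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    rows = []
    for cls in sorted(config.n_loci_per_class):
        for fam, name, k in _name_budget(cls, config.n_loci_per_class[cls]):
            for _ in range(k):
                length = int(rng.integers(lo, hi + 1))
                chrom, start = _place_interval(
                    occupied, chroms, sizes, probs, length, rng, cls)
                strand = "+" if rng.random() < 0.5 else "-"
                rows.append({
                    "chrom": chrom, "start": start, "end": start + length,
                    "strand": strand, "rep_name": name, "rep_family": fam,
                    "rep_class": cls,
                    "locus_id": make_locus_id(chrom, start, start + length, name),
                })
    annotation = (
        pd.DataFrame(rows, columns=["chrom", "start", "end", "strand",
                                    "rep_name", "rep_family", "rep_class",
                                    "locus_id"])
        .sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    )

    gene_rows = []
    repeat_pool = annotation if len(annotation) else None
    for i in range(config.n_genes):
        if config.gene_offset_from_repeats is not None and repeat_pool is not None:
            anchor = repeat_pool.iloc[int(rng.integers(0, len(repeat_pool)))]
            start = int(anchor["end"]) + config.gene_offset_from_repeats
            chrom = anchor["chrom"]
            if start + config.gene_length > config.chrom_sizes[chrom]:
                start = max(0, int(anchor["start"]) - config.gene_offset_from_repeats
                            - config.gene_length)
        else:
            ci = rng.choice(len(chroms), p=probs)
            chrom = chroms[ci]
            start = int(rng.integers(0, config.chrom_sizes[chrom] - config.gene_length))
        gene_rows.append({
            "chrom": chrom, "start": start, "end": start + config.gene_length,
            "strand": "+" if rng.random() < 0.5 else "-",
            "gene_id": f"gene_{i}",
        })
    genes = pd.DataFrame(gene_rows, columns=GENE_COLUMNS)
    return annotation, genes


def place_ccgg_sites(annotation: pd.DataFrame, config: SyntheticConfig,
                     rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Scatter CCGG (HpaII/MspI) sites in repeats and the background.

    Returns one row per site: chrom, pos, locus_id (NaN outside repeats) and
    rep_class.  Per-locus counts are Poisson with mean length * ccgg_rate;
    background sites landing inside a repeat are dropped so containment is
    unambiguous.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    rows = []
    for row in annotation.itertuples(index=False):
        n = rng.poisson((row.end - row.start) * config.ccgg_rate / 1000)
        if n == 0:
            continue
        positions = np.unique(rng.integers(row.start, row.end, size=n))
        for pos in positions:
            rows.append((row.chrom, int(pos), row.locus_id, row.rep_class))
    # background
    starts = {c: s.to_numpy() for c, s in annotation.groupby("chrom")["start"]}
    ends = {c: s.to_numpy() for c, s in annotation.groupby("chrom")["end"]}
    for chrom in sorted(config.chrom_sizes):
        size = config.chrom_sizes[chrom]
        n = rng.poisson(size * config.ccgg_background_rate / 1000)
        if n == 0:
            continue
        positions = np.unique(rng.integers(0, size, size=n))
        if chrom in starts:
            idx = np.searchsorted(starts[chrom], positions, side="right") - 1
            inside = (idx >= 0) & (positions < ends[chrom][np.maximum(idx, 0)])
            positions = positions[~inside]
        for pos in positions:
            rows.append((chrom, int(pos), None, None))
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "locus_id", "rep_class"])
    return sites.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


def _site_meth_probs(sites: pd.DataFrame, config: SyntheticConfig,
                     genotype: str) -> np.ndarray:
    if genotype not in GENOTYPES:
        raise ConfigError(f"unknown genotype {genotype!r}")
    present = sites["rep_class"].dropna().unique()
    for cls in present:
        if cls not in config.meth_prob or genotype not in config.meth_prob[cls]:
            raise ConfigError(
                f"no methylation probability configured for class {cls}")
    mapping = {cls: config.meth_prob[cls][genotype] for cls in present}
    return (
        sites["rep_class"].map(mapping)
        .fillna(config.background_meth_prob[genotype])
        .to_numpy(dtype=float)
    )


def _empty_records() -> pd.DataFrame:
    return pd.DataFrame({
        "chrom": pd.Series(dtype=str), "start": pd.Series(dtype=int),
        "end": pd.Series(dtype=int), "strand": pd.Series(dtype=str),
        "locus_id": pd.Series(dtype=object),
    })


def _sample_tags(sites: pd.DataFrame, weights: np.ndarray, depth: int,
                 label: str, rng: np.random.Generator) -> TagSet:
    total = weights.sum()
    if total == 0 or depth == 0 or len(sites) == 0:
        return TagSet(label, _empty_records())
    counts = rng.multinomial(depth, weights / total)
    rep = np.repeat(np.arange(len(sites)), counts)
    sub = sites.iloc[rep]
    records = pd.DataFrame({
        "chrom": sub["chrom"].to_numpy(),
        "start": sub["pos"].to_numpy(),
        "end": sub["pos"].to_numpy() + 1,
        "strand": "+",
        "locus_id": sub["locus_id"].to_numpy(),
    })
    return TagSet(label, records)


def simulate_help_tags(sites: pd.DataFrame, config: SyntheticConfig,
                       genotype: str,
                       rng: np.random.Generator | None = None,
                       ) -> tuple[TagSet, TagSet]:
    """Draw the HpaII and MspI tag libraries for one genotype.

    Bulk DNA pools many cells, so a CCGG site is not simply "on" or "off":
    each sampled fragment at a site is methylated independently with the
    configured (class, genotype) probability.  Conditional on the fixed
    library budget, the HpaII library is therefore a multinomial over sites
    with weights proportional to ``1 - meth_prob`` (a fully methylated
    genome emits no HpaII tags at all), while the MspI control draws the
    same budget uniformly over all sites irrespective of methylation.  The
    per-class HpaII tag expectation is exactly
    ``depth * class_weight_share``, i.e. proportional to
    ``n_sites * (1 - meth_prob)``.
    """
    rng = rng or np.random.default_rng(config.seed + 2)
    probs = _site_meth_probs(sites, config, genotype)
    hpaii = _sample_tags(sites, 1.0 - probs, config.library_depth["hpaii"],
                         f"hpaii_{genotype}", rng)
    mspi = _sample_tags(sites, np.ones(len(sites)),
                        config.library_depth["mspi"], f"mspi_{genotype}", rng)
    return hpaii, mspi


def build_truth(annotation: pd.DataFrame, config: SyntheticConfig,
                rng: np.random.Generator | None = None) -> SyntheticTruth:
    """Record the planted truth for a generated annotation.

    Per-locus expression log2FCs come from the per-name config; read-through
    status is drawn for the configured fraction of expression-planted LTR
    loci (a read-through call is only observable at a locus whose transcript
    is differential, so unplanted loci are never selected).
    """
    rng = rng or np.random.default_rng(config.seed + 3)
    locus_lfc = {
        row.locus_id: config.expr_log2fc[row.rep_name]
        for row in annotation.itertuples(index=False)
        if row.rep_name in config.expr_log2fc and config.expr_log2fc[row.rep_name] != 0
    }
    candidates = [
        row.locus_id for row in annotation.itertuples(index=False)
        if row.locus_id in locus_lfc and row.rep_class == "LTR"
    ]
    n_rt = int(round(config.readthrough_fraction * len(candidates)))
    readthrough = set(
        rng.choice(candidates, size=n_rt, replace=False)) if n_rt else set()
    deltas = {
        cls: (probs["control"], probs["mutant"])
        for cls, probs in config.meth_prob.items()
    }
    return SyntheticTruth(deltas, locus_lfc, readthrough)


def simulate_rna_reads(annotation: pd.DataFrame, truth: SyntheticTruth,
                       config: SyntheticConfig, genotype: str,
                       rng: np.random.Generator | None = None,
                       genes: pd.DataFrame | None = None) -> TagSet:
    """Draw a strand-specific unique-read RNA library for one genotype.

    Per repeat locus, the read count is Poisson with mean
    ``base_expression * 2**(log2FC * [genotype == mutant])``; reads fall
    uniformly on the transcript span on the locus strand.  Read-through loci
    transcribe from ``readthrough_offset`` bp upstream through the locus;
    a transcript that would start before position 0 is skipped (logged).
    When ``genes`` is given, each gene additionally contributes Poisson
    ``gene_expression`` reads in both genotypes — the stable transcriptome
    bulk that anchors library totals.
    """
    if genotype not in GENOTYPES:
        raise ConfigError(f"unknown genotype {genotype!r}")
    rng = rng or np.random.default_rng(config.seed + 4)
    read_len = config.rna_read_length
    chunks = []
    for row in annotation.itertuples(index=False):
        lfc = truth.locus_expr_log2fc.get(row.locus_id, 0.0)
        mean = config.base_expression * (2.0 ** lfc if genotype == "mutant" else 1.0)
        if mean == 0:
            continue
        span_start, span_end = row.start, row.end
        if row.locus_id in truth.readthrough_loci:
            span_start = row.start - config.readthrough_offset
            if span_start < 0:
                log.warning("read-through transcript for %s starts before the "
                            "chromosome; locus skipped", row.locus_id)
                continue
        n = rng.poisson(mean)
        if n == 0:
            continue
        hi = max(span_start + 1, span_end - read_len)
        starts = rng.integers(span_start, hi, size=n)
        chunks.append(pd.DataFrame({
            "chrom": row.chrom, "start": starts,
            "end": np.minimum(starts + read_len, span_end),
            "strand": row.strand, "locus_id": row.locus_id,
        }))
    if genes is not None and config.gene_expression > 0:
        for row in genes.itertuples(index=False):
            n = rng.poisson(config.gene_expression)
            if n == 0:
                continue
            hi = max(row.start + 1, row.end - read_len)
            starts = rng.integers(row.start, hi, size=n)
            chunks.append(pd.DataFrame({
                "chrom": row.chrom, "start": starts,
                "end": np.minimum(starts + read_len, row.end),
                "strand": row.strand, "locus_id": None,
            }))
    if chunks:
        records = pd.concat(chunks, ignore_index=True)
    else:
        records = _empty_records()
    return TagSet(f"rna_{genotype}", records)


@dataclass
class Scene:
    """A complete simulated experiment: annotation, sites, libraries, truth."""

    config: SyntheticConfig
    annotation: pd.DataFrame
    genes: pd.DataFrame
    sites: pd.DataFrame
    truth: SyntheticTruth
    tags: dict[str, TagSet]


def simulate_scene(config: SyntheticConfig | None = None,
                   seed: int | None = None) -> Scene:
    """Generate a full scene (annotation, CCGG sites, six libraries, truth).

    ``seed`` overrides ``config.seed``.  All randomness flows from a single
    generator so a fixed seed reproduces the scene byte for byte.
    """
    config = (config or SyntheticConfig()).validate()
    if seed is not None:
        config = dataclasses.replace(config, seed=seed)
    rng = np.random.default_rng(config.seed)
    annotation, genes = generate_annotation(config, rng)
    sites = place_ccgg_sites(annotation, config, rng)
    truth = build_truth(annotation, config, rng)
    tags: dict[str, TagSet] = {}
    for genotype in GENOTYPES:
        hpaii, mspi = simulate_help_tags(sites, config, genotype, rng)
        tags[f"hpaii_{genotype}"] = hpaii
        tags[f"mspi_{genotype}"] = mspi
        tags[f"rna_{genotype}"] = simulate_rna_reads(
            annotation, truth, config, genotype, rng, genes=genes)
    return Scene(config, annotation, genes, sites, truth, tags)


def write_scene(scene: Scene, outdir: str | Path) -> dict[str, Path]:
    """Write a scene to disk (RepeatMasker .out, BED, truth JSON, config echo)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["repeats_out"] = outdir / "repeats.out"
    write_repeatmasker_out(scene.annotation, paths["repeats_out"])
    paths["repeats_bed"] = outdir / "repeats.bed"
    write_bed(scene.annotation, paths["repeats_bed"])
    paths["genes_bed"] = outdir / "genes.bed"
    write_bed(scene.genes, paths["genes_bed"])
    for label, tagset in scene.tags.items():
        paths[label] = outdir / f"{label}.bed"
        write_bed(tagset, paths[label])
    paths["truth"] = outdir / "truth.json"
    scene.truth.to_json(paths["truth"])
    paths["config"] = outdir / "config.json"
    paths["config"].write_text(
        json.dumps(scene.config.to_dict(), indent=1, sort_keys=True))
    return paths
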