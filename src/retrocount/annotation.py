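"""Repeat and gene annotation I/O, tag-to-locus assignment and interval arithmetic.

All coordinates are 0-based half-open internally (the BED convention).
RepeatMasker ``.out`` files use 1-based inclusive query coordinates and are
converted on read and write, so a round trip through either dialect is the
identity on the internal representation.

A repeat annotation is a :class:`pandas.DataFrame` with the columns listed in
:data:`REPEAT_COLUMNS`; the ``locus_id`` (``chrom:start-end:name``) is the
stable per-locus key used by every downstream table.
"""
from __future__ import annotations

import logging
from bisect import insort
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

log = logging.getLogger(__name__)

REPEAT_COLUMNS = [
    "chrom", "start", "end", "strand",
    "rep_name", "rep_family", "rep_class", "locus_id",
]
GENE_COLUMNS = ["chrom", "start", "end", "strand", "gene_id"]
TAG_COLUMNS = ["chrom", "start", "end", "strand"]

#: Classes that are excluded from class-level differential tests by default.
#: These compartments are largely unmethylated in wild-type somatic cells, so
#: an HpaII-representation contrast carries no methylation signal for them.
LOW_COMPLEXITY_CLASSES = frozenset({"Low_complexity", "Simple_repeat"})


class ParseError(ValueError):
    """Raised for malformed annotation / alignment input."""


def make_locus_id(chrom: str, start: int, end: int, name: str) -> str:
    return f"{chrom}:{start}-{end}:{name}"


@dataclass
class TagSet:
    """Uniquely-mapped tag/read coordinates for one sequencing library.

    ``records`` holds one row per tag with columns chrom/start/end/strand and,
    for synthetic libraries, optionally the generating ``locus_id``.
    """

    library_label: str
    records: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in TAG_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"TagSet records missing columns {missing}")
        self.records = self.records.reset_index(drop=True)

    @property
    def total_count(self) -> int:
        return len(self.records)


def _split_class_family(token: str) -> tuple[str, str]:
    """Split a RepeatMasker class/family token; family defaults to class."""
    parts = token.split("/")
    rep_class = parts[0]
    rep_family = parts[1] if len(parts) > 1 else rep_class
    return rep_class, rep_family


def _finalise_repeat_frame(rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=REPEAT_COLUMNS)
    if df["locus_id"].duplicated().any():
        dup = df.loc[df["locus_id"].duplicated(), "locus_id"].iloc[0]
        raise ParseError(f"duplicate locus_id in annotation: {dup}")
    return df


def parse_repeatmasker_out(path: str | Path) -> pd.DataFrame:
    """Parse a RepeatMasker ``.out`` file into a repeat annotation frame.

    The standard layout has three header lines followed by whitespace-
    delimited records; query coordinates (columns 6-7, 1-based inclusive) are
    converted to 0-based half-open.  Strand ``C`` (complement) maps to ``-``.
    """
    rows: list[dict] = []
    with open(path) as fh:
        lines = fh.readlines()
    for lineno, line in enumerate(lines[3:], start=4):
        if not line.strip():
            continue
        parts = line.split()
        if not 14 <= len(parts) <= 16:
            raise ParseError(
                f"{path}:{lineno}: expected 14-16 whitespace-delimited "
                f"columns, found {len(parts)}"
            )
        try:
            begin, end = int(parts[5]), int(parts[6])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
        start = begin - 1
        if not start < end:
            raise ParseError(f"{path}:{lineno}: begin must be <= end")
        chrom = parts[4]
        strand = "-" if parts[8] in {"C", "-"} else "+"
        rep_name = parts[9]
        rep_class, rep_family = _split_class_family(parts[10])
        rows.append({
            "chrom": chrom, "start": start, "end": end, "strand": strand,
            "rep_name": rep_name, "rep_family": rep_family,
            "rep_class": rep_class,
            "locus_id": make_locus_id(chrom, start, end, rep_name),
        })
    return _finalise_repeat_frame(rows)


def write_repeatmasker_out(annotation: pd.DataFrame, path: str | Path) -> None:
    """Write a repeat annotation in the 15-column ``.out`` dialect.

    Alignment statistics (score, divergence, deletion, insertion, repeat-side
    coordinates) are not modelled and are written as placeholders.
    """
    header = (
        "   SW  perc perc perc  query      position in query           matching"
        "       repeat              position in  repeat\n"
        "score  div. del. ins.  sequence    begin     end    (left)    repeat"
        "         class/family         begin  end (left)   ID\n\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for i, row in enumerate(annotation.itertuples(index=False), start=1):
            cls = (
                row.rep_class
                if row.rep_family == row.rep_class
                else f"{row.rep_class}/{row.rep_family}"
            )
            strand = "C" if row.strand == "-" else "+"
            length = row.end - row.start
            fh.write(
                f"  100  0.0  0.0  0.0  {row.chrom} {row.start + 1} {row.end}"
                f" (0) {strand} {row.rep_name} {cls} 1 {length} (0) {i}\n"
            )


def parse_bed(path: str | Path, kind: str = "repeat",
              library_label: str | None = None):
    """Parse a BED3-BED6 file.

    ``kind`` selects the output object: ``"repeat"`` and ``"genes"`` return
    annotation frames, ``"tags"`` returns a :class:`TagSet`.  Strand defaults
    to ``+`` when the file has fewer than six columns.  For repeats the name
    column is read as a ``class/family/name`` triple (missing levels default
    to the level above).
    """
    if kind not in {"repeat", "genes", "tags"}:
        raise ValueError(f"unknown BED kind {kind!r}")
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: fewer than 3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ParseError(f"{path}:{lineno}: start >= end")
            name = parts[3] if len(parts) > 3 else "."
            strand = parts[5] if len(parts) > 5 and parts[5] in {"+", "-"} else "+"
            rows.append((parts[0], start, end, name, strand))

    if kind == "tags":
        records = pd.DataFrame(
            [(c, s, e, st) for c, s, e, _n, st in rows], columns=TAG_COLUMNS
        )
        return TagSet(library_label or str(path), records)
    if kind == "genes":
        out = [
            {"chrom": c, "start": s, "end": e, "strand": st,
             "gene_id": n if n != "." else f"gene_{i}"}
            for i, (c, s, e, n, st) in enumerate(rows)
        ]
        return pd.DataFrame(out, columns=GENE_COLUMNS)

    out = []
    for c, s, e, n, st in rows:
        parts = n.split("/")
        rep_class = parts[0]
        rep_family = parts[1] if len(parts) > 1 else rep_class
        rep_name = parts[2] if len(parts) > 2 else rep_family
        out.append({
            "chrom": c, "start": s, "end": e, "strand": st,
            "rep_name": rep_name, "rep_family": rep_family,
            "rep_class": rep_class,
            "locus_id": make_locus_id(c, s, e, rep_name),
        })
    return _finalise_repeat_frame(out)


def write_bed(obj, path: str | Path) -> None:
    """Write a repeat/gene annotation frame or a TagSet as BED6."""
    if isinstance(obj, TagSet):
        df = obj.records
        names = pd.Series([obj.library_label] * len(df))
    elif "locus_id" in obj.columns:
        df = obj
        names = (
            df["rep_class"].where(df["rep_class"] == df["rep_family"],
                                  df["rep_class"] + "/" + df["rep_family"])
            + "/" + df["rep_name"]
        )
    else:
        df = obj
        names = df["gene_id"]
    with open(path, "w") as fh:
        for (chrom, start, end, strand), name in zip(
            df[["chrom", "start", "end", "strand"]].itertuples(index=False),
            names,
        ):
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t0\t{strand}\n")


def filter_unique_reads(path: str | Path, min_mapq: int = 20,
                        require_single_hit: bool = True,
                        library_label: str | None = None) -> TagSet:
    """Load uniquely-mapped reads from SAM (filtered) or BED (pass-through).

    For SAM input, primary mapped alignments are kept when their MAPQ is at
    least ``min_mapq`` and, when ``require_single_hit`` and an ``NH`` tag is
    present, the reported hit count is 1.  BED input is assumed pre-filtered.
    """
    path = Path(path)
    if path.suffix.lower() != ".sam":
        return parse_bed(path, kind="tags", library_label=library_label)

    import pysam

    kept, dropped = [], 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for read in sam:
            if (read.is_unmapped or read.is_secondary or read.is_supplementary):
                dropped += 1
                continue
            if read.mapping_quality < min_mapq:
                dropped += 1
                continue
            if require_single_hit and read.has_tag("NH") and read.get_tag("NH") != 1:
                dropped += 1
                continue
            kept.append((
                read.reference_name, read.reference_start,
                read.reference_end, "-" if read.is_reverse else "+",
            ))
    if not kept and dropped:
        raise ParseError(f"{path}: no usable mapped alignments")
    log.info("filter_unique_reads(%s): kept %d, dropped %d", path, len(kept), dropped)
    return TagSet(library_label or path.stem,
                  pd.DataFrame(kept, columns=TAG_COLUMNS))


class LocusIndex:
    """Interval index over an annotation for tag-to-locus assignment.

    Overlap requires >=1 bp; multi-overlaps resolve to the largest overlap,
    ties to the leftmost (then shortest) locus, a deterministic convention.
    """

    def __init__(self, annotation: pd.DataFrame):
        self.trees: dict[str, IntervalTree] = {}
        self.annotation = annotation
        for chrom, sub in annotation.groupby("chrom", sort=False):
            tree = IntervalTree()
            for row in sub.itertuples(index=False):
                tree.addi(row.start, row.end, (row.start, row.end, row.locus_id))
            self.trees[chrom] = tree

    def assign(self, chrom: str, start: int, end: int) -> str | None:
        tree = self.trees.get(chrom)
        if tree is None:
            return None
        hits = tree.overlap(start, end)
        if not hits:
            return None
        best = min(
            hits,
            key=lambda iv: (
                -(min(end, iv.end) - max(start, iv.begin)),
                iv.begin, iv.end, iv.data[2],
            ),
        )
        return best.data[2]


def _assign_chrom_sorted(r_start: np.ndarray, r_end: np.ndarray,
                         s: np.ndarray, e: np.ndarray,
                         ids: np.ndarray) -> np.ndarray:
    """Vectorised assignment against sorted *non-overlapping* intervals.

    With non-overlapping intervals the candidates overlapping a read form a
    contiguous run [j0, j1); reads rarely span more than two intervals, so
    the two boundary candidates are compared vectorised (largest overlap,
    ties to the leftmost) and longer spans fall back to a scalar scan.
    """
    out = np.full(len(r_start), None, dtype=object)
    j1 = np.searchsorted(s, r_end, side="left")
    j0 = np.searchsorted(e, r_start, side="right")
    span = j1 - j0

    two = span >= 1
    idx_a = j0[two]
    idx_b = np.minimum(j0[two] + 1, j1[two] - 1)
    ra, re = r_start[two], r_end[two]
    ov_a = np.minimum(re, e[idx_a]) - np.maximum(ra, s[idx_a])
    ov_b = np.minimum(re, e[idx_b]) - np.maximum(ra, s[idx_b])
    pick_b = (idx_b != idx_a) & (ov_b > ov_a)
    out[np.flatnonzero(two)] = np.where(pick_b, ids[idx_b], ids[idx_a])

    for i in np.flatnonzero(span > 2):
        cands = range(j0[i], j1[i])
        best = min(cands, key=lambda j: (
            -(min(r_end[i], e[j]) - max(r_start[i], s[j])), s[j], e[j], ids[j]))
        out[i] = ids[best]
    return out


def assign_tags(tags: TagSet | pd.DataFrame, annotation: pd.DataFrame,
                index: LocusIndex | None = None) -> pd.Series:
    """Assign each tag to the repeat locus it overlaps (or ``None``).

    Returns an object Series aligned to the tag records.  Tags on
    chromosomes absent from the annotation are unassigned (logged once per
    chromosome).  Chromosomes whose annotated intervals do not overlap one
    another take a vectorised sorted-array path; overlapping annotations
    (nested RepeatMasker records) go through the interval tree with the same
    largest-overlap/leftmost tie rule.
    """
    records = tags.records if isinstance(tags, TagSet) else tags
    out = pd.Series(None, index=records.index, dtype=object)

    ann_by_chrom = {}
    for chrom, sub in annotation.groupby("chrom", sort=False):
        order = np.argsort(sub["start"].to_numpy(), kind="stable")
        s = sub["start"].to_numpy()[order]
        e = sub["end"].to_numpy()[order]
        ids = sub["locus_id"].to_numpy(dtype=object)[order]
        non_overlapping = bool((s[1:] >= e[:-1]).all()) if len(s) > 1 else True
        ann_by_chrom[chrom] = (s, e, ids, non_overlapping)

    for chrom, sub in records.groupby("chrom", sort=False):
        if chrom not in ann_by_chrom:
            log.warning("chromosome %s absent from annotation; tags unassigned", chrom)
            continue
        s, e, ids, non_overlapping = ann_by_chrom[chrom]
        r_start = sub["start"].to_numpy()
        r_end = sub["end"].to_numpy()
        if non_overlapping:
            out.loc[sub.index] = _assign_chrom_sorted(r_start, r_end, s, e, ids)
        else:
            if index is None:
                index = LocusIndex(annotation)
            out.loc[sub.index] = [
                index.assign(chrom, rs, re) for rs, re in zip(r_start, r_end)
            ]
    return out.where(out.notna(), None)


def shift_windows(annotation: pd.DataFrame, offset_bp: int, direction: str,
                  chrom_sizes: Mapping[str, int] | None = None,
                  repeats: pd.DataFrame | None = None,
                  strand_aware: bool = False) -> pd.DataFrame:
    """Shift each locus by ``offset_bp`` up- or downstream, width preserved.

    Up/downstream is in reference (plus-strand) orientation unless
    ``strand_aware`` is set, in which case the shift is reversed for minus-
    strand loci.  Windows that leave chromosome bounds are dropped (logged).
    Each surviving window carries ``neighbour_repeat``: whether it overlaps
    any interval of ``repeats`` (default: the input annotation), the control
    used to discount shifted-window signal explained by an adjacent repeat.
    """
    if offset_bp <= 0:
        raise ValueError("offset_bp must be positive")
    if direction not in {"upstream", "downstream"}:
        raise ValueError(f"direction must be upstream/downstream, got {direction!r}")
    sign = -1 if direction == "upstream" else 1
    signs = np.full(len(annotation), sign)
    if strand_aware:
        signs = np.where(annotation["strand"].to_numpy() == "-", -sign, sign)

    shifted = annotation.copy()
    shifted["start"] = annotation["start"].to_numpy() + signs * offset_bp
    shifted["end"] = annotation["end"].to_numpy() + signs * offset_bp

    keep = shifted["start"] >= 0
    if chrom_sizes is not None:
        bounds = shifted["chrom"].map(chrom_sizes)
        keep &= shifted["end"] <= bounds
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.info("shift_windows: dropped %d windows leaving chromosome bounds", n_dropped)
    shifted = shifted.loc[keep].reset_index(drop=True)

    flag_index = LocusIndex(repeats if repeats is not None else annotation)
    flags = [
        flag_index.assign(c, s, e) is not None
        for c, s, e in shifted[["chrom", "start", "end"]].itertuples(index=False)
    ]
    shifted["neighbour_repeat"] = flags
    return shifted


def distance_to_nearest_gene(annotation: pd.DataFrame,
                             genes: pd.DataFrame) -> pd.Series:
    """Distance (bp) from each repeat locus to its nearest gene.

    0 when overlapping, otherwise the minimum gap between interval ends;
    NaN for loci on chromosomes with no annotated gene.
    """
    if annotation.empty or genes.empty:
        raise ValueError("annotation and gene sets must be non-empty")
    result = pd.Series(np.nan, index=annotation["locus_id"], dtype=float)
    by_chrom = {}
    for chrom, sub in genes.groupby("chrom", sort=False):
        order = np.argsort(sub["start"].to_numpy(), kind="stable")
        gs = sub["start"].to_numpy()[order]
        ge = sub["end"].to_numpy()[order]
        by_chrom[chrom] = (gs, np.maximum.accumulate(ge))
    for row in annotation.itertuples(index=False):
        if row.chrom not in by_chrom:
            continue
        gs, cummax_ge = by_chrom[row.chrom]
        i = np.searchsorted(gs, row.end, side="left")
        best = np.inf
        if i > 0:
            left_end = cummax_ge[i - 1]
            best = 0.0 if left_end > row.start else row.start - left_end
        if i < len(gs) and best > 0:
            best = min(best, gs[i] - row.end)
        result.loc[row.locus_id] = best
    return result
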