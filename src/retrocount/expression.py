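"""Per-locus repeat expression from unique RNA reads, differential tests and
the shifted-window read-through control.

Counting reuses the overlap and tie-break rules of tag-to-locus assignment.
Differential expression between two conditions uses a conditional exact
binomial test: given the per-locus total n = m + c, the mutant count m is
binomial with success probability N_m/(N_m+N_c) under the null of equal
normalised expression (a negative-binomial exact test in the limit of zero
dispersion).  Two-sided p doubles the smaller tail, capped at 1.  Fold-change
distributions are summarised as Gaussian kernel densities with tail masses
beyond the +-5 log2 thresholds computed on the raw values.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import binom

from .annotation import TagSet, assign_tags, shift_windows
from .methylation import benjamini_hochberg

log = logging.getLogger(__name__)

STRAND_MODES = ("ignore", "sense", "antisense", "split")


def count_expression(reads: Mapping[str, TagSet], annotation: pd.DataFrame,
                     strand_mode: str = "ignore") -> pd.DataFrame:
    """Per-locus unique-read counts for each condition.

    ``reads`` maps condition label -> TagSet.  ``strand_mode`` controls how
    read strand relates to the annotated locus strand: ``ignore`` counts all
    overlapping reads, ``sense``/``antisense`` count only matching/opposite
    reads, and ``split`` counts all while also reporting per-condition
    ``sense_*``/``antisense_*`` columns (read strand is taken as transcript
    strand; conversion from dUTP library flags is a pre-processing step).
    """
    if strand_mode not in STRAND_MODES:
        raise ValueError(f"strand_mode must be one of {STRAND_MODES}")
    locus_strand = pd.Series(
        annotation["strand"].to_numpy(), index=annotation["locus_id"]
    )
    out = pd.DataFrame(index=pd.Index(annotation["locus_id"], name="locus_id"))
    for cond, tagset in reads.items():
        assignment = assign_tags(tagset, annotation)
        assigned = assignment.dropna()
        read_strand = tagset.records.loc[assigned.index, "strand"]
        same = read_strand.to_numpy() == assigned.map(locus_strand).to_numpy()
        if strand_mode == "sense":
            counted = assigned[same]
        elif strand_mode == "antisense":
            counted = assigned[~same]
        else:
            counted = assigned
        out[f"count_{cond}"] = (
            counted.value_counts().reindex(out.index, fill_value=0).astype(int)
        )
        if strand_mode == "split":
            out[f"sense_{cond}"] = (
                assigned[same].value_counts().reindex(out.index, fill_value=0).astype(int)
            )
            out[f"antisense_{cond}"] = (
                assigned[~same].value_counts().reindex(out.index, fill_value=0).astype(int)
            )
    if strand_mode == "split":
        sense_cols = [c for c in out.columns if c.startswith("sense_")]
        anti_cols = [c for c in out.columns if c.startswith("antisense_")]
        out["strand_sense"] = out[sense_cols].sum(axis=1)
        out["strand_antisense"] = out[anti_cols].sum(axis=1)
    return out.reset_index()


def binom_two_sided(k, n, p) -> np.ndarray:
    """Two-sided exact binomial p: double the smaller tail, capped at 1."""
    k = np.asarray(k, dtype=np.int64)
    n = np.asarray(n, dtype=np.int64)
    lower = binom.cdf(k, n, p)
    upper = binom.sf(k - 1, n, p)
    out = np.minimum(1.0, 2.0 * np.minimum(lower, upper))
    return np.where(n == 0, 1.0, out)


def differential_expression(counts: pd.DataFrame,
                            library_sizes: Mapping[str, int],
                            control: str = "control", mutant: str = "mutant",
                            min_total: int = 5) -> pd.DataFrame:
    """Per-locus differential expression records between two conditions.

    ``norm_log2fc = log2(((m+0.5)/N_m) / ((c+0.5)/N_c))``.  The exact
    binomial p conditions on the per-locus total; BH correction runs over
    informative loci only (total count >= ``min_total``; others get NaN).
    """
    n_c, n_m = library_sizes[control], library_sizes[mutant]
    if n_c <= 0 or n_m <= 0:
        raise ValueError("library sizes must be positive")
    out = counts.copy()
    c = out[f"count_{control}"].to_numpy()
    m = out[f"count_{mutant}"].to_numpy()
    out["norm_log2fc"] = np.log2(((m + 0.5) / n_m) / ((c + 0.5) / n_c))
    out["p_value"] = binom_two_sided(m, m + c, n_m / (n_m + n_c))
    out["informative"] = (m + c) >= min_total
    out["p_bh"] = np.nan
    informative = out["informative"].to_numpy()
    if informative.any():
        out.loc[informative, "p_bh"] = benjamini_hochberg(
            out.loc[informative, "p_value"].to_numpy()
        )
    return out


@dataclass
class DensitySummary:
    """Kernel density of fold changes plus tail mass beyond the thresholds."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    frac_above: float
    frac_below: float
    histogram_fallback: bool = False


def _silverman_bandwidth(x: np.ndarray) -> float:
    n = len(x)
    sd = np.std(x, ddof=1) if n > 1 else 0.0
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    return 0.9 * spread * n ** (-1 / 5)


def fold_change_density(records: pd.DataFrame | np.ndarray,
                        subset: pd.Series | np.ndarray | None = None,
                        bandwidth: float | str = "silverman",
                        thresholds: tuple[float, float] = (-5.0, 5.0),
                        gridsize: int = 512) -> DensitySummary:
    """Gaussian KDE over per-locus log2 fold changes.

    ``frac_above``/``frac_below`` are the fractions of raw values beyond the
    upper/lower threshold (not mass under the smoothed curve).  When the
    values are all identical the density degenerates and a normalised
    histogram is returned instead (logged).
    """
    values = (records["norm_log2fc"].to_numpy()
              if isinstance(records, pd.DataFrame) else np.asarray(records, float))
    if subset is not None:
        values = values[np.asarray(subset, dtype=bool)]
    if len(values) == 0:
        raise ValueError("subset is empty")
    lo, hi = thresholds
    frac_above = float(np.mean(values > hi))
    frac_below = float(np.mean(values < lo))

    h = _silverman_bandwidth(values) if bandwidth == "silverman" else float(bandwidth)
    if not np.isfinite(h) or h <= 0:
        log.info("degenerate fold-change values; falling back to histogram")
        span = max(1.0, abs(values[0]))
        grid = np.linspace(values.min() - span, values.max() + span, gridsize)
        density, edges = np.histogram(values, bins=gridsize - 1,
                                      range=(grid[0], grid[-1]), density=True)
        centres = (edges[:-1] + edges[1:]) / 2
        return DensitySummary(centres, density, 0.0, frac_above, frac_below, True)

    grid = np.linspace(values.min() - 4 * h, values.max() + 4 * h, gridsize)
    z = (grid[:, None] - values[None, :]) / h
    density = np.exp(-0.5 * z ** 2).sum(axis=1) / (len(values) * h * np.sqrt(2 * np.pi))
    return DensitySummary(grid, density, h, frac_above, frac_below)


def activation_fraction(records: pd.DataFrame,
                        subset: pd.Series | np.ndarray | None = None,
                        direction_threshold: float = 0.0) -> float:
    """Fraction of informative loci with norm_log2fc above the threshold.

    NaN when no informative locus is in scope (reported missing).
    """
    df = records
    if subset is not None:
        df = df.loc[np.asarray(subset, dtype=bool)]
    if "informative" in df.columns:
        df = df[df["informative"]]
    if df.empty:
        return float("nan")
    return float((df["norm_log2fc"] > direction_threshold).mean())


def strand_bias_test(sense: int, antisense: int) -> float:
    """Two-sided exact binomial test of sense vs antisense counts vs 0.5."""
    return float(binom_two_sided(sense, sense + antisense, 0.5))


def readthrough_control(reads: Mapping[str, TagSet], annotation: pd.DataFrame,
                        offset: int = 10_000, alpha: float = 0.05,
                        min_total: int = 5,
                        control: str = "control", mutant: str = "mutant",
                        chrom_sizes: Mapping[str, int] | None = None,
                        loci: pd.DataFrame | None = None) -> pd.DataFrame:
    """Body vs +-``offset`` shifted-window differential expression per locus.

    Differential expression is computed independently on the locus body and
    on width-matched windows shifted ``offset`` bp up- and downstream.  Each
    window records whether it overlaps any annotated repeat
    (``up_flagged``/``down_flagged``); flagged windows are discounted, since
    signal there is explained by the neighbouring repeat rather than by
    transcription running into the locus.  Classification per locus:

    - ``read_through``: upstream window significant and unflagged,
    - ``autonomous``: body significant, upstream window not significant or
      flagged,
    - ``ambiguous``: body significant but the downstream window is
      significant and unflagged,
    - ``none`` otherwise.
    """
    if loci is None:
        loci = annotation[annotation["rep_class"] == "LTR"].reset_index(drop=True)
    sizes = {cond: ts.total_count for cond, ts in reads.items()}

    def _diff(intervals: pd.DataFrame) -> pd.DataFrame:
        counts = count_expression(reads, intervals)
        return differential_expression(counts, sizes, control=control,
                                       mutant=mutant, min_total=min_total)

    body = _diff(loci).set_index("locus_id")
    out = loci[["locus_id", "rep_class", "rep_family", "rep_name"]].copy()
    out = out.set_index("locus_id")
    out["body_log2fc"] = body["norm_log2fc"]
    out["body_p_bh"] = body["p_bh"]

    for direction, prefix in (("upstream", "up"), ("downstream", "down")):
        windows = shift_windows(loci, offset, direction,
                                chrom_sizes=chrom_sizes, repeats=annotation)
        diff = _diff(windows).set_index("locus_id")
        out[f"{prefix}_log2fc"] = diff["norm_log2fc"]
        out[f"{prefix}_p_bh"] = diff["p_bh"]
        out[f"{prefix}_flagged"] = (
            windows.set_index("locus_id")["neighbour_repeat"]
            .reindex(out.index)
        )

    body_sig = out["body_p_bh"] < alpha
    up_sig = out["up_p_bh"] < alpha
    down_sig = out["down_p_bh"] < alpha
    up_clean = up_sig & (out["up_flagged"] == False)  # noqa: E712 (NaN-safe)
    down_clean = down_sig & (out["down_flagged"] == False)  # noqa: E712

    classification = np.where(
        up_clean, "read_through",
        np.where(body_sig & down_clean, "ambiguous",
                 np.where(body_sig, "autonomous", "none")),
    )
    out["classification"] = classification
    return out.reset_index()
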