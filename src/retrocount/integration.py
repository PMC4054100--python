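"""Join per-locus methylation and expression differentials and summarise.

The joined table puts expression log2 fold change on one axis and the
methylation change on the other.  Note the sign convention: per-locus HELP
statistics are fold changes in HpaII *tag abundance* (positive = more tags =
less methylation); here ``meth_log2fc`` is reported in *methylation*
direction, i.e. the negated tag fold change, so hypomethylated loci sit below
zero.  Quadrants are assigned against the +-5 (expression) and +-1
(methylation) log2 thresholds used throughout the downstream summaries.
"""
from __future__ import annotations

import itertools
import logging
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

log = logging.getLogger(__name__)


def repeat_group(rep_class: str, rep_name: str) -> str:
    """Biological grouping used in the summaries: IAP LTRs vs other LTRs vs
    each remaining repeat class."""
    if rep_class == "LTR":
        return "IAP LTR" if rep_name.startswith("IAP") else "non-IAP LTR"
    return rep_class


def _quadrant(meth: float, expr: float, meth_thresh: float,
              expr_thresh: float) -> str:
    meth_cat = "hypo" if meth < -meth_thresh else ("hyper" if meth > meth_thresh else None)
    expr_cat = "up" if expr > expr_thresh else ("down" if expr < -expr_thresh else None)
    if meth_cat is None and expr_cat is None:
        return "null"
    return f"{meth_cat or 'null'}+{expr_cat or 'null'}"


def join_loci(meth: pd.DataFrame, expr: pd.DataFrame,
              expr_thresh: float = 5.0, meth_thresh: float = 1.0,
              distances: pd.Series | None = None) -> pd.DataFrame:
    """Inner join of methylation and expression differentials on locus_id.

    ``meth_log2fc`` is the methylation-direction fold change (minus the HpaII
    tag fold change of the input).  Unmatched loci are counted and logged,
    never imputed.  Duplicate locus_ids in either input are an error.
    """
    for name, df in (("methylation", meth), ("expression", expr)):
        if df["locus_id"].duplicated().any():
            raise ValueError(f"duplicate locus_id in {name} table")
    m = meth.rename(columns={
        "norm_log2fc": "help_log2fc", "p_value": "meth_p", "p_bh": "meth_p_bh",
    })
    e = expr.rename(columns={
        "norm_log2fc": "expr_log2fc", "p_value": "expr_p", "p_bh": "expr_p_bh",
    })
    keep_m = ["locus_id", "help_log2fc", "meth_p", "meth_p_bh"] + [
        c for c in ("rep_class", "rep_family", "rep_name", "mspi_pass") if c in m.columns
    ]
    keep_e = ["locus_id", "expr_log2fc", "expr_p", "expr_p_bh"] + (
        ["informative"] if "informative" in e.columns else []
    )
    joined = m[keep_m].merge(e[keep_e], on="locus_id", how="inner")
    n_m_only = len(m) - len(joined)
    n_e_only = len(e) - len(joined)
    if n_m_only or n_e_only:
        log.info("join_loci: %d methylation-only and %d expression-only loci dropped",
                 n_m_only, n_e_only)
    joined["meth_log2fc"] = -joined["help_log2fc"]
    joined["quadrant"] = [
        _quadrant(mv, ev, meth_thresh, expr_thresh)
        for mv, ev in zip(joined["meth_log2fc"], joined["expr_log2fc"])
    ]
    if distances is not None:
        joined["distance_to_gene"] = joined["locus_id"].map(distances)
    return joined


def quadrant_counts(joined: pd.DataFrame) -> pd.Series:
    return joined["quadrant"].value_counts().sort_index()


def _box_stats(values: np.ndarray) -> dict:
    if len(values) == 0:
        return {"n": 0, "median": np.nan, "q1": np.nan, "q3": np.nan,
                "whisker_lo": np.nan, "whisker_hi": np.nan, "n_outliers": 0}
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = values[(values >= lo_fence) & (values <= hi_fence)]
    return {
        "n": len(values), "median": med, "q1": q1, "q3": q3,
        "whisker_lo": inside.min(), "whisker_hi": inside.max(),
        "n_outliers": int(len(values) - len(inside)),
    }


def conditional_summary(joined: pd.DataFrame,
                        condition: str = "hypomethylated",
                        alpha: float = 0.05,
                        use_bh: bool = False) -> pd.DataFrame:
    """Boxplot-style summary of one assay conditioned on the other.

    ``condition="hypomethylated"`` keeps loci with a significant methylation
    loss (raw p by default, matching the published "(P < 0.05)" filter; BH
    behind ``use_bh``) and summarises their expression fold changes per
    repeat group.  ``condition="upregulated"`` is the reciprocal: significant
    expression gains, summarising methylation fold changes.
    """
    if condition == "hypomethylated":
        p = joined["meth_p_bh"] if use_bh else joined["meth_p"]
        mask = (p < alpha) & (joined["meth_log2fc"] < 0)
        response = "expr_log2fc"
    elif condition == "upregulated":
        p = joined["expr_p_bh"] if use_bh else joined["expr_p"]
        mask = (p < alpha) & (joined["expr_log2fc"] > 0)
        response = "meth_log2fc"
    else:
        raise ValueError("condition must be 'hypomethylated' or 'upregulated'")
    groups = joined.apply(
        lambda r: repeat_group(r["rep_class"], r["rep_name"]), axis=1
    ) if len(joined) else pd.Series(dtype=object)
    rows = []
    for group in sorted(groups.unique()) if len(joined) else []:
        vals = joined.loc[mask & (groups == group), response].dropna().to_numpy()
        rows.append({"group": group, **_box_stats(vals)})
    return pd.DataFrame(
        rows, columns=["group", "n", "median", "q1", "q3",
                       "whisker_lo", "whisker_hi", "n_outliers"])


def overlap_upregulated(sets: Mapping[str, set]) -> pd.DataFrame:
    """Pairwise intersection/union counts and Jaccard indices of locus sets."""
    if len(sets) < 2:
        raise ValueError("need at least two sets to overlap")
    rows = []
    for (la, sa), (lb, sb) in itertools.combinations(sets.items(), 2):
        inter, union = len(sa & sb), len(sa | sb)
        rows.append({
            "set_a": la, "set_b": lb, "n_a": len(sa), "n_b": len(sb),
            "intersection": inter, "union": union,
            "jaccard": inter / union if union else np.nan,
        })
    return pd.DataFrame(rows)


def distance_summary(joined: pd.DataFrame, distances: pd.Series,
                     alpha: float = 0.05, use_bh: bool = True) -> pd.DataFrame:
    """Gene-distance distributions of upregulated loci vs the genome average.

    For each repeat group the distances of significantly upregulated loci are
    compared against all annotated loci (the baseline) with a two-sided
    rank-sum (Mann-Whitney) test.  Groups with no upregulated locus are
    reported with missing statistics.
    """
    baseline = distances.dropna().to_numpy()
    p = joined["expr_p_bh"] if use_bh else joined["expr_p"]
    de = joined[(p < alpha) & (joined["expr_log2fc"] > 0)]
    groups = de.apply(
        lambda r: repeat_group(r["rep_class"], r["rep_name"]), axis=1
    ) if len(de) else pd.Series(dtype=object)
    rows = []
    for group in sorted(groups.unique()) if len(de) else []:
        vals = de.loc[groups == group, "locus_id"].map(distances).dropna().to_numpy()
        row = {"group": group, "n_de": len(vals),
               "median_de": np.median(vals) if len(vals) else np.nan,
               "n_baseline": len(baseline),
               "median_baseline": np.median(baseline) if len(baseline) else np.nan,
               "rank_sum_p": np.nan}
        if len(vals) and len(baseline):
            row["rank_sum_p"] = mannwhitneyu(
                vals, baseline, alternative="two-sided").pvalue
        rows.append(row)
    return pd.DataFrame(rows, columns=["group", "n_de", "median_de",
                                       "n_baseline", "median_baseline",
                                       "rank_sum_p"])
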