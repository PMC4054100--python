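"""Differential DNA methylation statistics from HpaII-representation tag counts.

HpaII cuts only unmethylated CCGG sites, so the relative abundance of HpaII
tags over a repeat stratum reports its hypomethylation.  Two libraries
(tester = mutant, driver = control) are compared with an in-stratum vs
out-of-stratum 2x2 contingency table::

                 tester   driver
    in stratum      a        c
    out             b        d

with odds ratio (a*d)/(b*c), a two-sided Fisher exact test per stratum and
Bonferroni correction over the strata tested.  OR > 1 means a relative HpaII
tag excess (hypomethylation) in the tester library.  Only repeat-overlapping
tags enter the table; non-overlapping tags are discarded upstream.

Per-locus fold changes use depth-normalised pseudocounted ratios with a
locus-vs-rest-of-library Fisher test, Benjamini-Hochberg correction, and an
MspI copy-number filter (MspI is methylation-insensitive, so its per-locus
counts control for copy number rather than methylation).
"""
from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .annotation import LOW_COMPLEXITY_CLASSES, TagSet, assign_tags

log = logging.getLogger(__name__)

STRATIFY_LEVELS = ("class", "family", "name")


def odds_ratio(a: float, b: float, c: float, d: float,
               zero_correction: bool = True) -> tuple[float, bool]:
    """Cross-product odds ratio (a*d)/(b*c) of a 2x2 table.

    With any zero cell and ``zero_correction`` the Haldane-Anscombe +0.5 is
    added to every cell and the returned flag is True.  Raises when either
    library margin (a+b or c+d) is zero, where the ratio is undefined.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("contingency cells must be non-negative")
    if a + b == 0 or c + d == 0:
        raise ValueError("odds ratio undefined: empty library margin")
    corrected = False
    if 0 in (a, b, c, d):
        if zero_correction:
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
            corrected = True
        else:
            with np.errstate(divide="ignore", invalid="ignore"):
                return float(np.divide(a * d, b * c)), False
    return (a * d) / (b * c), corrected


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for a 2x2 table.

    Sums hypergeometric probabilities no larger than the observed table's
    (with 1e-7 relative tolerance on the float comparison).  Any degenerate
    margin returns p = 1: a table with an empty row or column carries no
    evidence against independence.  The pmf is evaluated in log space
    (gammaln), so arbitrarily large margins neither overflow nor crawl.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("contingency cells must be non-negative")
    n_total = a + b + c + d
    row1, col1 = a + b, a + c
    if row1 == 0 or col1 == 0 or row1 == n_total or col1 == n_total:
        return 1.0
    support = np.arange(max(0, row1 + col1 - n_total), min(row1, col1) + 1)

    def log_pmf(k):
        return (
            gammaln(row1 + 1) - gammaln(k + 1) - gammaln(row1 - k + 1)
            + gammaln(n_total - row1 + 1) - gammaln(col1 - k + 1)
            - gammaln(n_total - row1 - col1 + k + 1)
            - (gammaln(n_total + 1) - gammaln(col1 + 1)
               - gammaln(n_total - col1 + 1))
        )

    lp = log_pmf(support)
    lp_obs = log_pmf(np.array([a]))[0]
    return float(min(1.0, np.exp(lp[lp <= lp_obs + 1e-7]).sum()))


def bonferroni(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Family-wise Bonferroni adjustment: min(1, m*p)."""
    p = np.asarray(p_values, dtype=float)
    return np.minimum(1.0, len(p) * p)


def benjamini_hochberg(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Step-up Benjamini-Hochberg adjusted p-values (FDR control)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def _stratum_labels(annotation: pd.DataFrame, stratify_by: str) -> pd.Series:
    if stratify_by not in STRATIFY_LEVELS:
        raise ValueError(f"stratify_by must be one of {STRATIFY_LEVELS}")
    if stratify_by == "class":
        labels = annotation["rep_class"]
    elif stratify_by == "family":
        labels = annotation["rep_class"] + "/" + annotation["rep_family"]
    else:
        labels = annotation["rep_name"]
    return pd.Series(labels.to_numpy(), index=annotation["locus_id"])


def _assignment(tags: TagSet, annotation: pd.DataFrame,
                precomputed: pd.Series | None) -> pd.Series:
    if precomputed is not None:
        return precomputed
    records = tags.records
    if "locus_id" in records.columns:
        return records["locus_id"]
    return assign_tags(tags, annotation)


def class_counts(assignment_tester: pd.Series, assignment_driver: pd.Series,
                 annotation: pd.DataFrame, stratify_by: str = "class",
                 exclude_low_complexity: bool = True) -> pd.DataFrame:
    """Per-stratum repeat-overlapping tag counts for tester and driver.

    Unassigned tags are discarded; strata with zero tags in both libraries do
    not appear.  ``stratify_by`` selects class, class/family, or repeat name.
    """
    labels = _stratum_labels(annotation, stratify_by)
    if exclude_low_complexity:
        keep = ~annotation["rep_class"].isin(LOW_COMPLEXITY_CLASSES)
        labels = labels[annotation.loc[keep.to_numpy(), "locus_id"]]
    counts = {}
    for col, assignment in (("n_tester", assignment_tester),
                            ("n_driver", assignment_driver)):
        assigned = assignment.dropna()
        strata = assigned.map(labels)
        counts[col] = strata.dropna().value_counts()
    table = pd.DataFrame(counts).fillna(0).astype(int)
    table.index.name = "stratum"
    return table.sort_index()


def class_differential(tester: TagSet, driver: TagSet,
                       annotation: pd.DataFrame, stratify_by: str = "class",
                       exclude_low_complexity: bool = True,
                       zero_correction: bool = True,
                       assignments: tuple[pd.Series, pd.Series] | None = None,
                       ) -> pd.DataFrame:
    """Class-level differential methylation odds ratios with exact tests.

    One row per stratum with the 2x2 cells (a = tester in-stratum, b = tester
    out-of-stratum, c/d likewise for driver), the odds ratio (OR > 1 =
    hypomethylation in tester), two-sided Fisher p and Bonferroni-adjusted p.
    """
    a_t = _assignment(tester, annotation, assignments[0] if assignments else None)
    a_d = _assignment(driver, annotation, assignments[1] if assignments else None)
    table = class_counts(a_t, a_d, annotation, stratify_by, exclude_low_complexity)
    total_t = int(table["n_tester"].sum())
    total_d = int(table["n_driver"].sum())
    rows = []
    for stratum, (a, c) in table.iterrows():
        b, d = total_t - a, total_d - c
        or_, corrected = odds_ratio(a, b, c, d, zero_correction=zero_correction)
        rows.append({
            "stratum": stratum, "a": a, "b": b, "c": c, "d": d,
            "odds_ratio": or_, "p_value": fisher_exact_2x2(a, b, c, d),
            "zero_corrected": corrected,
        })
    out = pd.DataFrame(rows)
    if not out.empty:
        out["p_adj"] = bonferroni(out["p_value"].to_numpy())
    else:
        out["p_adj"] = pd.Series(dtype=float)
    return out


def locus_counts(assignment: pd.Series, annotation: pd.DataFrame) -> pd.Series:
    """Tag count per locus_id over the full annotation (zeros included)."""
    counts = assignment.dropna().value_counts()
    return counts.reindex(annotation["locus_id"], fill_value=0).astype(int)


def locus_differential(tester: TagSet, driver: TagSet,
                       annotation: pd.DataFrame,
                       mspi_tester: TagSet | None = None,
                       mspi_driver: TagSet | None = None,
                       min_mspi: int = 2,
                       assignments: tuple[pd.Series, pd.Series] | None = None,
                       mspi_assignments: tuple[pd.Series, pd.Series] | None = None,
                       ) -> pd.DataFrame:
    """Per-locus HpaII tag fold changes with exact tests and BH correction.

    ``norm_log2fc = log2(((a+0.5)/N_t) / ((c+0.5)/N_d))`` with N the
    repeat-assigned library totals; positive values mean an HpaII tag excess
    in the tester, i.e. relative hypomethylation.  Each locus is tested
    against the rest of its library by Fisher's exact test.  Loci failing the
    MspI copy-number filter (either MspI count < ``min_mspi``) are excluded
    from the BH family (``p_bh`` = NaN).  Only informative loci (>=1 tag in
    either library) are returned.
    """
    a_t = _assignment(tester, annotation, assignments[0] if assignments else None)
    a_d = _assignment(driver, annotation, assignments[1] if assignments else None)
    count_t = locus_counts(a_t, annotation)
    count_d = locus_counts(a_d, annotation)
    n_t, n_d = int(count_t.sum()), int(count_d.sum())
    if n_t == 0 or n_d == 0:
        raise ValueError("both libraries must have repeat-assigned tags")

    if mspi_tester is not None and mspi_driver is not None:
        m_t = locus_counts(
            _assignment(mspi_tester, annotation,
                        mspi_assignments[0] if mspi_assignments else None),
            annotation)
        m_d = locus_counts(
            _assignment(mspi_driver, annotation,
                        mspi_assignments[1] if mspi_assignments else None),
            annotation)
        mspi_pass = (m_t >= min_mspi) & (m_d >= min_mspi)
    else:
        log.warning("MspI libraries missing; copy-number filter skipped")
        mspi_pass = pd.Series(True, index=count_t.index)

    out = annotation[["locus_id", "rep_class", "rep_family", "rep_name"]].copy()
    out["count_tester"] = count_t.to_numpy()
    out["count_driver"] = count_d.to_numpy()
    out["mspi_pass"] = mspi_pass.to_numpy()
    out = out[(out["count_tester"] + out["count_driver"]) > 0].reset_index(drop=True)

    out["norm_log2fc"] = np.log2(
        ((out["count_tester"] + 0.5) / n_t) / ((out["count_driver"] + 0.5) / n_d)
    )
    out["p_value"] = [
        fisher_exact_2x2(a, n_t - a, c, n_d - c)
        for a, c in zip(out["count_tester"], out["count_driver"])
    ]
    out["p_bh"] = np.nan
    in_family = out["mspi_pass"].to_numpy()
    if in_family.any():
        out.loc[in_family, "p_bh"] = benjamini_hochberg(
            out.loc[in_family, "p_value"].to_numpy()
        )
    return out
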