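"""Exactly-specified small assay quantifications: bisulfite clone percent
methylation, ChIP percentage enrichment and housekeeping-normalised qRT-PCR.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

#: Cell codes of a bisulfite clone matrix: one row per sequenced clone, one
#: column per CpG position.
METHYLATED, UNMETHYLATED, UNKNOWN, NON_CONSENSUS = "M", "U", "?", "X"
VALID_CODES = {METHYLATED, UNMETHYLATED, UNKNOWN, NON_CONSENSUS}


def parse_clone_matrix(path: str | Path) -> pd.DataFrame:
    """Read a TSV bisulfite clone matrix of single-character codes (M/U/?/X)."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    bad = set(df.to_numpy().ravel()) - VALID_CODES
    if bad:
        raise ValueError(f"invalid clone-matrix codes: {sorted(bad)}")
    widths = df.notna().sum(axis=1)
    if widths.nunique() > 1:
        raise ValueError("clone matrix is not rectangular")
    return df


def percent_methylation(matrix: pd.DataFrame | np.ndarray,
                        column_subset: list[int] | None = None) -> float:
    """Percent methylation of scorable CpGs in a bisulfite clone matrix.

    ``100 * methylated / (methylated + unmethylated)``; unknown and
    non-consensus cells are excluded from the denominator.  A column subset
    restricts the calculation to specific CpG positions (e.g. a single
    HpaII-site CpG).  Raises when no cell is scorable.
    """
    arr = np.asarray(matrix, dtype=object)
    if column_subset is not None:
        arr = arr[:, column_subset]
    n_meth = int(np.sum(arr == METHYLATED))
    n_unmeth = int(np.sum(arr == UNMETHYLATED))
    if n_meth + n_unmeth == 0:
        raise ValueError("no scorable (M/U) CpG cells in scope")
    return 100.0 * n_meth / (n_meth + n_unmeth)


def chip_percent_enrichment(ip_quantity: float, input_quantity: float,
                            input_fraction: float = 1.0) -> float:
    """ChIP enrichment as % (immunoprecipitated DNA / input DNA).

    ``input_fraction`` scales the measured input aliquot to its whole-
    chromatin equivalent (e.g. 0.1 when 10% of chromatin was kept as input).
    """
    if input_quantity <= 0:
        raise ValueError("input quantity must be positive")
    if not 0 < input_fraction <= 1:
        raise ValueError("input_fraction must be in (0, 1]")
    return 100.0 * ip_quantity / (input_quantity / input_fraction)


def qpcr_relative_expression(ct_target: float, ct_reference: float,
                             efficiency: float = 2.0) -> float:
    """Relative expression by the delta-Ct method: efficiency**-(Ct_t - Ct_ref).

    An undetermined target Ct (NaN) yields expression 0.  Units are arbitrary
    and normalised to the reference (housekeeping) gene.
    """
    if efficiency <= 1:
        raise ValueError("amplification efficiency must exceed 1")
    if np.isnan(ct_target):
        return 0.0
    if np.isnan(ct_reference):
        raise ValueError("reference Ct is undetermined")
    return float(efficiency ** -(ct_target - ct_reference))


def qpcr_table(df: pd.DataFrame, efficiency: float = 2.0) -> pd.DataFrame:
    """Apply the delta-Ct method to a Ct table.

    Expects columns ``sample``, ``ct_target``, ``ct_reference`` and optional
    boolean ``no_rt_signal`` (signal in the reverse-transcriptase-negative
    control).  Samples failing the no-RT control get expression 0 and
    ``qc_fail`` True.
    """
    out = df.copy()
    out["expression"] = [
        qpcr_relative_expression(t, r, efficiency)
        for t, r in zip(out["ct_target"], out["ct_reference"])
    ]
    out["qc_fail"] = out.get("no_rt_signal", pd.Series(False, index=out.index))
    out["qc_fail"] = out["qc_fail"].fillna(False).astype(bool)
    out.loc[out["qc_fail"], "expression"] = 0.0
    return out
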