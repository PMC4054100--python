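"""Shared fixtures: tiny hand-built annotations and the simulated coupled
scenes reused across recovery tests (simulation is the expensive part, so
scenes are generated once per session)."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import retrocount as rc
from retrocount.annotation import make_locus_id
from retrocount.expression import count_expression, differential_expression
from retrocount.integration import join_loci
from retrocount.methylation import locus_differential

N_COUPLED_SEEDS = 20


def make_repeats(rows) -> pd.DataFrame:
    """Build a repeat annotation frame from (chrom, start, end, strand,
    name, family, cls) tuples."""
    out = []
    for chrom, start, end, strand, name, family, cls in rows:
        out.append({
            "chrom": chrom, "start": start, "end": end, "strand": strand,
            "rep_name": name, "rep_family": family, "rep_class": cls,
            "locus_id": make_locus_id(chrom, start, end, name),
        })
    return pd.DataFrame(out)


def brute_force_assign(records: pd.DataFrame, annotation: pd.DataFrame):
    """O(n*m) oracle for tag-to-locus assignment: largest overlap, ties to
    the leftmost (then shortest) locus."""
    out = []
    for _, tag in records.iterrows():
        best, best_key = None, None
        for _, loc in annotation.iterrows():
            if loc["chrom"] != tag["chrom"]:
                continue
            ov = min(tag["end"], loc["end"]) - max(tag["start"], loc["start"])
            if ov <= 0:
                continue
            key = (-ov, loc["start"], loc["end"], loc["locus_id"])
            if best_key is None or key < best_key:
                best, best_key = loc["locus_id"], key
        out.append(best)
    return out


def random_scene(rng: np.random.Generator, n_loci=30, n_tags=200,
                 chrom_len=20_000, allow_overlap=False):
    """Random small annotation + tag records for oracle-equivalence tests."""
    rows = []
    occupied = []
    i = 0
    while len(rows) < n_loci:
        start = int(rng.integers(0, chrom_len - 300))
        end = start + int(rng.integers(50, 300))
        if not allow_overlap and any(s < end and start < e for s, e in occupied):
            i += 1
            if i > 500:
                break
            continue
        occupied.append((start, end))
        rows.append(("chr1", start, end, "+", f"rep{len(rows)}", "fam", "LTR"))
    annotation = make_repeats(rows)
    tags = pd.DataFrame({
        "chrom": "chr1",
        "start": (starts := rng.integers(0, chrom_len - 60, size=n_tags)),
        "end": starts + rng.integers(1, 60, size=n_tags),
        "strand": rng.choice(["+", "-"], size=n_tags),
    })
    return annotation, tags


@pytest.fixture(scope="session")
def coupled_scenes():
    """Default (coupled) scenes with per-locus methylation + expression
    differentials and the joined table, over independent seeds."""
    out = []
    for seed in range(N_COUPLED_SEEDS):
        scene = rc.simulate_scene(seed=10_000 + seed)
        hp_m, hp_c = scene.tags["hpaii_mutant"], scene.tags["hpaii_control"]
        meth = locus_differential(
            hp_m, hp_c, scene.annotation,
            mspi_tester=scene.tags["mspi_mutant"],
            mspi_driver=scene.tags["mspi_control"],
            assignments=(hp_m.records["locus_id"], hp_c.records["locus_id"]),
            mspi_assignments=(scene.tags["mspi_mutant"].records["locus_id"],
                              scene.tags["mspi_control"].records["locus_id"]))
        reads = {"control": scene.tags["rna_control"],
                 "mutant": scene.tags["rna_mutant"]}
        counts = count_expression(reads, scene.annotation)
        sizes = {c: t.total_count for c, t in reads.items()}
        expr = differential_expression(counts, sizes)
        joined = join_loci(meth, expr)
        out.append({"scene": scene, "meth": meth, "expr": expr,
                    "joined": joined, "reads": reads})
    return out
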