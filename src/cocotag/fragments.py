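"""Fragment-level processing: BEDPE conversion, dedup, scaling, tracks.

Fragments are BED 0-based half-open intervals keyed by cell barcode.
Coverage tracks follow the assay's normalization: a per-sample scaling
factor 1e10 / total fragment coverage (summed fragment lengths), or — for
paired-sample comparisons — the same factor computed once on an anchor
mark (H3K27ac) and applied to every track of the pair.  Pseudobulk tracks
use a per-cluster factor 1e4 / cell count instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

FRAGMENT_COLUMNS = ["chrom", "start", "end", "cell"]


def read_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=FRAGMENT_COLUMNS, usecols=[0, 1, 2, 3],
    )
    return df


def write_bed(frags: pd.DataFrame, path: str | Path) -> None:
    frags[FRAGMENT_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


@dataclass(frozen=True)
class ScaleFactor:
    value: float
    basis: str  # coverage | cell_count | anchor_coverage

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError("scale factor must be positive")


def bedpe_to_fragments(bedpe: pd.DataFrame, insert_cap: int = 1000) -> tuple[pd.DataFrame, int]:
    """Collapse mate pairs into fragments spanning both mates.

    ``bedpe`` needs columns chrom1,start1,end1,chrom2,start2,end2,cell (extra
    columns ignored).  Cross-chromosome pairs are skipped and counted; the
    returned frame is sorted by (chrom, start, end, cell).  Fragments longer
    than ``insert_cap`` are dropped (they would not have aligned with the
    paired-end insert-size cap).
    """
    required = ["chrom1", "start1", "end1", "chrom2", "start2", "end2", "cell"]
    missing = [c for c in required if c not in bedpe.columns]
    if missing:
        raise ValueError(f"BEDPE missing columns: {missing}")
    same = bedpe["chrom1"] == bedpe["chrom2"]
    n_skipped = int((~same).sum())
    ok = bedpe[same]
    frags = pd.DataFrame(
        {
            "chrom": ok["chrom1"],
            "start": np.minimum(ok["start1"], ok["start2"]),
            "end": np.maximum(ok["end1"], ok["end2"]),
            "cell": ok["cell"],
        }
    )
    bad = frags["start"] >= frags["end"]
    if bad.any():
        raise ValueError(f"malformed BEDPE record at line {int(np.nonzero(bad.values)[0][0]) + 1}")
    frags = frags[(frags["end"] - frags["start"]) <= insert_cap]
    frags = frags.sort_values(["chrom", "start", "end", "cell"]).reset_index(drop=True)
    return frags, n_skipped


def deduplicate(frags: pd.DataFrame, mode: str = "single_cell") -> pd.DataFrame:
    """Remove duplicate fragments per cell (single-cell mode) or keep all (bulk).

    In single-cell data identical (chrom, start, end, cell) fragments are
    almost surely PCR duplicates, so one copy is kept; bulk data retains
    duplicates.
    """
    if mode == "bulk":
        return frags
    if mode != "single_cell":
        raise ValueError(f"unknown mode: {mode}")
    return (
        frags.drop_duplicates(subset=FRAGMENT_COLUMNS)
        .sort_values(FRAGMENT_COLUMNS)
        .reset_index(drop=True)
    )


def coverage_scale_factor(frags: pd.DataFrame) -> ScaleFactor:
    """1e10 / summed fragment length."""
    if len(frags) == 0:
        raise ValueError("cannot compute a scale factor on an empty fragment set")
    total = float((frags["end"] - frags["start"]).sum())
    return ScaleFactor(1e10 / total, basis="coverage")


def anchor_scale_factor(anchor_frags: pd.DataFrame) -> ScaleFactor:
    """Coverage factor computed on the anchor mark, applied to all paired tracks."""
    sf = coverage_scale_factor(anchor_frags)
    return ScaleFactor(sf.value, basis="anchor_coverage")


def make_bedgraph(
    frags: pd.DataFrame,
    factor: ScaleFactor | float,
    chrom_sizes: Mapping[str, int],
    precision: int = 5,
) -> pd.DataFrame:
    """Scaled fragment-pileup coverage as maximal constant-value intervals.

    Equivalent to ``bedtools genomecov -bg`` over fragments with a scale
    factor: per-base depth x factor, zero-depth runs omitted, fragments
    clipped to chromosome bounds.  Values are rounded to ``precision``
    decimals for byte-stable output.
    """
    value = factor.value if isinstance(factor, ScaleFactor) else float(factor)
    out = []
    for chrom, grp in frags.groupby("chrom", sort=True):
        size = chrom_sizes.get(chrom)
        if size is None:
            raise ValueError(f"chromosome {chrom} absent from chrom sizes")
        starts = np.clip(grp["start"].to_numpy(), 0, size)
        ends = np.clip(grp["end"].to_numpy(), 0, size)
        keep = starts < ends
        starts, ends = starts[keep], ends[keep]
        if starts.size == 0:
            continue
        # event sweep: +1 at starts, -1 at ends
        bounds = np.concatenate([starts, ends])
        deltas = np.concatenate([np.ones(starts.size), -np.ones(ends.size)])
        order = np.argsort(bounds, kind="stable")
        bounds, deltas = bounds[order], deltas[order]
        uniq, idx = np.unique(bounds, return_index=True)
        depth = np.add.reduceat(deltas, idx).cumsum()
        for i in range(uniq.size - 1):
            d = depth[i]
            if d > 0:
                out.append((chrom, int(uniq[i]), int(uniq[i + 1]), round(d * value, precision)))
    bg = pd.DataFrame(out, columns=["chrom", "start", "end", "value"])
    if len(bg):
        # merge adjacent intervals with equal value
        merged = []
        for chrom, grp in bg.groupby("chrom", sort=True):
            rows = grp.to_numpy(dtype=object)
            cur = list(rows[0])
            for r in rows[1:]:
                if r[1] == cur[2] and r[3] == cur[3]:
                    cur[2] = r[2]
                else:
                    merged.append(tuple(cur))
                    cur = list(r)
            merged.append(tuple(cur))
        bg = pd.DataFrame(merged, columns=["chrom", "start", "end", "value"])
    return bg


def write_bedgraph(bg: pd.DataFrame, path: str | Path, precision: int = 5) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, value in bg.itertuples(index=False):
            fh.write(f"{chrom}\t{start}\t{end}\t{value:.{precision}f}\n")


def pseudobulk(
    frags: pd.DataFrame, clusters: Mapping[str, str]
) -> tuple[dict[str, pd.DataFrame], dict[str, ScaleFactor], int]:
    """Group fragments by cell cluster with cell-number scale factors.

    Factor per cluster = 1e4 / number of cells in the cluster (so a
    10,000-cell cluster gets factor 1).  Cells absent from the mapping are
    excluded; their fragment count is returned.
    """
    cl = frags["cell"].map(clusters)
    n_dropped = int(cl.isna().sum())
    kept = frags[cl.notna()].copy()
    kept["_cluster"] = cl[cl.notna()]
    cells_per_cluster: dict[str, int] = {}
    for cell, c in clusters.items():
        cells_per_cluster[c] = cells_per_cluster.get(c, 0) + 1
    groups = {
        c: g.drop(columns="_cluster").reset_index(drop=True)
        for c, g in kept.groupby("_cluster", sort=True)
    }
    factors = {
        c: ScaleFactor(1e4 / n, basis="cell_count") for c, n in cells_per_cluster.items()
    }
    return groups, factors, n_dropped


def pseudobulk_genescores(scores: pd.DataFrame, clusters: Mapping[str, str]) -> pd.DataFrame:
    """Average a gene x cell score matrix within each cell cluster."""
    cl = pd.Series({c: clusters[c] for c in scores.columns if c in clusters})
    if cl.empty:
        raise ValueError("no score columns match the cluster map")
    return scores[cl.index].T.groupby(cl).mean().T


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes = {}
    with open(path) as fh:
        for line in fh:
            if line.strip():
                chrom, size = line.split()[:2]
                sizes[chrom] = int(size)
    return sizes
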