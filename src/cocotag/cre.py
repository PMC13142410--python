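"""Cis-regulatory element classification and domain statistics.

The element pipeline: per-lineage MACS-style summits are collapsed with a
100-bp greedy sweep (keeping the higher-scoring summit), re-centered into
fixed 200-bp windows, merged across lineages into a non-redundant feature
set, and quantified as CPM over per-(cluster, mark) fragment files.  After
removing the 5% lowest- and highest-signal rows, columns are standardized,
mark blocks are rescaled to a common Frobenius norm, and elements are
clustered on a weighted kNN graph of the PCA representation with Leiden.
Element classes are then characterized by promoter fraction (TSS +/- 2 kb
overlap), log2 observed/expected enrichment over gene-domain groups (with
softmax weights), Fisher-exact co-occurrence within gene domains, and
Mann-Whitney comparisons of per-gene element counts and signal.

Gene domains span from the end of the nearest upstream non-overlapping
gene to the start of the nearest downstream non-overlapping gene.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, mannwhitneyu
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors
from sklearn.preprocessing import StandardScaler
from statsmodels.stats.multitest import multipletests


# ---------------------------------------------------------------------------
# interval primitives (0-based half-open throughout)
# ---------------------------------------------------------------------------

def count_overlaps(query: pd.DataFrame, targets: pd.DataFrame) -> np.ndarray:
    """Per query interval, the number of target intervals overlapping >= 1 bp.

    Both frames need chrom/start/end columns.  Overlap of [a,b) and [c,d)
    requires a < d and c < b; an abutting interval does not count.
    """
    q = query.reset_index(drop=True)
    out = np.zeros(len(q), dtype=int)
    tg = {c: g for c, g in targets.groupby("chrom")}
    for chrom, grp in q.groupby("chrom"):
        t = tg.get(chrom)
        if t is None:
            continue
        starts = np.sort(t["start"].to_numpy())
        ends = np.sort(t["end"].to_numpy())
        n_start_before = np.searchsorted(starts, grp["end"].to_numpy(), side="left")
        n_end_before = np.searchsorted(ends, grp["start"].to_numpy(), side="right")
        out[grp.index.to_numpy()] = n_start_before - n_end_before
    return out


def overlaps_any(query: pd.DataFrame, targets: pd.DataFrame) -> np.ndarray:
    """Boolean: does each query interval overlap at least one target interval."""
    return count_overlaps(query, targets) > 0


def merge_intervals(intervals: pd.DataFrame) -> pd.DataFrame:
    """Union of overlapping (not merely abutting) intervals, sorted."""
    merged = []
    for chrom, g in intervals.sort_values(["chrom", "start", "end"]).groupby("chrom"):
        cur_s = cur_e = None
        for s, e in zip(g["start"], g["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s < cur_e:
                cur_e = max(cur_e, e)
            else:
                merged.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        merged.append((chrom, cur_s, cur_e))
    return pd.DataFrame(merged, columns=["chrom", "start", "end"])


# ---------------------------------------------------------------------------
# gene domains
# ---------------------------------------------------------------------------

def collapse_transcripts(transcripts: pd.DataFrame) -> pd.DataFrame:
    """One interval per gene: most upstream start to most downstream end."""
    g = transcripts.groupby(["chrom", "gene"], as_index=False).agg(
        start=("start", "min"), end=("end", "max")
    )
    return g[["chrom", "start", "end", "gene"]].sort_values(["chrom", "start"]).reset_index(drop=True)


def gene_domains(genes: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Assign each gene a regulatory domain bounded by its non-overlapping neighbors.

    ``genes`` has one row per gene (chrom, start, end, gene) — use
    ``collapse_transcripts`` first for transcript-level input.  The upstream
    boundary is the largest end among genes ending at or before this gene's
    start (the nearest upstream non-overlapping gene, which may not be the
    adjacent record when neighbors overlap each other); the downstream
    boundary is the smallest start among genes starting at or after this
    gene's end.  Chromosome-edge genes are bounded by the min/max annotated
    coordinate on the chromosome.  Invalid domains are dropped and counted.
    """
    out = []
    n_dropped = 0
    for chrom, g in genes.groupby("chrom"):
        s = g["start"].to_numpy()
        e = g["end"].to_numpy()
        lo, hi = int(s.min()), int(e.max())
        ends_sorted = np.sort(e)
        starts_sorted = np.sort(s)
        for start, end, gene in zip(s, e, g["gene"]):
            i = np.searchsorted(ends_sorted, start, side="right") - 1
            dstart = int(ends_sorted[i]) if i >= 0 else lo
            j = np.searchsorted(starts_sorted, end, side="left")
            dend = int(starts_sorted[j]) if j < starts_sorted.size else hi
            if dstart >= dend:
                n_dropped += 1
                continue
            out.append((chrom, dstart, dend, gene, int(start), int(end)))
    domains = pd.DataFrame(
        out, columns=["chrom", "domain_start", "domain_end", "gene", "gene_start", "gene_end"]
    ).sort_values(["chrom", "domain_start"]).reset_index(drop=True)
    return domains, n_dropped


# ---------------------------------------------------------------------------
# summits and windows
# ---------------------------------------------------------------------------

def merge_summits(summits: pd.DataFrame, collapse_bp: int = 100) -> pd.DataFrame:
    """Greedy single-sweep collapse of nearby summits, keeping the top score.

    Summits (chrom, start, score; position = start) within ``collapse_bp``
    of the currently retained summit are merged into it; the retained
    summit takes the position and score of its highest-scoring member, and
    subsequent distances are measured from that retained position.
    """
    kept_rows = []
    for chrom, g in summits.sort_values(["chrom", "start"]).groupby("chrom"):
        cur = None
        for row in g.itertuples(index=False):
            if cur is None:
                cur = row._asdict()
            elif row.start - cur["start"] <= collapse_bp:
                if row.score > cur["score"]:
                    cur = row._asdict()
            else:
                kept_rows.append(cur)
                cur = row._asdict()
        if cur is not None:
            kept_rows.append(cur)
    return pd.DataFrame(kept_rows).sort_values(["chrom", "start"]).reset_index(drop=True)


def summit_windows(
    summits: pd.DataFrame, width: int = 200, chrom_sizes: Mapping[str, int] | None = None
) -> pd.DataFrame:
    """Fixed-width windows centered on summit positions, clipped to bounds."""
    half = width // 2
    pos = summits["start"].to_numpy()
    start = pos - half
    end = pos + half
    start = np.maximum(start, 0)
    if chrom_sizes is not None:
        sizes = summits["chrom"].map(chrom_sizes).to_numpy()
        end = np.minimum(end, sizes)
    win = summits.copy()
    win["start"] = start
    win["end"] = end
    return win.reset_index(drop=True)


def cross_lineage_merge(
    window_sets: Sequence[pd.DataFrame],
    all_summits: pd.DataFrame,
    width: int = 200,
    chrom_sizes: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Non-redundant cross-lineage window set with re-centered wide merges.

    Per-lineage window sets are concatenated and overlap-merged; merged
    intervals wider than ``width`` (summits disagreed between lineages) are
    re-centered on the highest-scoring original summit they contain.
    """
    merged = merge_intervals(pd.concat(window_sets, ignore_index=True)[["chrom", "start", "end"]])
    rows = []
    sg = {c: g.sort_values("start") for c, g in all_summits.groupby("chrom")}
    for row in merged.itertuples(index=False):
        if row.end - row.start <= width:
            rows.append((row.chrom, row.start, row.end))
            continue
        cand = sg.get(row.chrom)
        if cand is not None:
            hit = cand[(cand["start"] >= row.start) & (cand["start"] < row.end)]
        else:
            hit = None
        if hit is None or len(hit) == 0:
            # no original summit inside: keep the merged interval's center
            mid = (row.start + row.end) // 2
        else:
            mid = int(hit.loc[hit["score"].idxmax(), "start"])
        half = width // 2
        s = max(mid - half, 0)
        e = mid + half
        if chrom_sizes is not None:
            e = min(e, chrom_sizes[row.chrom])
        rows.append((row.chrom, s, e))
    out = (
        pd.DataFrame(rows, columns=["chrom", "start", "end"])
        .drop_duplicates()
        .sort_values(["chrom", "start"])
        .reset_index(drop=True)
    )
    out["id"] = [f"peak{i}" for i in range(len(out))]
    return out


# ---------------------------------------------------------------------------
# quantification
# ---------------------------------------------------------------------------

@dataclass
class ElementMatrix:
    """200-bp element windows x (cluster, mark) CPM values."""

    windows: pd.DataFrame          # chrom, start, end, id (+ optional labels)
    values: pd.DataFrame           # index = window id, MultiIndex columns (cluster, mark)

    @property
    def marks(self) -> list[str]:
        return sorted({m for _, m in self.values.columns})

    def subset(self, ids: Sequence[str]) -> "ElementMatrix":
        ids = list(ids)
        win = self.windows.set_index("id").loc[ids].reset_index()
        win = win[[c for c in self.windows.columns]]
        return ElementMatrix(windows=win, values=self.values.loc[ids])


def quantify(
    windows: pd.DataFrame, fragments: Mapping[tuple[str, str], pd.DataFrame]
) -> ElementMatrix:
    """CPM of fragments overlapping each window per (cluster, mark) file.

    count = fragments overlapping the window by >= 1 bp; CPM = count * 1e6 /
    total fragments in that (cluster, mark) file.
    """
    win = windows.reset_index(drop=True)
    cols = {}
    for (cluster, mark), frags in fragments.items():
        total = len(frags)
        if total == 0:
            raise ValueError(f"empty fragment file for ({cluster}, {mark})")
        counts = count_overlaps(win[["chrom", "start", "end"]], frags)
        cols[(cluster, mark)] = counts * 1e6 / total
    values = pd.DataFrame(cols, index=win["id"])
    values.columns = pd.MultiIndex.from_tuples(values.columns, names=["cluster", "mark"])
    return ElementMatrix(windows=win, values=values)


def outlier_filter(
    matrix: ElementMatrix, low_q: float = 0.05, high_q: float = 0.95
) -> ElementMatrix:
    """Drop rows in the extreme tails of the cumulative-signal distribution.

    Cumulative signal = row sum over all columns; rows strictly below the
    ``low_q`` percentile or strictly above the ``high_q`` percentile are
    removed (a fully tied matrix is therefore retained whole).
    """
    sums = matrix.values.sum(axis=1)
    lo = np.percentile(sums, 100 * low_q)
    hi = np.percentile(sums, 100 * high_q)
    keep = matrix.values.index[(sums >= lo) & (sums <= hi)]
    return matrix.subset(list(keep))


# ---------------------------------------------------------------------------
# element clustering
# ---------------------------------------------------------------------------

def _normalized_features(values: pd.DataFrame) -> np.ndarray:
    """Column-standardize then equalize per-mark block Frobenius norms."""
    X = StandardScaler().fit_transform(values.to_numpy())
    X = np.nan_to_num(X)  # zero-variance columns -> 0
    marks = values.columns.get_level_values("mark")
    norms = {}
    for mark in marks.unique():
        block = X[:, marks == mark]
        norms[mark] = np.linalg.norm(block)
    target = float(np.median(list(norms.values())))
    for mark, norm in norms.items():
        if norm > 0:
            X[:, marks == mark] *= target / norm
    return X


def _leiden_on_pca(
    X: np.ndarray, n_pcs: int, k: int, resolution: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    n, d = X.shape
    if n_pcs > min(n, d):
        warnings.warn(f"n_pcs lowered from {n_pcs} to {min(n, d)}")
        n_pcs = min(n, d)
    pcs = PCA(n_components=n_pcs, random_state=seed).fit_transform(X)
    k_eff = min(k, n - 1)
    nn = NearestNeighbors(n_neighbors=k_eff).fit(pcs)
    dist, idx = nn.kneighbors(pcs)
    edges, weights = [], []
    seen = set()
    for i in range(n):
        for j, dij in zip(idx[i], dist[i]):
            if i == j:
                continue
            key = (min(i, j), max(i, j))
            if key in seen:
                continue
            seen.add(key)
            edges.append(key)
            weights.append(1.0 / max(dij, 1e-12))
    graph = ig.Graph(n=n, edges=edges)
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        weights=weights,
        resolution_parameter=resolution,
        seed=seed,
    )
    labels = np.asarray(part.membership)
    # canonicalize by descending class size
    order = pd.Series(labels).value_counts().index.to_list()
    remap = {old: new for new, old in enumerate(order)}
    return np.array([remap[l] for l in labels]), pcs


def cluster_elements(
    matrix: ElementMatrix,
    n_pcs: int = 16,
    k: int = 30,
    resolution: float = 4.0,
    seed: int = 0,
    embed: bool = False,
) -> tuple[pd.Series, np.ndarray | None]:
    """Leiden element classes from the normalized CPM matrix.

    Pipeline: column-standardize, equalize mark-block norms, PCA to
    ``n_pcs``, kNN graph with inverse-Euclidean edge weights, Leiden (RB
    configuration objective) at the given resolution.  Labels are relabeled
    by descending class size.  With ``embed=True`` a 2-D UMAP of the PCA
    representation (40 neighbors, min-dist 0.25) is also returned for
    reporting.
    """
    X = _normalized_features(matrix.values)
    labels, pcs = _leiden_on_pca(X, n_pcs, k, resolution, seed)
    emb = None
    if embed:
        import umap

        emb = umap.UMAP(
            n_neighbors=min(40, X.shape[0] - 1),
            min_dist=0.25,
            metric="euclidean",
            random_state=seed,
        ).fit_transform(pcs)
    return pd.Series(labels, index=matrix.values.index, name="element_class"), emb


def recluster(
    matrix: ElementMatrix,
    labels: pd.Series,
    selected: Sequence,
    n_pcs: int = 15,
    k: int = 30,
    resolution: float = 0.5,
    seed: int = 0,
) -> pd.Series:
    """Refine selected element classes at lower resolution.

    Rows whose label is in ``selected`` are re-embedded (PCA of the subset)
    and re-partitioned; their labels are overwritten with namespaced
    sublabels (``"<old>.<sub>"``).  Other rows keep their labels.
    """
    out = labels.astype(str).copy()
    mask = labels.isin(selected)
    if not mask.any():
        return out
    sub = matrix.subset(list(labels.index[mask]))
    X = _normalized_features(sub.values)
    sub_labels, _ = _leiden_on_pca(X, n_pcs, k, resolution, seed)
    out.loc[mask] = [
        f"{old}.{new}" for old, new in zip(labels[mask].astype(str), sub_labels)
    ]
    return out


# ---------------------------------------------------------------------------
# class characterization
# ---------------------------------------------------------------------------

def promoter_fraction(
    windows: pd.DataFrame,
    labels: pd.Series,
    tss: pd.DataFrame,
    flank: int = 2000,
    chrom_sizes: Mapping[str, int] | None = None,
) -> pd.Series:
    """Per element class, the fraction of windows overlapping TSS +/- flank.

    ``tss`` needs chrom and pos columns (or chrom/start for BED-style input,
    in which case start is used as the site).
    """
    pos_col = "pos" if "pos" in tss.columns else "start"
    prom = pd.DataFrame(
        {
            "chrom": tss["chrom"],
            "start": np.maximum(tss[pos_col] - flank, 0),
            "end": tss[pos_col] + flank,
        }
    )
    if chrom_sizes is not None:
        prom["end"] = np.minimum(prom["end"], prom["chrom"].map(chrom_sizes))
    win = windows.reset_index(drop=True)
    hit = overlaps_any(win[["chrom", "start", "end"]], prom)
    lab = labels.loc[win["id"]].to_numpy()
    return pd.Series(hit).groupby(lab).mean().rename("promoter_fraction")


def domain_enrichment(
    windows: pd.DataFrame,
    labels: pd.Series,
    domain_groups: Mapping[str, pd.DataFrame],
    group_genes: Mapping[str, Sequence[str]] | None = None,
    pseudocount: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """log2 observed/expected element-class x gene-domain-group enrichment.

    ``domain_groups`` maps group name to a domain table (chrom,
    domain_start, domain_end, gene).  If ``group_genes`` is given, gene
    membership across groups is verified disjoint (a gene in two groups is
    an error).  Expected counts are N_class x f_group with f_group the
    genome-wide fraction of windows overlapping the group's domains.
    Returns (log2 enrichment, row-softmax weights).
    """
    if group_genes is not None:
        seen: dict[str, str] = {}
        dupes = []
        for group, genes in group_genes.items():
            for gene in genes:
                if gene in seen and seen[gene] != group:
                    dupes.append(gene)
                seen[gene] = group
        if dupes:
            raise ValueError(f"genes assigned to more than one domain group: {sorted(set(dupes))}")

    win = windows.reset_index(drop=True)
    lab = labels.loc[win["id"]].to_numpy()
    classes = sorted(pd.unique(lab))
    groups = sorted(domain_groups)
    n_total = len(win)
    obs = pd.DataFrame(0.0, index=classes, columns=groups)
    frac = {}
    for group in groups:
        dom = domain_groups[group].rename(
            columns={"domain_start": "start", "domain_end": "end"}
        )
        hit = overlaps_any(win[["chrom", "start", "end"]], dom[["chrom", "start", "end"]])
        frac[group] = hit.mean() if n_total else 0.0
        for cls in classes:
            obs.loc[cls, group] = int(hit[lab == cls].sum())
    n_class = pd.Series({cls: int((lab == cls).sum()) for cls in classes})
    exp = pd.DataFrame(
        {g: n_class * frac[g] for g in groups}, index=classes
    )
    enrich = np.log2((obs + pseudocount) / (exp + pseudocount))
    w = np.exp(enrich - enrich.to_numpy().max(axis=1, keepdims=True))
    weights = w.div(w.sum(axis=1), axis=0)
    return enrich, weights


def cooccurrence(
    presence: pd.DataFrame, fdr: float = 0.05, pseudocount: float = 0.5
) -> pd.DataFrame:
    """Pairwise Fisher-exact co-occurrence of element classes across genes.

    ``presence`` is a boolean gene x element-class matrix (does the gene's
    domain contain >= 1 element of the class).  Per pair: two-sided Fisher
    exact p on the 2x2 table (both / only A / only B / neither) and a
    Haldane-stabilized log2 odds ratio (+0.5 in every cell).  P values are
    BH-adjusted across all pairs; ``significant`` marks FDR < ``fdr``.
    """
    cols = list(presence.columns)
    rows = []
    P = presence.to_numpy(dtype=bool)
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            a = int((P[:, i] & P[:, j]).sum())
            b = int((P[:, i] & ~P[:, j]).sum())
            c = int((~P[:, i] & P[:, j]).sum())
            d = int((~P[:, i] & ~P[:, j]).sum())
            _, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
            log2_or = float(
                np.log2(
                    ((a + pseudocount) * (d + pseudocount))
                    / ((b + pseudocount) * (c + pseudocount))
                )
            )
            rows.append((cols[i], cols[j], a, b, c, d, log2_or, p))
    out = pd.DataFrame(
        rows, columns=["class_a", "class_b", "both", "only_a", "only_b", "neither", "log2_or", "p"]
    )
    if len(out):
        out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
        out["significant"] = out["fdr"] < fdr
    else:
        out["fdr"] = []
        out["significant"] = []
    return out


def cooccurrence_network(
    cooc: pd.DataFrame, min_degree: int = 1, top_edges: int = 50
) -> pd.DataFrame:
    """Significant positive co-occurrences, backbone-filtered for plotting.

    Keeps significant edges with log2 OR > 0, trims to the ``top_edges``
    strongest by |log2 OR|, then drops nodes below ``min_degree``.
    """
    edges = cooc[(cooc["significant"]) & (cooc["log2_or"] > 0)].copy()
    edges = edges.reindex(edges["log2_or"].abs().sort_values(ascending=False).index)
    edges = edges.head(top_edges)
    while True:
        deg = pd.concat([edges["class_a"], edges["class_b"]]).value_counts()
        ok = deg[deg >= min_degree].index
        kept = edges[edges["class_a"].isin(ok) & edges["class_b"].isin(ok)]
        if len(kept) == len(edges):
            break
        edges = kept
    return edges.reset_index(drop=True)


def gene_element_counts(
    windows: pd.DataFrame,
    labels: pd.Series,
    domains: pd.DataFrame,
    classes: Sequence,
) -> pd.DataFrame:
    """Per gene, the number of windows of each listed class inside its domain."""
    win = windows.reset_index(drop=True)
    lab = labels.loc[win["id"]].to_numpy()
    dom = domains.rename(columns={"domain_start": "start", "domain_end": "end"})
    out = pd.DataFrame(0, index=domains["gene"], columns=list(classes))
    for cls in classes:
        sub = win[lab == cls][["chrom", "start", "end"]].reset_index(drop=True)
        if len(sub) == 0:
            continue
        counts = count_overlaps(dom[["chrom", "start", "end"]].reset_index(drop=True), sub)
        out[cls] = counts
    return out


def peak_max_signal(matrix: ElementMatrix, mark: str) -> pd.Series:
    """Per window, the maximum CPM for one mark across all clusters."""
    cols = [c for c in matrix.values.columns if c[1] == mark]
    if not cols:
        raise ValueError(f"mark {mark!r} not present in the matrix")
    return matrix.values[cols].max(axis=1).rename(f"max_{mark}")


def group_compare(
    values: pd.Series, groups: Mapping[str, Sequence], pairs: Sequence[tuple[str, str]]
) -> pd.DataFrame:
    """Two-sided Mann-Whitney U between gene groups, BH-adjusted.

    Uses the exact distribution for small untied samples and the
    tie-corrected normal approximation otherwise.
    """
    rows = []
    for g1, g2 in pairs:
        x = values.loc[[g for g in groups[g1] if g in values.index]].to_numpy()
        y = values.loc[[g for g in groups[g2] if g in values.index]].to_numpy()
        u, p = mannwhitneyu(x, y, alternative="two-sided")
        rows.append((g1, g2, len(x), len(y), float(u), float(p)))
    out = pd.DataFrame(rows, columns=["group_a", "group_b", "n_a", "n_b", "U", "p"])
    if len(out):
        out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    return out
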