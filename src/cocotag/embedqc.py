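"""Cell quality control, doublet removal and embedding-fidelity metrics.

Cells are retained when any one of the three modalities (two mono-occupancy
streams plus the combined co-occupancy stream) has more than ``min_frags``
fragments.  Doublets are removed at two levels: whole clusters whose
putative-doublet fraction exceeds a threshold, and k-means neighborhoods in
the batch-corrected embedding whose genotype-labeled doublet fraction
exceeds 15% (all cells in such groups are removed from every modality).

The S_pair statistic quantifies embedding fidelity for matched profiles of
the same cell: for each member of a pair, the fraction of sampled other
cells that sit closer to it than its true partner, averaged over the two
members.  S_pair near 0 means matched profiles are embedded unusually close
together; 0.5 is the chance level of unrelated cells.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans


def min_fragment_filter(counts: pd.DataFrame, min_frags: int = 250) -> pd.Index:
    """Retain cells with more than ``min_frags`` fragments in >= 1 modality.

    ``counts`` is a cell x modality frame of fragment counts (index = cell).
    The boundary is strict: exactly ``min_frags`` everywhere is dropped.
    """
    keep = (counts > min_frags).any(axis=1)
    return counts.index[keep]


def cluster_doublet_filter(
    doublet_scores: pd.Series,
    clusters: pd.Series,
    score_threshold: float,
    fraction_threshold: float,
) -> tuple[list, pd.Series]:
    """Clusters whose putative-doublet fraction exceeds the threshold.

    A cell is a putative doublet when its doublet score is strictly above
    ``score_threshold``; a cluster is removed when its putative-doublet
    fraction is strictly above ``fraction_threshold``.  Returns (removed
    cluster labels, per-cluster fractions).
    """
    is_doublet = doublet_scores > score_threshold
    frac = is_doublet.groupby(clusters).mean()
    removed = sorted(frac.index[frac > fraction_threshold])
    return removed, frac


def genotype_doublet_filter(
    embedding: np.ndarray,
    genotype_status: Sequence[str],
    n_groups: int = 100,
    max_doublet_fraction: float = 0.15,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Remove doublet-enriched k-means neighborhoods of the embedding.

    Cells are partitioned into ``n_groups`` k-means groups in the reduced
    space; groups whose genotype-labeled doublet fraction is strictly above
    ``max_doublet_fraction`` are doublet-enriched and all of their cells are
    removed (the same removal set applies to every modality).  Returns
    (keep mask, group labels, per-group doublet fractions).
    """
    X = np.asarray(embedding, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("embedding must be a non-empty 2-D array")
    status = np.asarray(genotype_status, dtype=object)
    if status.size != X.shape[0]:
        raise ValueError("genotype_status length must match embedding rows")
    k = min(n_groups, X.shape[0])
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    groups = km.fit_predict(X)
    is_doublet = status == "doublet"
    frac = np.array([is_doublet[groups == g].mean() for g in range(k)])
    bad = frac > max_doublet_fraction
    keep = ~bad[groups]
    return keep, groups, frac


def s_pair(
    embedding: np.ndarray,
    pairs: np.ndarray,
    sample_size: int = 5000,
    seed: int = 0,
    n_dims: int | None = 15,
) -> pd.DataFrame:
    """Pair-closeness score for matched same-cell profiles.

    For each member c of a pair (c, p): sample up to ``sample_size`` other
    cells (without replacement, excluding c and p) and compute the fraction
    closer to c than p is, by Euclidean distance over the first ``n_dims``
    embedding dimensions.  S_pair averages the two members' fractions.
    Returns a frame with columns (i, j, s_i, s_j, s_pair).
    """
    X = np.asarray(embedding, dtype=float)
    if n_dims is not None:
        X = X[:, :n_dims]
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 cells to score pairs")
    pairs = np.asarray(pairs, dtype=int)
    rng = np.random.default_rng(seed)
    rows = []
    all_idx = np.arange(n)
    for i, j in pairs:
        d_pair = float(np.linalg.norm(X[i] - X[j]))
        members = []
        for c, p in ((i, j), (j, i)):
            others = all_idx[(all_idx != c) & (all_idx != p)]
            if others.size > sample_size:
                others = rng.choice(others, size=sample_size, replace=False)
            d = np.linalg.norm(X[others] - X[c], axis=1)
            members.append(float((d < d_pair).mean()))
        rows.append((i, j, members[0], members[1], (members[0] + members[1]) / 2.0))
    return pd.DataFrame(rows, columns=["i", "j", "s_i", "s_j", "s_pair"])


def cluster_overlap_matrix(
    labels_a: pd.Series, labels_b: pd.Series
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-modality cluster contingency matrix over shared cells.

    Entry (a, b) counts cells labeled a in modality A and b in modality B.
    Returns (counts, row-normalized fractions).
    """
    common = labels_a.index.intersection(labels_b.index)
    counts = pd.crosstab(labels_a.loc[common], labels_b.loc[common])
    frac = counts.div(counts.sum(axis=1), axis=0)
    return counts, frac


def annotation_score(
    marker_sets: Mapping[str, Sequence[str]], ref_expr: pd.DataFrame
) -> tuple[pd.DataFrame, pd.Series]:
    """Score chromatin clusters against reference cell types by marker genes.

    ``ref_expr`` is gene x cell-type normalized expression; rows are z-scaled
    across cell types (zero-variance rows become 0).  Each matrix entry is
    the mean scaled expression of the cluster's marker genes in that cell
    type; markers absent from the reference are dropped and counted.
    """
    mu = ref_expr.mean(axis=1)
    sd = ref_expr.std(axis=1, ddof=0)
    z = ref_expr.sub(mu, axis=0).div(sd.replace(0, np.nan), axis=0).fillna(0.0)
    scores = {}
    missing = {}
    for cluster, genes in marker_sets.items():
        present = [g for g in genes if g in z.index]
        missing[cluster] = len(genes) - len(present)
        scores[cluster] = z.loc[present].mean(axis=0) if present else pd.Series(np.nan, index=z.columns)
    return pd.DataFrame(scores).T, pd.Series(missing, name="missing_markers")
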