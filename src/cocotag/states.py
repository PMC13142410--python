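"""Chromatin-state calling from pseudobulk gene scores.

Scores are modeled on the log10(score + 0.1) scale with a two-component
Gaussian mixture per mark; the per-mark threshold is the intersection of
the two weighted component densities — the point of equal likelihood
between the low- and high-signal components.  Each gene x cluster is then
classified per H3K4/H3K27me3 marker pair:

- **bivalent**  — H3K4, H3K27me3 and co-occupancy all above threshold
- **active**    — H3K4 above, H3K27me3 below
- **repressed** — H3K27me3 above, H3K4 below
- **unmarked**  — both below
- **other**     — H3K4 and H3K27me3 above but co-occupancy not above

"Above" is strict (>); a score exactly at the threshold counts as below.
A consensus state requires agreement of at least two of the three marker
pairs (H3K27me3 with H3K4me1/me2/me3).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

STATE_LABELS = ("active", "repressed", "bivalent", "unmarked", "other")


def log_transform(scores: np.ndarray | pd.DataFrame):
    """The modeling scale: log10(score + 0.1)."""
    return np.log10(scores + 0.1)


@dataclass
class MixtureFit:
    """Canonically ordered (mu1 < mu2) two-component Gaussian fit."""

    mu1: float
    mu2: float
    sigma1: float
    sigma2: float
    w1: float
    w2: float
    threshold: float
    converged: bool
    threshold_fallback: bool = False

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def intersection_threshold(
    w1: float, mu1: float, sigma1: float, w2: float, mu2: float, sigma2: float
) -> float:
    """Point of equal weighted component likelihood between the means.

    Solves w1*phi(x; mu1, sigma1) = w2*phi(x; mu2, sigma2).  With equal
    variances this reduces to (mu1+mu2)/2 + sigma^2*ln(w1/w2)/(mu2-mu1);
    otherwise the log-equation is quadratic and the root inside
    (mu1, mu2) is returned.  Raises ``ValueError`` if no root lies between
    the means (extreme weight/variance combinations).
    """
    if not mu1 < mu2:
        raise ValueError("requires mu1 < mu2")
    # log w1 - log s1 - (x-mu1)^2/(2 s1^2) = log w2 - log s2 - (x-mu2)^2/(2 s2^2)
    a = 1.0 / (2 * sigma2**2) - 1.0 / (2 * sigma1**2)
    b = mu1 / sigma1**2 - mu2 / sigma2**2
    c = (
        mu2**2 / (2 * sigma2**2)
        - mu1**2 / (2 * sigma1**2)
        + np.log(w1 / w2)
        + np.log(sigma2 / sigma1)
    )
    if abs(a) < 1e-14:
        x = -c / b
        roots = [x]
    else:
        disc = b * b - 4 * a * c
        if disc < 0:
            raise ValueError("densities do not intersect between the means")
        sq = np.sqrt(disc)
        roots = [(-b - sq) / (2 * a), (-b + sq) / (2 * a)]
    inside = [r for r in roots if mu1 < r < mu2]
    if not inside:
        raise ValueError("no density intersection between the component means")
    return float(inside[0])


def fit_mixture(
    values: Sequence[float] | np.ndarray,
    already_log: bool = False,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> MixtureFit:
    """Deterministic two-component EM fit on log10(score + 0.1).

    Initialization splits the data at the median (low/high halves supply
    the starting means, variances and equal weights), making the fit a pure
    function of the data.  Components are re-ordered so mu1 < mu2.  When
    the density intersection cannot be bracketed between the means the
    threshold falls back to the midpoint of the means and the fit is
    flagged.
    """
    x = np.asarray(values, dtype=float).ravel()
    x = x[np.isfinite(x)]
    if x.size < 20:
        raise ValueError("need at least 20 finite values to fit a mixture")
    if not already_log:
        if (x < 0).any():
            raise ValueError("raw scores must be non-negative")
        x = np.asarray(log_transform(x))
    if np.var(x) == 0:
        raise ValueError("no mixture structure: all values identical")

    med = np.median(x)
    lo, hi = x[x <= med], x[x > med]
    if hi.size == 0:  # heavy ties at the median
        lo, hi = x[x < med], x[x >= med]
    means_init = np.array([[lo.mean()], [hi.mean()]])
    var_floor = 1e-6
    vars_init = np.array([max(lo.var(), var_floor), max(hi.var(), var_floor)])
    gm = GaussianMixture(
        n_components=2,
        covariance_type="full",
        tol=tol,
        max_iter=max_iter,
        weights_init=np.array([0.5, 0.5]),
        means_init=means_init,
        precisions_init=(1.0 / vars_init).reshape(2, 1, 1),
        reg_covar=1e-10,
    )
    gm.fit(x.reshape(-1, 1))
    mus = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    ws = gm.weights_.ravel()
    order = np.argsort(mus)
    mu1, mu2 = mus[order]
    s1, s2 = sds[order]
    w1, w2 = ws[order]
    fallback = False
    try:
        thr = intersection_threshold(w1, mu1, s1, w2, mu2, s2)
    except ValueError:
        thr = float((mu1 + mu2) / 2)
        fallback = True
    return MixtureFit(
        mu1=float(mu1), mu2=float(mu2), sigma1=float(s1), sigma2=float(s2),
        w1=float(w1), w2=float(w2), threshold=thr,
        converged=bool(gm.converged_), threshold_fallback=fallback,
    )


def classify_states(
    k4: np.ndarray | pd.Series,
    k27: np.ndarray | pd.Series,
    cooc: np.ndarray | pd.Series,
    thr_k4: float,
    thr_k27: float,
    thr_cooc: float,
) -> np.ndarray:
    """Five-way state call per gene for one (H3K4 mark, H3K27me3) pair.

    Inputs must be on the same log10(score+0.1) scale as the thresholds.
    """
    k4_hi = np.asarray(k4) > thr_k4
    k27_hi = np.asarray(k27) > thr_k27
    co_hi = np.asarray(cooc) > thr_cooc
    out = np.full(k4_hi.shape, "other", dtype=object)
    out[k4_hi & ~k27_hi] = "active"
    out[~k4_hi & k27_hi] = "repressed"
    out[~k4_hi & ~k27_hi] = "unmarked"
    out[k4_hi & k27_hi & co_hi] = "bivalent"
    return out


def consensus(per_pair: Iterable[Sequence[str]]) -> np.ndarray:
    """Modal state over the three marker pairs if supported by >= 2 votes.

    ``per_pair`` is an iterable of three equally long label arrays.  Genes
    labeled "other" vote like any other label.  No 2-vote majority -> "none".
    """
    arrs = [np.asarray(a, dtype=object) for a in per_pair]
    if len(arrs) != 3:
        raise ValueError("consensus expects exactly three per-pair label arrays")
    n = arrs[0].size
    out = np.full(n, "none", dtype=object)
    a, b, c = arrs
    out[(a == b) | (a == c)] = a[(a == b) | (a == c)]
    only_bc = (a != b) & (a != c) & (b == c)
    out[only_bc] = b[only_bc]
    return out


def call_state_table(
    matrices: Mapping[str, pd.DataFrame],
    fits: Mapping[str, MixtureFit] | None = None,
) -> tuple[pd.DataFrame, dict[str, MixtureFit]]:
    """End-to-end state calling on gene x cluster score matrices.

    ``matrices`` maps H3K4me1/H3K4me2/H3K4me3, H3K27me3 and "cooccupancy"
    to gene x cluster score DataFrames (raw scale).  One mixture is fitted
    per mark on all values pooled across clusters (per-cluster fitting is
    possible by calling ``fit_mixture`` on individual columns).  Returns a
    long table (gene, cluster, state_H3K4me1, state_H3K4me2, state_H3K4me3,
    consensus) plus the fits.
    """
    needed = {"H3K4me1", "H3K4me2", "H3K4me3", "H3K27me3", "cooccupancy"}
    missing = needed - set(matrices)
    if missing:
        raise ValueError(f"missing score matrices: {sorted(missing)}")
    if fits is None:
        fits = {m: fit_mixture(matrices[m].to_numpy().ravel()) for m in needed}
    logs = {m: np.asarray(log_transform(matrices[m].to_numpy())) for m in needed}
    genes = matrices["H3K27me3"].index
    clusters = matrices["H3K27me3"].columns

    per_pair = {}
    for k4 in ("H3K4me1", "H3K4me2", "H3K4me3"):
        per_pair[k4] = classify_states(
            logs[k4].ravel(),
            logs["H3K27me3"].ravel(),
            logs["cooccupancy"].ravel(),
            fits[k4].threshold,
            fits["H3K27me3"].threshold,
            fits["cooccupancy"].threshold,
        )
    cons = consensus([per_pair[m] for m in ("H3K4me1", "H3K4me2", "H3K4me3")])
    idx = pd.MultiIndex.from_product([genes, clusters], names=["gene", "cluster"])
    table = pd.DataFrame(
        {
            "state_H3K4me1": per_pair["H3K4me1"],
            "state_H3K4me2": per_pair["H3K4me2"],
            "state_H3K4me3": per_pair["H3K4me3"],
            "consensus": cons,
        },
        index=idx,
    ).reset_index()
    return table, dict(fits)


@dataclass
class FateMap:
    """Root-to-lineage state transitions for a gene set."""

    counts: dict[str, pd.DataFrame]          # lineage -> root-state x downstream-state counts
    activation_fraction: pd.Series           # per root state: fraction active in >=1 lineage
    specificity: pd.DataFrame                # root state x (active in exactly k lineages) counts


def transition_table(
    root_states: Mapping[str, str], lineage_states: Mapping[str, Mapping[str, str]]
) -> FateMap:
    """Fate map of genes from a root population through downstream lineages.

    ``root_states`` maps gene -> state in the root cluster;
    ``lineage_states`` maps lineage -> (gene -> state in that lineage's
    terminal cluster).  Only genes present in the root and every lineage are
    counted.
    """
    lineages = sorted(lineage_states)
    genes = [g for g in root_states if all(g in lineage_states[l] for l in lineages)]
    all_states = list(STATE_LABELS) + ["none"]
    counts = {}
    for l in lineages:
        tab = pd.DataFrame(0, index=all_states, columns=all_states)
        for g in genes:
            tab.loc[root_states[g], lineage_states[l][g]] += 1
        counts[l] = tab
    n_active = pd.Series(
        {g: sum(lineage_states[l][g] == "active" for l in lineages) for g in genes}
    )
    root = pd.Series({g: root_states[g] for g in genes})
    frac = {}
    spec = pd.DataFrame(
        0, index=all_states, columns=[f"active_in_{k}" for k in range(1, len(lineages) + 1)]
    )
    for s in all_states:
        in_s = root == s
        n = int(in_s.sum())
        frac[s] = float((n_active[in_s] >= 1).mean()) if n else np.nan
        for k in range(1, len(lineages) + 1):
            spec.loc[s, f"active_in_{k}"] = int((n_active[in_s] == k).sum())
    return FateMap(counts=counts, activation_fraction=pd.Series(frac), specificity=spec)
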