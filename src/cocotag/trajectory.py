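"""Pseudotime utilities: scaling, module scores, smoothing, activation timing.

Pseudotime is the rank of each cell along a previously inferred trajectory,
scaled to [0, 100].  A gene-module score is the per-cell median of per-gene
z-scores.  Activation timing smooths a gene's profile along pseudotime with
tricube-weighted degree-2 local regression (loess), clamps non-positive
predictions to 0, min-max rescales to [0, 1], and reports the earliest
observed pseudotime whose scaled value exceeds 0.5.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata


def scale_pseudotime(order_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Rank cells by ``order_values`` and scale ranks to [0, 100].

    tau_i = 100 * (rank_i - 1) / (n - 1); ties share their mean rank.  A
    single cell gets tau = 0 by convention.
    """
    v = np.asarray(order_values, dtype=float)
    n = v.size
    if n == 0:
        return np.array([])
    if n == 1:
        return np.array([0.0])
    ranks = rankdata(v, method="average")
    return 100.0 * (ranks - 1) / (n - 1)


def module_score(scores: pd.DataFrame, gene_list: Sequence[str]) -> pd.Series:
    """Median per-cell z-score of a gene list (scores: gene x cell)."""
    present = [g for g in gene_list if g in scores.index]
    if not present:
        raise ValueError("no module genes found in the score matrix")
    sub = scores.loc[present]
    mu = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=0)
    z = sub.sub(mu, axis=0).div(sd.replace(0, np.nan), axis=0).fillna(0.0)
    return z.median(axis=0)


def loess(
    x: np.ndarray,
    y: np.ndarray,
    x_out: np.ndarray | None = None,
    span: float = 0.75,
    degree: int = 2,
) -> np.ndarray:
    """Tricube-weighted local polynomial regression (direct evaluation).

    For each prediction point the ``floor(span * n)`` nearest observations
    are weighted by tricube(d / d_max) and a degree-``degree`` weighted
    least-squares polynomial is evaluated at the point — the classic loess
    smoother with its usual defaults (span 0.75, locally quadratic).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if x_out is None:
        x_out = x
    q = int(np.floor(span * n))
    q = max(q, degree + 1)
    q = min(q, n)
    out = np.empty(x_out.size)
    for i, x0 in enumerate(np.asarray(x_out, dtype=float)):
        d = np.abs(x - x0)
        idx = np.argsort(d, kind="stable")[:q]
        dmax = d[idx[-1]]
        if dmax == 0:
            out[i] = y[idx].mean()
            continue
        u = d[idx] / dmax
        w = np.clip(1 - u**3, 0, None) ** 3
        xx = x[idx] - x0  # center for conditioning
        A = np.vander(xx, degree + 1, increasing=True)
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(A * sw[:, None], y[idx] * sw, rcond=None)
        out[i] = coef[0]
    return out


def smooth_profile(
    tau: np.ndarray, values: np.ndarray, span: float = 0.75
) -> np.ndarray:
    """Loess-smoothed profile at the observed pseudotimes, clamped at 0.

    Non-positive fitted values are set to 0 (gene scores are non-negative).
    Requires at least 10 points.
    """
    tau = np.asarray(tau, dtype=float)
    values = np.asarray(values, dtype=float)
    if tau.size < 10:
        raise ValueError("need at least 10 points to smooth a profile")
    order = np.argsort(tau, kind="stable")
    fitted = np.empty_like(tau)
    fitted[order] = loess(tau[order], values[order], span=span)
    return np.where(fitted > 0, fitted, 0.0)


def activation_time(
    tau: np.ndarray, values: np.ndarray, span: float = 0.75
) -> float | None:
    """Earliest pseudotime where the scaled smoothed profile exceeds 0.5.

    Pipeline: loess smooth -> clamp non-positives to 0 -> min-max rescale
    to [0, 1] -> first observed tau (in pseudotime order) with scaled value
    strictly above 0.5.  Flat profiles (zero range after smoothing) have no
    defined activation time and return ``None``.
    """
    tau = np.asarray(tau, dtype=float)
    smoothed = smooth_profile(tau, values, span=span)
    lo, hi = smoothed.min(), smoothed.max()
    # flat up to numerical noise of the local fits -> no activation defined
    if hi - lo <= 1e-10 * max(1.0, abs(hi)):
        return None
    scaled = (smoothed - lo) / (hi - lo)
    order = np.argsort(tau, kind="stable")
    above = scaled[order] > 0.5
    if not above.any():
        return None
    return float(tau[order][np.argmax(above)])


def activation_table(
    tau: np.ndarray,
    scores: pd.DataFrame,
    lineage: str,
    span: float = 0.75,
) -> pd.DataFrame:
    """Activation times for every gene (rows of ``scores``, columns = cells)."""
    rows = []
    for gene in scores.index:
        t = activation_time(tau, scores.loc[gene].to_numpy(), span=span)
        rows.append({"gene": gene, "lineage": lineage, "t_half": np.nan if t is None else t})
    return pd.DataFrame(rows)
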