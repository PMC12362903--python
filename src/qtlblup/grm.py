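"""Genomic relationship matrices (GRM).

VanRaden's first method builds the GRM from centered allele counts,

    G = W W' / (2 * sum_j p_j (1 - p_j)),   w_ij = x_ij - 2 p_j,

where x_ij is the 0/1/2 dosage of animal i at locus j and p_j the frequency
of the allele counted as 2.  The weighted variant inserts a diagonal weight
matrix D (here: per-locus variance contributions 2 p q alpha^2, normalised to
mean one so the diagonal of G stays near one):

    G1 = W D W' / (2 * sum_j p_j (1 - p_j)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GRM", "allele_frequencies", "vanraden_g", "weighted_g", "qtl_variance"]


@dataclass
class GRM:
    """A genomic relationship matrix and the quantities used to build it."""

    matrix: np.ndarray
    p: np.ndarray  # allele frequencies used for centering
    scale: float  # 2 * sum_j p_j (1 - p_j)
    weights: np.ndarray | None = None  # normalised diagonal of D; None = identity

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


def allele_frequencies(X: np.ndarray, rows: np.ndarray | None = None) -> np.ndarray:
    """Per-locus allele frequency: mean dosage / 2 over the reference animals."""
    X = np.asarray(X)
    if rows is not None:
        if len(rows) == 0:
            raise ValueError("reference animal set must be non-empty")
        X = X[rows]
    if X.shape[0] == 0:
        raise ValueError("reference animal set must be non-empty")
    return X.mean(axis=0, dtype=np.float64) / 2.0


def _center_and_scale(X: np.ndarray, p: np.ndarray | None):
    X = np.asarray(X, dtype=np.float64)
    p = allele_frequencies(X) if p is None else np.asarray(p, dtype=np.float64)
    if p.shape != (X.shape[1],):
        raise ValueError("allele frequency vector does not match locus count")
    scale = 2.0 * np.sum(p * (1.0 - p))
    if scale <= 0:
        raise ValueError("all loci fixed: GRM scale is zero")
    W = X - 2.0 * p
    return W, p, float(scale)


def vanraden_g(X: np.ndarray, p: np.ndarray | None = None) -> GRM:
    """VanRaden method-1 GRM; ``p`` defaults to frequencies of the input animals."""
    W, p, scale = _center_and_scale(X, p)
    G = (W @ W.T) / scale
    return GRM(G, p, scale, None)


def weighted_g(X: np.ndarray, weights: np.ndarray, p: np.ndarray | None = None) -> GRM:
    """Weighted GRM with D = diag(weights / mean(weights))."""
    w = np.asarray(weights, dtype=np.float64)
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    if not np.any(w > 0):
        raise ValueError("weights must not all be zero")
    W, p, scale = _center_and_scale(X, p)
    if w.shape != (W.shape[1],):
        raise ValueError("weight vector does not match locus count")
    d = w / w.mean()
    G = ((W * d) @ W.T) / scale
    return GRM(G, p, scale, d)


def qtl_variance(p, alpha) -> np.ndarray | float:
    """Additive variance contributed by a locus: 2 p (1 - p) alpha^2."""
    p = np.asarray(p, dtype=np.float64)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("allele frequencies must lie in [0, 1]")
    a = np.asarray(alpha, dtype=np.float64)
    out = 2.0 * p * (1.0 - p) * a**2
    return float(out) if out.ndim == 0 else out
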