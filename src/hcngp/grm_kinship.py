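"""VanRaden genomic relationship matrix, kinship diagnostics and PCA.

G = ZZ' / (2 * sum_i p_i (1 - p_i)) with Z the column-centered dosage matrix
(dosage - 2p). Under Hardy-Weinberg with unrelated individuals the diagonal
of G averages ~1 and off-diagonals ~0; full sibs average ~0.5. Singular G
(duplicated clones, n < rank) is handled by blending with the identity,
G* = (1-w) G + w I, the standard "bending" that preserves GEBV ranking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg

from .io_config import HcngpError, ValidationError

SYMMETRY_TOL = 1e-10


@dataclass
class RelationshipMatrix:
    """Symmetric clone-indexed covariance structure (VanRaden G or Gaussian K)."""
    clone_ids: list[str]
    values: np.ndarray
    kind: str = "vanraden_G"          # or "gaussian_K"
    blend: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.clone_ids)
        if self.values.shape != (n, n):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match {n} clones")
        if not np.allclose(self.values, self.values.T, atol=SYMMETRY_TOL):
            raise ValidationError("relationship matrix is not symmetric")
        if (np.diag(self.values) <= 0).any():
            raise ValidationError("relationship matrix has non-positive diagonal")

    @property
    def n(self) -> int:
        return len(self.clone_ids)

    def submatrix(self, rows: list[str], cols: list[str] | None = None) -> np.ndarray:
        idx = {c: i for i, c in enumerate(self.clone_ids)}
        ri = [idx[c] for c in rows]
        ci = [idx[c] for c in (cols if cols is not None else rows)]
        return self.values[np.ix_(ri, ci)]

    def restrict(self, clones: list[str]) -> "RelationshipMatrix":
        return RelationshipMatrix(list(clones), self.submatrix(list(clones)),
                                  kind=self.kind, blend=self.blend)


def vanraden_grm(Z: np.ndarray, p: np.ndarray,
                 clone_ids: list[str]) -> RelationshipMatrix:
    """G = ZZ' / (2 sum p_i(1-p_i)). Z must be centered with the matching p."""
    Z = np.asarray(Z, dtype=float)
    p = np.asarray(p, dtype=float)
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0:
        raise HcngpError("all markers monomorphic: VanRaden denominator is zero")
    G = (Z @ Z.T) / denom
    G = (G + G.T) / 2.0  # kill asymmetric rounding noise
    return RelationshipMatrix(list(clone_ids), G, kind="vanraden_G")


def blend_matrix(K: np.ndarray, blend: float) -> np.ndarray:
    """(1-w) K + w I: shrink toward the identity to restore full rank."""
    if blend == 0.0:
        return K
    return (1.0 - blend) * K + blend * np.eye(K.shape[0])


def grm_inverse(G: RelationshipMatrix, blend: float = 0.02) -> np.ndarray:
    """Inverse of the blended matrix G* = (1-w) G + w I.

    Raises a numeric error if G* is still not positive definite (e.g. blend=0
    on a singular G).
    """
    Gstar = blend_matrix(G.values, blend)
    try:
        c, low = scipy.linalg.cho_factor(Gstar)
    except np.linalg.LinAlgError as exc:
        raise HcngpError(
            f"relationship matrix singular even after blending ({blend})"
        ) from exc
    piv = np.abs(np.diag(c))
    # Cholesky pivots scale as sqrt(eigenvalue): 1e-6 flags eigenvalues
    # below ~1e-12 * norm, i.e. numerically singular
    if piv.min() <= 1e-6 * piv.max():
        raise HcngpError(
            f"relationship matrix singular even after blending ({blend})")
    return scipy.linalg.cho_solve((c, low), np.eye(G.n))


def kinship_diagnostics(G: RelationshipMatrix,
                        relatedness_threshold: float = 0.9) -> dict:
    """Distribution summaries of the diagonal (inbreeding) and off-diagonal
    (pairwise relatedness), plus pairs above the relatedness threshold
    (near-duplicates / clones sampled twice)."""
    V = G.values
    d = np.diag(V)
    iu = np.triu_indices(G.n, k=1)
    off = V[iu]
    extreme = [
        (G.clone_ids[i], G.clone_ids[j], float(V[i, j]))
        for i, j in zip(*iu) if V[i, j] >= relatedness_threshold
    ]
    summary = {
        "diagonal": {"min": float(d.min()), "mean": float(d.mean()),
                     "max": float(d.max())},
        "off_diagonal": {"min": float(off.min()) if off.size else np.nan,
                         "mean": float(off.mean()) if off.size else np.nan,
                         "max": float(off.max()) if off.size else np.nan},
        "extreme_pairs": extreme,
    }
    return summary


def grm_pca(G: RelationshipMatrix) -> dict:
    """Eigendecomposition of G: principal components of population structure.

    Returns eigenvalues (decreasing), per-clone scores (PC coordinates
    eigvec * sqrt(eigval)) and variance-explained fractions
    (eigenvalue / trace). Warns on substantially negative eigenvalues.
    """
    vals, vecs = scipy.linalg.eigh(G.values)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    trace = np.trace(G.values)
    if vals[-1] < -1e-8 * max(trace, 1.0):
        warnings.warn("relationship matrix is not PSD "
                      f"(min eigenvalue {vals[-1]:.3g}); consider blending")
    scores = vecs * np.sqrt(np.clip(vals, 0.0, None))[np.newaxis, :]
    frac = vals / trace
    return {
        "eigenvalues": vals,
        "scores": pd.DataFrame(
            scores, index=G.clone_ids,
            columns=[f"PC{i + 1}" for i in range(len(vals))]),
        "variance_explained": frac,
    }
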