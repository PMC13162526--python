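"""Gaussian-kernel construction and RKHS kernel regression fitted by MCMC.

The kernel over clones i, j is K_ij = exp(-d_ij * theta) with d_ij the
squared Euclidean distance between dosage vectors divided by the marker
count (so theta is portable across marker densities; plain Euclidean
distance is available as an alternative). The regression

    y = 1 beta + u + epsilon,   u ~ N(0, K sigma²_u)

is sampled by Gibbs in the eigenbasis of K (whitened coordinates), where
every full conditional is diagonal: this makes the sampler O(n) per
iteration after one eigendecomposition. h² is reported as the posterior
mean of sigma²_u / (sigma²_u + sigma²_e).

With K set to the VanRaden G this is exactly the GBLUP model sampled by
MCMC — the test suite checks the two agree — and it is also the machinery
used for validation-set h² during cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.spatial.distance

from .gblup import ModelFit
from .grm_kinship import RelationshipMatrix, blend_matrix
from .io_config import ConfigError, HcngpError

#: relative eigenvalue cutoff below which kernel directions carry no signal
_EIG_TOL = 1e-10


@dataclass
class KernelSpec:
    theta: float = 1.0
    distance: str = "squared_euclidean_mean"

    def validate(self) -> "KernelSpec":
        if self.theta <= 0:
            raise ConfigError(f"kernel theta must be > 0, got {self.theta}")
        if self.distance not in ("squared_euclidean_mean", "euclidean"):
            raise ConfigError(f"unknown distance kind {self.distance!r}")
        return self


def gaussian_kernel(dosage: np.ndarray, spec: KernelSpec,
                    clone_ids: list[str]) -> RelationshipMatrix:
    """K_ij = exp(-d_ij * theta); unit diagonal by construction.

    ``dosage`` must have no missing values (impute upstream). Distances are
    insensitive to column centering, so raw or centered dosages give the
    same kernel.
    """
    spec.validate()
    X = np.asarray(dosage, dtype=float)
    if np.isnan(X).any():
        raise HcngpError("kernel input contains missing dosages; impute first")
    sq = scipy.spatial.distance.squareform(
        scipy.spatial.distance.pdist(X, metric="sqeuclidean"))
    if spec.distance == "squared_euclidean_mean":
        d = sq / X.shape[1]
    else:
        d = np.sqrt(sq)
    K = np.exp(-d * spec.theta)
    np.fill_diagonal(K, 1.0)
    K = (K + K.T) / 2.0
    return RelationshipMatrix(list(clone_ids), K, kind="gaussian_K")


def fit_rkhs(blues, K: RelationshipMatrix, n_iter: int = 6000,
             burn_in: int = 700, seed: int = 0, df0: float = 5.0,
             s0: float | None = None, df_u: float = 5.0,
             s_u: float | None = None, thin: int = 10) -> ModelFit:
    """Gibbs-sample the kernel regression on the training clones in ``blues``.

    Variance priors are scaled-inverse-chi-square: the residual uses
    (``df0``, ``s0``) with ``s0`` derived from the response variance when not
    given, the kernel variance uses (``df_u``, ``s_u``) with the scale
    matched to the response variance and the mean kernel diagonal when not
    given. Setting df and scale to zero yields the Jeffreys limit
    (scale-invariant, data-dominated), used for validation-set h².
    """
    if n_iter <= burn_in:
        raise ConfigError(f"n_iter ({n_iter}) must exceed burn_in ({burn_in})")
    if isinstance(blues, pd.Series):
        y_ser = blues.astype(float)
    else:
        y_ser = blues.series().astype(float)
    train = list(y_ser.index)
    missing = [c for c in train if c not in set(K.clone_ids)]
    if missing:
        raise HcngpError(f"kernel lacks clone(s) {missing[:5]}")
    Ktt = K.submatrix(train)
    y = y_ser.to_numpy()
    n = len(y)

    vals, vecs = scipy.linalg.eigh(Ktt)
    trace = float(np.trace(Ktt))
    if vals[0] < -1e-8 * max(trace, 1.0):
        raise HcngpError(f"kernel is not PSD (min eigenvalue {vals[0]:.3g}); "
                         "blend it toward the identity first")
    keep = vals > _EIG_TOL * max(vals.max(), 1.0)
    d = vals[keep]
    U = vecs[:, keep]
    r = len(d)

    vary = max(float(np.var(y, ddof=1)) if n > 1 else 1.0, 1e-12)
    r2 = 0.5
    S0r = s0 if s0 is not None else vary * (1 - r2) * (df0 + 2)
    S_u = s_u if s_u is not None else \
        vary * r2 * (df_u + 2) / max(float(np.mean(np.diag(Ktt))), 1e-12)

    rng = np.random.default_rng(seed)
    t = U.T @ y                      # rotated response (r coords)
    x = U.T @ np.ones(n)
    beta = float(np.mean(y))
    alpha = np.zeros(r)
    sigu = vary * r2
    sige = vary * (1 - r2)

    n_keep = n_iter - burn_in
    alpha_mean = np.zeros(r)
    beta_mean = 0.0
    h2_mean = 0.0
    sigu_mean = 0.0
    sige_mean = 0.0
    n_store = n_iter // thin + 1
    sige_chain = np.full(n_store, np.nan)
    h2_chain = np.full(n_store, np.nan)
    ks = 0
    yty = float(y @ y)
    ysum = float(y.sum())

    for it in range(n_iter):
        resid = t - x * beta
        v = 1.0 / (1.0 / sige + 1.0 / (sigu * d))
        mean = v * resid / sige
        alpha = mean + rng.standard_normal(r) * np.sqrt(v)

        bhat = float(np.mean(y)) - float(x @ alpha) / n
        beta = bhat + rng.standard_normal() * np.sqrt(sige / n)

        sigu = max((S_u + float(np.sum(alpha ** 2 / d)))
                   / (2.0 * rng.gamma((df_u + r) / 2.0, 1.0)), 1e-12)
        # residual: in-span part plus the out-of-span part of (y - beta*1),
        # which carries no genetic signal (alpha = 0 there by construction)
        rb = t - x * beta
        e2_span = float(np.sum((rb - alpha) ** 2))
        e2_perp = max(yty - 2 * beta * ysum + n * beta * beta
                      - float(rb @ rb), 0.0)
        sige = max((S0r + e2_span + e2_perp)
                   / (2.0 * rng.gamma((df0 + n) / 2.0, 1.0)), 1e-12)

        h2 = sigu / (sigu + sige)
        if it % thin == 0:
            sige_chain[ks] = sige
            h2_chain[ks] = h2
            ks += 1
        if it >= burn_in:
            alpha_mean += alpha
            beta_mean += beta
            h2_mean += h2
            sigu_mean += sigu
            sige_mean += sige

    alpha_mean /= n_keep
    u = U @ alpha_mean
    return ModelFit(
        model="rkhs",
        beta=beta_mean / n_keep,
        gebv=pd.Series(u, index=train),
        varcomp={"sigma2_u": sigu_mean / n_keep, "sigma2_e": sige_mean / n_keep},
        h2=h2_mean / n_keep,
        meta={"n_iter": n_iter, "burn_in": burn_in, "seed": seed,
              "kind": K.kind, "sige_chain": sige_chain[:ks],
              "h2_chain": h2_chain[:ks], "n_eigen": r},
    )


def predict_rkhs(fit: ModelFit, K_full: RelationshipMatrix,
                 validation_ids: list[str], blend: float = 0.0) -> pd.Series:
    """u_val = K_vt K_tt^-1 u_train; prediction = beta + u_val."""
    train = fit.clone_ids
    known = set(K_full.clone_ids)
    absent = [c for c in list(validation_ids) + train if c not in known]
    if absent:
        raise HcngpError(f"kernel lacks clone(s) {absent[:5]}")
    Ktt = blend_matrix(K_full.submatrix(train), blend)
    Kvt = (1.0 - blend) * K_full.submatrix(list(validation_ids), train)
    # least-squares solve = pseudo-inverse on singular kernels; exact because
    # the sampled u lies in the range of K_tt (eigenbasis construction)
    uhat = scipy.linalg.lstsq(Ktt, fit.gebv.to_numpy())[0]
    return pd.Series(Kvt @ uhat + fit.beta, index=list(validation_ids))
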