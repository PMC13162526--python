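"""GBLUP: genomic best linear unbiased prediction on a relationship matrix.

Model: Y = 1 beta + g + epsilon, g ~ N(0, K sigma²_g), epsilon ~ N(0, I
sigma²_e), with Y the per-clone BLUEs treated as equally weighted responses
(their standard errors are not propagated — the usual two-stage shortcut).
Variance components come from EM-REML (with guarded Aitken acceleration) on
Henderson's equations; training GEBVs are the BLUPs

    g_hat = sigma²_g K (sigma²_g K + sigma²_e I)^(-1) (y - 1 beta)

and validation clones are predicted by the conditional mean of the joint
Gaussian, g_val = K_vt K_tt^(-1) g_hat.

Narrow-sense heritability is reported as h² = sigma²_g / (sigma²_g +
sigma²_e). When K is built from the same centered dosages as a ridge
regression on marker effects, GBLUP GEBVs coincide with the RR-BLUP
predictions — an identity the test suite checks numerically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grm_kinship import RelationshipMatrix, blend_matrix
from .io_config import HcngpError, logger
from .pheno_blues import em_reml

DEFAULT_BLEND = 0.02


@dataclass
class ModelFit:
    """A fitted genomic prediction model (REML or MCMC based)."""
    model: str
    beta: float
    gebv: pd.Series                  # training clones
    varcomp: dict
    h2: float
    meta: dict = field(default_factory=dict)

    @property
    def clone_ids(self) -> list[str]:
        return list(self.gebv.index)

    def to_json_dict(self) -> dict:
        return {"model": self.model, "beta": self.beta, "h2": self.h2,
                "varcomp": self.varcomp,
                "meta": {k: v for k, v in self.meta.items()
                         if np.isscalar(v) or isinstance(v, str)}}


def _training_series(blues) -> pd.Series:
    """Accept a BlueSet or a clone-indexed Series of BLUEs."""
    if isinstance(blues, pd.Series):
        return blues.astype(float)
    return blues.series().astype(float)


def fit_gblup(blues, K: RelationshipMatrix, blend: float = DEFAULT_BLEND,
              tol: float = 1e-6, max_iter: int = 500) -> ModelFit:
    """REML fit of the GBLUP model on the training clones in ``blues``.

    A VanRaden G built from column-centered dosages is singular (the vector
    of ones is in its null space), so the random effect is parameterized
    through the eigendecomposition of the (optionally blended) K: g = U
    D^(1/2) a with a ~ N(0, I sigma²_g), which EM-REML handles without ever
    inverting K. ``blend = 0`` is legitimate here and keeps the model exactly
    the K-covariance one.
    """
    y_ser = _training_series(blues)
    train = list(y_ser.index)
    missing = [c for c in train if c not in set(K.clone_ids)]
    if missing:
        raise HcngpError(f"relationship matrix lacks clone(s) {missing[:5]}"
                         + ("..." if len(missing) > 5 else ""))
    Kb = blend_matrix(K.submatrix(train), blend)
    y = y_ser.to_numpy()
    n = len(y)
    vals, vecs = np.linalg.eigh(Kb)
    if vals[0] < -1e-8 * max(float(np.trace(Kb)), 1.0):
        raise HcngpError("relationship matrix has substantially negative "
                         "eigenvalues; blend it toward the identity")
    keep = vals > 1e-12 * max(vals.max(), 1.0)
    Zeff = vecs[:, keep] * np.sqrt(vals[keep])[np.newaxis, :]
    X = np.ones((n, 1))
    res = em_reml(y, X, [("sigma2_g", Zeff, None)], tol=tol,
                  max_iter=max_iter, accelerate=True)
    if not res["converged"]:
        logger.warning("GBLUP REML flagged as non-converged")
    s_g, s_e = res["varcomp"]["sigma2_g"], res["varcomp"]["sigma2_e"]
    h2 = s_g / (s_g + s_e)
    beta = float(res["beta"][0])
    ghat = Zeff @ res["u"]["sigma2_g"]
    # w_vec = sigma2_g V^-1 (y - 1 beta) lets validation clones be predicted
    # without inverting K: g_val = (1-blend) K_vt w_vec
    V = s_g * Kb + s_e * np.eye(n)
    w_vec = s_g * np.linalg.solve(V, y - beta)
    return ModelFit(
        model="gblup",
        beta=beta,
        gebv=pd.Series(ghat, index=train),
        varcomp={"sigma2_g": s_g, "sigma2_e": s_e},
        h2=float(h2),
        meta={"blend": blend, "converged": res["converged"],
              "kind": K.kind, "w_vec": w_vec},
    )


def predict_gebv(fit: ModelFit, K_full: RelationshipMatrix,
                 validation_ids: list[str]) -> pd.Series:
    """Validation GEBVs by the Gaussian conditional mean K_vt K_tt^-1 g_hat.

    Computed through the stored w_vec = sigma²_g V^-1 (y - 1 beta), which
    equals K_vt K_tt^-1 g_hat whenever K_tt is invertible (g_hat =
    K_tt w_vec) and remains exact for singular K_tt because g_hat lies in
    its range. The blend used at fit time applies to the training block
    only; the identity contributes nothing to validation-by-training
    covariances, which are scaled by (1 - blend).
    """
    train = fit.clone_ids
    known = set(K_full.clone_ids)
    absent = [c for c in list(validation_ids) + train if c not in known]
    if absent:
        raise HcngpError(f"relationship matrix lacks clone(s) {absent[:5]}")
    w = fit.meta.get("blend", DEFAULT_BLEND)
    Kvt = (1.0 - w) * K_full.submatrix(list(validation_ids), train)
    return pd.Series(Kvt @ fit.meta["w_vec"], index=list(validation_ids))
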