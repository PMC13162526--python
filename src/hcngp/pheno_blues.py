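"""Multi-location mixed model: REML variance components, per-clone BLUEs, H².

The plot-mean HCN score is modelled as

    y = X beta + Z_b block(trial) + Z_cl clone:trial + epsilon

with clone FIXED (cell-means coding, so the GLS estimates are the per-clone
BLUEs) and block-within-trial and clone-by-trial random. Year is folded into
location as a trial factor (location-year combinations). A companion fit with
clone RANDOM supplies the clone variance needed for broad-sense heritability

    H² = sigma²_c / (sigma²_c + sigma²_cl + sigma²_e)

on the entry-mean scale exactly as conventionally printed for this design
(no division of sigma²_cl or sigma²_e by location or replicate counts; an
entry-mean alternative is available as a separate function).

Variance components are estimated by EM-REML on Henderson's mixed-model
equations; EM is monotone in the REML objective, which the test suite
asserts along the stored iteration path.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import scipy.linalg

from .io_config import HcngpError, PhenotypeSet, logger

REML_TOL = 1e-6
REML_MAX_ITER = 200
_VAR_FLOOR_FRAC = 1e-8


@dataclass
class VarianceComponents:
    sigma2_c: float      # clone
    sigma2_b: float      # block within trial (location-year)
    sigma2_cl: float     # clone x trial interaction
    sigma2_e: float      # plot residual
    converged: bool = True

    def as_dict(self) -> dict:
        return {"sigma2_c": self.sigma2_c, "sigma2_b": self.sigma2_b,
                "sigma2_cl": self.sigma2_cl, "sigma2_e": self.sigma2_e,
                "converged": self.converged}


@dataclass
class BlueSet:
    """Per-clone BLUEs with their REML backdrop."""
    blues: pd.DataFrame              # clone_id, blue, se
    varcomp: VarianceComponents
    H2: float
    grand_mean: float
    reml_path: Optional[list] = None

    @property
    def clone_ids(self) -> list[str]:
        return list(self.blues["clone_id"])

    def series(self) -> pd.Series:
        return pd.Series(self.blues["blue"].to_numpy(),
                         index=self.blues["clone_id"])


# ---------------------------------------------------------------------------
# EM-REML core (shared with the GBLUP module)
# ---------------------------------------------------------------------------

def em_reml(y: np.ndarray, X: np.ndarray, terms: list[tuple[str, np.ndarray, Optional[np.ndarray]]],
            tol: float = REML_TOL, max_iter: int = REML_MAX_ITER,
            init: Optional[dict] = None, track_path: bool = False,
            accelerate: bool = False):
    """EM-REML for y = X beta + sum_i Z_i u_i + e, u_i ~ N(0, K_i sigma²_i).

    ``terms`` is a list of (name, Z_i, Kinv_i) with Kinv_i = None meaning the
    identity covariance. Returns a dict with beta, u (per term), varcomp
    (per term + 'sigma2_e'), standard errors of beta, convergence flag and,
    optionally, the variance-component path across iterations.

    ``accelerate`` turns on Aitken delta-squared extrapolation of the variance
    components every few EM steps (guarded: rejected when it leaves the
    positive orthant or is not finite). Plain EM is monotone in the REML
    objective; the accelerated path need not be, so acceleration is off by
    default and off whenever the path is tracked.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise HcngpError("fixed-effect design is rank deficient: clone "
                         "effects are confounded with the trial design")
    if n <= p:
        raise HcngpError("no residual degrees of freedom: clone effects are "
                         "confounded with plots (n <= number of fixed effects)")

    W = np.hstack([X] + [Z for _, Z, _ in terms])
    WtW = W.T @ W
    Wty = W.T @ y
    yty = float(y @ y)
    q = [Z.shape[1] for _, Z, _ in terms]
    offs = np.cumsum([p] + q)

    vary = max(float(np.var(y)), 1e-12)
    floor = _VAR_FLOOR_FRAC * vary
    sig = {name: vary / (len(terms) + 1) for name, _, _ in terms}
    sig_e = vary / (len(terms) + 1)
    if init:
        sig.update({k: v for k, v in init.items() if k != "sigma2_e"})
        sig_e = init.get("sigma2_e", sig_e)

    path = []
    hist: list[np.ndarray] = []
    converged = False
    beta = np.zeros(p)
    u = {name: np.zeros(k) for (name, _, _), k in zip(terms, q)}
    se_beta = np.zeros(p)
    for _ in range(max_iter):
        C = WtW.copy()
        for t, (name, _, Kinv) in enumerate(terms):
            lam = sig_e / max(sig[name], floor)
            a, b = offs[t], offs[t + 1]
            if Kinv is None:
                C[a:b, a:b] += lam * np.eye(q[t])
            else:
                C[a:b, a:b] += lam * Kinv
        try:
            cf = scipy.linalg.cho_factor(C)
        except np.linalg.LinAlgError as exc:
            raise HcngpError("mixed-model equations singular; the design is "
                             "confounded") from exc
        Cinv = scipy.linalg.cho_solve(cf, np.eye(C.shape[0]))
        s = Cinv @ Wty
        beta = s[:p]
        new_sig = {}
        for t, (name, _, Kinv) in enumerate(terms):
            a, b = offs[t], offs[t + 1]
            ut = s[a:b]
            u[name] = ut
            if Kinv is None:
                quad = float(ut @ ut)
                tr = float(np.trace(Cinv[a:b, a:b]))
            else:
                quad = float(ut @ Kinv @ ut)
                tr = float(np.trace(Kinv @ Cinv[a:b, a:b]))
            new_sig[name] = max((quad + sig_e * tr) / q[t], floor)
        new_sig_e = max(float(yty - s @ Wty) / (n - p), floor)
        se_beta = np.sqrt(np.maximum(np.diag(Cinv[:p, :p]), 0.0) * new_sig_e)
        if track_path:
            path.append({**new_sig, "sigma2_e": new_sig_e})
        rel = max(
            max(abs(new_sig[k] - sig[k]) / (sig[k] + 1e-12) for k in sig),
            abs(new_sig_e - sig_e) / (sig_e + 1e-12),
        )
        if accelerate and not track_path:
            hist.append(np.array([*new_sig.values(), new_sig_e]))
            if len(hist) >= 3:
                t0, t1, t2 = hist[-3], hist[-2], hist[-1]
                d1, d2 = t1 - t0, t2 - t1
                with np.errstate(divide="ignore", invalid="ignore"):
                    ratio = np.where(np.abs(d1) > 1e-300, d2 / d1, 0.0)
                    # geometric extrapolation theta_inf = t2 + d2*r/(1-r),
                    # component-wise, only for stable contractions
                    ok = (ratio > 0) & (ratio < 0.999)
                    acc = np.where(ok, t2 + d2 * ratio / (1.0 - ratio), t2)
                if np.all(np.isfinite(acc)) and np.all(acc > floor):
                    keys = list(new_sig)
                    new_sig = dict(zip(keys, acc[:-1]))
                    new_sig_e = float(acc[-1])
                    hist.clear()
        sig, sig_e = new_sig, new_sig_e
        if rel < tol:
            converged = True
            break
    if not converged:
        logger.warning("EM-REML did not converge in %d iterations "
                       "(returning last iterate)", max_iter)
    # one final solve at the converged variance components so beta/u/se are
    # consistent with the reported varcomp (not one EM step behind)
    C = WtW.copy()
    for t, (name, _, Kinv) in enumerate(terms):
        lam = sig_e / max(sig[name], floor)
        a, b = offs[t], offs[t + 1]
        C[a:b, a:b] += lam * (np.eye(q[t]) if Kinv is None else Kinv)
    cf = scipy.linalg.cho_factor(C)
    Cinv = scipy.linalg.cho_solve(cf, np.eye(C.shape[0]))
    s = Cinv @ Wty
    beta = s[:p]
    for t, (name, _, _) in enumerate(terms):
        u[name] = s[offs[t]:offs[t + 1]]
    se_beta = np.sqrt(np.maximum(np.diag(Cinv[:p, :p]), 0.0) * sig_e)
    return {
        "beta": beta, "se_beta": se_beta, "u": u,
        "varcomp": {**sig, "sigma2_e": sig_e},
        "converged": converged, "path": path if track_path else None,
    }


def reml_loglik(y: np.ndarray, X: np.ndarray,
                terms: list[tuple[str, np.ndarray, Optional[np.ndarray]]],
                varcomp: dict) -> float:
    """Direct REML log-likelihood (small-n oracle for monotonicity checks)."""
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = len(y)
    V = varcomp["sigma2_e"] * np.eye(n)
    for name, Z, Kinv in terms:
        K = np.eye(Z.shape[1]) if Kinv is None else np.linalg.inv(Kinv)
        V += varcomp[name] * (Z @ K @ Z.T)
    Vinv = np.linalg.inv(V)
    XtVinvX = X.T @ Vinv @ X
    beta = np.linalg.solve(XtVinvX, X.T @ Vinv @ y)
    r = y - X @ beta
    _, ld_v = np.linalg.slogdet(V)
    _, ld_x = np.linalg.slogdet(XtVinvX)
    return float(-0.5 * (ld_v + ld_x + r @ Vinv @ r))


# ---------------------------------------------------------------------------
# Phenotypic analysis
# ---------------------------------------------------------------------------

def _design(pheno: PhenotypeSet):
    df = pheno.data.copy()
    df["trial"] = df["location"].astype(str) + "_" + df["year"].astype(str)
    df["block"] = df["trial"] + ":" + df["block_id"].astype(str)
    df["clone_trial"] = df["clone_id"].astype(str) + ":" + df["trial"]
    return df


def _dummies(series: pd.Series) -> tuple[np.ndarray, list[str]]:
    cat = pd.Categorical(series)
    Z = pd.get_dummies(cat, dtype=float).to_numpy()
    return Z, list(cat.categories)


def fit_mixed_model(pheno: PhenotypeSet, tol: float = REML_TOL,
                    max_iter: int = REML_MAX_ITER,
                    track_path: bool = False) -> BlueSet:
    """Fit the trial mixed model and return BLUEs, variance components and H².

    Two REML fits are run: clone fixed (cell-means GLS -> BLUEs and their
    standard errors) and clone random (sigma²_c for H²). The clone-by-trial
    term is included only when at least two trials are present (with a single
    trial it is confounded with clone).
    """
    df = _design(pheno)
    if df["clone_id"].nunique() < 2:
        raise HcngpError("need at least 2 clones")
    y = df["plot_mean"].to_numpy(dtype=float)
    X, clone_levels = _dummies(df["clone_id"])
    Zb, _ = _dummies(df["block"])
    n_trials = df["trial"].nunique()
    multi_trial = n_trials >= 2

    terms_fixed = [("sigma2_b", Zb, None)]
    if multi_trial:
        Zcl, _ = _dummies(df["clone_trial"])
        terms_fixed.append(("sigma2_cl", Zcl, None))
    else:
        logger.info("single trial: clone-by-trial term dropped (confounded)")

    fit_f = em_reml(y, X, terms_fixed, tol=tol, max_iter=max_iter,
                    track_path=track_path, accelerate=True)
    blues = pd.DataFrame({
        "clone_id": clone_levels,
        "blue": fit_f["beta"],
        "se": fit_f["se_beta"],
    })

    # companion fit: clone random, intercept fixed -> sigma2_c for H2
    Xr = np.ones((len(y), 1))
    Zc, _ = _dummies(df["clone_id"])
    terms_rand = [("sigma2_c", Zc, None), ("sigma2_b", Zb, None)]
    if multi_trial:
        terms_rand.append(("sigma2_cl", Zcl, None))
    fit_r = em_reml(y, Xr, terms_rand, tol=tol, max_iter=max_iter,
                    accelerate=True)

    vc = VarianceComponents(
        sigma2_c=fit_r["varcomp"]["sigma2_c"],
        sigma2_b=fit_r["varcomp"]["sigma2_b"],
        sigma2_cl=fit_r["varcomp"].get("sigma2_cl", 0.0),
        sigma2_e=fit_r["varcomp"]["sigma2_e"],
        converged=fit_f["converged"] and fit_r["converged"],
    )
    return BlueSet(
        blues=blues,
        varcomp=vc,
        H2=broad_sense_H2(vc),
        grand_mean=float(np.mean(fit_f["beta"])),
        reml_path=fit_f["path"],
    )


def broad_sense_H2(vc: VarianceComponents) -> float:
    """H² = sigma²_c / (sigma²_c + sigma²_cl + sigma²_e), entry scale as printed."""
    denom = vc.sigma2_c + vc.sigma2_cl + vc.sigma2_e
    if denom <= 0:
        raise HcngpError("H2 undefined: all variance components are zero")
    return vc.sigma2_c / denom


def broad_sense_H2_entry_mean(vc: VarianceComponents, n_locations: int,
                              n_plots: int) -> float:
    """Conventional entry-mean alternative: interaction and residual variances
    divided by the numbers of locations and plots. Off by default; the
    headline H² uses :func:`broad_sense_H2`."""
    denom = (vc.sigma2_c + vc.sigma2_cl / n_locations
             + vc.sigma2_e / n_plots)
    if denom <= 0:
        raise HcngpError("H2 undefined: all variance components are zero")
    return vc.sigma2_c / denom
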