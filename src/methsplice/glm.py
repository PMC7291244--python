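"""Batched IRLS fitting of many small GLMs sharing one design shape.

The genome-wide scans fit one small GLM per feature (per exon bin, per gene,
per probe-bin combination).  Looping over statsmodels fits is too slow at
tens of thousands of features, so this module implements iteratively
reweighted least squares vectorized across features with ``numpy`` batch
linear algebra.  Supported families:

* ``binomial``  — logit link; response is a proportion in [0, 1] with
  per-observation trial counts (quasi-binomial when the Pearson dispersion
  is applied to the standard errors).
* ``poisson``   — log link, optional offset (quasi-Poisson via dispersion).
* ``negbin``    — log link with a fixed per-feature dispersion ``alpha``
  (NB2 variance mu + alpha * mu**2).

Prior weights of zero mask observations (used for per-feature missing data).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_ETA_MAX = 30.0
_MU_EPS = 1e-10


@dataclass
class BatchedGLMResult:
    coef: np.ndarray            # (C, p)
    cov_unscaled: np.ndarray    # (C, p, p) — multiply by dispersion for quasi SEs
    mu: np.ndarray              # (C, n) fitted means
    pearson_phi: np.ndarray     # (C,) Pearson chi2 / df_resid
    df_resid: np.ndarray        # (C,)
    converged: np.ndarray       # (C,) bool
    separated: np.ndarray       # (C,) bool — runaway coefficients (binomial)

    def se(self, quasi: bool = True, phi: np.ndarray | None = None) -> np.ndarray:
        """Standard errors; scaled by sqrt(dispersion) when ``quasi``."""
        base = np.sqrt(np.maximum(np.diagonal(self.cov_unscaled, axis1=1, axis2=2), 0.0))
        if quasi:
            scale = self.pearson_phi if phi is None else phi
            base = base * np.sqrt(np.maximum(scale, _MU_EPS))[:, None]
        return base


def _as_batched_X(X: np.ndarray, C: int) -> tuple[np.ndarray, bool]:
    X = np.asarray(X, dtype=float)
    if X.ndim == 2:
        return X, True
    if X.ndim == 3 and X.shape[0] == C:
        return X, False
    raise ValueError("X must be (n, p) shared or (C, n, p) batched")


def batched_glm(
    y: np.ndarray,
    X: np.ndarray,
    family: str,
    trials: np.ndarray | None = None,
    offset: np.ndarray | None = None,
    weights: np.ndarray | None = None,
    alpha: np.ndarray | None = None,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> BatchedGLMResult:
    y = np.asarray(y, dtype=float)
    if y.ndim != 2:
        raise ValueError("y must be (C, n)")
    C, n = y.shape
    Xa, shared = _as_batched_X(X, C)
    p = Xa.shape[-1]
    w_prior = np.ones((C, n)) if weights is None else np.asarray(weights, float)
    off = np.zeros((C, n)) if offset is None else np.broadcast_to(
        np.asarray(offset, float), (C, n)).copy()

    if family == "binomial":
        m = np.ones((C, n)) if trials is None else np.broadcast_to(
            np.asarray(trials, float), (C, n))
        mu = np.clip((y * m + 0.5) / (m + 1.0), 1e-4, 1 - 1e-4)
        eta = np.log(mu / (1 - mu))
    elif family in ("poisson", "negbin"):
        mu = np.maximum(y, 0.0) + np.maximum(y.mean(axis=1, keepdims=True), 0.1) * 0.1
        eta = np.log(mu)
        if family == "negbin":
            if alpha is None:
                raise ValueError("negbin family requires alpha")
            alpha = np.asarray(alpha, float).reshape(C, 1)
    else:
        raise ValueError(f"unknown family {family!r}")

    coef = np.zeros((C, p))
    eta_lin = eta - off
    converged = np.zeros(C, dtype=bool)

    for _ in range(max_iter):
        if family == "binomial":
            dmu = mu * (1 - mu)
            irls_w = w_prior * m * dmu
        elif family == "poisson":
            dmu = mu
            irls_w = w_prior * mu
        else:  # negbin
            dmu = mu
            irls_w = w_prior * mu / (1.0 + alpha * mu)
        z = eta_lin + (y - mu) / np.maximum(dmu, _MU_EPS)
        if shared:
            A = np.einsum("ni,cn,nj->cij", Xa, irls_w, Xa, optimize=True)
            b = np.einsum("ni,cn->ci", Xa, irls_w * z, optimize=True)
        else:
            A = np.einsum("cni,cn,cnj->cij", Xa, irls_w, Xa, optimize=True)
            b = np.einsum("cni,cn->ci", Xa, irls_w * z, optimize=True)
        try:
            new_coef = np.linalg.solve(A, b[..., None])[..., 0]
        except np.linalg.LinAlgError:
            ridge = 1e-8 * np.eye(p)
            new_coef = np.linalg.solve(A + ridge, b[..., None])[..., 0]
        if not np.all(np.isfinite(new_coef)):
            # singular feature (e.g. constant response): freeze at zero update
            bad = ~np.isfinite(new_coef).all(axis=1)
            new_coef[bad] = coef[bad]
        delta = np.max(np.abs(new_coef - coef), axis=1)
        coef = new_coef
        if shared:
            eta_lin = coef @ Xa.T
        else:
            eta_lin = np.einsum("cni,ci->cn", Xa, coef, optimize=True)
        eta = np.clip(eta_lin + off, -_ETA_MAX, _ETA_MAX)
        eta_lin = eta - off
        if family == "binomial":
            mu = 1.0 / (1.0 + np.exp(-eta))
            mu = np.clip(mu, _MU_EPS, 1 - _MU_EPS)
        else:
            mu = np.exp(eta)
            mu = np.maximum(mu, _MU_EPS)
        converged = delta < tol
        if converged.all():
            break

    df_resid = (w_prior > 0).sum(axis=1) - p
    if family == "binomial":
        var = mu * (1 - mu) / np.maximum(m, _MU_EPS)
        separated = np.abs(coef).max(axis=1) > 15.0
    elif family == "poisson":
        var = mu
        separated = np.zeros(C, dtype=bool)
    else:
        var = mu + alpha * mu ** 2
        separated = np.zeros(C, dtype=bool)
    resid2 = w_prior * (y - mu) ** 2 / np.maximum(var, _MU_EPS)
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = resid2.sum(axis=1) / np.where(df_resid > 0, df_resid, np.nan)

    # final unscaled covariance from the information matrix at convergence
    if family == "binomial":
        irls_w = w_prior * m * mu * (1 - mu)
    elif family == "poisson":
        irls_w = w_prior * mu
    else:
        irls_w = w_prior * mu / (1.0 + alpha * mu)
    if shared:
        A = np.einsum("ni,cn,nj->cij", Xa, irls_w, Xa, optimize=True)
    else:
        A = np.einsum("cni,cn,cnj->cij", Xa, irls_w, Xa, optimize=True)
    try:
        cov = np.linalg.inv(A)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(A)

    return BatchedGLMResult(
        coef=coef, cov_unscaled=cov, mu=mu, pearson_phi=phi,
        df_resid=df_resid.astype(float), converged=converged, separated=separated,
    )


def drop_aliased_columns(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str], list[str]]:
    """Drop linearly dependent design columns, keeping earlier columns.

    Columns are scanned left to right; a column that does not increase the
    rank of the kept set is dropped ("last-entered first").  Returns the
    reduced matrix, kept names and dropped names.
    """
    X = np.asarray(X, dtype=float)
    kept_idx: list[int] = []
    dropped: list[str] = []
    rank = 0
    for j in range(X.shape[1]):
        trial = X[:, kept_idx + [j]]
        new_rank = np.linalg.matrix_rank(trial)
        if new_rank > rank:
            kept_idx.append(j)
            rank = new_rank
        else:
            dropped.append(names[j])
    return X[:, kept_idx], [names[j] for j in kept_idx], dropped
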