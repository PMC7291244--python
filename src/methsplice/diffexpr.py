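"""Genome-wide differential tests: expression, exon usage, methylation.

Three simplified but statistically faithful re-implementations:

* ``test_dge`` — per-gene negative-binomial log-linear Wald test with
  method-of-moments dispersion shrunk toward a mean-dispersion trend.
* ``test_deu`` — per-bin quasi-binomial logit model of the bin's share of its
  gene's reads, with per-bin overdispersion shrunk toward a fitted trend.
* ``test_dmr`` — probe-wise linear model of M-values with an empirical-Bayes
  moderated t-statistic (residual variances shrunk toward a common prior
  estimated by moment matching of the scaled-F distribution of the sample
  variances, on the log scale).

All p-values are adjusted with Benjamini-Hochberg.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import special, stats

from .glm import batched_glm, drop_aliased_columns

logger = logging.getLogger(__name__)

RESULT_COLUMNS = ["feature_id", "effect", "se", "stat", "p", "fdr"]
_DISP_FLOOR = 1e-8


def benjamini_hochberg(p) -> np.ndarray:
    """Step-up BH adjusted p-values, monotonized and capped at 1.

    NaN entries propagate NaN and do not count toward the number of tests.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    ps = p[ok]
    m = ps.size
    if m == 0:
        return out
    if (ps < 0).any() or (ps > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    order = np.argsort(ps, kind="mergesort")
    ranked = ps[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    vals = np.empty(m)
    vals[order] = np.minimum(adj, 1.0)
    out[ok] = vals
    return out


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------

def build_design(
    sheet: pd.DataFrame,
    covariates: tuple[str, ...] = ("condition",),
    pcs: pd.DataFrame | None = None,
    min_resid_df: int = 2,
) -> pd.DataFrame:
    """Build a full-rank design matrix from the sample sheet.

    ``covariates`` may contain ``condition``, ``sex``, ``age``, the five drug
    flags, ``batch_date``, ``flowcell``; principal-component scores are
    appended when ``pcs`` is given.  Aliased columns (e.g. drug flags that are
    constant or perfectly confounded with condition) are dropped
    deterministically, later-entered columns first, with a logged warning.
    The condition indicator (DCM = 1) is always first after the intercept.
    """
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(sheet))}
    for cov in covariates:
        if cov == "condition":
            cols["condition"] = (sheet["condition"] == "DCM").to_numpy(float)
        elif cov == "sex":
            cols["sex"] = (sheet["sex"] == "F").to_numpy(float)
        elif cov == "age":
            cols["age"] = sheet["age"].to_numpy(float)
        elif cov in ("tacrolimus", "mycophenolate", "steroid", "everolimus",
                     "ciclosporin"):
            cols[cov] = sheet[cov].to_numpy(float)
        elif cov in ("batch_date", "flowcell"):
            levels = sorted(sheet[cov].astype(str).unique())
            for lev in levels[1:]:
                cols[f"{cov}_{lev}"] = (sheet[cov].astype(str) == lev).to_numpy(float)
        else:
            raise ValueError(f"unknown covariate {cov!r}")
    if pcs is not None:
        aligned = pcs.loc[sheet["sample_id"]]
        for c in pcs.columns:
            cols[c] = aligned[c].to_numpy(float)
    names = list(cols)
    X = np.column_stack([cols[c] for c in names])
    if "condition" not in names:
        raise ValueError("design must include the condition column")
    Xr, kept, dropped = drop_aliased_columns(X, names)
    if dropped:
        logger.warning("build_design: dropped aliased columns: %s", ", ".join(dropped))
    if "condition" not in kept:
        raise ValueError("condition column was aliased away; design unusable")
    # small cohorts: trim trailing covariates so residual df stays positive
    n = Xr.shape[0]
    trimmed = []
    while Xr.shape[1] > max(n - min_resid_df, 2):
        for j in range(Xr.shape[1] - 1, -1, -1):
            if kept[j] not in ("intercept", "condition"):
                trimmed.append(kept.pop(j))
                Xr = np.delete(Xr, j, axis=1)
                break
        else:
            break
    if trimmed:
        logger.warning("build_design: trimmed covariates to preserve residual "
                       "degrees of freedom: %s", ", ".join(trimmed))
    return pd.DataFrame(Xr, columns=kept, index=sheet["sample_id"].to_numpy())


# ---------------------------------------------------------------------------
# dispersion trend + shrinkage
# ---------------------------------------------------------------------------

def fit_dispersion_trend(raw: np.ndarray, mean: np.ndarray,
                         shrink_weight: float = 0.5) -> pd.DataFrame:
    """Fit a log-log linear mean-dispersion trend and shrink toward it.

    The shrunken value is the geometric interpolation
    ``exp(w * log(trend) + (1 - w) * log(raw))`` and therefore always lies
    between the (floored) raw value and the trend.
    """
    raw_f = np.maximum(np.nan_to_num(raw, nan=_DISP_FLOOR), _DISP_FLOOR)
    mean_f = np.maximum(np.nan_to_num(mean, nan=_DISP_FLOOR), _DISP_FLOOR)
    usable = raw_f > _DISP_FLOOR * 10
    log_mean = np.log(mean_f)
    if usable.sum() >= 10 and np.std(log_mean[usable]) > 0:
        slope, intercept = np.polyfit(log_mean[usable], np.log(raw_f[usable]), 1)
        trend = np.exp(intercept + slope * log_mean)
    else:
        trend = np.full_like(raw_f, np.exp(np.mean(np.log(raw_f[usable])))
                             if usable.any() else _DISP_FLOOR)
    trend = np.maximum(trend, _DISP_FLOOR)
    shrunk = np.exp(shrink_weight * np.log(trend)
                    + (1.0 - shrink_weight) * np.log(raw_f))
    return pd.DataFrame({"disp_raw": raw_f, "disp_trend": trend,
                         "disp_shrunk": shrunk})


# ---------------------------------------------------------------------------
# DGE: negative-binomial Wald test
# ---------------------------------------------------------------------------

def test_dge(
    gene_counts: pd.DataFrame,
    design: pd.DataFrame,
    size_factors: pd.Series,
    shrink_weight: float = 0.5,
) -> pd.DataFrame:
    """Per-gene NB log-linear model with log size-factor offset, Wald test.

    Dispersions are method-of-moments estimates shrunk toward a log-mean
    trend; the Wald test is on the condition coefficient (natural-log scale;
    the reported ``effect`` is the log2 fold change).
    """
    samples = list(design.index)
    y = gene_counts[samples].to_numpy(float)
    X = design.to_numpy(float)
    j_cond = list(design.columns).index("condition")
    offset = np.log(size_factors.loc[samples].to_numpy(float))

    nonzero = y.sum(axis=1) > 0
    res = pd.DataFrame({"feature_id": gene_counts.index})
    for c in RESULT_COLUMNS[1:]:
        res[c] = np.nan
    if nonzero.sum() == 0:
        return res
    ysub = y[nonzero]

    pois = batched_glm(ysub, X, "poisson", offset=offset[None, :])
    mu = pois.mu
    with np.errstate(invalid="ignore", divide="ignore"):
        alpha_raw = ((ysub - mu) ** 2 - mu).sum(axis=1) / (mu ** 2).sum(axis=1)
    alpha_raw = np.maximum(alpha_raw, 0.0)
    norm_mean = (ysub / np.exp(offset)[None, :]).mean(axis=1)
    disp = fit_dispersion_trend(alpha_raw, norm_mean, shrink_weight)
    alpha = disp["disp_shrunk"].to_numpy()

    nb = batched_glm(ysub, X, "negbin", offset=offset[None, :], alpha=alpha)
    se = nb.se(quasi=False)[:, j_cond]
    coef = nb.coef[:, j_cond]
    with np.errstate(invalid="ignore", divide="ignore"):
        z = coef / se
    p = 2.0 * stats.norm.sf(np.abs(z))

    res.loc[nonzero, "effect"] = coef / np.log(2.0)
    res.loc[nonzero, "se"] = se / np.log(2.0)
    res.loc[nonzero, "stat"] = z
    res.loc[nonzero, "p"] = p
    res["fdr"] = benjamini_hochberg(res["p"].to_numpy())
    logger.info("test_dge: %d genes tested, %d all-zero", int(nonzero.sum()),
                int((~nonzero).sum()))
    return res


# ---------------------------------------------------------------------------
# DEU: quasi-binomial proportion model with dispersion shrinkage
# ---------------------------------------------------------------------------

def gene_of_bin(bin_ids) -> np.ndarray:
    """Gene part of 'gene:bin' feature ids."""
    return np.array([b.rsplit(":", 1)[0] for b in bin_ids])


def gene_totals_from_bins(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-gene total inclusion counts, broadcast back to each bin row."""
    genes = gene_of_bin(counts.index)
    totals = counts.groupby(genes).transform("sum")
    return totals


def test_deu(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    shrink_weight: float = 0.5,
) -> pd.DataFrame:
    """Per-bin quasi-binomial logit model of bin count vs gene total.

    The response is the bin's fraction of its gene's reads; the test is a
    t-test on the condition coefficient with the per-bin Pearson dispersion
    shrunk toward a fitted mean-dispersion trend.  Bins of single-bin genes
    (bin count equals gene total in every sample) are reported as NA.
    """
    samples = list(design.index)
    inc = counts[samples].to_numpy(float)
    totals = gene_totals_from_bins(counts[samples]).to_numpy(float)
    X = design.to_numpy(float)
    j_cond = list(design.columns).index("condition")
    n, p_dim = X.shape

    res = pd.DataFrame({"feature_id": counts.index})
    for c in RESULT_COLUMNS[1:]:
        res[c] = np.nan
    single_bin = (inc == totals).all(axis=1)
    if single_bin.any():
        logger.info("test_deu: %d single-bin-gene bins reported NA",
                    int(single_bin.sum()))
    testable = ~single_bin
    if testable.sum() == 0:
        return res
    inc_t = inc[testable]
    tot_t = totals[testable]
    w = (tot_t > 0).astype(float)
    prop = np.where(tot_t > 0, inc_t / np.maximum(tot_t, 1.0), 0.0)

    fit = batched_glm(prop, X, "binomial", trials=tot_t, weights=w)
    disp = fit_dispersion_trend(fit.pearson_phi, inc_t.mean(axis=1), shrink_weight)
    phi = disp["disp_shrunk"].to_numpy()
    se = fit.se(quasi=True, phi=phi)[:, j_cond]
    coef = fit.coef[:, j_cond]
    df = fit.df_resid
    with np.errstate(invalid="ignore", divide="ignore"):
        t = coef / se
    pval = 2.0 * stats.t.sf(np.abs(t), np.maximum(df, 1.0))
    pval[df <= 0] = np.nan

    res.loc[testable, "effect"] = coef
    res.loc[testable, "se"] = se
    res.loc[testable, "stat"] = t
    res.loc[testable, "p"] = pval
    for c in disp.columns:
        res[c] = np.nan
        res.loc[testable, c] = disp[c].to_numpy()
    res["fdr"] = benjamini_hochberg(res["p"].to_numpy())
    return res


# ---------------------------------------------------------------------------
# DMR: empirical-Bayes moderated t on M-values
# ---------------------------------------------------------------------------

def _trigamma_inverse(y: float, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        step = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + step
        if abs(step) < 1e-10 * x:
            break
    return float(x)


def squeeze_variances(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Estimate the prior (d0, s0^2) of the scaled-F model of sample variances.

    Moment matching on log s^2: under the hierarchical model,
    log s^2 = log s0^2 + log F(df, d0) up to known digamma offsets, so the
    mean and excess variance of log s^2 identify s0^2 and d0.  Returns
    ``(inf, exp(mean))`` when the excess variance is non-positive (complete
    pooling); callers should fall back to the ordinary t when the estimate is
    non-finite in a degenerate direction.
    """
    ok = np.isfinite(s2) & (s2 > 0)
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar <= 0:
        return np.inf, float(np.exp(emean))
    d0 = 2.0 * _trigamma_inverse(evar)
    s0_2 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_2


def test_dmr(
    m_values: pd.DataFrame,
    design: pd.DataFrame,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Probe-wise linear model of M-values with a moderated t-statistic.

    Residual variances are shrunk to the posterior
    ``s_post^2 = (d0 * s0^2 + d * s^2) / (d0 + d)`` with the prior estimated
    from all probes; the moderated t on the condition coefficient has
    ``d0 + d`` degrees of freedom.  ``prior_df`` overrides the estimated d0
    (0 recovers the ordinary t; inf pools all probes at s0^2).
    """
    samples = list(design.index)
    Y = m_values[samples].to_numpy(float)
    X = design.to_numpy(float)
    j_cond = list(design.columns).index("condition")
    n, p_dim = X.shape
    df = float(n - p_dim)
    if df <= 0:
        raise ValueError("no residual degrees of freedom in the DMR design")

    XtX_inv = np.linalg.inv(X.T @ X)
    coefs = Y @ X @ XtX_inv.T
    resid = Y - coefs @ X.T
    s2 = (resid ** 2).sum(axis=1) / df
    v_cond = XtX_inv[j_cond, j_cond]

    if prior_df is None:
        d0, s0_2 = squeeze_variances(s2, df)
        if not (np.isfinite(d0) or d0 == np.inf) or not np.isfinite(s0_2):
            logger.warning("test_dmr: prior estimation failed; ordinary t used")
            d0, s0_2 = 0.0, 1.0
    else:
        d0 = float(prior_df)
        s0_2 = squeeze_variances(s2, df)[1] if d0 > 0 else 1.0
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
        df_total = 1e9
    else:
        s2_post = (d0 * s0_2 + df * s2) / (d0 + df)
        df_total = d0 + df

    effect = coefs[:, j_cond]
    se = np.sqrt(np.maximum(s2_post, 1e-300) * v_cond)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = effect / se
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    res = pd.DataFrame({
        "feature_id": m_values.index,
        "effect": effect,
        "se": se,
        "stat": t,
        "p": p,
        "fdr": benjamini_hochberg(p),
    })
    res.attrs["prior_df"] = d0
    res.attrs["prior_var"] = s0_2
    return res
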