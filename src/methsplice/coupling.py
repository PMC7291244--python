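"""Methylation-splicing coupling: PSI, flank regression, EWAS, differential correlation.

The central quantities:

* **PSI** (percent spliced-in) per exon bin and sample, from length-normalized
  inclusion reads vs. skip-junction (exclusion) reads.
* **Flank regression**: one pooled quasi-Poisson regression per condition and
  pair kind, of group-summed bin inclusion counts on the group-mean intronic
  methylation of the flanking probe, with a log gene-total offset and an
  optional log10(distance) adjustment.
* **EWAS scan**: per (probe, bin) combination within a gene and per condition,
  a quasi-binomial logit model of PSI on beta with the top two methylation
  principal components as covariates; effect sizes reported as odds ratios
  per 0.01 increment of beta.
* **Differential correlation**: Fisher's z test comparing the within-group
  Pearson correlations r(beta, PSI) between disease and control, BH-adjusted
  in the screening cohort, with nominal and directional replication in the
  independent replication cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .diffexpr import benjamini_hochberg, gene_totals_from_bins
from .glm import batched_glm

logger = logging.getLogger(__name__)

DEFAULT_JUNCTION_LENGTH = 99  # read length 100 minus 1


class CouplingError(ValueError):
    pass


# ---------------------------------------------------------------------------
# PSI
# ---------------------------------------------------------------------------

def compute_psi(
    inclusion: pd.DataFrame,
    exclusion: pd.DataFrame,
    bin_widths: pd.Series,
    junction_length: float = DEFAULT_JUNCTION_LENGTH,
) -> pd.DataFrame:
    """Percent-spliced-in per bin and sample.

    ``PSI = (I / L_b) / (I / L_b + E / L_J)`` with inclusion reads I,
    exclusion (skip-junction) reads E, bin width L_b and effective junction
    length L_J.  NA where both I and E are zero.
    """
    if (inclusion.to_numpy() < 0).any() or (exclusion.to_numpy() < 0).any():
        raise CouplingError("negative counts in PSI input")
    if not inclusion.index.equals(exclusion.index):
        exclusion = exclusion.reindex(inclusion.index, fill_value=0)
    widths = bin_widths.loc[inclusion.index].to_numpy(float)[:, None]
    inc = inclusion.to_numpy(float)
    exc = exclusion[inclusion.columns].to_numpy(float)
    dens_in = inc / widths
    dens_ex = exc / float(junction_length)
    denom = dens_in + dens_ex
    with np.errstate(invalid="ignore", divide="ignore"):
        psi = np.where(denom > 0, dens_in / denom, np.nan)
    return pd.DataFrame(psi, index=inclusion.index, columns=inclusion.columns)


# ---------------------------------------------------------------------------
# flank regression (Table-1-style)
# ---------------------------------------------------------------------------

@dataclass
class FlankRegressionResult:
    group: str
    kind: str
    adjusted: bool
    coefficient: float
    se: float
    p: float
    n_pairs: int
    dispersion: float


def flank_regression(
    pairs: pd.DataFrame,
    inclusion: pd.DataFrame,
    beta: pd.DataFrame,
    sheet: pd.DataFrame,
    group: str,
    kind: str,
    adjust_distance: bool = False,
) -> FlankRegressionResult:
    """Pooled quasi-Poisson regression of exon usage on flanking methylation.

    One observation per flank pair of the given ``kind``: the response is the
    bin's inclusion count summed over the group's samples, the offset is the
    log of the gene-total count summed over the same samples, the predictor is
    the group-mean beta of the probe, optionally adjusted by log10(distance).
    Standard errors are scaled by the Pearson dispersion and the p-value is
    t-based.
    """
    samples = sheet.loc[sheet["condition"] == group, "sample_id"].tolist()
    if not samples:
        raise CouplingError(f"no samples in group {group!r}")
    sub = pairs[pairs["kind"] == kind]
    key = sub["gene_id"] + ":" + sub["bin_id"]
    keep = key.isin(inclusion.index) & sub["probe_id"].isin(beta.index)
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("flank_regression: %d pairs dropped (bin or probe "
                    "filtered upstream)", n_drop)
    sub = sub[keep]
    key = key[keep]

    inc_sum = inclusion[samples].sum(axis=1)
    totals = gene_totals_from_bins(inclusion[samples]).sum(axis=1)
    y = inc_sum.loc[key].to_numpy(float)
    tot = totals.loc[key].to_numpy(float)
    x = beta.loc[sub["probe_id"], samples].mean(axis=1).to_numpy(float)

    ok = tot > 0
    if (~ok).any():
        logger.info("flank_regression: %d pairs with zero gene total excluded",
                    int((~ok).sum()))
    y, tot, x = y[ok], tot[ok], x[ok]
    dist = sub["distance"].to_numpy(float)[ok]
    return fit_flank_glm(y, tot, x, dist if adjust_distance else None,
                         group=group, kind=kind)


def fit_flank_glm(
    y: np.ndarray,
    totals: np.ndarray,
    beta: np.ndarray,
    distance: np.ndarray | None = None,
    group: str = "",
    kind: str = "",
) -> FlankRegressionResult:
    """Quasi-Poisson fit of pair counts on methylation (one row per pair).

    ``log E[y] = log(totals) + a + b * beta [+ c * log10(distance)]`` with
    Pearson dispersion and a t-based p-value on ``b``.
    """
    y = np.asarray(y, float)
    totals = np.asarray(totals, float)
    x = np.asarray(beta, float)
    if y.size < 10:
        raise CouplingError(f"only {y.size} usable pairs; need at least 10")
    if np.ptp(x) == 0:
        raise CouplingError("degenerate predictor: methylation identical across pairs")
    cols = [np.ones_like(x), x]
    if distance is not None:
        cols.append(np.log10(np.maximum(np.asarray(distance, float), 1.0)))
    X = np.column_stack(cols)
    model = sm.GLM(y, X, family=sm.families.Poisson(), offset=np.log(totals))
    fit = model.fit()
    df_resid = y.size - X.shape[1]
    mu = fit.fittedvalues
    phi = float(np.sum((y - mu) ** 2 / mu) / df_resid)
    se = np.sqrt(np.diag(fit.cov_params()) * phi)
    tstat = fit.params[1] / se[1]
    p = float(2.0 * stats.t.sf(abs(tstat), df_resid))
    return FlankRegressionResult(
        group=group, kind=kind, adjusted=distance is not None,
        coefficient=float(fit.params[1]), se=float(se[1]), p=p,
        n_pairs=int(y.size), dispersion=phi,
    )


def flank_regression_table(pairs, inclusion, beta, sheet,
                           groups=("DCM", "control"),
                           kinds=("intron-exon", "exon-intron")) -> pd.DataFrame:
    """All (group, kind, adjusted) flank regressions as one tidy table."""
    rows = []
    for adjusted in (False, True):
        for kind in kinds:
            for group in groups:
                r = flank_regression(pairs, inclusion, beta, sheet, group,
                                     kind, adjust_distance=adjusted)
                rows.append(vars(r))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# gene-wise (probe, bin) combinations and the EWAS scan
# ---------------------------------------------------------------------------

def build_gene_combinations(probes: pd.DataFrame, introns: pd.DataFrame,
                            bins: pd.DataFrame) -> pd.DataFrame:
    """All (intronic probe, exon bin) combinations within the same gene.

    A probe contributes to a gene if it lies inside one of the gene's introns;
    it is then combined with every bin of that gene (local and remote
    regulation within the gene).
    """
    if introns.empty:
        return pd.DataFrame(columns=["probe_id", "gene_id", "bin_id"])
    rows = []
    by_chrom = {c: g.sort_values("start") for c, g in introns.groupby("chrom")}
    for chrom, grp in probes.groupby("chrom", sort=False):
        sub = by_chrom.get(chrom)
        if sub is None:
            continue
        istart = sub["start"].to_numpy()
        iend = sub["end"].to_numpy()
        genes = sub["gene_id"].to_numpy()
        prefix_max = np.maximum.accumulate(iend)
        for pos, pid in zip(grp["pos"].to_numpy(), grp["probe_id"].to_numpy()):
            j = np.searchsorted(istart, pos, side="right") - 1
            hits = set()
            while j >= 0 and prefix_max[j] >= pos:
                if iend[j] >= pos:
                    hits.add(genes[j])
                j -= 1
            for g in hits:
                rows.append((pid, g))
    pg = pd.DataFrame(rows, columns=["probe_id", "gene_id"]).drop_duplicates()
    combos = pg.merge(bins[["gene_id", "bin_id"]], on="gene_id")
    return combos.sort_values(["gene_id", "probe_id", "bin_id"]).reset_index(drop=True)


def _masked_pearson(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation of (C, n) arrays under a 0/1 mask."""
    n = w.sum(axis=1)
    sx = (w * x).sum(axis=1)
    sy = (w * y).sum(axis=1)
    sxx = (w * x * x).sum(axis=1)
    syy = (w * y * y).sum(axis=1)
    sxy = (w * x * y).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sy / n
        vx = sxx - sx ** 2 / n
        vy = syy - sy ** 2 / n
        r = cov / np.sqrt(vx * vy)
    return np.clip(r, -1.0, 1.0)


def ewas_scan(
    beta: pd.DataFrame,
    psi: pd.DataFrame,
    combos: pd.DataFrame,
    pcs: pd.DataFrame,
    sheet: pd.DataFrame,
    group: str,
    min_samples: int = 5,
    n_pcs: int = 2,
    chunk_size: int = 20_000,
) -> pd.DataFrame:
    """Per (probe, bin) quasi-binomial logit model of PSI on beta + PC1 + PC2.

    Returns one association record per testable combination with the logit
    coefficient per unit beta, the odds ratio per 0.01 beta with its 95% CI,
    a t-based p-value, and the unadjusted within-group Pearson r(beta, PSI).
    Combinations with fewer than ``min_samples`` non-missing samples or a
    degenerate (constant) PSI are skipped with a logged count.
    """
    samples = sheet.loc[sheet["condition"] == group, "sample_id"].tolist()
    if len(samples) < min_samples:
        raise CouplingError(f"group {group!r} has fewer than {min_samples} samples")
    key = combos["gene_id"] + ":" + combos["bin_id"]
    usable = key.isin(psi.index) & combos["probe_id"].isin(beta.index)
    combos = combos[usable].reset_index(drop=True)
    key = key[usable].reset_index(drop=True)

    pc_arr = pcs.loc[samples].to_numpy(float)[:, :n_pcs]
    beta_all = beta[samples]
    psi_all = psi[samples]
    n = len(samples)

    records = []
    n_skipped = 0
    for lo in range(0, len(combos), chunk_size):
        idx = slice(lo, min(lo + chunk_size, len(combos)))
        b = beta_all.loc[combos["probe_id"].iloc[idx]].to_numpy(float)
        y = psi_all.loc[key.iloc[idx]].to_numpy(float)
        w = np.isfinite(y).astype(float)
        yf = np.nan_to_num(y)
        n_valid = w.sum(axis=1)
        # degenerate: too few samples or constant PSI over valid samples
        mean_valid = (w * yf).sum(axis=1) / np.maximum(n_valid, 1.0)
        spread = (w * (yf - mean_valid[:, None]) ** 2).sum(axis=1)
        bspread = (w * (b - (w * b).sum(axis=1, keepdims=True)
                        / np.maximum(n_valid, 1.0)[:, None]) ** 2).sum(axis=1)
        ok = ((n_valid >= max(min_samples, 3 + pc_arr.shape[1]))
              & (spread > 0) & (bspread > 0))
        n_skipped += int((~ok).sum())
        if not ok.any():
            continue
        C = int(ok.sum())
        X = np.empty((C, n, 2 + pc_arr.shape[1]))
        X[:, :, 0] = 1.0
        X[:, :, 1] = b[ok]
        for j in range(pc_arr.shape[1]):
            X[:, :, 2 + j] = pc_arr[:, j]
        fit = batched_glm(yf[ok], X, "binomial", weights=w[ok])
        se = fit.se(quasi=True)[:, 1]
        coef = fit.coef[:, 1]
        df = fit.df_resid
        with np.errstate(invalid="ignore", divide="ignore"):
            t = coef / se
        pval = 2.0 * stats.t.sf(np.abs(t), np.maximum(df, 1.0))
        tcrit = stats.t.ppf(0.975, np.maximum(df, 1.0))
        r = _masked_pearson(b[ok], yf[ok], w[ok])
        sub = combos.iloc[idx][ok]
        records.append(pd.DataFrame({
            "probe_id": sub["probe_id"].to_numpy(),
            "gene_id": sub["gene_id"].to_numpy(),
            "bin_id": sub["bin_id"].to_numpy(),
            "group": group,
            "coefficient": coef,
            "or_per_001": np.exp(0.01 * coef),
            "or_ci_low": np.exp(0.01 * (coef - tcrit * se)),
            "or_ci_high": np.exp(0.01 * (coef + tcrit * se)),
            "p": pval,
            "r": r,
            "n": n_valid[ok].astype(int),
            "separated": fit.separated,
        }))
    if n_skipped:
        logger.info("ewas_scan[%s]: %d combinations skipped (few samples or "
                    "degenerate)", group, n_skipped)
    if not records:
        return pd.DataFrame(columns=["probe_id", "gene_id", "bin_id", "group",
                                     "coefficient", "or_per_001", "or_ci_low",
                                     "or_ci_high", "p", "r", "n", "separated"])
    return pd.concat(records, ignore_index=True)


def variance_explained(
    beta: pd.DataFrame,
    psi: pd.DataFrame,
    combos: pd.DataFrame,
    min_samples: int = 5,
) -> dict:
    """Mean R^2 of PSI ~ beta over all combinations, with a normal CI.

    Per combination the R^2 of the simple linear regression equals the
    squared Pearson correlation; the summary is the mean across tests with
    CI = mean +/- 1.96 * sd / sqrt(n_tests).
    """
    key = combos["gene_id"] + ":" + combos["bin_id"]
    usable = key.isin(psi.index) & combos["probe_id"].isin(beta.index)
    combos = combos[usable]
    key = key[usable]
    b = beta.loc[combos["probe_id"], beta.columns].to_numpy(float)
    y = psi.loc[key, beta.columns].to_numpy(float)
    w = np.isfinite(y).astype(float)
    yf = np.nan_to_num(y)
    r = _masked_pearson(b, yf, w)
    n_valid = w.sum(axis=1)
    ok = (n_valid >= min_samples) & np.isfinite(r)
    r2 = r[ok] ** 2
    n_tests = int(r2.size)
    mean = float(np.mean(r2)) if n_tests else np.nan
    sd = float(np.std(r2, ddof=1)) if n_tests > 1 else np.nan
    half = 1.96 * sd / np.sqrt(n_tests) if n_tests > 1 else np.nan
    return {"mean_r2": mean, "ci_low": mean - half, "ci_high": mean + half,
            "n_tests": n_tests}


# ---------------------------------------------------------------------------
# Fisher's z differential correlation
# ---------------------------------------------------------------------------

def fisher_z_diffcor(r1, n1, r2, n2):
    """Fisher's z test comparing two independent Pearson correlations.

    ``z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3))`` with a
    two-sided normal p-value.  Requires |r| < 1 and n >= 4 in both groups.
    """
    r1 = np.asarray(r1, float)
    r2 = np.asarray(r2, float)
    n1 = np.asarray(n1, float)
    n2 = np.asarray(n2, float)
    if np.any(np.abs(r1) >= 1) or np.any(np.abs(r2) >= 1):
        raise CouplingError("|r| = 1: Fisher transform is infinite")
    if np.any(n1 < 4) or np.any(n2 < 4):
        raise CouplingError("Fisher's z requires at least 4 samples per group")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = 2.0 * stats.norm.sf(np.abs(z))
    return z, p


def diffcor_scan(assoc_dcm: pd.DataFrame, assoc_control: pd.DataFrame,
                 fdr_threshold: float = 0.05) -> pd.DataFrame:
    """Differential-correlation test over matched (probe, bin) combinations.

    Joins the two groups' association records, applies Fisher's z per
    combination, adjusts with BH across all combinations, and flags
    ``screened`` records at FDR below the threshold.  Unmatched combinations
    are skipped with a logged count.
    """
    keys = ["probe_id", "gene_id", "bin_id"]
    merged = assoc_dcm.merge(assoc_control, on=keys, suffixes=("_dcm", "_control"))
    n_unmatched = len(assoc_dcm) + len(assoc_control) - 2 * len(merged)
    if n_unmatched:
        logger.info("diffcor_scan: %d unmatched records skipped", n_unmatched)
    r1 = np.clip(merged["r_dcm"].to_numpy(float), -1 + 1e-12, 1 - 1e-12)
    r2 = np.clip(merged["r_control"].to_numpy(float), -1 + 1e-12, 1 - 1e-12)
    z, p = fisher_z_diffcor(r1, merged["n_dcm"], r2, merged["n_control"])
    out = merged[keys].copy()
    out["r_dcm"] = merged["r_dcm"]
    out["r_control"] = merged["r_control"]
    out["n_dcm"] = merged["n_dcm"]
    out["n_control"] = merged["n_control"]
    out["z"] = z
    out["p"] = p
    out["fdr"] = benjamini_hochberg(p)
    out["screened"] = out["fdr"] < fdr_threshold
    return out


def directional_replication(
    screen: pd.DataFrame,
    repl: pd.DataFrame,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Replication of screened differential-correlation candidates.

    ``replicated``: screened in the screening cohort and raw differential-
    correlation p below the threshold in the replication cohort.
    ``directionally_replicated``: additionally, the sign of r in each group
    agrees across cohorts and disease and control correlations have opposite
    signs.  Candidates absent from the replication cohort are not replicated.
    """
    keys = ["probe_id", "gene_id", "bin_id"]
    merged = screen.merge(repl, on=keys, how="left", suffixes=("", "_repl"))
    missing = merged["p_repl"].isna()
    if missing.any() and merged["screened"].where(missing, False).any():
        logger.info("directional_replication: %d screened candidates absent "
                    "from the replication cohort",
                    int((merged["screened"] & missing).sum()))
    merged["replicated"] = (merged["screened"]
                            & (merged["p_repl"] < p_threshold).fillna(False))
    sign_dcm_consistent = (np.sign(merged["r_dcm"])
                           == np.sign(merged["r_dcm_repl"]))
    sign_ctrl_consistent = (np.sign(merged["r_control"])
                            == np.sign(merged["r_control_repl"]))
    opposite = np.sign(merged["r_dcm"]) != np.sign(merged["r_control"])
    merged["directionally_replicated"] = (
        merged["replicated"] & sign_dcm_consistent.fillna(False)
        & sign_ctrl_consistent.fillna(False) & opposite
    )
    return merged


# ---------------------------------------------------------------------------
# DEU / DMR intersection
# ---------------------------------------------------------------------------

def intersect_deu_dmr(
    deu: pd.DataFrame,
    dmr: pd.DataFrame,
    pairs: pd.DataFrame,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Flank pairs whose bin is differentially used AND probe differentially methylated.

    A pair is a co-occurrence hit iff its bin's DEU raw p and its probe's DMR
    raw p are both below ``alpha``.  Returns the annotated pair table and a
    report of pair and distinct-gene counts per pair kind.
    """
    deu_p = deu.set_index("feature_id")["p"]
    dmr_p = dmr.set_index("feature_id")["p"]
    key = pairs["gene_id"] + ":" + pairs["bin_id"]
    out = pairs.copy()
    out["deu_p"] = deu_p.reindex(key).to_numpy()
    out["dmr_p"] = dmr_p.reindex(pairs["probe_id"]).to_numpy()
    out["hit"] = (out["deu_p"] < alpha) & (out["dmr_p"] < alpha)
    report = {}
    for kind, grp in out.groupby("kind"):
        hits = grp[grp["hit"]]
        report[kind] = {"n_pairs": int(len(hits)),
                        "n_genes": int(hits["gene_id"].nunique())}
    for kind in ("intron-exon", "exon-intron"):
        report.setdefault(kind, {"n_pairs": 0, "n_genes": 0})
    return out, report
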