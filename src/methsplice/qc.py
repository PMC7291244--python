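"""Sample, probe and bin filtering; count normalization; M-values; PCA covariates.

Filters mirror standard practice for joint RNA-seq / 450K-array studies:
samples need at least one million feature-assigned reads; probes on sex
chromosomes, probes overlapping common variants and cross-reactive probes are
dropped; exonic bins with a total inclusion count below six across all
retained samples are removed.  Counts are normalized with median-of-ratios
size factors, computed per cohort (no cross-cohort batch correction).  Beta
values are clipped to [eps, 1 - eps] before the logit M-value transform so
the linear-model scale stays finite.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BETA_EPS = 1e-6

SAMPLE_SHEET_COLUMNS = [
    "sample_id", "condition", "cohort", "sex", "age",
    "tacrolimus", "mycophenolate", "steroid", "everolimus", "ciclosporin",
    "batch_date", "flowcell", "assigned_reads",
]
DRUG_COLUMNS = ["tacrolimus", "mycophenolate", "steroid", "everolimus", "ciclosporin"]


class QCError(ValueError):
    pass


def filter_samples(
    sheet: pd.DataFrame,
    counts: pd.DataFrame,
    min_assigned: int = 1_000_000,
    extra_matrices: list[pd.DataFrame] | None = None,
):
    """Drop samples with fewer than ``min_assigned`` assigned reads.

    The boundary is kept: a sample with exactly ``min_assigned`` reads passes.
    Returns the filtered sheet and count matrix (and any extra matrices,
    column-subset to the surviving samples).
    """
    keep = sheet["assigned_reads"] >= min_assigned
    kept = sheet.loc[keep].reset_index(drop=True)
    if kept.empty:
        raise QCError("no samples survive the assigned-read filter")
    dropped = sheet.loc[~keep, "sample_id"].tolist()
    if dropped:
        logger.info("filter_samples: dropped %d of %d samples: %s",
                    len(dropped), len(sheet), ", ".join(dropped))
    ids = kept["sample_id"].tolist()
    out = [kept, counts[ids]]
    if extra_matrices is not None:
        out.extend(m[[c for c in ids if c in m.columns]] for m in extra_matrices)
    return tuple(out)


def filter_probes(probes: pd.DataFrame) -> pd.DataFrame:
    """Remove SNP-affected, cross-reactive and sex-chromosome probes."""
    bad = (probes["flag_snp"] | probes["flag_cross_reactive"]
           | probes["flag_sex_chrom"])
    kept = probes.loc[~bad].reset_index(drop=True)
    logger.info("filter_probes: %d of %d probes retained", len(kept), len(probes))
    return kept


def filter_low_count_bins(counts: pd.DataFrame, min_total: int = 6,
                          extra_matrices: list[pd.DataFrame] | None = None):
    """Remove bins whose inclusion-count row sum over all samples is < min_total."""
    keep = counts.sum(axis=1) >= min_total
    kept = counts.loc[keep]
    logger.info("filter_low_count_bins: %d of %d bins retained",
                int(keep.sum()), len(counts))
    if extra_matrices is not None:
        return (kept, *[m.loc[m.index.intersection(kept.index)].reindex(kept.index)
                        for m in extra_matrices])
    return kept


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Each sample's factor is the median over all-positive bins of
    count / geometric-mean(bin row).  If no bin is positive in every sample,
    falls back to total-count scaling with a warning.
    """
    mat = counts.to_numpy(dtype=float)
    if mat.shape[1] == 1:
        return pd.Series([1.0], index=counts.columns, name="size_factor")
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        logger.warning("size_factors: no bin positive in all samples; "
                       "falling back to total-count scaling")
        totals = mat.sum(axis=0)
        if (totals <= 0).any():
            raise QCError("size_factors: a sample has zero total count")
        factors = totals
    else:
        sub = mat[positive]
        log_geo = np.log(sub).mean(axis=1, keepdims=True)
        ratios = np.log(sub) - log_geo
        factors = np.exp(np.median(ratios, axis=0))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def clip_beta(beta: pd.DataFrame | np.ndarray, eps: float = BETA_EPS):
    return np.clip(beta, eps, 1.0 - eps)


def beta_to_m(beta: pd.DataFrame) -> pd.DataFrame:
    """M = log2(beta / (1 - beta)) after clipping beta into (0, 1)."""
    clipped = clip_beta(beta.to_numpy(dtype=float))
    m = np.log2(clipped / (1.0 - clipped))
    return pd.DataFrame(m, index=beta.index, columns=beta.columns)


def m_to_beta(m: pd.DataFrame) -> pd.DataFrame:
    """Inverse of :func:`beta_to_m`."""
    arr = np.asarray(m, dtype=float)
    beta = 1.0 / (1.0 + 2.0 ** (-arr))
    if isinstance(m, pd.DataFrame):
        return pd.DataFrame(beta, index=m.index, columns=m.columns)
    return beta


def top_principal_components(matrix: pd.DataFrame, k: int = 2) -> pd.DataFrame:
    """Scores of the top-k principal components of the sample space.

    Rows of ``matrix`` are features (probes), columns are samples.  Rows are
    centered, then the SVD of the centered matrix gives sample scores.  For
    determinism each component's sign is fixed so that its largest-magnitude
    feature loading is positive.
    """
    n_samples = matrix.shape[1]
    if k >= n_samples:
        raise QCError(f"k={k} must be smaller than the number of samples ({n_samples})")
    x = matrix.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise QCError("matrix contains missing values; filter before PCA")
    x = x - x.mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    signs = np.sign(u[np.argmax(np.abs(u), axis=0), np.arange(u.shape[1])])
    signs[signs == 0] = 1.0
    scores = (vt * signs[:, None]).T * s
    return pd.DataFrame(scores[:, :k], index=matrix.columns,
                        columns=[f"PC{i + 1}" for i in range(k)])
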