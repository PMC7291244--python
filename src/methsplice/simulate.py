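"""Ground-truth-labelled synthetic datasets for the methylation-splicing pipeline.

The generator emulates the statistical structure of a two-cohort cardiac
tissue study: a gene annotation with alternative transcripts, 450K-style
methylation probes placed in introns (and some in exons and intergenic
space), beta values that are logit-normal per probe, negative-binomial exon
inclusion/exclusion counts driven by gene expression and per-bin usage
proportions, and the planted effects the analysis is meant to recover:

* positive methylation->usage coupling on flank pairs (on the usage logit);
* differential exon usage (logit shift in disease) and differential
  methylation (M-value shift in disease) for labelled subsets;
* differential gene expression for a labelled gene subset;
* *group-reversed* loci where the within-group methylation-PSI correlation
  has opposite sign in disease and control (the replicated antisense-lncRNA
  pattern), with the correlation planted at configured targets by exact
  construction on the usage scale;
* *same-sign* loci whose correlations differ in magnitude but not sign,
  which the directional-replication filter must reject;
* multiplicative batch effects on counts, additive batch effects on
  M-values, and immunosuppressant flags present only in controls (the
  controls emulate transplanted hearts), confounding drugs with condition.

Default cohort sizes are 34 disease / 21 control (screening) and
11 / 5 (replication).  Identical configuration and seed give identical
datasets.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import GeneModel, build_flank_pairs, derive_introns, write_gtf
from .qc import filter_probes

logger = logging.getLogger(__name__)


class SimulationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    seed: int = 0
    # annotation layout
    n_genes: int = 500
    bins_per_gene: tuple[int, int] = (2, 15)
    bin_width: tuple[int, int] = (60, 400)
    intron_width: tuple[int, int] = (300, 20_000)   # log-uniform
    n_chromosomes: int = 4
    n_sex_chrom_genes: int = 2
    antisense_pair: bool = True
    # probes
    probes_per_intron: float = 0.6                  # Poisson mean
    frac_exonic_probes: float = 0.3                 # relative to intronic count
    n_intergenic_probes: int = 40
    frac_flag_snp: float = 0.02
    frac_flag_cross: float = 0.02
    # cohorts: (n disease, n control)
    screening: tuple[int, int] = (34, 21)
    replication: tuple[int, int] = (11, 5)
    n_low_read_samples: int = 0
    # expression / counts
    gene_log_mean: float = 5.0                      # natural-log reads per gene/sample
    gene_log_sd: float = 1.0
    nb_alpha: float = 0.05
    library_sd: float = 0.2
    read_length: int = 100
    # usage & coupling
    base_usage_logit: tuple[float, float] = (-2.5, 0.0)
    coupling_coef: float = 0.35
    coupling_fraction: float = 1.0
    # planted differential effects
    dge_fraction: float = 0.05
    dge_log2fc: float = 1.0
    deu_fraction: float = 0.05
    deu_effect: float = 1.0
    dmr_fraction: float = 0.05
    dmr_effect: float = 1.0
    # group-reversed and same-sign correlation loci
    n_reversed_loci: int = 5
    reversed_r: tuple[float, float] = (-0.6, 0.6)                # (r disease, r control)
    reversed_r_replication: tuple[float, float] = (-0.9, 0.9)
    n_samesign_loci: int = 0
    samesign_r: tuple[float, float] = (0.95, 0.1)
    samesign_r_replication: tuple[float, float] = (0.97, 0.15)
    special_expr: float = 3000.0                    # expression of special-locus genes
    special_nb_alpha: float = 0.01
    special_psi_sd: float = 0.22
    # methylation
    m_noise_sd: float = 0.5
    # batches
    n_batches: int = 2
    batch_sd_counts: float = 0.1
    batch_sd_m: float = 0.1

    def validate(self) -> None:
        for frac in (self.coupling_fraction, self.dge_fraction, self.deu_fraction,
                     self.dmr_fraction, self.frac_flag_snp, self.frac_flag_cross):
            if not 0.0 <= frac <= 1.0:
                raise SimulationError(f"fraction {frac} outside [0, 1]")
        for n_dcm, n_ctrl in (self.screening, self.replication):
            if n_dcm < 4 or n_ctrl < 4:
                raise SimulationError("each group needs at least 4 samples")
        if self.n_genes < 1:
            raise SimulationError("need at least one gene")


@dataclass
class TruthTable:
    genes: pd.DataFrame      # gene_id, expr_mean, nb_alpha, is_dge, log2fc, is_special
    bins: pd.DataFrame       # feature_id, gene_id, bin_id, base_logit, is_deu, deu_effect
    probes: pd.DataFrame     # probe_id, is_dmr, dmr_effect
    pairs: pd.DataFrame      # kind, probe_id, gene_id, bin_id, is_coupled, coef
    special_loci: pd.DataFrame  # probe_id, gene_id, bin_id, label, r targets


@dataclass
class CohortData:
    name: str
    sheet: pd.DataFrame
    beta: pd.DataFrame
    inclusion: pd.DataFrame
    exclusion: pd.DataFrame


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    gene_models: list[GeneModel]
    bins: pd.DataFrame
    introns: pd.DataFrame
    probes: pd.DataFrame
    pairs: pd.DataFrame          # flank pairs over blocklist-filtered probes
    cohorts: dict[str, CohortData] = field(default_factory=dict)
    truth: TruthTable | None = None


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """NB2 draw with var = mean + alpha * mean^2 (Poisson limit at alpha ~ 0)."""
    mean = np.maximum(np.asarray(mean, float), 1e-12)
    alpha = np.broadcast_to(np.asarray(alpha, float), mean.shape)
    out = np.empty(mean.shape, dtype=np.int64)
    tiny = alpha < 1e-8
    if tiny.any():
        out[tiny] = rng.poisson(mean[tiny])
    if (~tiny).any():
        n = 1.0 / alpha[~tiny]
        p = n / (n + mean[~tiny])
        out[~tiny] = rng.negative_binomial(n, p)
    return out


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _exact_corr_scores(rng: np.random.Generator, anchor: np.ndarray,
                       r: float) -> np.ndarray:
    """Standardized scores with sample correlation exactly ``r`` to ``anchor``."""
    n = anchor.size
    xc = anchor - anchor.mean()
    nx = np.linalg.norm(xc)
    if nx == 0:
        return rng.standard_normal(n)
    xu = xc / nx
    e = rng.standard_normal(n)
    ec = e - e.mean()
    ec = ec - (ec @ xu) * xu
    ne = np.linalg.norm(ec)
    if ne == 0:
        ec = np.zeros(n)
    else:
        ec = ec / ne
    v = r * xu + np.sqrt(max(0.0, 1.0 - r * r)) * ec
    return v * np.sqrt(n - 1)


# ---------------------------------------------------------------------------
# annotation + probe layout
# ---------------------------------------------------------------------------

def _layout_genes(config: SimulationConfig, rng: np.random.Generator):
    """Place genes with bins/introns on synthetic chromosomes; build transcripts."""
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    cursors = {c: 1000 for c in chroms}
    cursors["chrX"] = 1000
    models: list[GeneModel] = []
    bin_rows = []
    lo_b, hi_b = config.bins_per_gene
    lo_w, hi_w = config.bin_width
    lo_i, hi_i = config.intron_width

    def add_gene(gene_id: str, chrom: str, strand: str, start: int):
        n_b = int(rng.integers(lo_b, hi_b + 1))
        widths = rng.integers(lo_w, hi_w + 1, size=n_b)
        iw = np.exp(rng.uniform(np.log(lo_i), np.log(hi_i), size=max(n_b - 1, 0)))
        iw = np.maximum(iw.astype(int), 2)
        exons = []
        pos = start
        for k in range(n_b):
            exons.append((pos, pos + int(widths[k]) - 1))
            pos = exons[-1][1] + 1
            if k < n_b - 1:
                pos += int(iw[k])
        txs = [(f"{gene_id}.t1", list(exons))]
        if n_b >= 4:
            skip = int(rng.integers(1, n_b - 1))
            txs.append((f"{gene_id}.t2",
                        [e for j, e in enumerate(exons) if j != skip]))
        models.append(GeneModel(gene_id, chrom, strand, txs))
        for k, (s, e) in enumerate(exons):
            bin_rows.append((gene_id, f"E{k + 1:03d}", chrom, strand,
                             s, e, e - s + 1))
        return exons[-1][1]

    for i in range(config.n_genes):
        if i >= config.n_genes - config.n_sex_chrom_genes:
            chrom = "chrX"
        else:
            chrom = chroms[i % len(chroms)]
        strand = "+" if rng.random() < 0.5 else "-"
        start = cursors[chrom]
        end = add_gene(f"G{i:05d}", chrom, strand, start)
        cursors[chrom] = end + int(rng.integers(5000, 20_000))

    if config.antisense_pair and config.n_genes >= 1:
        # antisense gene overlapping the first gene (the TTN / TTN-AS1 situation)
        host = models[0]
        host_start = host.transcripts[0][1][0][0]
        add_gene("G00000-AS", host.chrom, "-" if host.strand == "+" else "+",
                 host_start + 137)

    bins = pd.DataFrame(bin_rows, columns=["gene_id", "bin_id", "chrom",
                                           "strand", "start", "end", "width"])
    return models, bins


def _place_probes(config: SimulationConfig, rng: np.random.Generator,
                  bins: pd.DataFrame, introns: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for _, row in introns.iterrows():
        k = int(rng.poisson(config.probes_per_intron))
        if k == 0:
            continue
        width = row["end"] - row["start"] + 1
        k = min(k, width)
        pos = rng.choice(np.arange(row["start"], row["end"] + 1), size=k,
                         replace=False)
        for p in np.sort(pos):
            rows.append((row["chrom"], int(p)))
    n_intronic = len(rows)
    n_exonic = int(round(config.frac_exonic_probes * n_intronic))
    if n_exonic and len(bins):
        idx = rng.integers(0, len(bins), size=n_exonic)
        for j in idx:
            b = bins.iloc[j]
            rows.append((b["chrom"], int(rng.integers(b["start"], b["end"] + 1))))
    max_end = bins.groupby("chrom")["end"].max()
    for _ in range(config.n_intergenic_probes):
        chrom = rng.choice(max_end.index.to_numpy())
        rows.append((chrom, int(max_end[chrom] + rng.integers(1000, 100_000))))

    probes = pd.DataFrame(rows, columns=["chrom", "pos"])
    probes = probes.sample(frac=1.0, random_state=int(rng.integers(2 ** 31)))
    probes = probes.reset_index(drop=True)
    probes.insert(0, "probe_id",
                  [f"cg{j:08d}" for j in range(len(probes))])
    probes["flag_snp"] = rng.random(len(probes)) < config.frac_flag_snp
    probes["flag_cross_reactive"] = rng.random(len(probes)) < config.frac_flag_cross
    probes["flag_sex_chrom"] = probes["chrom"].isin(["chrX", "chrY"])
    return probes


# ---------------------------------------------------------------------------
# sample sheets
# ---------------------------------------------------------------------------

_DRUG_PROBS = {"tacrolimus": 0.8, "mycophenolate": 0.7, "steroid": 0.6,
               "everolimus": 0.2, "ciclosporin": 0.3}


def _make_sheet(cohort: str, n_dcm: int, n_ctrl: int,
                config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    tag = cohort[:4].upper()
    conditions = ["DCM"] * n_dcm + ["control"] * n_ctrl
    extra = ["DCM" if rng.random() < 0.5 else "control"
             for _ in range(config.n_low_read_samples)]
    for i, cond in enumerate(conditions + extra):
        low = i >= len(conditions)
        row = {
            "sample_id": f"{tag}_{cond[:3].upper()}_{i:02d}",
            "condition": cond,
            "cohort": cohort,
            "sex": "F" if rng.random() < 0.4 else "M",
            "age": int(np.clip(rng.normal(55, 10), 20, 85)),
            "batch_date": f"{tag}_D{int(rng.integers(config.n_batches))}",
            "flowcell": f"{tag}_FC{int(rng.integers(config.n_batches))}",
            "assigned_reads": int(rng.integers(400_000, 999_999)) if low
            else int(rng.integers(1_200_000, 20_000_000)),
        }
        for drug, prob in _DRUG_PROBS.items():
            # immunosuppressants only in controls (transplanted hearts)
            row[drug] = bool(cond == "control" and rng.random() < prob)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# main generator
# ---------------------------------------------------------------------------

def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate a complete two-cohort dataset with a TruthTable.

    Deterministic for a fixed config (all randomness flows from
    ``config.seed``).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    models, bins = _layout_genes(config, rng)
    introns = derive_introns(bins)
    probes = _place_probes(config, rng, bins, introns)
    probes_ok = filter_probes(probes)
    pairs = build_flank_pairs(probes_ok, introns, bins)

    gene_ids = bins["gene_id"].unique()
    n_genes = len(gene_ids)
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    bin_key = bins["gene_id"] + ":" + bins["bin_id"]
    bin_pos = {k: i for i, k in enumerate(bin_key)}
    n_bins = len(bins)
    probe_pos = {p: i for i, p in enumerate(probes["probe_id"])}
    n_probes = len(probes)

    # --- gene expression and DGE truth -------------------------------------
    expr = np.exp(rng.normal(config.gene_log_mean, config.gene_log_sd, n_genes))
    nb_alpha = np.full(n_genes, config.nb_alpha)
    is_dge = rng.random(n_genes) < config.dge_fraction
    lfc = np.where(is_dge, rng.choice([-1.0, 1.0], n_genes) * config.dge_log2fc, 0.0)

    # --- special (reversed / same-sign) loci --------------------------------
    n_special = config.n_reversed_loci + config.n_samesign_loci
    ie_pairs = pairs[pairs["kind"] == "intron-exon"].drop_duplicates("probe_id")
    cand = ie_pairs.sample(frac=1.0, random_state=int(rng.integers(2 ** 31)))
    chosen_rows = []
    used_genes: set[str] = set()
    for _, row in cand.iterrows():
        if len(chosen_rows) >= n_special:
            break
        if row["gene_id"] in used_genes:
            continue
        chosen_rows.append(row)
        used_genes.add(row["gene_id"])
    if len(chosen_rows) < n_special:
        raise SimulationError(
            f"requested {n_special} special loci but only {len(chosen_rows)} "
            "eligible (probe, bin) pairs in distinct genes are available"
        )
    special_rows = []
    for j, row in enumerate(chosen_rows):
        label = "reversed" if j < config.n_reversed_loci else "samesign"
        r_s = config.reversed_r if label == "reversed" else config.samesign_r
        r_r = (config.reversed_r_replication if label == "reversed"
               else config.samesign_r_replication)
        special_rows.append({
            "probe_id": row["probe_id"], "gene_id": row["gene_id"],
            "bin_id": row["bin_id"], "label": label,
            "r_dcm_screening": r_s[0], "r_control_screening": r_s[1],
            "r_dcm_replication": r_r[0], "r_control_replication": r_r[1],
        })
    special = pd.DataFrame(special_rows, columns=[
        "probe_id", "gene_id", "bin_id", "label", "r_dcm_screening",
        "r_control_screening", "r_dcm_replication", "r_control_replication"])
    special_bin_idx = np.array(
        [bin_pos[g + ":" + b] for g, b in zip(special["gene_id"], special["bin_id"])],
        dtype=int) if len(special) else np.array([], dtype=int)
    special_probe_idx = np.array([probe_pos[p] for p in special["probe_id"]],
                                 dtype=int) if len(special) else np.array([], dtype=int)
    is_special_gene = np.zeros(n_genes, dtype=bool)
    for g in special["gene_id"]:
        is_special_gene[gene_pos[g]] = True
    expr[is_special_gene] = config.special_expr
    nb_alpha[is_special_gene] = config.special_nb_alpha
    is_dge[is_special_gene] = False
    lfc[is_special_gene] = 0.0

    # --- bin usage baselines and DEU truth ----------------------------------
    base_logit = rng.uniform(*config.base_usage_logit, n_bins)
    bins_per_gene_count = bins.groupby("gene_id")["bin_id"].transform("count")
    multi_bin = (bins_per_gene_count > 1).to_numpy()
    special_bin_mask = np.zeros(n_bins, dtype=bool)
    special_bin_mask[special_bin_idx] = True
    gene_special_mask = np.array(
        [is_special_gene[gene_pos[g]] for g in bins["gene_id"]])
    is_deu = ((rng.random(n_bins) < config.deu_fraction)
              & multi_bin & ~gene_special_mask)
    deu_effect = np.where(is_deu, rng.choice([-1.0, 1.0], n_bins)
                          * config.deu_effect, 0.0)

    # --- probe baselines and DMR truth --------------------------------------
    comp = rng.random(n_probes) < 0.5
    m0 = np.where(comp, rng.normal(-2.2, 0.8, n_probes),
                  rng.normal(2.2, 0.8, n_probes))
    m0[special_probe_idx] = rng.uniform(-1.0, 1.0, len(special_probe_idx))
    special_probe_mask = np.zeros(n_probes, dtype=bool)
    special_probe_mask[special_probe_idx] = True
    is_dmr = (rng.random(n_probes) < config.dmr_fraction) & ~special_probe_mask
    dmr_effect = np.where(is_dmr, rng.choice([-1.0, 1.0], n_probes)
                          * config.dmr_effect, 0.0)

    # --- coupled pairs -------------------------------------------------------
    pair_bin_idx = np.array([bin_pos[g + ":" + b]
                             for g, b in zip(pairs["gene_id"], pairs["bin_id"])],
                            dtype=int)
    pair_probe_idx = np.array([probe_pos[p] for p in pairs["probe_id"]], dtype=int)
    is_coupled = ((rng.random(len(pairs)) < config.coupling_fraction)
                  & ~special_bin_mask[pair_bin_idx])
    pair_coef = np.where(is_coupled, config.coupling_coef, 0.0)

    truth = TruthTable(
        genes=pd.DataFrame({"gene_id": gene_ids, "expr_mean": expr,
                            "nb_alpha": nb_alpha, "is_dge": is_dge,
                            "log2fc": lfc, "is_special": is_special_gene}),
        bins=pd.DataFrame({"feature_id": bin_key, "gene_id": bins["gene_id"],
                           "bin_id": bins["bin_id"], "base_logit": base_logit,
                           "is_deu": is_deu, "deu_effect": deu_effect}),
        probes=pd.DataFrame({"probe_id": probes["probe_id"], "m0": m0,
                             "is_dmr": is_dmr, "dmr_effect": dmr_effect}),
        pairs=pairs.assign(is_coupled=is_coupled, coef=pair_coef),
        special_loci=special,
    )

    dataset = SimulatedDataset(config=config, gene_models=models, bins=bins,
                               introns=introns, probes=probes, pairs=pairs,
                               truth=truth)

    gene_idx_of_bin = np.array([gene_pos[g] for g in bins["gene_id"]], dtype=int)
    widths = bins["width"].to_numpy(float)
    junction_len = float(config.read_length - 1)
    single_bin = ~multi_bin

    for cohort, (n_dcm, n_ctrl) in (("screening", config.screening),
                                    ("replication", config.replication)):
        sheet = _make_sheet(cohort, n_dcm, n_ctrl, config, rng)
        n_s = len(sheet)
        is_dcm = (sheet["condition"] == "DCM").to_numpy()
        batch_idx = sheet["batch_date"].astype("category").cat.codes.to_numpy()
        n_batch_levels = batch_idx.max() + 1

        # methylation
        m_batch = rng.normal(0.0, config.batch_sd_m, (n_probes, n_batch_levels))
        M = (m0[:, None] + dmr_effect[:, None] * is_dcm[None, :]
             + m_batch[:, batch_idx]
             + rng.normal(0.0, config.m_noise_sd, (n_probes, n_s)))
        beta_mat = 1.0 / (1.0 + 2.0 ** (-M))
        beta_df = pd.DataFrame(beta_mat, index=probes["probe_id"].to_numpy(),
                               columns=sheet["sample_id"].to_numpy())

        # usage logits with coupling + DEU
        u = np.repeat(base_logit[:, None], n_s, axis=1)
        if len(pairs):
            contrib = pair_coef[:, None] * (beta_mat[pair_probe_idx, :] - 0.5)
            np.add.at(u, pair_bin_idx, contrib)
        u += deu_effect[:, None] * is_dcm[None, :]
        pi = np.clip(_sigmoid(u), 0.02, 0.98)

        # special loci: exact-correlation construction per group
        r_cols = (f"r_dcm_{cohort}", f"r_control_{cohort}")
        for k in range(len(special)):
            b_idx = special_bin_idx[k]
            p_idx = special_probe_idx[k]
            psi_row = np.empty(n_s)
            for grp_mask, r_col in ((is_dcm, r_cols[0]), (~is_dcm, r_cols[1])):
                anchor = beta_mat[p_idx, grp_mask]
                scores = _exact_corr_scores(rng, anchor, float(special[r_col].iloc[k]))
                psi_row[grp_mask] = 0.5 + config.special_psi_sd * scores
            pi[b_idx] = np.clip(psi_row, 0.03, 0.97)

        # counts
        lib = np.exp(rng.normal(0.0, config.library_sd, n_s))
        gene_mean = (expr[:, None] * lib[None, :]
                     * 2.0 ** (lfc[:, None] * is_dcm[None, :]))
        c_batch = np.exp(rng.normal(0.0, config.batch_sd_counts,
                                    (n_bins, n_batch_levels)))
        bin_batch = c_batch[:, batch_idx]
        mean_inc = gene_mean[gene_idx_of_bin, :] * pi * bin_batch
        mean_exc = (gene_mean[gene_idx_of_bin, :] * (1.0 - pi) * bin_batch
                    * (junction_len / widths[:, None]))
        alpha_bin = nb_alpha[gene_idx_of_bin][:, None]
        inc = _nb_draw(rng, mean_inc, alpha_bin)
        exc = _nb_draw(rng, mean_exc, alpha_bin)
        exc[single_bin, :] = 0

        idx = bin_key.to_numpy()
        cols = sheet["sample_id"].to_numpy()
        dataset.cohorts[cohort] = CohortData(
            name=cohort, sheet=sheet,
            beta=beta_df,
            inclusion=pd.DataFrame(inc, index=idx, columns=cols),
            exclusion=pd.DataFrame(exc, index=idx, columns=cols),
        )

    logger.info("simulate_dataset: %d genes, %d bins, %d probes, %d flank pairs",
                n_genes, n_bins, n_probes, len(pairs))
    return dataset


# ---------------------------------------------------------------------------
# pair-level generator for regression recovery/calibration studies
# ---------------------------------------------------------------------------

def simulate_flank_pairs(
    n_pairs: int,
    coef: float,
    phi: float = 2.0,
    intercept: float = -2.0,
    dist_coef: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Pair-level counts with a planted coefficient on the linear predictor.

    Each row is one flank pair: group-summed inclusion count ``y`` with
    ``E[y] = total * exp(intercept + coef * beta + dist_coef * log10(dist))``
    and quasi-Poisson noise ``Var[y] = phi * E[y]``.  Used for parameter
    recovery and null calibration of the flank regression at configurable n.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    beta = rng.uniform(0.05, 0.95, n_pairs)
    totals = np.exp(rng.uniform(5.0, 9.0, n_pairs)).round().astype(int)
    dist = (10.0 ** rng.uniform(2.0, 4.3, n_pairs)).round().astype(int)
    mu = totals * np.exp(intercept + coef * beta + dist_coef * np.log10(dist))
    if phi <= 1.0 + 1e-9:
        y = rng.poisson(mu)
    else:
        size = mu / (phi - 1.0)
        y = rng.negative_binomial(size, 1.0 / phi)
    return pd.DataFrame({"y": y, "total": totals, "beta": beta,
                         "distance": dist})


# ---------------------------------------------------------------------------
# fixtures and on-disk output
# ---------------------------------------------------------------------------

FIXTURE_CONFIGS: dict[str, dict] = {
    # unit-test scale: full pipeline in seconds
    "tiny": dict(n_genes=5, bins_per_gene=(3, 6), probes_per_intron=1.0,
                 screening=(4, 4), replication=(4, 4), n_reversed_loci=1,
                 n_samesign_loci=0, n_sex_chrom_genes=1, n_intergenic_probes=5,
                 deu_fraction=0.2, dmr_fraction=0.2, dge_fraction=0.2),
    # statistical-test scale: 20 reversed among thousands of null combinations
    "small": dict(n_genes=500, screening=(30, 20), replication=(11, 5),
                  n_reversed_loci=20, n_samesign_loci=5),
    # study scale: flank-pair count of each kind near 41,000
    "study_scale": dict(n_genes=5000, probes_per_intron=1.15,
                        screening=(34, 21), replication=(11, 5),
                        n_reversed_loci=5, n_samesign_loci=2),
}

STUDY_SCALE_PAIR_RANGE = (33_000, 49_000)


def make_fixture(size: str, seed: int = 0) -> SimulatedDataset:
    """Generate a named fixture: ``tiny``, ``small`` or ``study_scale``."""
    if size not in FIXTURE_CONFIGS:
        raise SimulationError(f"unknown fixture size {size!r}")
    config = SimulationConfig(seed=seed, **FIXTURE_CONFIGS[size])
    ds = simulate_dataset(config)
    if size == "study_scale":
        n_ie = int((ds.pairs["kind"] == "intron-exon").sum())
        lo, hi = STUDY_SCALE_PAIR_RANGE
        if not lo <= n_ie <= hi:
            raise SimulationError(
                f"study_scale fixture produced {n_ie} intron-exon pairs, "
                f"outside [{lo}, {hi}]")
    return ds


def _write_tsv(df: pd.DataFrame, path: Path, index_label=None) -> None:
    df.to_csv(path, sep="\t", index=index_label is not None,
              index_label=index_label, float_format="%.8g")


def write_dataset(ds: SimulatedDataset, outdir: str | Path) -> dict:
    """Write the dataset as plain-text files; returns the manifest dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_gtf(ds.gene_models, outdir / "annotation.gtf")
    _write_tsv(ds.probes[["probe_id", "chrom", "pos"]], outdir / "probe_manifest.tsv")
    for flag, fname in (("flag_snp", "blocklist_snp.txt"),
                        ("flag_cross_reactive", "blocklist_cross_reactive.txt")):
        ids = ds.probes.loc[ds.probes[flag], "probe_id"]
        (outdir / fname).write_text("\n".join(ids) + ("\n" if len(ids) else ""))
    for cohort, data in ds.cohorts.items():
        cdir = outdir / cohort
        cdir.mkdir(exist_ok=True)
        data.sheet.to_csv(cdir / "samples.csv", index=False)
        _write_tsv(data.beta, cdir / "beta.tsv", index_label="probe_id")
        _write_tsv(data.inclusion, cdir / "inclusion.tsv", index_label="feature_id")
        _write_tsv(data.exclusion, cdir / "exclusion.tsv", index_label="feature_id")
    tdir = outdir / "truth"
    tdir.mkdir(exist_ok=True)
    for name in ("genes", "bins", "probes", "pairs", "special_loci"):
        _write_tsv(getattr(ds.truth, name), tdir / f"{name}.tsv")

    hashes = {}
    for path in sorted(outdir.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            hashes[str(path.relative_to(outdir))] = hashlib.sha256(
                path.read_bytes()).hexdigest()
    manifest = {"config": asdict(ds.config), "sha256": hashes}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     sort_keys=True) + "\n")
    return manifest
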