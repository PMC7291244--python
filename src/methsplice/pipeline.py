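"""Stage-wise pipeline over an output directory; the engine behind the CLI.

Each stage reads the artifacts of its upstream stages from the working
directory, writes TSV/BED/JSON artifacts, and logs its filter accounting.
Cohorts are processed fully independently (own QC, size factors, principal
components); the replication join is the only cross-cohort step.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotation, coupling, diffexpr, qc, simulate

logger = logging.getLogger(__name__)

COHORTS = ("screening", "replication")

DMR_COVARIATES = ("condition", "sex", "age", "tacrolimus", "mycophenolate",
                  "steroid", "everolimus", "ciclosporin")


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    seed: int = 0
    fixture: str = "tiny"                  # used by the simulate stage
    min_assigned: int = 1_000_000
    min_bin_total: int = 6
    alpha: float = 0.05                    # raw-p threshold for DEU/DMR overlay
    screening_fdr: float = 0.05
    replication_p: float = 0.05
    n_pcs: int = 2
    junction_length: float = coupling.DEFAULT_JUNCTION_LENGTH
    deu_covariates: tuple = ("condition",)
    dge_covariates: tuple = ("condition",)
    dmr_covariates: tuple = DMR_COVARIATES

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**known)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for name in ("min_assigned", "min_bin_total", "alpha",
                     "screening_fdr", "replication_p", "junction_length"):
            if getattr(self, name) <= 0:
                raise PipelineError(f"threshold {name} must be positive")


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise PipelineError(
            f"missing artifact {path}; run the '{producer}' subcommand first")
    return path


def _read_tsv(path: Path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


class Pipeline:
    """All analysis stages over one working directory."""

    def __init__(self, outdir: str | Path, config: PipelineConfig | None = None):
        self.outdir = Path(outdir)
        self.config = config or PipelineConfig()
        self.outdir.mkdir(parents=True, exist_ok=True)

    # -- paths ---------------------------------------------------------------
    def data_dir(self) -> Path:
        return self.outdir / "data"

    def ann_dir(self) -> Path:
        return self.outdir / "annotation"

    def cohort_dir(self, cohort: str) -> Path:
        d = self.outdir / cohort
        d.mkdir(exist_ok=True)
        return d

    # -- stages ---------------------------------------------------------------
    def simulate(self) -> None:
        ds = simulate.make_fixture(self.config.fixture, seed=self.config.seed)
        simulate.write_dataset(ds, self.data_dir())
        logger.info("simulate: wrote %s fixture to %s", self.config.fixture,
                    self.data_dir())

    def pair(self) -> None:
        data = self.data_dir()
        gtf = _require(data / "annotation.gtf", "simulate")
        manifest = _require(data / "probe_manifest.tsv", "simulate")
        models = annotation.read_gtf(gtf)
        bins = annotation.flatten_gene_models(models)
        introns = annotation.derive_introns(bins)
        blocklists = {}
        for flag, fname in (("flag_snp", "blocklist_snp.txt"),
                            ("flag_cross_reactive", "blocklist_cross_reactive.txt")):
            if (data / fname).exists():
                blocklists[flag] = data / fname
        probes = annotation.read_probe_manifest(manifest, blocklists)
        probes_ok = qc.filter_probes(probes)
        pairs = annotation.build_flank_pairs(probes_ok, introns, bins)
        ann = self.ann_dir()
        ann.mkdir(exist_ok=True)
        bins.to_csv(ann / "bins.tsv", sep="\t", index=False)
        introns.to_csv(ann / "introns.tsv", sep="\t", index=False)
        pairs.to_csv(ann / "pairs.tsv", sep="\t", index=False)
        probes_ok.to_csv(ann / "probes_filtered.tsv", sep="\t", index=False)
        annotation.write_bins_bed(bins, ann / "bins.bed")
        logger.info("pair: %d bins, %d introns, %d pairs", len(bins),
                    len(introns), len(pairs))

    def qc(self, cohort: str) -> None:
        data = self.data_dir() / cohort
        ann = self.ann_dir()
        _require(ann / "pairs.tsv", "pair")
        sheet = pd.read_csv(_require(data / "samples.csv", "simulate"))
        inclusion = _read_tsv(_require(data / "inclusion.tsv", "simulate"))
        exclusion = _read_tsv(data / "exclusion.tsv")
        beta = _read_tsv(data / "beta.tsv")
        cfg = self.config

        sheet, inclusion, exclusion, beta = qc.filter_samples(
            sheet, inclusion, cfg.min_assigned, [exclusion, beta])
        probes_ok = pd.read_csv(ann / "probes_filtered.tsv", sep="\t")
        beta = beta.loc[beta.index.intersection(probes_ok["probe_id"])]
        inclusion, exclusion = qc.filter_low_count_bins(
            inclusion, cfg.min_bin_total, [exclusion])
        factors = qc.size_factors(inclusion)
        m_values = qc.beta_to_m(beta)
        pcs = qc.top_principal_components(m_values, cfg.n_pcs)

        out = self.cohort_dir(cohort)
        sheet.to_csv(out / "samples_qc.csv", index=False)
        inclusion.to_csv(out / "inclusion_qc.tsv", sep="\t", index_label="feature_id")
        exclusion.to_csv(out / "exclusion_qc.tsv", sep="\t", index_label="feature_id")
        beta.to_csv(out / "beta_qc.tsv", sep="\t", index_label="probe_id")
        m_values.to_csv(out / "m_values.tsv", sep="\t", index_label="probe_id")
        factors.to_frame().to_csv(out / "size_factors.tsv", sep="\t",
                                  index_label="sample_id")
        pcs.to_csv(out / "pcs.tsv", sep="\t", index_label="sample_id")
        report = pd.DataFrame([
            ("samples_retained", len(sheet)),
            ("probes_retained", len(beta)),
            ("bins_retained", len(inclusion)),
        ], columns=["item", "count"])
        report.to_csv(out / "qc_report.tsv", sep="\t", index=False)
        logger.info("qc[%s]: %d samples, %d probes, %d bins", cohort,
                    len(sheet), len(beta), len(inclusion))

    # -- differential stages ---------------------------------------------------
    def _load_qc(self, cohort: str):
        out = self.cohort_dir(cohort)
        _require(out / "inclusion_qc.tsv", "qc")
        sheet = pd.read_csv(out / "samples_qc.csv")
        inclusion = _read_tsv(out / "inclusion_qc.tsv")
        exclusion = _read_tsv(out / "exclusion_qc.tsv")
        beta = _read_tsv(out / "beta_qc.tsv")
        m_values = _read_tsv(out / "m_values.tsv")
        factors = _read_tsv(out / "size_factors.tsv")["size_factor"]
        pcs = _read_tsv(out / "pcs.tsv")
        return sheet, inclusion, exclusion, beta, m_values, factors, pcs

    def dge(self, cohort: str) -> None:
        sheet, inclusion, _, _, _, factors, _ = self._load_qc(cohort)
        genes = diffexpr.gene_of_bin(inclusion.index)
        gene_counts = inclusion.groupby(genes).sum()
        design = diffexpr.build_design(sheet, self.config.dge_covariates)
        res = diffexpr.test_dge(gene_counts, design, factors)
        res.to_csv(self.cohort_dir(cohort) / "dge.tsv", sep="\t", index=False)
        logger.info("dge[%s]: %d genes, %d with fdr<0.05", cohort, len(res),
                    int((res["fdr"] < 0.05).sum()))

    def deu(self, cohort: str) -> None:
        sheet, inclusion, _, _, _, _, _ = self._load_qc(cohort)
        design = diffexpr.build_design(sheet, self.config.deu_covariates)
        res = diffexpr.test_deu(inclusion, design)
        res.to_csv(self.cohort_dir(cohort) / "deu.tsv", sep="\t", index=False)
        logger.info("deu[%s]: %d bins, %d with p<%.2f", cohort, len(res),
                    int((res["p"] < self.config.alpha).sum()), self.config.alpha)

    def dmr(self, cohort: str) -> None:
        sheet, _, _, _, m_values, _, pcs = self._load_qc(cohort)
        design = diffexpr.build_design(sheet, self.config.dmr_covariates, pcs=pcs)
        res = diffexpr.test_dmr(m_values, design)
        res.to_csv(self.cohort_dir(cohort) / "dmr.tsv", sep="\t", index=False)
        logger.info("dmr[%s]: %d probes, %d with p<%.2f", cohort, len(res),
                    int((res["p"] < self.config.alpha).sum()), self.config.alpha)

    def psi(self, cohort: str) -> None:
        _, inclusion, exclusion, _, _, _, _ = self._load_qc(cohort)
        bins = pd.read_csv(_require(self.ann_dir() / "bins.tsv", "pair"), sep="\t")
        widths = pd.Series(bins["width"].to_numpy(),
                           index=bins["gene_id"] + ":" + bins["bin_id"])
        psi = coupling.compute_psi(inclusion, exclusion, widths,
                                   self.config.junction_length)
        psi.to_csv(self.cohort_dir(cohort) / "psi.tsv", sep="\t",
                   index_label="feature_id")

    def flank(self, cohort: str) -> None:
        sheet, inclusion, _, beta, _, _, _ = self._load_qc(cohort)
        pairs = pd.read_csv(_require(self.ann_dir() / "pairs.tsv", "pair"), sep="\t")
        table = coupling.flank_regression_table(pairs, inclusion, beta, sheet)
        table.to_csv(self.cohort_dir(cohort) / "flank_regression.tsv",
                     sep="\t", index=False)
        logger.info("flank[%s]:\n%s", cohort, table.to_string(index=False))

    def ewas(self, cohort: str) -> None:
        sheet, _, _, beta, _, _, pcs = self._load_qc(cohort)
        out = self.cohort_dir(cohort)
        psi = _read_tsv(_require(out / "psi.tsv", "psi"))
        ann = self.ann_dir()
        probes = pd.read_csv(ann / "probes_filtered.tsv", sep="\t")
        introns = pd.read_csv(ann / "introns.tsv", sep="\t")
        bins = pd.read_csv(ann / "bins.tsv", sep="\t")
        combos = coupling.build_gene_combinations(probes, introns, bins)
        min_group = int(sheet["condition"].value_counts().min())
        n_pcs = int(np.clip(min_group - 3, 0, self.config.n_pcs))
        min_samples = min(5, min_group)
        for group in ("DCM", "control"):
            assoc = coupling.ewas_scan(beta, psi, combos, pcs, sheet, group,
                                       min_samples=min_samples, n_pcs=n_pcs)
            assoc.to_csv(out / f"ewas_{group}.tsv", sep="\t", index=False)
        ve = coupling.variance_explained(beta, psi, combos)
        with open(out / "variance_explained.json", "w") as fh:
            json.dump(ve, fh, indent=2)
        logger.info("ewas[%s]: mean R^2 = %.4f over %d tests", cohort,
                    ve["mean_r2"], ve["n_tests"])

    def diffcor(self, cohort: str) -> None:
        out = self.cohort_dir(cohort)
        dcm = pd.read_csv(_require(out / "ewas_DCM.tsv", "ewas"), sep="\t")
        ctrl = pd.read_csv(_require(out / "ewas_control.tsv", "ewas"), sep="\t")
        dcm = dcm.rename(columns={"r": "r_dcm", "n": "n_dcm"})
        ctrl = ctrl.rename(columns={"r": "r_control", "n": "n_control"})
        keys = ["probe_id", "gene_id", "bin_id"]
        res = coupling.diffcor_scan(
            dcm[keys + ["r_dcm", "n_dcm"]],
            ctrl[keys + ["r_control", "n_control"]],
            fdr_threshold=self.config.screening_fdr)
        res.to_csv(out / "diffcor.tsv", sep="\t", index=False)
        # Manhattan-ready table: probe genomic position vs diffcor p
        probes = pd.read_csv(self.ann_dir() / "probes_filtered.tsv", sep="\t")
        pos = probes.set_index("probe_id")[["chrom", "pos"]]
        man = res.join(pos, on="probe_id")[["chrom", "pos", "p", "fdr"]]
        man.to_csv(out / "manhattan.tsv", sep="\t", index=False)
        logger.info("diffcor[%s]: %d combinations, %d screened", cohort,
                    len(res), int(res["screened"].sum()))

    def replicate(self) -> None:
        screen = pd.read_csv(
            _require(self.cohort_dir("screening") / "diffcor.tsv", "diffcor"),
            sep="\t")
        repl = pd.read_csv(
            _require(self.cohort_dir("replication") / "diffcor.tsv", "diffcor"),
            sep="\t")
        res = coupling.directional_replication(screen, repl,
                                               self.config.replication_p)
        res.to_csv(self.outdir / "replication.tsv", sep="\t", index=False)
        # Tables-2/3-style candidate report: ORs with CI per group per cohort
        cands = res[res["directionally_replicated"]]
        rows = []
        for cohort in COHORTS:
            out = self.cohort_dir(cohort)
            for group in ("DCM", "control"):
                path = out / f"ewas_{group}.tsv"
                if not path.exists():
                    continue
                assoc = pd.read_csv(path, sep="\t")
                sub = assoc.merge(cands[["probe_id", "gene_id", "bin_id"]],
                                  on=["probe_id", "gene_id", "bin_id"])
                for _, a in sub.iterrows():
                    rows.append({
                        "cohort": cohort, "group": group,
                        "variable": f"{a['probe_id']} vs {a['gene_id']}:{a['bin_id']}",
                        "odds_ratio_per_0.01": a["or_per_001"],
                        "ci_low": a["or_ci_low"], "ci_high": a["or_ci_high"],
                        "p": a["p"],
                    })
        pd.DataFrame(rows).to_csv(self.outdir / "candidates.tsv", sep="\t",
                                  index=False)
        logger.info("replicate: %d screened, %d replicated, %d directional",
                    int(res["screened"].sum()), int(res["replicated"].sum()),
                    int(res["directionally_replicated"].sum()))

    def intersect(self, cohort: str = "screening") -> None:
        out = self.cohort_dir(cohort)
        deu = pd.read_csv(_require(out / "deu.tsv", "deu"), sep="\t")
        dmr = pd.read_csv(_require(out / "dmr.tsv", "dmr"), sep="\t")
        pairs = pd.read_csv(_require(self.ann_dir() / "pairs.tsv", "pair"), sep="\t")
        hits, report = coupling.intersect_deu_dmr(deu, dmr, pairs,
                                                  self.config.alpha)
        hits.to_csv(out / "deu_dmr_pairs.tsv", sep="\t", index=False)
        with open(out / "deu_dmr_intersection.json", "w") as fh:
            json.dump(report, fh, indent=2)
        bins = pd.read_csv(self.ann_dir() / "bins.tsv", sep="\t")
        hit_bins = hits.loc[hits["hit"], ["gene_id", "bin_id"]].drop_duplicates()
        bed_bins = bins.merge(hit_bins, on=["gene_id", "bin_id"])
        annotation.write_bins_bed(bed_bins, out / "deu_dmr_hits.bed")
        logger.info("intersect[%s]: %s", cohort, report)

    def report(self) -> dict:
        summary: dict = {"config": asdict(self.config)}
        for cohort in COHORTS:
            out = self.cohort_dir(cohort)
            entry: dict = {}
            if (out / "deu.tsv").exists():
                deu = pd.read_csv(out / "deu.tsv", sep="\t")
                entry["deu_hits"] = int((deu["p"] < self.config.alpha).sum())
                entry["deu_tested"] = int(deu["p"].notna().sum())
            if (out / "dmr.tsv").exists():
                dmr = pd.read_csv(out / "dmr.tsv", sep="\t")
                entry["dmr_hits"] = int((dmr["p"] < self.config.alpha).sum())
                entry["dmr_tested"] = int(dmr["p"].notna().sum())
            if (out / "deu_dmr_intersection.json").exists():
                entry["deu_dmr_intersection"] = json.loads(
                    (out / "deu_dmr_intersection.json").read_text())
            if (out / "flank_regression.tsv").exists():
                entry["flank_regression"] = pd.read_csv(
                    out / "flank_regression.tsv", sep="\t").to_dict("records")
            if (out / "variance_explained.json").exists():
                entry["variance_explained"] = json.loads(
                    (out / "variance_explained.json").read_text())
            if (out / "diffcor.tsv").exists():
                dc = pd.read_csv(out / "diffcor.tsv", sep="\t")
                entry["diffcor_tested"] = int(len(dc))
                entry["diffcor_screened"] = int(dc["screened"].sum())
            if entry:
                summary[cohort] = entry
        if (self.outdir / "replication.tsv").exists():
            rep = pd.read_csv(self.outdir / "replication.tsv", sep="\t")
            summary["replication"] = {
                "screened": int(rep["screened"].sum()),
                "replicated": int(rep["replicated"].sum()),
                "directionally_replicated": int(
                    rep["directionally_replicated"].sum()),
            }
        with open(self.outdir / "report.json", "w") as fh:
            json.dump(summary, fh, indent=2, default=str)
        return summary

    def run_all(self) -> dict:
        self.simulate()
        self.pair()
        for cohort in COHORTS:
            self.qc(cohort)
            self.dge(cohort)
            self.deu(cohort)
            self.dmr(cohort)
            self.psi(cohort)
            self.flank(cohort)
            self.ewas(cohort)
            self.diffcor(cohort)
        self.replicate()
        self.intersect("screening")
        return self.report()
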