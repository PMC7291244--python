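"""Screening for group-reversed methylation-splicing correlations.

The two-cohort design: per (intronic probe, exon bin) combination, compute
the within-group correlation of methylation with PSI in disease and control,
test the difference with Fisher's z, screen at FDR < 0.05 in the screening
cohort, and keep only candidates that replicate *with the same direction* in
the replication cohort.  The generator plants group-reversed loci (disease
and control correlations with opposite signs, the TTN-AS1-like signature)
and same-sign confounds that the directionality filter must reject.
"""

import numpy as np
import pandas as pd

from methsplice import (
    build_gene_combinations,
    compute_psi,
    diffcor_scan,
    directional_replication,
    ewas_scan,
    filter_probes,
    make_fixture,
    top_principal_components,
    beta_to_m,
)

ds = make_fixture("small", seed=1)
keys = ["probe_id", "gene_id", "bin_id"]


def diffcor_of(cohort):
    c = ds.cohorts[cohort]
    probes_ok = filter_probes(ds.probes)
    combos = build_gene_combinations(probes_ok, ds.introns, ds.bins)
    widths = pd.Series(ds.bins["width"].to_numpy(),
                       index=ds.bins["gene_id"] + ":" + ds.bins["bin_id"])
    psi = compute_psi(c.inclusion, c.exclusion, widths)
    pcs = top_principal_components(beta_to_m(c.beta), 2)
    min_group = int(c.sheet["condition"].value_counts().min())
    n_pcs = int(np.clip(min_group - 3, 0, 2))
    scans = {
        g: ewas_scan(c.beta, psi, combos, pcs, c.sheet, g,
                     min_samples=min(5, min_group), n_pcs=n_pcs)
        for g in ("DCM", "control")
    }
    dcm = scans["DCM"].rename(columns={"r": "r_dcm", "n": "n_dcm"})
    ctrl = scans["control"].rename(columns={"r": "r_control", "n": "n_control"})
    return diffcor_scan(dcm[keys + ["r_dcm", "n_dcm"]],
                        ctrl[keys + ["r_control", "n_control"]])


screen = diffcor_of("screening")
repl = diffcor_of("replication")
rep = directional_replication(screen, repl)

print(f"combinations tested        : {len(screen)}")
print(f"screened (FDR < 0.05)      : {int(screen['screened'].sum())}")
print(f"replicated (raw p < 0.05)  : {int(rep['replicated'].sum())}")
print(f"directionally replicated   : {int(rep['directionally_replicated'].sum())}\n")

# compare against the planted truth
truth = ds.truth.special_loci[keys + ["label"]]
merged = rep.merge(truth, on=keys, how="left")
merged["label"] = merged["label"].fillna("null")
print("outcome by planted label:")
print(merged.groupby("label")[["screened", "replicated",
                               "directionally_replicated"]].sum(), "\n")

hits = rep[rep["directionally_replicated"]]
print("top directional candidates (screening-cohort correlations):")
print(hits[keys + ["r_dcm", "r_control", "p"]]
      .sort_values("p").head(5).to_string(index=False))
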