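"""PSI, flank regression, EWAS scan, Fisher's z and the DEU/DMR intersection."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from methsplice import (
    build_gene_combinations,
    compute_psi,
    diffcor_scan,
    directional_replication,
    ewas_scan,
    fisher_z_diffcor,
    fit_flank_glm,
    intersect_deu_dmr,
    simulate_flank_pairs,
    variance_explained,
)
from methsplice.coupling import CouplingError
from methsplice.qc import top_principal_components


def _mat(vals, index, cols=("s0", "s1")):
    return pd.DataFrame(vals, index=index, columns=list(cols))


# ---------------------------------------------------------------------------
# PSI
# ---------------------------------------------------------------------------

def test_psi_trivial_cases():
    idx = ["g:E001", "g:E002", "g:E003"]
    inc = _mat([[10, 10], [0, 0], [0, 0]], idx)
    exc = _mat([[0, 0], [5, 5], [0, 0]], idx)
    widths = pd.Series([100, 100, 100], index=idx)
    psi = compute_psi(inc, exc, widths)
    assert (psi.loc["g:E001"] == 1.0).all()       # only inclusion evidence
    assert (psi.loc["g:E002"] == 0.0).all()       # only exclusion evidence
    assert psi.loc["g:E003"].isna().all()         # no evidence at all


def test_psi_matches_length_normalized_formula():
    rng = np.random.default_rng(0)
    idx = [f"g:E{i:03d}" for i in range(20)]
    inc = _mat(rng.integers(0, 50, (20, 2)), idx)
    exc = _mat(rng.integers(0, 50, (20, 2)), idx)
    widths = pd.Series(rng.integers(60, 400, 20), index=idx)
    lj = 99.0
    psi = compute_psi(inc, exc, widths, junction_length=lj)
    for i in range(20):
        for j, s in enumerate(["s0", "s1"]):
            di = inc.iloc[i, j] / widths.iloc[i]
            de = exc.iloc[i, j] / lj
            if di + de == 0:
                assert np.isnan(psi.iloc[i, j])
            else:
                assert psi.iloc[i, j] == pytest.approx(di / (di + de))


def test_psi_rejects_negative_counts():
    idx = ["g:E001"]
    with pytest.raises(CouplingError):
        compute_psi(_mat([[-1, 0]], idx), _mat([[0, 0]], idx),
                    pd.Series([10], index=idx))


@settings(derandomize=True, max_examples=100, deadline=None)
@given(st.integers(0, 100), st.integers(0, 100),
       st.integers(60, 400), st.floats(10, 200))
def test_psi_bounded_property(i, e, width, lj):
    idx = ["g:E001"]
    psi = compute_psi(_mat([[i, i]], idx), _mat([[e, e]], idx),
                      pd.Series([width], index=idx), junction_length=lj)
    v = psi.iloc[0, 0]
    if i == 0 and e == 0:
        assert np.isnan(v)
    else:
        assert 0.0 <= v <= 1.0


# ---------------------------------------------------------------------------
# flank regression
# ---------------------------------------------------------------------------

def test_flank_glm_recovers_planted_coefficient():
    pairs = simulate_flank_pairs(20_000, coef=0.35, phi=2.0, seed=0)
    res = fit_flank_glm(pairs["y"], pairs["total"], pairs["beta"])
    assert res.coefficient == pytest.approx(0.35, abs=0.05)
    assert res.dispersion == pytest.approx(2.0, rel=0.2)
    assert res.n_pairs == 20_000


def test_flank_glm_distance_adjustment_recovers_both_terms():
    pairs = simulate_flank_pairs(30_000, coef=0.3, phi=1.0, dist_coef=-0.2,
                                 seed=1)
    res = fit_flank_glm(pairs["y"], pairs["total"], pairs["beta"],
                        distance=pairs["distance"])
    assert res.adjusted
    assert res.coefficient == pytest.approx(0.3, abs=0.05)


def test_flank_glm_guards():
    with pytest.raises(CouplingError):
        fit_flank_glm(np.ones(5), np.ones(5) * 10, np.linspace(0, 1, 5))
    with pytest.raises(CouplingError):
        fit_flank_glm(np.ones(20), np.ones(20) * 10, np.full(20, 0.5))


# ---------------------------------------------------------------------------
# Fisher's z
# ---------------------------------------------------------------------------

def test_fisher_z_worked_value():
    z, p = fisher_z_diffcor(0.5, 50, 0.0, 50)
    assert z == pytest.approx(np.arctanh(0.5) / np.sqrt(2.0 / 47.0))
    assert z == pytest.approx(2.6629, abs=1e-3)
    assert p == pytest.approx(0.00774, abs=1e-4)


def test_fisher_z_antisymmetric_and_zero_under_equality():
    z1, _ = fisher_z_diffcor(0.4, 30, -0.2, 25)
    z2, _ = fisher_z_diffcor(-0.2, 25, 0.4, 30)
    assert z1 == pytest.approx(-z2)
    z0, p0 = fisher_z_diffcor(0.3, 30, 0.3, 40)
    assert z0 == pytest.approx(0.0)
    assert p0 == pytest.approx(1.0)


def test_fisher_z_input_guards():
    with pytest.raises(CouplingError):
        fisher_z_diffcor(1.0, 30, 0.0, 30)
    with pytest.raises(CouplingError):
        fisher_z_diffcor(0.5, 3, 0.0, 30)


# ---------------------------------------------------------------------------
# EWAS scan
# ---------------------------------------------------------------------------

def _toy_scan(rng, n=24, coef=8.0):
    samples = [f"s{i}" for i in range(n)]
    sheet = pd.DataFrame({"sample_id": samples, "condition": ["DCM"] * n})
    beta = pd.DataFrame(rng.uniform(0.2, 0.8, (3, n)),
                        index=["cg1", "cg2", "cg3"], columns=samples)
    logits = coef * (beta.loc[["cg1", "cg2", "cg3"]].to_numpy() - 0.5)
    psi = pd.DataFrame(
        1 / (1 + np.exp(-(logits + rng.normal(0, 0.3, (3, n))))),
        index=["gA:E001", "gA:E002", "gB:E001"], columns=samples)
    combos = pd.DataFrame({
        "probe_id": ["cg1", "cg2", "cg3"],
        "gene_id": ["gA", "gA", "gB"],
        "bin_id": ["E001", "E002", "E001"],
    })
    m = np.log2(beta / (1 - beta))
    pcs = top_principal_components(m, 2)
    return ewas_scan(beta, psi, combos, pcs, sheet, "DCM"), coef


def test_ewas_scan_or_identity_and_positive_association():
    rng = np.random.default_rng(2)
    res, _ = _toy_scan(rng)
    assert len(res) == 3
    np.testing.assert_allclose(res["or_per_001"],
                               np.exp(0.01 * res["coefficient"]), rtol=1e-12)
    assert (res["or_ci_low"] <= res["or_per_001"]).all()
    assert (res["or_per_001"] <= res["or_ci_high"]).all()
    assert (res["coefficient"] > 0).all()
    assert (res["r"] > 0.5).all()


def test_ewas_scan_skips_degenerate_combinations():
    rng = np.random.default_rng(3)
    n = 12
    samples = [f"s{i}" for i in range(n)]
    sheet = pd.DataFrame({"sample_id": samples, "condition": ["DCM"] * n})
    beta = pd.DataFrame(rng.uniform(0.2, 0.8, (1, n)), index=["cg1"],
                        columns=samples)
    psi = pd.DataFrame(np.full((1, n), 0.5), index=["gA:E001"], columns=samples)
    combos = pd.DataFrame({"probe_id": ["cg1"], "gene_id": ["gA"],
                           "bin_id": ["E001"]})
    pcs = top_principal_components(
        pd.DataFrame(rng.normal(size=(10, n)), columns=samples), 2)
    res = ewas_scan(beta, psi, combos, pcs, sheet, "DCM")
    assert res.empty  # constant PSI is untestable


def test_build_gene_combinations_cross_bin():
    introns = pd.DataFrame({
        "gene_id": ["gA"], "chrom": ["chr1"], "start": [201], "end": [299],
        "upstream_bin_id": ["E001"], "downstream_bin_id": ["E002"],
    })
    bins = pd.DataFrame({
        "gene_id": ["gA", "gA", "gB"], "bin_id": ["E001", "E002", "E001"],
    })
    probes = pd.DataFrame({"probe_id": ["cg1", "cg2"], "chrom": ["chr1", "chr1"],
                           "pos": [250, 500]})
    combos = build_gene_combinations(probes, introns, bins)
    # cg1 is intronic in gA: paired with every gA bin; cg2 is outside all introns
    assert combos[["probe_id", "gene_id", "bin_id"]].values.tolist() == [
        ["cg1", "gA", "E001"], ["cg1", "gA", "E002"]]


# ---------------------------------------------------------------------------
# variance explained
# ---------------------------------------------------------------------------

def test_variance_explained_null_mean_r2_is_one_over_n_minus_one():
    rng = np.random.default_rng(4)
    n, n_tests = 21, 4000
    samples = [f"s{i}" for i in range(n)]
    beta = pd.DataFrame(rng.uniform(size=(n_tests, n)),
                        index=[f"cg{i}" for i in range(n_tests)],
                        columns=samples)
    psi = pd.DataFrame(rng.uniform(size=(n_tests, n)),
                       index=[f"g{i}:E001" for i in range(n_tests)],
                       columns=samples)
    combos = pd.DataFrame({
        "probe_id": [f"cg{i}" for i in range(n_tests)],
        "gene_id": [f"g{i}" for i in range(n_tests)],
        "bin_id": ["E001"] * n_tests,
    })
    ve = variance_explained(beta, psi, combos)
    assert ve["n_tests"] == n_tests
    # under independence E[r^2] = 1 / (n - 1)
    assert ve["mean_r2"] == pytest.approx(1.0 / (n - 1), rel=0.15)
    assert ve["ci_low"] < 1.0 / (n - 1) < ve["ci_high"]


def test_variance_explained_grows_with_coupling_strength():
    rng = np.random.default_rng(5)
    n, n_tests = 30, 500
    samples = [f"s{i}" for i in range(n)]
    combos = pd.DataFrame({
        "probe_id": [f"cg{i}" for i in range(n_tests)],
        "gene_id": [f"g{i}" for i in range(n_tests)],
        "bin_id": ["E001"] * n_tests,
    })
    means = []
    for strength in (0.0, 0.5, 2.0):
        b = rng.uniform(size=(n_tests, n))
        y = strength * b + rng.normal(0, 1, (n_tests, n))
        beta = pd.DataFrame(b, index=combos["probe_id"], columns=samples)
        psi = pd.DataFrame(1 / (1 + np.exp(-y)),
                           index=combos["gene_id"] + ":E001", columns=samples)
        means.append(variance_explained(beta, psi, combos)["mean_r2"])
    assert means[0] < means[1] < means[2]


# ---------------------------------------------------------------------------
# diffcor / replication logic
# ---------------------------------------------------------------------------

def _assoc(rows, group):
    r_col, n_col = f"r_{group}", f"n_{group}"
    return pd.DataFrame(rows, columns=["probe_id", "gene_id", "bin_id",
                                       r_col, n_col])


def test_diffcor_scan_flags_reversed_combination():
    dcm = _assoc([("cg1", "gA", "E001", -0.9, 30),
                  ("cg2", "gA", "E002", 0.1, 30)], "dcm")
    ctrl = _assoc([("cg1", "gA", "E001", 0.9, 20),
                   ("cg2", "gA", "E002", 0.05, 20)], "control")
    res = diffcor_scan(dcm, ctrl)
    by = res.set_index("probe_id")
    assert bool(by.loc["cg1", "screened"])
    assert not bool(by.loc["cg2", "screened"])
    # z matches the direct computation
    z, p = fisher_z_diffcor(-0.9, 30, 0.9, 20)
    assert by.loc["cg1", "z"] == pytest.approx(z)


def test_directional_replication_definitions():
    keys = ["probe_id", "gene_id", "bin_id"]
    screen = pd.DataFrame({
        "probe_id": ["a", "b", "c", "d"],
        "gene_id": ["g"] * 4, "bin_id": ["E001"] * 4,
        "r_dcm": [-0.8, -0.8, -0.8, 0.7],
        "r_control": [0.8, 0.8, 0.8, 0.6],
        "n_dcm": [30] * 4, "n_control": [20] * 4,
        "z": [-5.0] * 4, "p": [1e-7] * 4, "fdr": [1e-5] * 4,
        "screened": [True, True, True, True],
    })
    repl = pd.DataFrame({
        "probe_id": ["a", "b", "c"],
        "gene_id": ["g"] * 3, "bin_id": ["E001"] * 3,
        # a: replicates directionally; b: p too large; c: DCM sign flips
        "r_dcm": [-0.9, -0.9, 0.9],
        "r_control": [0.9, 0.9, 0.9],
        "n_dcm": [11] * 3, "n_control": [5] * 3,
        "z": [-4.0, -1.0, 4.0], "p": [1e-4, 0.4, 1e-4],
        "fdr": [1e-3, 0.6, 1e-3], "screened": [True, False, True],
    })
    res = directional_replication(screen, repl).set_index("probe_id")
    assert bool(res.loc["a", "directionally_replicated"])
    assert not bool(res.loc["b", "replicated"])
    assert bool(res.loc["c", "replicated"])
    assert not bool(res.loc["c", "directionally_replicated"])
    # d: absent from replication entirely
    assert not bool(res.loc["d", "replicated"])
    # same-sign candidate never passes the directionality filter
    samesign = screen.copy()
    samesign.loc[:, "r_dcm"] = 0.9
    res2 = directional_replication(samesign, repl).set_index("probe_id")
    assert not res2["directionally_replicated"].any()


# ---------------------------------------------------------------------------
# DEU/DMR intersection
# ---------------------------------------------------------------------------

def test_intersect_deu_dmr_toy_example():
    # three pairs: only the first has both DEU p and DMR p below alpha
    pairs = pd.DataFrame({
        "kind": ["intron-exon", "intron-exon", "exon-intron"],
        "probe_id": ["cg1", "cg2", "cg1"],
        "gene_id": ["gA", "gA", "gB"],
        "bin_id": ["E001", "E002", "E001"],
        "distance": [50, 70, 90],
    })
    deu = pd.DataFrame({"feature_id": ["gA:E001", "gA:E002", "gB:E001"],
                        "p": [0.01, 0.20, 0.01]})
    dmr = pd.DataFrame({"feature_id": ["cg1", "cg2"], "p": [0.03, 0.40]})
    out, report = intersect_deu_dmr(deu, dmr, pairs, alpha=0.05)
    assert out["hit"].tolist() == [True, False, True]
    assert report["intron-exon"] == {"n_pairs": 1, "n_genes": 1}
    assert report["exon-intron"] == {"n_pairs": 1, "n_genes": 1}


def test_intersect_handles_missing_features_as_non_hits():
    pairs = pd.DataFrame({
        "kind": ["intron-exon"], "probe_id": ["cgX"], "gene_id": ["gA"],
        "bin_id": ["E001"], "distance": [10],
    })
    deu = pd.DataFrame({"feature_id": ["gA:E001"], "p": [0.001]})
    dmr = pd.DataFrame({"feature_id": ["cgOther"], "p": [0.001]})
    out, report = intersect_deu_dmr(deu, dmr, pairs)
    assert not out["hit"].any()
    assert report["intron-exon"] == {"n_pairs": 0, "n_genes": 0}
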