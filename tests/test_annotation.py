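"""Exon-bin flattening, intron derivation and flank pairing vs brute force."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from methsplice import (
    GeneModel,
    build_flank_pairs,
    derive_introns,
    flatten_gene_models,
    median_pair_distance,
    read_gtf,
    read_probe_manifest,
    write_gtf,
)
from methsplice.annotation import AnnotationError


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def oracle_bins(model: GeneModel) -> list[tuple[int, int]]:
    """Maximal runs of exon-covered positions not crossing any exon boundary."""
    lo = min(s for _, ex in model.transcripts for s, _ in ex)
    hi = max(e for _, ex in model.transcripts for _, e in ex)
    covered = np.zeros(hi - lo + 2, dtype=bool)
    boundary = np.zeros(hi - lo + 2, dtype=bool)  # bin must start here
    for _, exons in model.transcripts:
        for s, e in exons:
            covered[s - lo:e - lo + 1] = True
            boundary[s - lo] = True
            boundary[e - lo + 1] = True
    out = []
    start = None
    for i in range(len(covered)):
        if covered[i] and (start is None or boundary[i]):
            if start is not None:
                out.append((start + lo, i - 1 + lo))
            start = i
        elif not covered[i] and start is not None:
            out.append((start + lo, i - 1 + lo))
            start = None
    return out


def oracle_pairs(probes, introns, bins) -> set[tuple]:
    out = set()
    for p in probes.itertuples():
        for iv in introns.itertuples():
            if iv.chrom == p.chrom and iv.start <= p.pos <= iv.end:
                up = bins[(bins["gene_id"] == iv.gene_id)
                          & (bins["bin_id"] == iv.upstream_bin_id)].iloc[0]
                down = bins[(bins["gene_id"] == iv.gene_id)
                            & (bins["bin_id"] == iv.downstream_bin_id)].iloc[0]
                out.add(("exon-intron", p.probe_id, iv.gene_id,
                         iv.upstream_bin_id, p.pos - up["end"]))
                out.add(("intron-exon", p.probe_id, iv.gene_id,
                         iv.downstream_bin_id, down["start"] - p.pos))
    return out


def random_gene(rng: np.random.Generator, gene_id="G", chrom="chr1") -> GeneModel:
    n_cuts = rng.integers(2, 8)
    cuts = np.sort(rng.choice(np.arange(100, 1000), size=2 * n_cuts, replace=False))
    exon_pool = [(int(cuts[i]), int(cuts[i + 1] - 1)) for i in range(0, 2 * n_cuts, 2)]
    transcripts = []
    for t in range(rng.integers(1, 4)):
        keep = [ex for ex in exon_pool if rng.random() < 0.7]
        if not keep:
            keep = [exon_pool[0]]
        transcripts.append((f"t{t}", keep))
    return GeneModel(gene_id, chrom, "+" if rng.random() < 0.5 else "-", transcripts)


# ---------------------------------------------------------------------------
# flattening
# ---------------------------------------------------------------------------

def test_flatten_two_transcripts_split_at_internal_boundary():
    # classic two-transcript case: [100,200] and [150,200] share an end but
    # the second's start at 150 cuts the first exon in two
    g = GeneModel("G1", "chr1", "+", [("t1", [(100, 200)]), ("t2", [(150, 200)])])
    bins = flatten_gene_models([g])
    assert bins[["bin_id", "start", "end"]].values.tolist() == [
        ["E001", 100, 149], ["E002", 150, 200]]
    assert bins["width"].tolist() == [50, 51]


def test_flatten_matches_oracle_on_random_genes():
    rng = np.random.default_rng(0)
    for _ in range(50):
        g = random_gene(rng)
        got = flatten_gene_models([g])[["start", "end"]].to_records(index=False)
        assert [(s, e) for s, e in got] == oracle_bins(g)


def test_flatten_bins_ordered_and_disjoint(tiny_ds):
    for _, grp in tiny_ds.bins.groupby("gene_id"):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        assert (starts[1:] > ends[:-1]).all()
        assert (ends >= starts).all()
        assert list(grp["bin_id"]) == [f"E{i + 1:03d}" for i in range(len(grp))]


def test_flatten_independent_for_overlapping_genes():
    a = GeneModel("A", "chr1", "+", [("t1", [(100, 300)])])
    b = GeneModel("B", "chr1", "-", [("t1", [(200, 400)])])
    bins = flatten_gene_models([a, b])
    assert bins.loc[bins["gene_id"] == "A", ["start", "end"]].values.tolist() == [[100, 300]]
    assert bins.loc[bins["gene_id"] == "B", ["start", "end"]].values.tolist() == [[200, 400]]


@settings(derandomize=True, max_examples=50, deadline=None)
@given(st.integers(0, 10_000))
def test_flatten_partition_property(seed):
    # bins exactly tile the exonic footprint and never cross an exon boundary
    rng = np.random.default_rng(seed)
    g = random_gene(rng)
    bins = flatten_gene_models([g])
    footprint = set()
    for _, exons in g.transcripts:
        for s, e in exons:
            footprint.update(range(s, e + 1))
    tiled = set()
    bin_starts = set(bins["start"])
    bin_ends = set(bins["end"])
    for b in bins.itertuples():
        seg = set(range(b.start, b.end + 1))
        assert not (tiled & seg)
        tiled |= seg
    assert tiled == footprint
    # every transcript exon boundary is also a bin boundary
    for _, exons in g.transcripts:
        for s, e in exons:
            assert s in bin_starts
            assert e in bin_ends


def test_validate_rejects_bad_models():
    with pytest.raises(AnnotationError):
        GeneModel("G", "chr1", "+", []).validate()
    with pytest.raises(AnnotationError):
        GeneModel("G", "chr1", "*", [("t", [(1, 2)])]).validate()
    with pytest.raises(AnnotationError):
        GeneModel("G", "chr1", "+", [("t", [(10, 5)])]).validate()
    with pytest.raises(AnnotationError):
        GeneModel("G", "chr1", "+", [("t", [(1, 10), (5, 20)])]).validate()


# ---------------------------------------------------------------------------
# introns
# ---------------------------------------------------------------------------

def test_derive_introns_gaps_and_flanks():
    g = GeneModel("G", "chr1", "+", [("t", [(100, 200), (300, 400), (401, 500)])])
    bins = flatten_gene_models([g])
    introns = derive_introns(bins)
    # abutting bins [300,400][401,500] produce no intron
    assert len(introns) == 1
    iv = introns.iloc[0]
    assert (iv["start"], iv["end"]) == (201, 299)
    assert iv["upstream_bin_id"] == "E001"
    assert iv["downstream_bin_id"] == "E002"


def test_derive_introns_matches_gap_oracle(tiny_ds):
    for gene_id, grp in tiny_ds.bins.groupby("gene_id"):
        grp = grp.sort_values("start")
        expected = [(int(e) + 1, int(s) - 1)
                    for e, s in zip(grp["end"][:-1], grp["start"][1:])
                    if e + 1 <= s - 1]
        got = tiny_ds.introns[tiny_ds.introns["gene_id"] == gene_id]
        assert list(zip(got["start"], got["end"])) == expected


# ---------------------------------------------------------------------------
# flank pairs
# ---------------------------------------------------------------------------

def _probe_frame(rows):
    return pd.DataFrame(rows, columns=["probe_id", "chrom", "pos"])


def test_pair_distances_worked_example():
    # probe at 250 inside intron [201,299]: 50 bp from the upstream bin end
    # (200) and 50 bp from the downstream bin start (300)
    g = GeneModel("G", "chr1", "+", [("t", [(100, 200), (300, 400)])])
    bins = flatten_gene_models([g])
    introns = derive_introns(bins)
    probes = _probe_frame([("cg1", "chr1", 250)])
    pairs = build_flank_pairs(probes, introns, bins)
    assert len(pairs) == 2
    by_kind = pairs.set_index("kind")
    assert by_kind.loc["exon-intron", "distance"] == 50
    assert by_kind.loc["exon-intron", "bin_id"] == "E001"
    assert by_kind.loc["intron-exon", "distance"] == 50
    assert by_kind.loc["intron-exon", "bin_id"] == "E002"


def test_exonic_probe_yields_no_pair():
    g = GeneModel("G", "chr1", "+", [("t", [(100, 200), (300, 400)])])
    bins = flatten_gene_models([g])
    introns = derive_introns(bins)
    pairs = build_flank_pairs(_probe_frame([("cg1", "chr1", 150),
                                            ("cg2", "chr1", 300)]),
                              introns, bins)
    assert pairs.empty


def test_probe_on_unknown_chromosome_skipped():
    g = GeneModel("G", "chr1", "+", [("t", [(100, 200), (300, 400)])])
    bins = flatten_gene_models([g])
    introns = derive_introns(bins)
    pairs = build_flank_pairs(_probe_frame([("cg1", "chr9", 250)]), introns, bins)
    assert pairs.empty


def test_pairs_match_bruteforce_on_random_layouts():
    rng = np.random.default_rng(1)
    for _ in range(25):
        models = [random_gene(rng, gene_id=f"G{i}",
                              chrom=f"chr{rng.integers(1, 3)}") for i in range(4)]
        bins = flatten_gene_models(models)
        introns = derive_introns(bins)
        probes = _probe_frame([
            (f"cg{j}", f"chr{rng.integers(1, 3)}", int(rng.integers(80, 1020)))
            for j in range(30)])
        got = build_flank_pairs(probes, introns, bins)
        got_set = {tuple(r) for r in got.to_records(index=False)}
        assert got_set == oracle_pairs(probes, introns, bins)


def test_pairs_deterministic_under_input_reordering(tiny_ds):
    probes = tiny_ds.probes
    base = build_flank_pairs(probes, tiny_ds.introns, tiny_ds.bins)
    shuffled = build_flank_pairs(
        probes.sample(frac=1.0, random_state=3),
        tiny_ds.introns.sample(frac=1.0, random_state=4),
        tiny_ds.bins)
    pd.testing.assert_frame_equal(base, shuffled)


def test_median_pair_distance_matches_sort_oracle(tiny_ds):
    pairs = build_flank_pairs(tiny_ds.probes, tiny_ds.introns, tiny_ds.bins)
    d = sorted(pairs["distance"])
    n = len(d)
    expect = d[n // 2] if n % 2 else (d[n // 2 - 1] + d[n // 2]) / 2
    assert median_pair_distance(pairs) == expect


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def test_gtf_round_trip(tmp_path, tiny_ds):
    path = tmp_path / "x.gtf"
    write_gtf(tiny_ds.gene_models, path)
    back = read_gtf(path)
    orig = {m.gene_id: m for m in tiny_ds.gene_models}
    assert set(orig) == {m.gene_id for m in back}
    for m in back:
        o = orig[m.gene_id]
        assert (m.chrom, m.strand) == (o.chrom, o.strand)
        assert sorted(m.transcripts) == sorted(o.transcripts)
    # flattening the round-tripped models gives identical bins
    got = flatten_gene_models(back).sort_values(
        ["gene_id", "start"]).reset_index(drop=True)
    want = tiny_ds.bins.sort_values(
        ["gene_id", "start"]).reset_index(drop=True)
    pd.testing.assert_frame_equal(got, want)


def test_probe_manifest_blocklists_and_sex_flag(tmp_path):
    manifest = tmp_path / "probes.tsv"
    pd.DataFrame({
        "probe_id": ["cg1", "cg2", "cg3"],
        "chrom": ["chr1", "chrX", "chr2"],
        "pos": [10, 20, 30],
    }).to_csv(manifest, sep="\t", index=False)
    snp = tmp_path / "snp.txt"
    snp.write_text("cg3\n")
    probes = read_probe_manifest(manifest, {"flag_snp": snp})
    assert probes["flag_sex_chrom"].tolist() == [False, True, False]
    assert probes["flag_snp"].tolist() == [False, False, True]
    assert probes["flag_cross_reactive"].tolist() == [False] * 3
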