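"""Genomic scaffold: exon-bin flattening, intron derivation and flank-pair construction.

Transcript exons of a gene are flattened into disjoint counting bins split at
every exon boundary observed across that gene's transcripts (the DEXSeq-style
"exonic bin").  Introns are the gaps between consecutive bins.  A methylation
probe falling inside an intron is paired with the bin immediately downstream
(an *intron-exon* pair) and the bin immediately upstream (an *exon-intron*
pair); these pairs are the observation unit of the flanking-methylation
regression.

Coordinates are 1-based inclusive throughout (GTF convention); BED output is
converted to 0-based half-open at the I/O boundary only.  Strand is recorded
but pairing and distances are in genomic orientation: the probe manifest
carries no strand, so "upstream/downstream" is read on the forward genome.
Genes are flattened independently, so antisense-overlapping gene pairs
(e.g. TTN / TTN-AS1) each keep their own bins and a probe pairs within each
gene whose intron contains it.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BIN_COLUMNS = ["gene_id", "bin_id", "chrom", "strand", "start", "end", "width"]
INTRON_COLUMNS = ["gene_id", "chrom", "start", "end",
                  "upstream_bin_id", "downstream_bin_id"]
PAIR_COLUMNS = ["kind", "probe_id", "gene_id", "bin_id", "distance"]
PROBE_COLUMNS = ["probe_id", "chrom", "pos",
                 "flag_snp", "flag_cross_reactive", "flag_sex_chrom"]

SEX_CHROMS = frozenset({"chrX", "chrY", "X", "Y"})


class AnnotationError(ValueError):
    """Malformed gene-model or probe input."""


@dataclass
class GeneModel:
    """A gene with its transcript exon structures.

    Exon intervals are 1-based inclusive ``(start, end)`` tuples; each
    transcript's exons must be sorted by start and non-overlapping.
    """

    gene_id: str
    chrom: str
    strand: str
    transcripts: list[tuple[str, list[tuple[int, int]]]] = field(default_factory=list)

    def validate(self) -> None:
        if not self.transcripts or all(not ex for _, ex in self.transcripts):
            raise AnnotationError(f"gene {self.gene_id} has no exons")
        if self.strand not in {"+", "-"}:
            raise AnnotationError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        for tx_id, exons in self.transcripts:
            prev_end = None
            for start, end in exons:
                if start > end:
                    raise AnnotationError(
                        f"gene {self.gene_id} transcript {tx_id}: "
                        f"exon start {start} > end {end}"
                    )
                if prev_end is not None and start <= prev_end:
                    raise AnnotationError(
                        f"gene {self.gene_id} transcript {tx_id}: exons overlap "
                        f"or are unsorted near position {start}"
                    )
                prev_end = end


def flatten_gene_models(models: list[GeneModel]) -> pd.DataFrame:
    """Flatten transcripts of each gene into disjoint exonic bins.

    The exonic footprint (union of all transcript exons) is split at every
    distinct exon boundary observed in any transcript of the gene; the
    resulting maximal covered segments are labelled ``E001``, ``E002``, ... in
    genomic order.  Overlapping genes are flattened independently.

    Returns a DataFrame with columns ``gene_id, bin_id, chrom, strand, start,
    end, width``.
    """
    rows = []
    for model in models:
        model.validate()
        # cut points: every exon start, and every position just past an exon end
        cuts: set[int] = set()
        for _, exons in model.transcripts:
            for start, end in exons:
                cuts.add(start)
                cuts.add(end + 1)
        cuts_sorted = np.array(sorted(cuts))
        starts = cuts_sorted[:-1]
        ends = cuts_sorted[1:] - 1
        # a candidate segment is a bin iff covered by at least one exon;
        # coverage is constant between consecutive cuts, so testing the
        # segment start suffices
        exon_starts = []
        exon_ends = []
        for _, exons in model.transcripts:
            for s, e in exons:
                exon_starts.append(s)
                exon_ends.append(e)
        exon_starts = np.array(exon_starts)
        exon_ends = np.array(exon_ends)
        covered = [
            bool(np.any((exon_starts <= s) & (exon_ends >= s))) for s in starts
        ]
        ordinal = 0
        for s, e, cov in zip(starts, ends, covered):
            if not cov:
                continue
            ordinal += 1
            rows.append(
                (model.gene_id, f"E{ordinal:03d}", model.chrom, model.strand,
                 int(s), int(e), int(e - s + 1))
            )
    return pd.DataFrame(rows, columns=BIN_COLUMNS)


def derive_introns(bins: pd.DataFrame) -> pd.DataFrame:
    """One intron per gap between consecutive bins of a gene.

    The intron between bins ``prev`` and ``next`` is ``[prev.end + 1,
    next.start - 1]``; abutting bins produce no intron.  The flanking bin ids
    are carried along for pairing.
    """
    rows = []
    for gene_id, grp in bins.groupby("gene_id", sort=False):
        grp = grp.sort_values("start")
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        bin_ids = grp["bin_id"].to_numpy()
        chrom = grp["chrom"].iloc[0]
        for i in range(len(grp) - 1):
            lo, hi = ends[i] + 1, starts[i + 1] - 1
            if lo <= hi:
                rows.append((gene_id, chrom, int(lo), int(hi),
                             bin_ids[i], bin_ids[i + 1]))
    return pd.DataFrame(rows, columns=INTRON_COLUMNS)


def build_flank_pairs(
    probes: pd.DataFrame,
    introns: pd.DataFrame,
    bins: pd.DataFrame,
) -> pd.DataFrame:
    """Pair each intronic probe with its adjacent exonic bins.

    For every probe located strictly inside an intron of a gene, one
    *intron-exon* pair is emitted with the bin immediately downstream
    (``distance = bin.start - pos``) and one *exon-intron* pair with the bin
    immediately upstream (``distance = pos - bin.end``).  A probe exactly on a
    bin boundary is exonic and yields no pair.  Probes on chromosomes absent
    from the annotation are skipped with a logged count.

    ``probes`` must already be blocklist-filtered.
    """
    if introns.empty or probes.empty:
        return pd.DataFrame(columns=PAIR_COLUMNS)
    bin_start = bins.set_index(["gene_id", "bin_id"])["start"].to_dict()
    bin_end = bins.set_index(["gene_id", "bin_id"])["end"].to_dict()

    rows = []
    n_skipped_chrom = 0
    intron_chroms = set(introns["chrom"].unique())
    for chrom, probe_grp in probes.groupby("chrom", sort=False):
        if chrom not in intron_chroms:
            n_skipped_chrom += len(probe_grp)
            continue
        sub = introns[introns["chrom"] == chrom].sort_values(
            "start", kind="mergesort").reset_index(drop=True)
        istart = sub["start"].to_numpy()
        iend = sub["end"].to_numpy()
        gene_arr = sub["gene_id"].to_numpy()
        up_arr = sub["upstream_bin_id"].to_numpy()
        down_arr = sub["downstream_bin_id"].to_numpy()
        # introns of different genes may overlap; bound the backward scan
        # with the running maximum of intron ends
        prefix_max_end = np.maximum.accumulate(iend)
        pos_arr = probe_grp["pos"].to_numpy()
        pid_arr = probe_grp["probe_id"].to_numpy()
        for pos, probe_id in zip(pos_arr, pid_arr):
            j = np.searchsorted(istart, pos, side="right") - 1
            while j >= 0 and prefix_max_end[j] >= pos:
                if iend[j] >= pos:
                    gene_id = gene_arr[j]
                    up_bin = up_arr[j]
                    down_bin = down_arr[j]
                    rows.append(("exon-intron", probe_id, gene_id, up_bin,
                                 int(pos - bin_end[(gene_id, up_bin)])))
                    rows.append(("intron-exon", probe_id, gene_id, down_bin,
                                 int(bin_start[(gene_id, down_bin)] - pos)))
                j -= 1
    if n_skipped_chrom:
        logger.info("build_flank_pairs: skipped %d probes on chromosomes "
                    "absent from annotation", n_skipped_chrom)
    pairs = pd.DataFrame(rows, columns=PAIR_COLUMNS)
    pairs = pairs.sort_values(["gene_id", "bin_id", "probe_id", "kind"],
                              kind="mergesort").reset_index(drop=True)
    return pairs


def median_pair_distance(pairs: pd.DataFrame) -> float:
    """Median genomic distance (bp) over all flank pairs."""
    return float(np.median(pairs["distance"].to_numpy()))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_ATTR_RE = {
    "gene_id": re.compile(r'gene_id "([^"]+)"'),
    "transcript_id": re.compile(r'transcript_id "([^"]+)"'),
}


def read_gtf(path) -> list[GeneModel]:
    """Read exon records from a GTF file into GeneModel objects."""
    genes: dict[str, GeneModel] = {}
    tx_exons: dict[tuple[str, str], list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != "exon":
                continue
            chrom, start, end, strand, attrs = (
                fields[0], int(fields[3]), int(fields[4]), fields[6], fields[8]
            )
            m_gene = _ATTR_RE["gene_id"].search(attrs)
            m_tx = _ATTR_RE["transcript_id"].search(attrs)
            if m_gene is None or m_tx is None:
                raise AnnotationError(f"GTF exon record lacks gene_id/transcript_id: {line!r}")
            gene_id, tx_id = m_gene.group(1), m_tx.group(1)
            if gene_id not in genes:
                genes[gene_id] = GeneModel(gene_id, chrom, strand, [])
            tx_exons.setdefault((gene_id, tx_id), []).append((start, end))
    for (gene_id, tx_id), exons in tx_exons.items():
        genes[gene_id].transcripts.append((tx_id, sorted(exons)))
    return list(genes.values())


def write_gtf(models: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for model in models:
            for tx_id, exons in model.transcripts:
                for start, end in exons:
                    attrs = f'gene_id "{model.gene_id}"; transcript_id "{tx_id}";'
                    fh.write("\t".join([
                        model.chrom, "methsplice", "exon", str(start), str(end),
                        ".", model.strand, ".", attrs,
                    ]) + "\n")


def read_probe_manifest(path, blocklists: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a probe manifest TSV; optionally flag probes from blocklist files.

    ``blocklists`` maps flag column names (``flag_snp``,
    ``flag_cross_reactive``) to one-probe-id-per-line text files.  The
    sex-chromosome flag is always derived from the chromosome.
    """
    probes = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    for col in ("flag_snp", "flag_cross_reactive"):
        if col not in probes.columns:
            probes[col] = False
        else:
            probes[col] = probes[col].astype(bool)
    if blocklists:
        for col, listpath in blocklists.items():
            with open(listpath) as fh:
                ids = {line.strip() for line in fh if line.strip()}
            probes[col] = probes[col] | probes["probe_id"].isin(ids)
    probes["flag_sex_chrom"] = probes["chrom"].isin(SEX_CHROMS)
    return probes[PROBE_COLUMNS + [c for c in probes.columns if c not in PROBE_COLUMNS]]


def write_bins_bed(bins: pd.DataFrame, path) -> None:
    """Write bins as BED (0-based half-open)."""
    bed = pd.DataFrame({
        "chrom": bins["chrom"],
        "start": bins["start"] - 1,
        "end": bins["end"],
        "name": bins["gene_id"] + ":" + bins["bin_id"],
        "score": 0,
        "strand": bins["strand"],
    })
    bed.to_csv(path, sep="\t", header=False, index=False)
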