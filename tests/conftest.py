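"""Shared fixtures: synthetic datasets at two scales and toy-CDS builders."""

from __future__ import annotations

import numpy as np
import pysam
import pytest

import plastedit as pe

# ---------------------------------------------------------------------------
# synthetic datasets
# ---------------------------------------------------------------------------


def tiny_config(**overrides) -> pe.SimConfig:
    """A 2 kb two-gene configuration small enough for nested-loop oracles."""
    kwargs = dict(
        genome_length=2000,
        n_genes=2,
        trna_genes=0,
        intron_genes=1,
        n_edits=8,
        cds_codon_range=(40, 60),
        mean_coverage=80.0,
        read_length=50,
        error_rate=0.01,
        start_codon_test_gene=False,
        seed=7,
    )
    kwargs.update(overrides)
    return pe.SimConfig(**kwargs)


@pytest.fixture(scope="session")
def demo_config() -> pe.SimConfig:
    return pe.SimConfig(seed=11)


@pytest.fixture(scope="session")
def demo_dataset(demo_config, tmp_path_factory) -> pe.SimOutput:
    """Default study conditions: 20 kb, 100 edits, 200x coverage."""
    return pe.simulate_dataset(demo_config, tmp_path_factory.mktemp("demo"))


@pytest.fixture(scope="session")
def demo_calls(demo_dataset):
    """Filtered reads, pileups and called sites for both tissues."""
    out = {}
    for tissue, sam in demo_dataset.sam_per_tissue.items():
        reads = pe.filter_alignments(
            pe.read_sam(sam), pe.AlignmentFilterParams(), demo_dataset.genome
        )
        pileup = pe.build_pileup(reads, demo_dataset.genome)
        sites = pe.call_edits(pileup, demo_dataset.genome, demo_dataset.features)
        out[tissue] = {"reads": reads, "pileup": pileup, "sites": sites}
    return out


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory) -> pe.SimOutput:
    return pe.simulate_dataset(tiny_config(), tmp_path_factory.mktemp("tiny"))


# ---------------------------------------------------------------------------
# hand-built alignments and toy genes
# ---------------------------------------------------------------------------


def make_header(genome: pe.ReferenceGenome) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"}, "SQ": [{"SN": genome.name, "LN": len(genome)}]}
    )


def make_read(
    header: pysam.AlignmentHeader,
    name: str,
    seq: str,
    pos1: int,
    flag: int = 0,
    cigar: str | None = None,
    nm: int | None = None,
) -> pysam.AlignedSegment:
    read = pysam.AlignedSegment(header)
    read.query_name = name
    read.query_sequence = seq
    read.flag = flag
    read.reference_id = 0
    read.reference_start = pos1 - 1
    read.mapping_quality = 60
    read.cigarstring = cigar or f"{len(seq)}M"
    if nm is not None:
        read.set_tag("NM", nm)
    return read


def build_toy_gene(
    codons: dict[int, str],
    n_codons: int = 120,
    start_codon: str = "ATG",
    gene_start: int = 101,
    strand: str = "+",
    gene_id: str = "toy",
    flank: int = 200,
):
    """A single-exon CDS with prescribed codons, embedded in random flanks.

    ``codons`` maps 1-based codon index -> codon (index 1 is the start
    codon unless overridden there).  Returns (genome, feature).
    """
    rng = np.random.default_rng(12345)
    from plastedit.simulate import SENSE_CODONS, STOP_CODONS

    body = [start_codon] + [
        SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), n_codons - 2)
    ] + [STOP_CODONS[0]]
    for idx, codon in codons.items():
        body[idx - 1] = codon
    coding = "".join(body)
    if strand == "-":
        insert = pe.genome.reverse_complement(coding)
    else:
        insert = coding
    left = "".join("ACGT"[i] for i in rng.integers(0, 4, flank))
    right = "".join("ACGT"[i] for i in rng.integers(0, 4, flank))
    seq = left[: gene_start - 1] + insert + right
    genome = pe.ReferenceGenome("toy_ref", seq)
    feature = pe.FeatureRecord(
        gene_id, "CDS", [(gene_start, gene_start + len(coding) - 1)], strand
    )
    return genome, feature


def edit_site_at(
    position: int,
    edit_type: str = pe.C_TO_U,
    strand: str = "+",
    edited: int = 50,
    depth: int = 100,
) -> pe.EditSite:
    eff = edited / depth
    return pe.EditSite(
        position=position,
        transcript_strand=strand,
        orientation=strand,
        edit_type=edit_type,
        edited_count=edited,
        depth=depth,
        efficiency=eff,
        efficiency_class=pe.classify_efficiency(eff),
        homopolymer_flag=False,
    )


def cds_genomic_position(feature: pe.FeatureRecord, cds_pos: int) -> int:
    """Genomic coordinate of a 1-based spliced-CDS offset."""
    remaining = cds_pos
    if feature.strand == "+":
        for s, e in feature.intervals:
            n = e - s + 1
            if remaining <= n:
                return s + remaining - 1
            remaining -= n
    else:
        for s, e in reversed(feature.intervals):
            n = e - s + 1
            if remaining <= n:
                return e - remaining + 1
            remaining -= n
    raise ValueError("cds_pos beyond feature")


# ---------------------------------------------------------------------------
# independent oracles (nested loops; no shared code with the implementation)
# ---------------------------------------------------------------------------


def naive_pileup_counts(reads, genome: pe.ReferenceGenome) -> dict[tuple[int, str], int]:
    counts: dict[tuple[int, str], int] = {}
    for read in reads:
        seq = read.query_sequence
        for qpos, rpos in read.get_aligned_pairs(matches_only=True):
            base = seq[qpos].upper()
            if base in "ACGT":
                key = (rpos + 1, base)
                counts[key] = counts.get(key, 0) + 1
    return counts


def naive_call_edits(
    counts: dict[tuple[int, str], int],
    genome: pe.ReferenceGenome,
    features,
    min_coverage=10,
    min_count=2,
    min_frequency=0.05,
):
    """Exhaustive per-position re-derivation of the calling rules."""
    mismatch_rules = {
        ("C", "T"): (pe.C_TO_U, "+"),
        ("G", "A"): (pe.C_TO_U, "-"),
        ("T", "C"): (pe.U_TO_C, "+"),
        ("A", "G"): (pe.U_TO_C, "-"),
    }
    calls = set()
    for pos in range(1, len(genome) + 1):
        depth = sum(counts.get((pos, b), 0) for b in "ACGT")
        if depth < min_coverage:
            continue
        ref = genome.base(pos)
        strand = None
        for f in features:
            if f.contains(pos):
                strand = f.strand
        for (rb, ab), (etype, s) in mismatch_rules.items():
            if ref != rb:
                continue
            if strand is not None and s != strand:
                continue
            alt = counts.get((pos, ab), 0)
            if alt >= min_count and alt / depth >= min_frequency:
                calls.add((pos, etype, s, alt, depth))
    return calls
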