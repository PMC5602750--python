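"""Synthetic plastome, planted edits and error-bearing aligned reads.

The generator emulates the statistical structure a plastid editing analysis
assumes: a small genome with stranded single- and multi-exon genes, tRNAs and
intergenic spacers; planted C-to-U / U-to-C edits whose per-tissue efficiency
spans the partial-editing spectrum; uniform substitution sequencing error; and
coverage in the hundreds to thousands of folds, as plastid-enriched RNA-seq
libraries typically achieve.  Everything is a deterministic function of the
seed, and a truth table accompanies every read set so recovery can be scored.

Planted edits are spaced at least one read length apart.  Real plastomes
carry on the order of one edit per kilobase, so a single read essentially
never spans two edits; the miniature genome is denser, and the spacing rule
restores that property so the similarity filter does not couple neighbouring
sites.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .conversions import C_TO_U, U_TO_C, plus_strand_bases
from .errors import ConfigurationError
from .genome import (
    BASE_TO_CODE,
    CODE_TO_BASE,
    FeatureRecord,
    ReferenceGenome,
    feature_strand_array,
    reverse_complement,
)

STOP_CODONS = ("TAA", "TAG", "TGA")
SENSE_CODONS = tuple(
    "".join(c)
    for c in itertools.product("ACGT", repeat=3)
    if "".join(c) not in STOP_CODONS
)

_CLASS_CODES = {"IGS": 0, "CDS": 1, "tRNA": 2, "rRNA": 3, "intron": 4}
_CLASS_NAMES = {v: k for k, v in _CLASS_CODES.items()}


@dataclass
class SimConfig:
    """Study conditions for a synthetic run.

    Defaults describe a 20 kb miniature plastome with 100 planted edits whose
    efficiencies span 10-95%, 200-fold coverage of 100 bp reads and a 0.2%
    per-base substitution error rate.
    """

    genome_length: int = 20_000
    n_genes: int = 12
    intron_genes: int | None = None  # None: auto (up to 2)
    trna_genes: int | None = None  # None: auto (up to 2)
    read_length: int = 100
    mean_coverage: float = 200.0
    error_rate: float = 0.002
    n_edits: int = 100
    efficiency_range: tuple[float, float] = (0.10, 0.95)
    tissue_labels: tuple[str, ...] = ("leaf", "flower")
    seed: int = 0
    gc_content: float = 0.37
    u_to_c_fraction: float = 0.08
    cds_codon_range: tuple[int, int] = (100, 300)
    intron_length_range: tuple[int, int] = (80, 150)
    trna_length: int = 72
    min_spacer: int = 60
    start_codon_test_gene: bool = True
    plant_homopolymer_edit: bool = True
    plant_tissue_specific: bool = True
    plant_differential: bool = True
    differential_deltas: tuple[float, ...] | None = None
    expression_multipliers: dict[str, float] | None = None
    genome_name: str = "synthetic_plastome"

    @property
    def resolved_trna_genes(self) -> int:
        if self.trna_genes is not None:
            return self.trna_genes
        return min(2, self.n_genes // 3)

    @property
    def resolved_intron_genes(self) -> int:
        if self.intron_genes is not None:
            return self.intron_genes
        return min(2, (self.n_genes - self.resolved_trna_genes) // 3)

    def validate(self) -> None:
        if self.genome_length <= 0:
            raise ConfigurationError("genome_length must be positive")
        if self.n_genes < 0 or self.n_edits < 0:
            raise ConfigurationError("n_genes and n_edits must be non-negative")
        if not 0 <= self.error_rate < 1:
            raise ConfigurationError("error_rate must be in [0, 1)")
        lo, hi = self.efficiency_range
        if not 0 <= lo <= hi <= 1:
            raise ConfigurationError("efficiency_range must satisfy 0 <= lo <= hi <= 1")
        if self.resolved_trna_genes + 0 > self.n_genes:
            raise ConfigurationError("trna_genes exceeds n_genes")
        if self.resolved_intron_genes > self.n_genes - self.resolved_trna_genes:
            raise ConfigurationError("intron_genes exceeds the number of CDS genes")
        if self.read_length <= 0 or self.mean_coverage <= 0:
            raise ConfigurationError("read_length and mean_coverage must be positive")
        if not 0 < self.gc_content < 1:
            raise ConfigurationError("gc_content must be in (0, 1)")
        if self.cds_codon_range[0] < 15:
            raise ConfigurationError("cds_codon_range minimum must be >= 15")


@dataclass
class TruthRecord:
    """A planted edit with its per-tissue true efficiency."""

    position: int  # 1-based plus-strand coordinate
    strand: str  # transcript strand the conversion is defined on
    edit_type: str  # C-to-U | U-to-C
    true_efficiency: dict[str, float]
    feature_class: str  # CDS | tRNA | intron | IGS
    feature_id: str


def _random_background(rng: np.random.Generator, n: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    codes = rng.choice(4, size=n, p=p)
    return CODE_TO_BASE[codes].tobytes().decode()


def _random_coding(rng: np.random.Generator, n_internal: int, start: str) -> str:
    idx = rng.integers(0, len(SENSE_CODONS), size=n_internal)
    stop = STOP_CODONS[rng.integers(0, 3)]
    return start + "".join(SENSE_CODONS[i] for i in idx) + stop


def generate_genome(config: SimConfig) -> tuple[ReferenceGenome, list[FeatureRecord]]:
    """Build a miniature plastome with non-overlapping stranded genes.

    Every CDS has a length divisible by three, starts with ATG (ACG for the
    designated start-creation test gene) and ends with a stop codon.  One
    plus-strand CDS carries an embedded CCCCCCC homopolymer run so the
    caller's masking rule is always exercised.
    """
    config.validate()
    rng = np.random.default_rng([7919, config.seed])

    n_trna = config.resolved_trna_genes
    n_intron = config.resolved_intron_genes
    n_cds = config.n_genes - n_trna

    # gene descriptors in construction order
    specs: list[dict] = []
    strands = list((rng.integers(0, 2, size=config.n_genes) * 2 - 1))
    strand_of = lambda i: "+" if strands[i] > 0 else "-"
    # guarantee both strands among CDS genes where possible
    cds_idx = list(range(n_cds))
    if n_cds >= 1:
        strands[0] = 1  # homopolymer host / first CDS on plus strand
    if n_cds >= 2 and all(strands[i] > 0 for i in cds_idx):
        strands[n_cds - 1] = -1

    lo_c, hi_c = config.cds_codon_range
    # gene 0 hosts the homopolymer run; the next gene (if requested) carries a
    # non-ATG initiation codon; introns go to the remaining single-exon genes
    acg_gene = min(1, n_cds - 1) if (config.start_codon_test_gene and n_cds > 0) else -1
    special = {0, acg_gene} if n_cds > 0 else set()
    intron_hosts = [i for i in range(n_cds) if i not in special][:n_intron]
    if len(intron_hosts) < n_intron:
        raise ConfigurationError(
            "not enough plain CDS genes to host the requested introns"
        )
    for i in range(n_cds):
        start = "ACG" if i == acg_gene else "ATG"
        n_internal = int(rng.integers(lo_c, hi_c + 1))
        coding = _random_coding(rng, n_internal, start)
        if i == 0:
            # embed a CCCCCCC run across codons 11-13 (all sense, Pro-rich)
            coding = coding[:30] + "CCCCCCC" + coding[37:]
        has_intron = i in intron_hosts
        intron_seq = ""
        exon1_len = len(coding)
        if has_intron:
            b = int(rng.integers(*config.intron_length_range))
            intron_seq = _random_background(rng, b, config.gc_content)
            exon1_len = int(rng.integers(30, len(coding) - 30))
        specs.append(
            dict(
                gene_id=f"g{i + 1:02d}",
                kind="CDS",
                coding=coding,
                intron=intron_seq,
                exon1_len=exon1_len,
                strand=strand_of(i),
            )
        )
    for j in range(n_trna):
        specs.append(
            dict(
                gene_id=f"trn{j + 1:02d}",
                kind="tRNA",
                coding=_random_background(rng, config.trna_length, config.gc_content),
                intron="",
                exon1_len=config.trna_length,
                strand=strand_of(n_cds + j),
            )
        )

    # placement order and spacers
    order = list(rng.permutation(len(specs))) if specs else []
    payloads = []
    for k in order:
        sp = specs[k]
        seq = sp["coding"][: sp["exon1_len"]] + sp["intron"] + sp["coding"][sp["exon1_len"]:]
        if sp["strand"] == "-":
            seq = reverse_complement(seq)
        payloads.append(seq)
    total_payload = sum(len(p) for p in payloads)
    n_gaps = len(specs) + 1
    min_total = total_payload + config.min_spacer * n_gaps
    if config.genome_length < min_total:
        raise ConfigurationError(
            f"genome_length {config.genome_length} too small for "
            f"{config.n_genes} genes (need >= {min_total})"
        )
    extra = config.genome_length - min_total
    alloc = rng.multinomial(extra, [1.0 / n_gaps] * n_gaps)

    parts: list[str] = []
    features: list[FeatureRecord] = []
    pos = 1
    for gap_i, k in enumerate(order):
        spacer = _random_background(rng, config.min_spacer + int(alloc[gap_i]), config.gc_content)
        parts.append(spacer)
        pos += len(spacer)
        sp = specs[k]
        payload = payloads[gap_i]
        length = len(payload)
        s = pos
        if sp["kind"] == "tRNA":
            features.append(
                FeatureRecord(sp["gene_id"], "tRNA", [(s, s + length - 1)], sp["strand"])
            )
        else:
            a = sp["exon1_len"]
            b = len(sp["intron"])
            c = len(sp["coding"]) - a
            if b == 0:
                exons = [(s, s + length - 1)]
            elif sp["strand"] == "+":
                exons = [(s, s + a - 1), (s + a + b, s + length - 1)]
                features.append(
                    FeatureRecord(
                        f"{sp['gene_id']}.intron1", "intron",
                        [(s + a, s + a + b - 1)], sp["strand"],
                    )
                )
            else:
                exons = [(s, s + c - 1), (s + c + b, s + length - 1)]
                features.append(
                    FeatureRecord(
                        f"{sp['gene_id']}.intron1", "intron",
                        [(s + c, s + c + b - 1)], sp["strand"],
                    )
                )
            features.append(FeatureRecord(sp["gene_id"], "CDS", exons, sp["strand"]))
        parts.append(payload)
        pos += length
    tail = _random_background(
        rng, config.min_spacer + int(alloc[-1]) if specs else config.genome_length,
        config.gc_content,
    )
    parts.append(tail)
    sequence = "".join(parts)
    assert len(sequence) == config.genome_length
    genome = ReferenceGenome(config.genome_name, sequence)
    features.sort(key=lambda f: (f.start, f.feature_id))
    return genome, features


# ---------------------------------------------------------------------------
# edit planting
# ---------------------------------------------------------------------------

def _position_annotation(features: list[FeatureRecord], length: int):
    class_arr = np.zeros(length, dtype=np.int8)
    fid_arr = np.full(length, -1, dtype=np.int32)
    for i, feat in enumerate(features):
        code = _CLASS_CODES[feat.feature_class]
        for s, e in feat.intervals:
            class_arr[s - 1 : e] = code
            fid_arr[s - 1 : e] = i
    return class_arr, fid_arr


def _eligible_mask(
    codes: np.ndarray, strand_arr: np.ndarray, edit_type: str
) -> np.ndarray:
    """Positions where an edit of ``edit_type`` is consistent with the
    reference base and (if inside a feature) the transcript strand."""
    c = {b: BASE_TO_CODE[b] for b in "ACGT"}
    if edit_type == C_TO_U:
        plus_ok = codes == c["C"]
        minus_ok = codes == c["G"]
    else:
        plus_ok = codes == c["T"]
        minus_ok = codes == c["A"]
    return (
        ((strand_arr == 1) & plus_ok)
        | ((strand_arr == 2) & minus_ok)
        | ((strand_arr == 0) & (plus_ok | minus_ok))
    )


def plant_edits(
    genome: ReferenceGenome,
    features: list[FeatureRecord],
    config: SimConfig,
) -> list[TruthRecord]:
    """Choose ``n_edits`` edit positions and draw per-tissue efficiencies.

    Positions are strand-consistent, unique, at least one read length apart,
    kept away from homopolymer runs (except one deliberately planted inside a
    run when ``plant_homopolymer_edit`` is set) and span every feature class
    present in the annotation plus both strands.
    """
    config.validate()
    n = config.n_edits
    if n == 0:
        return []
    rng = np.random.default_rng([104729, config.seed])
    L = len(genome)
    codes = genome.codes
    strand_arr = feature_strand_array(features, L)
    class_arr, fid_arr = _position_annotation(features, L)
    hp_mask = genome.homopolymer_mask(6, pad=1)
    rl = config.read_length

    interior_lo = rl + 1
    interior_hi = L - rl
    interior_len = interior_hi - interior_lo + 1
    if interior_len <= 0:
        raise ConfigurationError("genome shorter than two read lengths")
    w = interior_len // n
    m = (rl + 1) // 2
    if w < 2 * m + 2:
        raise ConfigurationError(
            f"cannot place {n} edits >= {rl} bp apart in a {L} bp genome"
        )

    elig = {t: _eligible_mask(codes, strand_arr, t) for t in (C_TO_U, U_TO_C)}
    usable = {t: elig[t] & ~hp_mask for t in (C_TO_U, U_TO_C)}

    picks: list[int | None] = [None] * n  # 0-based positions, one per bin
    types: list[str] = [C_TO_U] * n
    want_uc = rng.random(n) < config.u_to_c_fraction
    for i in range(n):
        b_lo = (interior_lo - 1) + i * w + m  # 0-based window bounds
        b_hi = (interior_lo - 1) + (i + 1) * w - m
        for etype in ([U_TO_C, C_TO_U] if want_uc[i] else [C_TO_U, U_TO_C]):
            cand = np.nonzero(usable[etype][b_lo:b_hi])[0]
            if cand.size:
                picks[i] = b_lo + int(rng.choice(cand))
                types[i] = etype
                break
        if picks[i] is None:
            raise ConfigurationError(
                "not enough eligible positions outside homopolymer runs"
            )

    def spacing_ok(pos0: int, skip_bin: int) -> bool:
        for j, p in enumerate(picks):
            if j != skip_bin and p is not None and abs(p - pos0) < rl:
                return False
        return True

    def bin_of(pos0: int) -> int:
        b = (pos0 - (interior_lo - 1)) // w
        return min(max(b, 0), n - 1)

    # make sure every annotated class (and both CDS strands) received an edit
    present = {
        ("CDS", "+"): any(f.feature_class == "CDS" and f.strand == "+" for f in features),
        ("CDS", "-"): any(f.feature_class == "CDS" and f.strand == "-" for f in features),
        ("tRNA", None): any(f.feature_class == "tRNA" for f in features),
        ("intron", None): any(f.feature_class == "intron" for f in features),
        ("IGS", None): True,
    }

    def covers(pos0: int, req: tuple) -> bool:
        cls, strand = req
        if _CLASS_NAMES[int(class_arr[pos0])] != cls:
            return False
        if strand is not None:
            return strand_arr[pos0] == (1 if strand == "+" else 2)
        return True

    requirements = [r for r, p in present.items() if p]
    if n >= len(requirements):
        for req in requirements:
            if any(p is not None and covers(p, req) for p in picks):
                continue
            cls, strand = req
            mask = class_arr == _CLASS_CODES[cls]
            if strand is not None:
                mask = mask & (strand_arr == (1 if strand == "+" else 2))
            cand = np.nonzero(
                mask & (usable[C_TO_U] | usable[U_TO_C])
            )[0]
            cand = cand[(cand >= interior_lo - 1) & (cand <= interior_hi - 1)]
            cand = cand[rng.permutation(cand.size)]
            placed = False
            for pos0 in cand:
                b = bin_of(int(pos0))
                if spacing_ok(int(pos0), b):
                    picks[b] = int(pos0)
                    types[b] = C_TO_U if usable[C_TO_U][pos0] else U_TO_C
                    placed = True
                    break
            if not placed:
                raise ConfigurationError(f"no eligible position for class {cls}")

    hp_bin = None
    if config.plant_homopolymer_edit:
        placed = False
        for start, end, base in genome.homopolymer_runs:
            for pos in range(start, end + 1):
                pos0 = pos - 1
                if not interior_lo - 1 <= pos0 <= interior_hi - 1:
                    continue
                if not elig[C_TO_U][pos0] and not elig[U_TO_C][pos0]:
                    continue
                b = bin_of(pos0)
                if spacing_ok(pos0, b):
                    picks[b] = pos0
                    types[b] = C_TO_U if elig[C_TO_U][pos0] else U_TO_C
                    hp_bin = b
                    placed = True
                    break
            if placed:
                break
        if not placed:
            raise ConfigurationError("no homopolymer run can host a planted edit")

    # efficiencies
    lo, hi = config.efficiency_range
    tissues = list(config.tissue_labels)
    eff_rows: list[dict[str, float]] = []
    if config.differential_deltas is not None and len(tissues) >= 2:
        deltas = np.array(
            [config.differential_deltas[i % len(config.differential_deltas)] for i in range(n)]
        )
        rng.shuffle(deltas)
        for i in range(n):
            d = float(deltas[i])
            base_e = float(rng.uniform(lo, max(lo, hi - d)))
            pair = (base_e + d, base_e) if rng.random() < 0.5 else (base_e, base_e + d)
            row = {tissues[0]: min(pair[0], 1.0), tissues[1]: min(pair[1], 1.0)}
            for t in tissues[2:]:
                row[t] = float(rng.uniform(lo, hi))
            eff_rows.append(row)
    else:
        for _i in range(n):
            eff_rows.append({t: float(rng.uniform(lo, hi)) for t in tissues})
        if len(tissues) >= 2 and config.differential_deltas is None:
            candidates = [i for i in range(n) if i != hp_bin]
            if config.plant_tissue_specific and candidates:
                i = candidates[int(rng.integers(len(candidates)))]
                eff_rows[i][tissues[1]] = 0.0
                candidates.remove(i)
            if config.plant_differential and candidates and hi - lo > 0.20:
                i = candidates[int(rng.integers(len(candidates)))]
                eff_rows[i][tissues[0]] = hi
                eff_rows[i][tissues[1]] = lo

    records = []
    for i in range(n):
        pos0 = picks[i]
        assert pos0 is not None
        etype = types[i]
        if strand_arr[pos0] == 1:
            strand = "+"
        elif strand_arr[pos0] == 2:
            strand = "-"
        else:
            ref = chr(CODE_TO_BASE[codes[pos0]])
            strand = "+" if ref in ("C", "T") else "-"
        fid = int(fid_arr[pos0])
        records.append(
            TruthRecord(
                position=pos0 + 1,
                strand=strand,
                edit_type=etype,
                true_efficiency=eff_rows[i],
                feature_class=_CLASS_NAMES[int(class_arr[pos0])],
                feature_id=features[fid].feature_id if fid >= 0 else "IGS",
            )
        )
    records.sort(key=lambda r: r.position)
    # sanity: reference base consistent with edit type and strand
    for rec in records:
        ref_expect, _alt = plus_strand_bases(rec.edit_type, rec.strand)
        assert genome.base(rec.position) == ref_expect
    return records


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def simulate_reads(
    genome: ReferenceGenome,
    truth: list[TruthRecord],
    config: SimConfig,
    tissue: str,
    path: str | Path,
    features: list[FeatureRecord] | None = None,
) -> Path:
    """Write an ungapped, correctly placed SAM read set for one tissue.

    Each read overlapping a planted position carries the edited base with
    probability equal to that tissue's true efficiency, independently per
    read; every base is then substituted by a uniformly chosen other base
    with probability ``error_rate``.  Alignments are correct by construction
    (full-length match CIGAR) and carry an NM tag.
    """
    config.validate()
    if tissue not in config.tissue_labels:
        raise ConfigurationError(f"unknown tissue {tissue!r}")
    ti = config.tissue_labels.index(tissue)
    rng = np.random.default_rng([15485863, config.seed, ti])
    L = len(genome)
    rl = config.read_length
    if rl > L:
        raise ConfigurationError("read_length exceeds genome length")
    n_reads = int(round(config.mean_coverage * L / rl))
    n_starts = L - rl + 1

    starts = _draw_starts(rng, genome, config, features, n_reads, n_starts)
    starts.sort(kind="stable")

    mat = genome.codes[starts[:, None] + np.arange(rl)[None, :]]
    pristine = mat.copy()

    for rec in truth:
        e = rec.true_efficiency.get(tissue, 0.0)
        p0 = rec.position - 1
        i0 = int(np.searchsorted(starts, p0 - rl + 1, side="left"))
        i1 = int(np.searchsorted(starts, p0, side="right"))
        if i1 <= i0:
            continue
        idx = np.arange(i0, i1)
        if e > 0:
            hit = rng.random(idx.size) < e
            sel = idx[hit]
            _ref, alt = plus_strand_bases(rec.edit_type, rec.strand)
            mat[sel, p0 - starts[sel]] = BASE_TO_CODE[alt]
        else:
            rng.random(idx.size)  # keep the stream aligned across tissues

    if config.error_rate > 0:
        chunk = 65536
        for c0 in range(0, n_reads, chunk):
            block = mat[c0 : c0 + chunk]
            err = rng.random(block.shape) < config.error_rate
            n_err = int(err.sum())
            if n_err:
                shift = rng.integers(1, 4, size=n_err).astype(np.uint8)
                block[err] = (block[err] + shift) % 4

    nm = (mat != pristine).sum(axis=1)
    rev = rng.random(n_reads) < 0.5

    lines = [
        "@HD\tVN:1.6\tSO:coordinate",
        f"@SQ\tSN:{genome.name}\tLN:{L}",
        f"@PG\tID:plastedit\tPN:plastedit\tVN:{__version__}",
    ]
    qual = "I" * rl
    ascii_mat = CODE_TO_BASE[mat]
    raw = ascii_mat.tobytes()
    cigar = f"{rl}M"
    name_prefix = f"{tissue}."
    for i in range(n_reads):
        seq = raw[i * rl : (i + 1) * rl].decode()
        flag = 16 if rev[i] else 0
        lines.append(
            f"{name_prefix}{i:07d}\t{flag}\t{genome.name}\t{starts[i] + 1}\t60\t"
            f"{cigar}\t*\t0\t0\t{seq}\t{qual}\tNM:i:{int(nm[i])}"
        )
    out = Path(path)
    out.write_text("\n".join(lines) + "\n")
    return out


def _draw_starts(
    rng: np.random.Generator,
    genome: ReferenceGenome,
    config: SimConfig,
    features: list[FeatureRecord] | None,
    n_reads: int,
    n_starts: int,
) -> np.ndarray:
    """Uniform start positions, optionally reweighted per gene.

    With ``expression_multipliers`` set, a start position is weighted by the
    multiplier of the feature whose exons contain the read midpoint, so a
    gene with multiplier 2 receives about twice the reads of its neighbours.
    """
    if not config.expression_multipliers:
        return rng.integers(0, n_starts, size=n_reads)
    if features is None:
        raise ConfigurationError(
            "expression_multipliers requires the feature list to be passed "
            "to simulate_reads"
        )
    weight_by_pos = np.ones(len(genome))
    by_id = {f.feature_id: f for f in features}
    for fid, factor in config.expression_multipliers.items():
        if fid not in by_id:
            raise ConfigurationError(f"unknown feature in expression_multipliers: {fid}")
        if factor < 0:
            raise ConfigurationError("expression multipliers must be non-negative")
        for s, e in by_id[fid].intervals:
            weight_by_pos[s - 1 : e] = factor
    mid = config.read_length // 2
    w = weight_by_pos[np.arange(n_starts) + mid]
    return rng.choice(n_starts, size=n_reads, p=w / w.sum())


# ---------------------------------------------------------------------------
# truth-table round trip and one-call dataset helper
# ---------------------------------------------------------------------------

def write_truth_table(
    truth: list[TruthRecord], tissues: list[str] | tuple[str, ...], path: str | Path
) -> None:
    rows = []
    for rec in truth:
        row = {
            "position": rec.position,
            "strand": rec.strand,
            "edit_type": rec.edit_type,
            "feature_class": rec.feature_class,
            "feature_id": rec.feature_id,
        }
        for t in tissues:
            row[t] = rec.true_efficiency.get(t, 0.0)
        rows.append(row)
    pd.DataFrame(
        rows,
        columns=["position", "strand", "edit_type", "feature_class", "feature_id", *tissues],
    ).to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_truth_table(path: str | Path) -> list[TruthRecord]:
    df = pd.read_csv(path, sep="\t")
    fixed = {"position", "strand", "edit_type", "feature_class", "feature_id"}
    tissues = [c for c in df.columns if c not in fixed]
    return [
        TruthRecord(
            position=int(row["position"]),
            strand=row["strand"],
            edit_type=row["edit_type"],
            true_efficiency={t: float(row[t]) for t in tissues},
            feature_class=row["feature_class"],
            feature_id=row["feature_id"],
        )
        for _, row in df.iterrows()
    ]


@dataclass
class SimOutput:
    """File manifest of one synthetic dataset."""

    genome_fasta: Path
    gff3: Path
    truth_tsv: Path
    sam_per_tissue: dict[str, Path]
    genome: ReferenceGenome = field(repr=False)
    features: list[FeatureRecord] = field(repr=False)
    truth: list[TruthRecord] = field(repr=False)


def simulate_dataset(config: SimConfig, outdir: str | Path) -> SimOutput:
    """Generate genome, annotation, truth table and one SAM per tissue."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, features = generate_genome(config)
    truth = plant_edits(genome, features, config)
    fasta = outdir / "genome.fasta"
    gff3 = outdir / "annotation.gff3"
    truth_tsv = outdir / "truth.tsv"
    genome.to_fasta(fasta)
    from .genome import write_gff3

    write_gff3(features, genome, gff3)
    write_truth_table(truth, list(config.tissue_labels), truth_tsv)
    sams = {}
    for tissue in config.tissue_labels:
        sam = outdir / f"{tissue}.sam"
        simulate_reads(genome, truth, config, tissue, sam, features=features)
        sams[tissue] = sam
    return SimOutput(fasta, gff3, truth_tsv, sams, genome, features, truth)
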