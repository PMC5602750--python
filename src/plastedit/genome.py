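"""Reference genome and feature containers, plus FASTA/GFF3 round-trips.

The plastome is held as a plain plus-strand nucleotide string with 1-based,
closed coordinates throughout (matching GFF3 conventions).  Homopolymer runs
are tracked on the reference because sequencing slippage inside long runs
mimics low-frequency editing and must be masked by the caller.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import cached_property
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AnnotationError, DataError

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: uint8 code per base used by the vectorised pileup/simulator paths
BASE_TO_CODE = {b: i for i, b in enumerate(BASES)}
CODE_TO_BASE = np.frombuffer(BASES.encode(), dtype=np.uint8)

_ASCII_TO_CODE = np.full(256, 255, dtype=np.uint8)
for _b, _c in BASE_TO_CODE.items():
    _ASCII_TO_CODE[ord(_b)] = _c
    _ASCII_TO_CODE[ord(_b.lower())] = _c


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes (A=0, C=1, G=2, T=3)."""
    return _ASCII_TO_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def decode_sequence(codes: np.ndarray) -> str:
    return CODE_TO_BASE[codes].tobytes().decode()


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def find_homopolymer_runs(sequence: str, min_run: int = 6) -> list[tuple[int, int, str]]:
    """Maximal runs of identical bases with length >= ``min_run``.

    Returns 1-based closed ``(start, end, base)`` tuples.
    """
    runs = []
    pos = 1
    for base, group in itertools.groupby(sequence):
        n = sum(1 for _ in group)
        if n >= min_run:
            runs.append((pos, pos + n - 1, base))
        pos += n
    return runs


@dataclass
class ReferenceGenome:
    """A named (conceptually circular) plastome sequence.

    Reads are treated as linearly placed, so all coordinate arithmetic here is
    linear; circularity only matters for read placement, which the simulator
    avoids by not spanning the origin.
    """

    name: str
    sequence: str

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()

    def __len__(self) -> int:
        return len(self.sequence)

    @cached_property
    def codes(self) -> np.ndarray:
        return encode_sequence(self.sequence)

    @cached_property
    def homopolymer_runs(self) -> list[tuple[int, int, str]]:
        """Maximal runs of >= 6 identical bases (the masking default)."""
        return find_homopolymer_runs(self.sequence, 6)

    def homopolymer_mask(self, min_run: int = 6, pad: int = 1) -> np.ndarray:
        """Boolean mask (index 0 = position 1) of positions inside, or within
        ``pad`` of, a homopolymer run of length >= ``min_run``."""
        mask = np.zeros(len(self.sequence), dtype=bool)
        for start, end, _base in find_homopolymer_runs(self.sequence, min_run):
            lo = max(1, start - pad)
            hi = min(len(self.sequence), end + pad)
            mask[lo - 1 : hi] = True
        return mask

    def base(self, position: int) -> str:
        """Plus-strand base at a 1-based position."""
        if not 1 <= position <= len(self.sequence):
            raise DataError(f"position {position} outside genome {self.name!r}")
        return self.sequence[position - 1]

    def slice(self, start: int, end: int) -> str:
        """Plus-strand subsequence over the 1-based closed interval."""
        if start < 1 or end > len(self.sequence) or start > end:
            raise DataError(f"interval [{start}, {end}] outside genome {self.name!r}")
        return self.sequence[start - 1 : end]

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def from_fasta(cls, path: str | Path) -> "ReferenceGenome":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise DataError(f"no sequences in {path}")
        rec = records[0]
        return cls(name=rec.id, sequence=str(rec.seq))

    def to_fasta(self, path: str | Path) -> None:
        rec = SeqRecord(Seq(self.sequence), id=self.name, description="")
        with open(path, "w") as fh:
            SeqIO.write([rec], fh, "fasta")


@dataclass
class FeatureRecord:
    """A stranded genomic feature, possibly multi-exon (1-based, closed).

    ``intervals`` are stored in ascending genomic order regardless of strand;
    transcript order for minus-strand features is handled by the coordinate
    helpers below.  ``phase`` is the GFF3 phase of the transcript-first exon
    (0 for complete CDS models).
    """

    feature_id: str
    feature_class: str  # CDS | tRNA | rRNA | intron
    intervals: list[tuple[int, int]]
    strand: str
    phase: int = 0

    def __post_init__(self) -> None:
        self.intervals = sorted((int(s), int(e)) for s, e in self.intervals)
        if self.strand not in "+-":
            raise AnnotationError(f"{self.feature_id}: strand must be + or -")
        for (s, e), (s2, _e2) in zip(self.intervals, self.intervals[1:]):
            if s2 <= e:
                raise AnnotationError(f"{self.feature_id}: overlapping intervals")
        for s, e in self.intervals:
            if s > e:
                raise AnnotationError(f"{self.feature_id}: empty interval ({s}, {e})")

    @property
    def start(self) -> int:
        return self.intervals[0][0]

    @property
    def end(self) -> int:
        return self.intervals[-1][1]

    @property
    def length(self) -> int:
        return sum(e - s + 1 for s, e in self.intervals)

    def contains(self, position: int) -> bool:
        return any(s <= position <= e for s, e in self.intervals)

    def transcript_offset(self, position: int) -> int:
        """1-based offset of a genomic position within the spliced feature,
        counted in transcript (5'->3') orientation."""
        if not self.contains(position):
            raise AnnotationError(
                f"position {position} not inside feature {self.feature_id}"
            )
        if self.strand == "+":
            offset = 0
            for s, e in self.intervals:
                if position > e:
                    offset += e - s + 1
                else:
                    return offset + position - s + 1
        else:
            offset = 0
            for s, e in reversed(self.intervals):
                if position < s:
                    offset += e - s + 1
                else:
                    return offset + e - position + 1
        raise AssertionError("unreachable")

    def spliced_sequence(self, genome: ReferenceGenome) -> str:
        """Spliced feature sequence in transcript orientation (DNA alphabet)."""
        parts = [genome.slice(s, e) for s, e in self.intervals]
        seq = "".join(parts)
        return reverse_complement(seq) if self.strand == "-" else seq


def feature_strand_array(features: list[FeatureRecord], genome_length: int) -> np.ndarray:
    """Per-position transcript strand: 0 = intergenic, 1 = plus, 2 = minus.

    Raises on positions claimed by features of opposite strand, because the
    transcript orientation of an edit there would be ambiguous.
    """
    arr = np.zeros(genome_length, dtype=np.int8)
    for feat in features:
        code = 1 if feat.strand == "+" else 2
        for s, e in feat.intervals:
            if e > genome_length:
                raise AnnotationError(f"{feat.feature_id} extends past genome end")
            seg = arr[s - 1 : e]
            if np.any((seg != 0) & (seg != code)):
                raise AnnotationError(
                    f"{feat.feature_id}: conflicting strand with an overlapping feature"
                )
            seg[:] = code
    return arr


# ---------------------------------------------------------------------------
# GFF3 round-trip.  CDS models are written as a `gene` parent with one `CDS`
# line per exon; tRNA/rRNA/intron features are single top-level lines.
# ---------------------------------------------------------------------------

def write_gff3(features: list[FeatureRecord], genome: ReferenceGenome, path: str | Path) -> None:
    lines = ["##gff-version 3", f"##sequence-region {genome.name} 1 {len(genome)}"]
    for feat in sorted(features, key=lambda f: (f.start, f.feature_id)):
        if feat.feature_class == "CDS":
            lines.append(
                "\t".join(
                    [
                        genome.name, "plastedit", "gene", str(feat.start), str(feat.end),
                        ".", feat.strand, ".", f"ID={feat.feature_id}",
                    ]
                )
            )
            exons = feat.intervals if feat.strand == "+" else list(reversed(feat.intervals))
            phase = feat.phase
            ordered = []
            for s, e in exons:
                ordered.append(((s, e), phase))
                phase = (3 - ((e - s + 1 - phase) % 3)) % 3
            for i, ((s, e), ph) in enumerate(sorted(ordered, key=lambda t: t[0][0]), 1):
                lines.append(
                    "\t".join(
                        [
                            genome.name, "plastedit", "CDS", str(s), str(e), ".",
                            feat.strand, str(ph),
                            f"ID={feat.feature_id}.cds{i};Parent={feat.feature_id}",
                        ]
                    )
                )
        else:
            s, e = feat.start, feat.end
            lines.append(
                "\t".join(
                    [
                        genome.name, "plastedit", feat.feature_class, str(s), str(e),
                        ".", feat.strand, ".", f"ID={feat.feature_id}",
                    ]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path: str | Path) -> list[FeatureRecord]:
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    features: list[FeatureRecord] = []
    for gene in db.features_of_type("gene"):
        exons = sorted(
            (c.start, c.end) for c in db.children(gene, featuretype="CDS")
        )
        if not exons:
            exons = [(gene.start, gene.end)]
        first = min(
            db.children(gene, featuretype="CDS"),
            key=lambda c: c.start if gene.strand == "+" else -c.end,
            default=None,
        )
        phase = 0
        if first is not None and first.frame not in (None, "."):
            phase = int(first.frame)
        features.append(
            FeatureRecord(
                feature_id=gene.id,
                feature_class="CDS",
                intervals=exons,
                strand=gene.strand,
                phase=phase,
            )
        )
    for ftype in ("tRNA", "rRNA", "intron"):
        for feat in db.features_of_type(ftype):
            features.append(
                FeatureRecord(
                    feature_id=feat.id,
                    feature_class=ftype,
                    intervals=[(feat.start, feat.end)],
                    strand=feat.strand,
                )
            )
    features.sort(key=lambda f: (f.start, f.feature_id))
    return features
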