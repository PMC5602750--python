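"""Alignment filtering and strand-aware per-position base counting.

Reads arrive as SAM records (pysam).  Two quality fractions gate every read:
the aligned fraction of the read and the identity of the aligned part.  The
surviving reads are reduced to a dense (genome length x 4) matrix of
plus-strand base counts; SAM already stores minus-strand reads in plus-strand
space, so no re-complementing is needed at this stage.  Transcript-strand
orientation is applied later by the caller, because intergenic positions have
no annotated strand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
import pysam

from .errors import DataError
from .genome import ReferenceGenome, encode_sequence

logger = logging.getLogger(__name__)

# CIGAR operations that consume both query and reference
_ALIGNED_OPS = {0, 7, 8}  # M, =, X
_QUERY_OPS = {0, 1, 4, 7, 8}  # consume query
_REF_OPS = {0, 2, 3, 7, 8}  # consume reference


@dataclass
class AlignmentFilterParams:
    """Thresholds on the aligned-length fraction and alignment identity."""

    min_length_fraction: float = 0.98
    min_similarity: float = 0.98

    def __post_init__(self) -> None:
        for name in ("min_length_fraction", "min_similarity"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")


@dataclass
class PileupColumn:
    """Per-position depth and plus-strand base counts."""

    position: int  # 1-based
    ref_base: str
    count_a: int
    count_c: int
    count_g: int
    count_t: int

    @property
    def depth(self) -> int:
        return self.count_a + self.count_c + self.count_g + self.count_t

    def count(self, base: str) -> int:
        return getattr(self, f"count_{base.lower()}")


def alignment_stats(
    read: pysam.AlignedSegment, genome: ReferenceGenome | None = None
) -> tuple[int, int, int]:
    """(read length, aligned length, matching bases) for one alignment.

    Matches come from the NM tag when present (indel lengths are subtracted
    so NM reduces to the mismatch count); otherwise the read is compared
    base-by-base against the reference.
    """
    if read.query_sequence is None or read.cigartuples is None:
        raise DataError("read lacks sequence or CIGAR")
    read_len = read.query_length
    aligned_len = sum(n for op, n in read.cigartuples if op in _ALIGNED_OPS)
    indel_len = sum(n for op, n in read.cigartuples if op in (1, 2))
    if read.has_tag("NM"):
        mismatches = int(read.get_tag("NM")) - indel_len
        return read_len, aligned_len, aligned_len - max(0, mismatches)
    if genome is None:
        raise DataError("no NM tag and no reference genome to compare against")
    matches = 0
    seq = read.query_sequence
    ref = genome.sequence
    for qpos, rpos in read.get_aligned_pairs(matches_only=True):
        if seq[qpos].upper() == ref[rpos]:
            matches += 1
    return read_len, aligned_len, matches


def filter_alignments(
    reads: Iterable[pysam.AlignedSegment],
    params: AlignmentFilterParams | None = None,
    genome: ReferenceGenome | None = None,
) -> list[pysam.AlignedSegment]:
    """Keep reads whose aligned fraction and identity meet the thresholds.

    Unmapped or malformed records are skipped (count logged); input order is
    preserved.
    """
    params = params or AlignmentFilterParams()
    kept: list[pysam.AlignedSegment] = []
    skipped = 0
    for read in reads:
        if read.is_unmapped:
            skipped += 1
            continue
        try:
            read_len, aligned_len, matches = alignment_stats(read, genome)
        except DataError:
            skipped += 1
            continue
        if read_len == 0 or aligned_len == 0:
            skipped += 1
            continue
        if (
            aligned_len / read_len >= params.min_length_fraction
            and matches / aligned_len >= params.min_similarity
        ):
            kept.append(read)
    if skipped:
        logger.info("filter_alignments: skipped %d unmapped/malformed records", skipped)
    return kept


class Pileup:
    """Dense per-position base counts against one reference sequence."""

    def __init__(self, genome: ReferenceGenome, counts: np.ndarray):
        if counts.shape != (len(genome), 4):
            raise ValueError("counts must be (genome length, 4)")
        self.genome = genome
        self.counts = counts

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def column(self, position: int) -> PileupColumn:
        if not 1 <= position <= len(self.genome):
            raise DataError(f"position {position} outside genome")
        a, c, g, t = (int(x) for x in self.counts[position - 1])
        return PileupColumn(position, self.genome.base(position), a, c, g, t)

    def columns(self, covered_only: bool = True) -> Iterator[PileupColumn]:
        idx = np.nonzero(self.depth > 0)[0] if covered_only else range(len(self.genome))
        for i in idx:
            yield self.column(int(i) + 1)

    def base_count(self, position: int, base: str) -> int:
        return int(self.counts[position - 1, "ACGT".index(base)])

    def to_dataframe(self, covered_only: bool = True) -> pd.DataFrame:
        depth = self.depth
        idx = np.nonzero(depth > 0)[0] if covered_only else np.arange(len(self.genome))
        return pd.DataFrame(
            {
                "position": idx + 1,
                "ref_base": [self.genome.sequence[i] for i in idx],
                "depth": depth[idx],
                "count_A": self.counts[idx, 0],
                "count_C": self.counts[idx, 1],
                "count_G": self.counts[idx, 2],
                "count_T": self.counts[idx, 3],
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def build_pileup(
    reads: Iterable[pysam.AlignedSegment], genome: ReferenceGenome
) -> Pileup:
    """Count read bases per reference position (plus-strand space).

    Reads with indels contribute only their aligned (match/mismatch)
    positions.  The result is independent of read input order.
    """
    L = len(genome)
    flat = np.zeros(L * 4, dtype=np.int64)
    pos_chunks: list[np.ndarray] = []
    chunk_size = 0
    offsets_cache: dict[int, np.ndarray] = {}

    def flush() -> None:
        nonlocal pos_chunks, chunk_size
        if pos_chunks:
            idx = np.concatenate(pos_chunks)
            flat[:] += np.bincount(idx, minlength=L * 4)
            pos_chunks = []
            chunk_size = 0

    for read in reads:
        if read.is_unmapped or read.query_sequence is None:
            continue
        start = read.reference_start  # 0-based
        if start < 0 or (read.reference_end or 0) > L:
            raise DataError(
                f"alignment {read.query_name} at {start + 1} outside genome "
                f"{genome.name!r} (length {L})"
            )
        codes = encode_sequence(read.query_sequence)
        cig = read.cigartuples or []
        if all(op in _ALIGNED_OPS for op, _n in cig):
            n = codes.size
            if n not in offsets_cache:
                offsets_cache[n] = np.arange(n)
            rpos = start + offsets_cache[n]
            qcodes = codes
        else:
            pairs = read.get_aligned_pairs(matches_only=True)
            if not pairs:
                continue
            qpos = np.fromiter((q for q, _r in pairs), dtype=np.int64, count=len(pairs))
            rpos = np.fromiter((r for _q, r in pairs), dtype=np.int64, count=len(pairs))
            qcodes = codes[qpos]
        valid = qcodes < 4  # drop N and other ambiguity codes
        pos_chunks.append(rpos[valid] * 4 + qcodes[valid])
        chunk_size += int(valid.sum())
        if chunk_size > 4_000_000:
            flush()
    flush()
    return Pileup(genome, flat.reshape(L, 4))


def read_sam(path: str | Path) -> list[pysam.AlignedSegment]:
    """Materialise all records of a SAM/BAM file."""
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        return list(fh)
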