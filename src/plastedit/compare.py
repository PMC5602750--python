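"""Between-tissue comparison of editing efficiency, and RPKM expression.

Differential editing works on percentage-point differences of raw
efficiencies (a site edited at 93% in leaf and 64% in flower is "up 29%"),
with the conventional 20-point threshold.  Tissue-specific status requires
the other tissue to fail all calling thresholds *with adequate coverage*;
undercovered sites are "unknown", not specific.

RPKM = count / (exon kb) / (million mapped reads), with reads assigned to a
gene when the alignment midpoint falls inside its exons (avoids double
counting at gene boundaries) and the library size taken as the reads mapped
to the plastid reference after filtering.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import pysam

from .calling import CallParams, EditSite
from .conversions import plus_strand_bases
from .errors import ConfigurationError, DataError
from .genome import FeatureRecord
from .pileup import Pileup


@dataclass
class DifferentialRecord:
    """Merged per-site editing status across tissues."""

    position: int
    orientation: str
    transcript_strand: str
    edit_type: str
    efficiency: dict[str, float | None]  # None where coverage is inadequate
    depth: dict[str, int]
    called: dict[str, bool]
    status: str  # common | tissue_specific:<tissue> | partial | unknown
    delta: float | None  # first tissue minus second, percentage points/100
    differential_flag: bool
    direction: str  # up | down | none
    low_coverage: bool

    @property
    def key(self) -> tuple[int, str, str]:
        return (self.position, self.orientation, self.edit_type)


def merge_tissues(
    calls_per_tissue: Mapping[str, list[EditSite]],
    pileups: Mapping[str, Pileup],
    params: CallParams | None = None,
    diff_threshold: float = 0.20,
) -> list[DifferentialRecord]:
    """Union the per-tissue call sets and classify each site.

    Efficiency in a tissue where the site was *not* called is looked up from
    that tissue's pileup (so a 3% value is recorded rather than "absent")
    whenever coverage clears ``min_coverage``.  With exactly two tissues the
    delta and an up/down direction (first tissue relative to second) are
    computed; sites undercovered in either tissue are flagged and excluded
    from differential counts.
    """
    params = params or CallParams()
    tissues = list(calls_per_tissue)
    if set(pileups) < set(tissues):
        raise ConfigurationError("a pileup is required for every tissue")
    two = len(tissues) == 2

    by_key: dict[tuple, dict[str, EditSite]] = {}
    for tissue, sites in calls_per_tissue.items():
        for site in sites:
            by_key.setdefault(site.key, {})[tissue] = site

    records = []
    for key in sorted(by_key):
        position, orientation, edit_type = key
        per_tissue = by_key[key]
        any_site = next(iter(per_tissue.values()))
        _ref, alt_base = plus_strand_bases(edit_type, orientation)
        eff: dict[str, float | None] = {}
        depth: dict[str, int] = {}
        called: dict[str, bool] = {}
        for tissue in tissues:
            called[tissue] = tissue in per_tissue
            if called[tissue]:
                s = per_tissue[tissue]
                eff[tissue] = s.efficiency
                depth[tissue] = s.depth
            else:
                pu = pileups[tissue]
                d = int(pu.depth[position - 1])
                depth[tissue] = d
                eff[tissue] = (
                    pu.base_count(position, alt_base) / d
                    if d >= params.min_coverage
                    else None
                )

        n_called = sum(called.values())
        if n_called == len(tissues):
            status = "common"
        elif n_called == 1:
            (only,) = [t for t in tissues if called[t]]
            others_covered = all(
                eff[t] is not None for t in tissues if t != only
            )
            status = f"tissue_specific:{only}" if others_covered else "unknown"
        else:
            status = "partial"

        delta: float | None = None
        differential = False
        direction = "none"
        low_coverage = any(eff[t] is None for t in tissues)
        if two and not low_coverage:
            delta = eff[tissues[0]] - eff[tissues[1]]  # type: ignore[operator]
            if delta >= diff_threshold:
                differential, direction = True, "up"
            elif delta <= -diff_threshold:
                differential, direction = True, "down"
        records.append(
            DifferentialRecord(
                position=position,
                orientation=orientation,
                transcript_strand=any_site.transcript_strand,
                edit_type=edit_type,
                efficiency=eff,
                depth=depth,
                called=called,
                status=status,
                delta=delta,
                differential_flag=differential,
                direction=direction,
                low_coverage=low_coverage,
            )
        )
    return records


def differential_to_frame(
    records: list[DifferentialRecord], tissues: list[str]
) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "position": r.position,
            "transcript_strand": r.transcript_strand,
            "orientation": r.orientation,
            "edit_type": r.edit_type,
        }
        for t in tissues:
            row[f"efficiency_{t}"] = (
                round(r.efficiency[t], 4) if r.efficiency[t] is not None else None
            )
            row[f"depth_{t}"] = r.depth[t]
            row[f"called_{t}"] = r.called[t]
        row.update(
            {
                "status": r.status,
                "delta": round(r.delta, 4) if r.delta is not None else None,
                "differential": r.differential_flag,
                "direction": r.direction,
                "low_coverage": r.low_coverage,
            }
        )
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

@dataclass
class ExpressionRecord:
    """Per-gene read count and RPKM for one library."""

    gene: str
    exon_length: int
    count: int
    rpkm: float


def compute_rpkm(
    reads: Iterable[pysam.AlignedSegment],
    genes: list[FeatureRecord],
    library_size: int | None = None,
) -> list[ExpressionRecord]:
    """Midpoint-assigned read counts normalised to RPKM.

    ``library_size`` defaults to the number of reads supplied (the filtered,
    plastid-mapped library).
    """
    genes = list(genes)
    for g in genes:
        if g.length == 0:
            raise DataError(f"gene {g.feature_id} has zero exon length")
    max_end = max((g.end for g in genes), default=0)
    owner = np.full(max_end + 1, -1, dtype=np.int32)  # 1-based positions
    for i, g in enumerate(genes):
        for s, e in g.intervals:
            owner[s : e + 1] = i

    counts = np.zeros(len(genes), dtype=np.int64)
    n_reads = 0
    for read in reads:
        if read.is_unmapped:
            continue
        n_reads += 1
        start = read.reference_start  # 0-based
        end = read.reference_end or (start + 1)
        mid = (start + end - 1) // 2 + 1  # 1-based midpoint
        if 1 <= mid <= max_end and owner[mid] >= 0:
            counts[owner[mid]] += 1
    if library_size is None:
        library_size = n_reads
    if library_size == 0:
        raise DataError("zero mapped reads; RPKM undefined")
    return [
        ExpressionRecord(
            gene=g.feature_id,
            exon_length=g.length,
            count=int(counts[i]),
            rpkm=counts[i] / (g.length / 1e3) / (library_size / 1e6),
        )
        for i, g in enumerate(genes)
    ]


def expression_table(
    reads_per_tissue: Mapping[str, Iterable[pysam.AlignedSegment]],
    genes: list[FeatureRecord],
) -> pd.DataFrame:
    """Per-gene RPKM for every tissue plus the first/second tissue ratio.

    The ratio column mirrors the leaf/flower fold-change convention; a zero
    denominator leaves the ratio undefined (NaN), never infinite.
    """
    tissues = list(reads_per_tissue)
    frames = {}
    for tissue in tissues:
        recs = compute_rpkm(reads_per_tissue[tissue], genes)
        frames[tissue] = {r.gene: r for r in recs}
    rows = []
    for g in genes:
        row = {"gene": g.feature_id, "exon_length": g.length}
        for tissue in tissues:
            rec = frames[tissue][g.feature_id]
            row[f"count_{tissue}"] = rec.count
            row[f"rpkm_{tissue}"] = rec.rpkm
        if len(tissues) == 2:
            num = row[f"rpkm_{tissues[0]}"]
            den = row[f"rpkm_{tissues[1]}"]
            row["ratio"] = num / den if den > 0 else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
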