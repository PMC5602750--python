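"""C-to-U / U-to-C edit calling from pileup columns.

A site is reported when its coverage, edited-read count and edited-read
frequency all clear the calling thresholds (defaults 10, 2 and 5%).  Editing
efficiency is the fraction of reads carrying the converted base, binned into
the five-class partial-editing scheme:

    full   > 90%
    high   (60%, 90%]
    medium (40%, 60%]
    low    (20%, 40%]
    poor   [5%, 20%]

The bins the scheme is usually quoted with overlap at their endpoints;
lower-exclusive/upper-inclusive intervals are adopted (poor closed at 5%) so
every called site falls in exactly one class.

Sites inside or immediately adjacent to a homopolymer run of six or more
identical bases are flagged: slippage errors mimic editing there, and flagged
sites are excluded from downstream summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .conversions import FROM_MISMATCH
from .errors import DataError
from .genome import FeatureRecord, ReferenceGenome, feature_strand_array
from .pileup import Pileup

EFFICIENCY_CLASSES = ("full", "high", "medium", "low", "poor")


@dataclass
class CallParams:
    """Variant-calling thresholds and the homopolymer masking rule."""

    min_coverage: int = 10
    min_count: int = 2
    min_frequency: float = 0.05
    homopolymer_min_run: int = 6  # masks runs "of more than five"

    def __post_init__(self) -> None:
        if self.min_coverage < 1:
            raise ValueError("min_coverage must be >= 1")
        if not 0 < self.min_frequency <= 1:
            raise ValueError("min_frequency must be in (0, 1]")


@dataclass
class EditSite:
    """One called conversion at a genomic position.

    ``orientation`` is the strand the conversion chemistry was evaluated on;
    ``transcript_strand`` equals it inside annotated features and is
    ``unassigned`` in intergenic space.
    """

    position: int
    transcript_strand: str  # +, -, unassigned
    orientation: str  # + or -
    edit_type: str  # C-to-U | U-to-C
    edited_count: int
    depth: int
    efficiency: float
    efficiency_class: str
    homopolymer_flag: bool

    @property
    def key(self) -> tuple[int, str, str]:
        return (self.position, self.orientation, self.edit_type)


def classify_efficiency(efficiency: float) -> str:
    """Assign the five-bin partial-editing class; raises below the 5% floor."""
    if efficiency > 1:
        raise ValueError(f"efficiency {efficiency} > 1")
    if efficiency > 0.90:
        return "full"
    if efficiency > 0.60:
        return "high"
    if efficiency > 0.40:
        return "medium"
    if efficiency > 0.20:
        return "low"
    if efficiency >= 0.05:
        return "poor"
    raise ValueError(
        f"efficiency {efficiency:.4f} below the 5% calling floor; "
        "such a site should not have been called"
    )


def call_edits(
    pileup: Pileup,
    genome: ReferenceGenome,
    features: list[FeatureRecord],
    params: CallParams | None = None,
) -> list[EditSite]:
    """Evaluate every pileup column for a C-to-U or U-to-C conversion.

    Inside a stranded feature only that strand's chemistry is considered;
    intergenic columns are evaluated in the orientation that yields a valid
    conversion (each reference base admits exactly one).  Only the two
    editing mismatch classes are ever called; other mismatches contribute to
    depth but are treated as noise.
    """
    params = params or CallParams()
    if pileup.genome.name != genome.name:
        raise DataError("pileup was built against a different genome")
    L = len(genome)
    counts = pileup.counts
    depth = counts.sum(axis=1)
    ref = genome.codes
    strand_arr = feature_strand_array(features, L)
    hp_mask = genome.homopolymer_mask(params.homopolymer_min_run, pad=1)

    sites: list[EditSite] = []
    base_idx = {b: i for i, b in enumerate("ACGT")}
    for (ref_base, alt_base), (edit_type, strand) in FROM_MISMATCH.items():
        scode = 1 if strand == "+" else 2
        alt = counts[:, base_idx[alt_base]]
        with np.errstate(divide="ignore", invalid="ignore"):
            freq = np.where(depth > 0, alt / np.maximum(depth, 1), 0.0)
        mask = (
            (ref == base_idx[ref_base])
            & ((strand_arr == scode) | (strand_arr == 0))
            & (depth >= params.min_coverage)
            & (alt >= params.min_count)
            & (freq >= params.min_frequency)
        )
        for i in np.nonzero(mask)[0]:
            in_feature = strand_arr[i] == scode
            eff = float(alt[i]) / float(depth[i])
            sites.append(
                EditSite(
                    position=int(i) + 1,
                    transcript_strand=strand if in_feature else "unassigned",
                    orientation=strand,
                    edit_type=edit_type,
                    edited_count=int(alt[i]),
                    depth=int(depth[i]),
                    efficiency=eff,
                    efficiency_class=classify_efficiency(eff),
                    homopolymer_flag=bool(hp_mask[i]),
                )
            )
    sites.sort(key=lambda s: (s.position, s.edit_type))
    return sites


def sites_to_frame(sites: list[EditSite]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "position": s.position,
                "transcript_strand": s.transcript_strand,
                "orientation": s.orientation,
                "edit_type": s.edit_type,
                "edited_count": s.edited_count,
                "depth": s.depth,
                "efficiency": round(s.efficiency, 4),
                "efficiency_class": s.efficiency_class,
                "homopolymer_flag": s.homopolymer_flag,
            }
            for s in sites
        ],
        columns=[
            "position", "transcript_strand", "orientation", "edit_type",
            "edited_count", "depth", "efficiency", "efficiency_class",
            "homopolymer_flag",
        ],
    )


def write_sites(sites: list[EditSite], path: str | Path) -> None:
    sites_to_frame(sites).to_csv(path, sep="\t", index=False)


def read_sites(path: str | Path) -> list[EditSite]:
    df = pd.read_csv(path, sep="\t")
    return [
        EditSite(
            position=int(r.position),
            transcript_strand=str(r.transcript_strand),
            orientation=str(r.orientation),
            edit_type=str(r.edit_type),
            edited_count=int(r.edited_count),
            depth=int(r.depth),
            efficiency=float(r.efficiency),
            efficiency_class=str(r.efficiency_class),
            homopolymer_flag=bool(r.homopolymer_flag),
        )
        for r in df.itertuples()
    ]
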