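"""Feature assignment, codon consequences and sequence-context profiling.

Each called site is assigned to the unique feature covering it (intergenic
otherwise).  CDS sites get a spliced, transcript-oriented coordinate and a
translated consequence under the standard genetic code: creation of a start
codon (an annotated non-ATG initiation codon becoming ATG), creation of a
stop codon, or a synonymous/non-synonymous substitution, with the
Kyte-Doolittle hydropathy change of the amino-acid swap.

Site labels follow the field's convention: ``<gene>-<cds position>`` for
protein-coding sites (petG-56 style) and the genomic position for all other
sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

from .calling import EditSite
from .conversions import C_TO_U
from .errors import AnnotationError, DataError
from .genome import FeatureRecord, ReferenceGenome, reverse_complement

EFFECTS = ("synonymous", "nonsynonymous", "start_created", "stop_created")

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]


def _translate_codon(codon_dna: str) -> str:
    """One-letter amino acid, '*' for stop (standard code)."""
    return str(Seq(codon_dna).translate(table=1))


@dataclass
class CodonConsequence:
    """Translated consequence of a single CDS edit."""

    gene: str
    cds_position: int  # 1-based offset within the spliced CDS
    codon_index: int  # 1-based codon number
    codon_position: int  # 1, 2 or 3
    ref_codon: str  # RNA alphabet (e.g. ACA)
    edited_codon: str  # RNA alphabet (e.g. AUA)
    ref_aa: str
    edited_aa: str
    effect: str
    hydropathy_delta: float


@dataclass
class AnnotatedSite:
    """An EditSite plus its feature assignment and (for CDS) consequence."""

    site: EditSite
    feature_class: str  # CDS | tRNA | rRNA | intron | IGS
    feature_id: str
    label: str
    cds_position: int | None = None
    consequence: CodonConsequence | None = None

    @property
    def position(self) -> int:
        return self.site.position

    @property
    def key(self) -> tuple[int, str, str]:
        return self.site.key

    def to_dict(self) -> dict:
        d = {
            "position": self.site.position,
            "transcript_strand": self.site.transcript_strand,
            "orientation": self.site.orientation,
            "edit_type": self.site.edit_type,
            "edited_count": self.site.edited_count,
            "depth": self.site.depth,
            "efficiency": round(self.site.efficiency, 4),
            "efficiency_class": self.site.efficiency_class,
            "homopolymer_flag": self.site.homopolymer_flag,
            "feature_class": self.feature_class,
            "feature_id": self.feature_id,
            "label": self.label,
            "cds_position": self.cds_position,
        }
        c = self.consequence
        d.update(
            {
                "codon_index": c.codon_index if c else None,
                "codon_position": c.codon_position if c else None,
                "ref_codon": c.ref_codon if c else None,
                "edited_codon": c.edited_codon if c else None,
                "ref_aa": c.ref_aa if c else None,
                "edited_aa": c.edited_aa if c else None,
                "effect": c.effect if c else None,
                "hydropathy_delta": c.hydropathy_delta if c else None,
            }
        )
        return d


def assign_feature(
    site: EditSite, features: list[FeatureRecord]
) -> AnnotatedSite:
    """Assign a site to the unique feature covering its position.

    Positions in no annotated feature are intergenic (IGS).  Overlapping
    conflicting features raise, listing the conflict.
    """
    hits = [f for f in features if f.contains(site.position)]
    if len(hits) > 1:
        ids = ", ".join(f.feature_id for f in hits)
        raise AnnotationError(
            f"position {site.position} covered by conflicting features: {ids}"
        )
    if not hits:
        return AnnotatedSite(site, "IGS", "IGS", str(site.position))
    feat = hits[0]
    if feat.feature_class == "CDS":
        cds_pos = feat.transcript_offset(site.position)
        return AnnotatedSite(
            site, "CDS", feat.feature_id, f"{feat.feature_id}-{cds_pos}", cds_pos
        )
    return AnnotatedSite(site, feat.feature_class, feat.feature_id, str(site.position))


def _to_rna(codon_dna: str) -> str:
    return codon_dna.replace("T", "U")


def codon_consequence(
    site: EditSite, gene: FeatureRecord, genome: ReferenceGenome
) -> CodonConsequence:
    """Translate the consequence of a single edit inside a CDS.

    The effect is computed per edit against the reference CDS; co-edited
    codons are each annotated independently.  Start-codon creation is only
    flagged at codon 1 of a CDS whose annotated initiation codon is non-ATG.
    """
    if gene.feature_class != "CDS":
        raise AnnotationError(f"{gene.feature_id} is not a CDS")
    cds = gene.spliced_sequence(genome)
    cds_pos = gene.transcript_offset(site.position)
    if cds_pos > len(cds):
        raise AnnotationError(
            f"cds position {cds_pos} beyond spliced length {len(cds)}"
        )
    ref_base = cds[cds_pos - 1]
    if site.edit_type == C_TO_U:
        expect, edited_base = "C", "T"
    else:
        expect, edited_base = "T", "C"
    if ref_base != expect:
        raise AnnotationError(
            f"{gene.feature_id}-{cds_pos}: transcript base {ref_base} does not "
            f"match a {site.edit_type} conversion"
        )
    codon_index = (cds_pos - 1) // 3 + 1
    codon_position = (cds_pos - 1) % 3 + 1
    start = (codon_index - 1) * 3
    ref_codon = cds[start : start + 3]
    edited_codon = (
        ref_codon[: codon_position - 1] + edited_base + ref_codon[codon_position:]
    )
    ref_aa = _translate_codon(ref_codon)
    edited_aa = _translate_codon(edited_codon)
    if codon_index == 1 and edited_codon == "ATG" and ref_codon != "ATG":
        effect = "start_created"
        delta = 0.0
    elif edited_aa == "*" and ref_aa != "*":
        effect = "stop_created"
        delta = 0.0
    elif ref_aa == edited_aa:
        effect = "synonymous"
        delta = 0.0
    else:
        effect = "nonsynonymous"
        delta = KYTE_DOOLITTLE[edited_aa] - KYTE_DOOLITTLE[ref_aa]
    return CodonConsequence(
        gene=gene.feature_id,
        cds_position=cds_pos,
        codon_index=codon_index,
        codon_position=codon_position,
        ref_codon=_to_rna(ref_codon),
        edited_codon=_to_rna(edited_codon),
        ref_aa=ref_aa,
        edited_aa=edited_aa,
        effect=effect,
        hydropathy_delta=delta,
    )


def annotate_sites(
    sites: list[EditSite],
    features: list[FeatureRecord],
    genome: ReferenceGenome,
) -> list[AnnotatedSite]:
    """Feature assignment plus codon consequence for every CDS site."""
    by_id = {f.feature_id: f for f in features}
    out = []
    for site in sites:
        ann = assign_feature(site, features)
        if ann.feature_class == "CDS":
            ann.consequence = codon_consequence(site, by_id[ann.feature_id], genome)
        out.append(ann)
    return out


def neighbor_context(
    sites: list[AnnotatedSite], genome: ReferenceGenome
) -> pd.DataFrame:
    """Nucleotide frequencies immediately 5' (-1) and 3' (+1) of the edits.

    Computed in transcript orientation (unassigned sites use their calling
    orientation), separately for protein-coding and non-protein-coding
    sites; T is reported as U.  Sites lacking a neighbour at a genome end
    are excluded.  Frequencies at each (group, offset) sum to 1.
    """
    rows = []
    skipped = 0
    for ann in sites:
        pos = ann.position
        if pos <= 1 or pos >= len(genome):
            skipped += 1
            continue
        strand = ann.site.orientation
        if strand == "+":
            minus1, plus1 = genome.base(pos - 1), genome.base(pos + 1)
        else:
            minus1 = reverse_complement(genome.base(pos + 1))
            plus1 = reverse_complement(genome.base(pos - 1))
        group = "protein_coding" if ann.feature_class == "CDS" else "non_protein_coding"
        rows.append((group, -1, minus1.replace("T", "U")))
        rows.append((group, +1, plus1.replace("T", "U")))
    if skipped:
        import logging

        logging.getLogger(__name__).info(
            "neighbor_context: excluded %d site(s) at genome ends", skipped
        )
    if not rows:
        return pd.DataFrame(columns=["group", "offset", "base", "frequency"])
    df = pd.DataFrame(rows, columns=["group", "offset", "base"])
    freq = (
        df.groupby(["group", "offset"])["base"]
        .value_counts(normalize=True)
        .rename("frequency")
        .reset_index()
    )
    return freq


@dataclass
class SequenceWindow:
    """Transcript-oriented window around an edit, edited and unedited."""

    unedited: str
    edited: str
    site_index: int  # 0-based index of the edited base within the window
    truncated: bool


def extract_window(
    site: EditSite,
    genome: ReferenceGenome,
    upstream: int,
    downstream: int,
) -> SequenceWindow:
    """Transcript-strand sequence covering [-upstream, +downstream].

    Windows running past a genome end are truncated and flagged.  Useful for
    cis-element inspection (-30/+10) and structure-window extraction
    (50 nt each side).
    """
    if upstream < 0 or downstream < 0:
        raise DataError("window extents must be non-negative")
    pos = site.position
    strand = site.orientation
    if strand == "+":
        lo_want, hi_want = pos - upstream, pos + downstream
    else:
        lo_want, hi_want = pos - downstream, pos + upstream
    lo = max(1, lo_want)
    hi = min(len(genome), hi_want)
    truncated = (lo != lo_want) or (hi != hi_want)
    plus = genome.slice(lo, hi)
    idx_plus = pos - lo
    if site.edit_type == C_TO_U:
        alt = "T" if strand == "+" else "A"
    else:
        alt = "C" if strand == "+" else "G"
    edited_plus = plus[:idx_plus] + alt + plus[idx_plus + 1 :]
    if strand == "+":
        return SequenceWindow(plus, edited_plus, idx_plus, truncated)
    return SequenceWindow(
        reverse_complement(plus),
        reverse_complement(edited_plus),
        len(plus) - 1 - idx_plus,
        truncated,
    )


def annotated_to_frame(sites: list[AnnotatedSite]) -> pd.DataFrame:
    cols = [
        "position", "transcript_strand", "orientation", "edit_type",
        "edited_count", "depth", "efficiency", "efficiency_class",
        "homopolymer_flag", "feature_class", "feature_id", "label",
        "cds_position", "codon_index", "codon_position", "ref_codon",
        "edited_codon", "ref_aa", "edited_aa", "effect", "hydropathy_delta",
    ]
    return pd.DataFrame([s.to_dict() for s in sites], columns=cols)


def write_annotated(sites: list[AnnotatedSite], path: str | Path) -> None:
    annotated_to_frame(sites).to_csv(path, sep="\t", index=False)
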