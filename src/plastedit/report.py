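"""Summary accounting over annotated edit sites.

Produces the per-tissue / common / total count table editing surveys report:
total edits split by conversion type, protein-coding edits by codon position
and consequence, and non-coding edits by feature class — together with the
derived percentages (efficiency-class shares, codon-position shares,
synonymy shares and edits per genome nucleotide).  Homopolymer-flagged sites
are excluded before any accounting.

The set-algebra helpers make the table's arithmetic explicit:
``union = tissueA + tissueB - common`` holds for every row.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

from .calling import EFFICIENCY_CLASSES
from .conversions import C_TO_U

ROW_ORDER = [
    "protein_coding",
    "codon_position_1",
    "codon_position_2",
    "codon_position_3",
    "start_codon_created",
    "stop_codon_created",
    "nonsynonymous",
    "synonymous",
    "non_protein_coding",
    "tRNA",
    "rRNA",
    "intron",
    "IGS",
    "c_to_u",
    "u_to_c",
    "all_edits",
]


def union_count(n_a: int, n_b: int, n_common: int) -> int:
    """Size of the union of two tissues' edit sets from the common count."""
    return n_a + n_b - n_common


def specific_count(n_tissue: int, n_common: int) -> int:
    """Edits seen in one tissue only."""
    return n_tissue - n_common


def newly_discovered(n_total: int, n_known: int) -> int:
    """Edits beyond a previously reported set."""
    return n_total - n_known


def percentage(part: float, whole: float, decimals: int = 1) -> float:
    """Share of ``part`` in ``whole`` as a percentage, printed-rounded."""
    if whole == 0:
        return 0.0
    return round(100.0 * part / whole, decimals)


def _classify_row(row: pd.Series) -> list[str]:
    cats = ["all_edits"]
    cats.append("c_to_u" if row["edit_type"] == C_TO_U else "u_to_c")
    if row["feature_class"] == "CDS":
        cats.append("protein_coding")
        cp = row.get("codon_position")
        if pd.notna(cp):
            cats.append(f"codon_position_{int(cp)}")
        effect = row.get("effect")
        if effect == "start_created":
            cats.append("start_codon_created")
        elif effect == "stop_created":
            cats.append("stop_codon_created")
        elif effect == "synonymous":
            cats.append("synonymous")
        elif effect == "nonsynonymous":
            cats.append("nonsynonymous")
    else:
        cats.append("non_protein_coding")
        cats.append(row["feature_class"])
    return cats


@dataclass
class SummaryTable:
    """Count table (rows = categories, columns = tissues/common/total) plus
    the derived percentage report."""

    counts: pd.DataFrame
    percentages: dict
    genome_length: int
    tissues: list[str]

    def validate(self) -> None:
        """Internal accounting identities; raises AssertionError on breakage."""
        c = self.counts
        if len(self.tissues) == 2:
            a, b = self.tissues
            for row in c.index:
                assert c.loc[row, "total"] == union_count(
                    int(c.loc[row, a]), int(c.loc[row, b]), int(c.loc[row, "common"])
                ), f"union identity broken for {row}"
        for col in c.columns:
            assert (
                c.loc["c_to_u", col] + c.loc["u_to_c", col] == c.loc["all_edits", col]
            ), f"conversion split broken for {col}"
            assert (
                c.loc["protein_coding", col] + c.loc["non_protein_coding", col]
                == c.loc["all_edits", col]
            )
            assert (
                sum(c.loc[f"codon_position_{i}", col] for i in (1, 2, 3))
                == c.loc["protein_coding", col]
            ), f"codon positions do not sum for {col}"
            assert (
                c.loc["start_codon_created", col]
                + c.loc["stop_codon_created", col]
                + c.loc["synonymous", col]
                + c.loc["nonsynonymous", col]
                == c.loc["protein_coding", col]
            ), f"consequence split broken for {col}"
            assert (
                c.loc["tRNA", col] + c.loc["rRNA", col] + c.loc["intron", col]
                + c.loc["IGS", col] == c.loc["non_protein_coding", col]
            )

    def to_files(self, counts_path: str | Path, pct_path: str | Path) -> None:
        self.counts.to_csv(counts_path, sep="\t")
        Path(pct_path).write_text(json.dumps(self.percentages, indent=2) + "\n")


def summarize(
    annotated: Mapping[str, pd.DataFrame],
    genome_length: int,
    known_sites: set[tuple[int, str, str]] | None = None,
) -> SummaryTable:
    """Build the summary table from per-tissue annotated site frames.

    ``annotated`` maps tissue -> frame as written by the annotator (one row
    per called site).  Sites are matched across tissues by (position,
    orientation, edit type).  ``known_sites`` optionally marks previously
    reported edits so the newly-discovered count can be derived.
    """
    tissues = list(annotated)
    frames = {}
    for tissue, df in annotated.items():
        df = df.copy()
        if "homopolymer_flag" in df.columns:
            df = df[~df["homopolymer_flag"].astype(bool)]
        df["site_key"] = list(
            zip(df["position"].astype(int), df["orientation"], df["edit_type"])
        )
        frames[tissue] = df

    all_keys: dict[tuple, pd.Series] = {}
    key_tissues: dict[tuple, set[str]] = {}
    for tissue, df in frames.items():
        for _, row in df.iterrows():
            key = row["site_key"]
            all_keys.setdefault(key, row)
            key_tissues.setdefault(key, set()).add(tissue)

    counts = pd.DataFrame(
        0, index=ROW_ORDER, columns=[*tissues, "common", "total"], dtype=int
    )
    for key, row in all_keys.items():
        cats = _classify_row(row)
        present = key_tissues[key]
        for cat in cats:
            for tissue in present:
                counts.loc[cat, tissue] += 1
            if present == set(tissues):
                counts.loc[cat, "common"] += 1
            counts.loc[cat, "total"] += 1

    pct: dict = {}
    # efficiency-class share per tissue (of that tissue's called sites)
    eff_share = {}
    for tissue, df in frames.items():
        n = len(df)
        eff_share[tissue] = {
            cls: percentage((df["efficiency_class"] == cls).sum(), n, 1)
            for cls in EFFICIENCY_CLASSES
        }
    pct["efficiency_class_share"] = eff_share
    total_pc = int(counts.loc["protein_coding", "total"])
    pct["codon_position_share"] = {
        f"position_{i}": percentage(
            int(counts.loc[f"codon_position_{i}", "total"]), total_pc, 0
        )
        for i in (1, 2, 3)
    }
    pct["consequence_share"] = {
        "synonymous": percentage(int(counts.loc["synonymous", "total"]), total_pc, 0),
        "nonsynonymous": percentage(
            int(counts.loc["nonsynonymous", "total"]), total_pc, 0
        ),
    }
    pct["edits_per_nucleotide_pct"] = percentage(
        int(counts.loc["all_edits", "total"]), genome_length, 2
    )
    if known_sites is not None:
        n_known = sum(1 for k in all_keys if k in known_sites)
        pct["previously_reported"] = n_known
        pct["newly_discovered"] = newly_discovered(
            int(counts.loc["all_edits", "total"]), n_known
        )

    return SummaryTable(counts, pct, genome_length, tissues)
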