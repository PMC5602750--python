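# Methods

## Model and procedure

`plastedit` treats plastid RNA editing as a per-position binomial
observation problem.  At a genomic position with sequencing depth *n*, the
number of reads carrying the converted base is modelled as Binomial(*n*,
*e*) where *e* is the editing efficiency, contaminated by a uniform
per-base substitution error.  Only the two biologically meaningful mismatch
classes are considered: C→U (reference C with T reads on a plus-strand
transcript, reference G with A reads on a minus-strand one) and the rare
reverse U→C.  Each reference base admits exactly one editing interpretation
(C→ plus-strand C-to-U, G→ minus-strand C-to-U, T→ plus-strand U-to-C, A→
minus-strand U-to-C), so intergenic positions — which have no annotated
transcript strand — are evaluated in the orientation their base admits and
reported with `transcript_strand = unassigned`.

The pipeline stages are: (1) alignment filtering, (2) pileup, (3) edit
calling with homopolymer masking, (4) feature/codon annotation, (5)
between-tissue merge and differential classification, (6) RPKM expression,
(7) summary accounting.

## Parameters

| Parameter | Default | Meaning |
|---|---|---|
| `min_length_fraction` | 0.98 | aligned length / read length needed to keep a read |
| `min_similarity` | 0.98 | matches / aligned length needed to keep a read |
| `min_coverage` | 10 | minimum depth at a callable position |
| `min_count` | 2 | minimum edited-read count |
| `min_frequency` | 0.05 | minimum edited-read fraction |
| `homopolymer_min_run` | 6 | run length (bp) that triggers masking |
| `diff_threshold` | 0.20 | efficiency difference (fraction) for a differential call |

The similarity fraction is defined over the alignment (matches / aligned
length); with the NM tag present, matches are derived as aligned length
minus substitution count.  No base-quality or mapping-quality cutoffs are
applied by default.

Efficiency classes partition (5%, 100%] with lower-exclusive,
upper-inclusive bins — full >90%, high (60, 90]%, medium (40, 60]%, low
(20, 40]%, poor [5, 20]% — the poor bin closed at the 5% calling floor so
every called site has exactly one class.  The bins these schemes are quoted
with overlap at their endpoints; this convention resolves the ties (0.90 is
"high", 0.91 is "full").

Homopolymer masking covers a run of ≥6 identical bases plus one base on
each side, because slippage errors concentrate at run borders.  Flagged
sites are still written to the call tables (provenance) but excluded from
summaries, context profiles and recovery scoring.

Differential editing uses raw efficiency differences in percentage points
(93% vs 64% is "up 29 points"), never class changes.  "Tissue-specific"
requires the other tissue to fail the calling thresholds while covered at
`min_coverage` or better; an undercovered comparison tissue yields
"unknown" and the site is excluded from differential counts.  For a site
called in only one tissue the other tissue's efficiency is looked up from
its pileup, so a 3% value is recorded rather than "absent".

RPKM = count / (exon kb) / (million mapped reads).  A read belongs to a
gene when its alignment midpoint falls in the gene's exons — midpoint
assignment avoids double counting where reads straddle gene boundaries —
and the library size is the filtered, plastid-mapped read count.  A zero
denominator leaves a ratio undefined (NaN), never infinite.

## Synthetic data: what it emulates and what it does not

The generator emulates the statistical structure the analysis assumes: a
small (default 20 kb) plastome at 37% GC with stranded genes packed between
intergenic spacers — single- and two-exon CDSs (length divisible by three,
ATG start, one gene with an ACG initiation codon for start-creation tests,
no internal stops), tRNAs, annotated introns, and one CDS carrying an
embedded CCCCCCC run so masking is always exercised.  Edits are planted on
strand-consistent bases across every feature class and both strands, with
per-tissue efficiencies drawn uniformly from a configurable range
(default 10–95%), one tissue-specific site, one >20-point differential
pair, and (optionally) one site inside a homopolymer run.  Reads are
ungapped, uniformly placed, correct by construction, and carry the edited
base per read with probability equal to the tissue's true efficiency before
a uniform substitution error (default 0.2%) is applied.  All outputs are a
deterministic function of the seed.

Planted edits are spaced at least one read length apart.  Real plastomes
carry roughly one edit per kilobase, so a single read essentially never
spans two edits; a 20 kb miniature with 100 edits is several-fold denser,
and without the spacing rule the 98% identity filter would preferentially
drop reads carrying two true edits plus one sequencing error, biasing
efficiency estimates at clustered sites.  The spacing restores the
real-data property at miniature scale.

Deliberately not emulated: paired-end or spliced reads, indels, base-quality
profiles, inverted-repeat duplication (multi-mapping), DNA contamination,
reads spanning the circular origin, and non-uniform fragment biases.
Passing recovery tests therefore demonstrates the correctness of the
counting, thresholding and classification logic under the stated error
model — not robustness to mapping artifacts or library-preparation biases
in real data.

An optional per-gene expression multiplier reweights read starts by the
multiplier of the gene containing the read midpoint (default uniform),
which makes RPKM scaling testable.

## Recovery experiments (problem sizes)

Two seeded experiments back the recovery claims, both run by
`scripts/acceptance.py` and the test suite:

- **Caller recovery** — 20 kb genome, 100 edits at 10–95% efficiency, two
  tissues at 200× coverage, 0.2% error.  Scored per tissue over truth sites
  outside homopolymer masks with true efficiency at or above the planted
  minimum: sensitivity, false calls at unplanted positions, and the
  fraction of called efficiencies within three binomial standard errors
  `3·sqrt(e(1−e)/depth)` of truth.
- **Differential recovery** — 160 edits with planted between-tissue deltas
  cycling through 0, 0.10, 0.25 and 0.50 at 1000× coverage (within the
  coverage range plastid-enriched libraries reach).  At depth ~1000 the
  standard error of an efficiency difference is ≤ 0.023, so the 20-point
  rule separates the 0.25 class from the null with the margins the tests
  assert (≥95% sensitivity at Δ=0.25, ≥95% specificity at Δ=0).  Depth in
  the low hundreds would put the binomial noise of a 0.25-point difference
  on top of the 0.20 threshold, which is a property of the rule itself, not
  of the implementation.

## Numerical and design choices

- Coordinates are 1-based and closed everywhere (GFF3 convention); pileup
  matrices are dense `(genome length, 4)` integer arrays.
- The frequency threshold compares `edited/depth ≥ min_frequency` in double
  precision; exact boundary cases (5 of 100 reads at the 5% floor) pass.
- Effects are computed per single edit against the reference CDS; co-edited
  codons are annotated independently (a third-position edit next to a
  second-position edit is synonymous on its own even when the pair changes
  the residue).
- Start-codon creation is only flagged at codon 1 of a CDS annotated with a
  non-ATG initiation codon; internal ACG→AUG is ordinary nonsynonymous.
- Hydropathy uses the Kyte–Doolittle scale (via Biopython); the delta is 0
  for synonymous, start- and stop-affecting edits.
- Ties in intergenic orientation cannot arise (each base admits one
  interpretation), so no preference rule is ever needed at runtime.
- Degenerate inputs: an empty pileup yields an empty call list; a genome
  with no genes is all intergenic; a zero-length gene or an empty library
  raises a data error rather than emitting infinities.
- Percentages follow printed-precision rounding: one decimal for shares,
  two for the per-nucleotide editing rate, integer percentages where the
  convention is integer.

## Known limitations

- The caller assumes substitution-only evidence; indel-containing reads
  contribute only their aligned positions.
- No per-site statistical test is performed (single libraries per tissue);
  the frequency floor is the operative detection rule.
- Multi-mapping between inverted-repeat copies is not resolved; calls are
  reported per mapped coordinate.
- RNA secondary-structure and tRNA-fold consequences of edits are out of
  scope; the window extractor only supplies the sequences such tools need.
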