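# Methods

## Background and scope

Obligate endosymbionts of planthoppers (Hemiptera: Fulgoromorpha) live in
dedicated host organs and provision their sap-feeding hosts with the ten
essential amino acids (EAAs) and B vitamins their diet lacks.  Long-term
host restriction drives genome erosion: chromosomes shrink to 130–500 kb,
GC content drops to 18–27%, and genes pseudogenize.  One conspicuous
erosion signature is the *split gene*: an annotation pipeline reports a
gene as two adjacent CDS because a single in-frame internal stop codon
interrupts the ORF, while merging the halves restores one uninterrupted
reading frame.

The package implements four analyses over such genomes — split-gene
detection with stop-codon usage statistics, nutritional pathway
completeness and consortium complementarity, and pairwise genome
comparisons — plus a truth-tracked synthetic genome generator so every
analysis is testable without downloading deposited assemblies.

## Split-gene detection

A pair of neighbouring CDS (A, B) on the same strand is a split candidate
iff:

1. B is the next CDS downstream of A in coding orientation, at a gap of
   0–`max_gap` nt (default 30);
2. the merged span from A's start to B's end is a multiple of 3;
3. translating the merged span in A's frame (bacterial code, table 11)
   yields exactly one internal stop, located at or after A's annotated
   terminal codon and before B's first codon;
4. both halves are at least `min_half_length` codons (default 10).

Pairing is greedy left-to-right in coding orientation; when a middle
fragment could pair with either neighbour, the smaller gap wins, and chains
of three or more fragments reduce to successive pairs (logged).  Each CDS
joins at most one candidate, and the merged annotation is emitted with
1-based inclusive coordinates and a deterministic
`<first_locus_tag>_merged` tag.

This geometric criterion deliberately replaces homology evidence (BlastX
domain inspection against an external database), which is how such splits
are classically confirmed.  The consequence is an identifiability limit:
two complete, frame-compatible ORFs separated by a short stop-free
in-frame spacer are indistinguishable from a genuine split.  An optional
user-supplied homology table (pairs of locus tags asserted homologous) can
override the geometric filter for real genomes.

Stop-codon usage is tabulated for three groups: (1) terminal stops of
intact genes (features flagged pseudo excluded by default; CDS not ending
in a stop are excluded and counted), (2) the internal stop of each
candidate — equivalently the first half's terminal stop — and (3) the
terminal stop of each candidate's second half.  Percentages are rounded to
integers, half away from zero, matching how such tables are printed.  The
TGA enrichment among internal stops relative to intact genes is reported,
never asserted: it is an empirical observation bearing on possible
stop-codon repurposing in AT-rich genomes, and the package draws no
inference about it.

## Pathway completeness and consortium complementarity

A curated catalog defines each biosynthesis pathway as an ordered list of
enzymatic steps, each step a set of alternative gene symbols (isozymes or
alternative routes, e.g. `dapC/argD`, `aroF/aroG/aroH`).  The shipped
catalog covers the 10 EAA pathways plus cysteine, riboflavin and biotin.
Steps explicitly named in the study's text are marked `source=text` in the
shipped presence fixture; the remainder are transcribed from canonical
enterobacterial pathway gene sets and marked `source=figure`.  Two
transcription choices matter:

- **Methionine** is catalogued as the two terminal reactions (`metC`,
  `metE/metH`) — the steps the symbionts actually encode — with upstream
  reactions treated as complemented outside the catalog.  This makes
  "jointly produce all 10 EAAs" well defined without inflating every
  member's methionine deficit.
- **Biotin** keeps `bioH` and `bioW` as separate steps (they are
  alternative routes to pimeloyl-CoA in different lineages), so a genome
  missing both reports two missing steps rather than one.

Presence calling is by annotated gene symbol — case-insensitive, through a
synonym map (`ribG→ribD` etc.) — never by homology search, which keeps the
scoring exact and testable; a symbol carried only by a merged split gene
scores `present_split`, which counts toward coverage but stays visible in
reports.  Pseudo-flagged CDS never count.

A step is covered when at least one alternative is present;
completeness = covered/total steps.  The consortium union covers a step
when any member covers it.  `jointly_complete` additionally tolerates a
whitelist of genes treated as host-complemented or consistently absent in
the clade (default `ilvA`, `hisN`, `yigB`); union completeness itself is
computed without the whitelist so consortia remain comparable.  Union
coverage is monotone in members, idempotent under duplication, and
whitelist enlargement can never turn `jointly_complete` off — all three
are property-tested, and union completeness is checked exhaustively
against a set-union oracle on all 2^15 presence patterns of a 3-genome ×
5-step instance.

## Pairwise comparisons

**Rotation normalization.**  Circular genomes may be deposited at
different start coordinates.  The offset of B relative to A is the modal
circular diagonal `(pos_A − pos_B) mod L` over k-mers unique in both
genomes (k = 17); ties break to the smallest offset.  For
substitution-only divergence this is the longest collinear anchor chain.

**SNP counting.**  After orientation detection (shared unique k-mers,
forward vs reverse complement) and rotation normalization, equal-length
pairs are compared column by column: a substitution is a column with two
differing unambiguous bases; columns involving ambiguity codes are tallied
separately.  Column-wise comparison is used deliberately instead of a
minimum-edit alignment, whose optima may swap two adjacent substitutions
for an insertion–deletion pair of equal cost.  Unequal-length pairs fall
back to edlib global alignment with extended CIGAR, counting gap runs as
indel events; pairs differing by more than 10% in length are rejected as
not a closed pair.

**16S identity.**  Global alignment with free terminal gaps (match +1,
mismatch −1, gap open −2, extend −0.5); identity = matches over aligned
columns, where terminal gap columns are excluded and internal gap columns
count in the denominator; orientation is auto-detected; rounding half away
from zero mirrors whole-percent reporting.

**ANI.**  OrthoANI-style: each genome is chopped into non-overlapping
1020-nt fragments (trailing remainder discarded; at least 5 fragments
required per genome); each fragment is placed in the other genome by best
semi-global (infix) alignment, searching across the origin for circular
targets; reciprocal best fragment pairs with coverage ≥ 0.7 contribute the
mean of their two identities; ANI is the mean over contributing pairs, and
is reported as undefined — not zero — when no pair qualifies.  Identity
here is edit-distance identity, so values can deviate by a small margin
(typically < 0.1 point at high similarity) from BLAST-based web
calculators.

**Orthologue sharing.**  Reciprocal best hits between proteomes, scored by
normalized edit similarity (1 − edit distance / max length) with
lexicographic tie-breaks; a deliberate simplification of scored local
alignment that is deterministic, fast, and exact on the planted 1:1 maps
it is tested against.  No orthogroup graph clustering is attempted.

**Genome statistics.**  Length, GC% (computed over unambiguous bases only,
one decimal, half away from zero), and CDS / pseudogene / rRNA / tRNA
counts.

## Synthetic genome generator

The generator emulates the statistical regime of reduced endosymbiont
chromosomes; defaults define the reference study conditions:

| parameter | default | rationale |
|---|---|---|
| `genome_length` | 150 000 nt | mid-range of 130–500 kb observed chromosomes |
| `gc_target` | 0.20 | the 18–27% GC regime |
| `n_genes` | 150 | ~150–180 CDS per reduced chromosome |
| `mean_gene_length` | 250 codons | ~750 nt mean CDS ⇒ ~85% coding density at these counts |
| `intergenic_mean` / `intergenic_min` | 120 / 40 nt | dense packing; see below |
| `split_stop_distribution` | TAA .55, TAG .09, TGA .36 | observed internal-stop usage of split genes |
| terminal stop usage | TAA .80, TAG .07, TGA .13 | observed intact-gene usage |

Sequence is sampled position-independently with nucleotide weights set by
`gc_target`; gene bodies are sampled codon-wise with in-frame stops
rejected and resampled (no mutation–selection model).  Because the three
stop codons are AT-rich, rejection raises realized GC slightly
(≈ +0.7 points at GC 20%), comfortably inside the guaranteed ±2-point
band, which is verified by direct counting.  Gene lengths are gamma
distributed (shape 6) with a 60-codon floor so every gene stays
splittable; layout feasibility is validated before any output.

The minimum intergenic spacer (40 nt) is above the detector's default
`max_gap` (30 nt) by construction: as noted above, a split gene and two
ORFs separated by a short in-frame spacer are geometrically
indistinguishable, so exact planted-truth recovery (precision = recall
= 1.0) is only a well-posed requirement when spacers exceed the gap
threshold.  Real genomes violate this — overlapping genes and operonic
spacing occur — which is precisely where homology evidence is needed.

Planting operations are substitution-only and truth-tracked: split
planting rewrites exactly one mid-gene codon (both halves ≥ 10 codons) to
a stop drawn from `split_stop_distribution` and replaces the feature with
two CDS halves, the first ending at (and including) the internal stop;
SNP planting places exactly n substitutions at distinct positions,
redrawing (bounded retries) any that would create or destroy an in-frame
stop inside a CDS, so split-gene truth survives; 16S pairs realize the
identity target exactly to one site in 1500.  Every operation consumes a
single explicit seed and is bit-reproducible across platforms (no
unordered iteration feeds the stream).

What the generator does *not* emulate — and what passing tests therefore
do not establish about real data: indels, rearrangements and
recombination; codon usage and amino-acid composition beyond AT bias;
operonic gene order and overlapping genes; rRNA/tRNA genes; sequencing or
assembly error.  In particular, exact SNP-count recovery holds for the
substitution-only model; on real pairs containing indels (as one deposited
pair does), substitution and indel counts are reported separately and
depend on alignment conventions.

## Problem sizes used in the shipped analyses

The automated checks run the generator at the reference regime (150 kb,
150 genes, 20 planted splits; 68-SNP pair; 1500-nt 16S pairs at 96%/84%)
and the stop-usage statistic at 1000 planted splits on a 1.3-Mb,
1100-gene genome, where observed group-2 frequencies sit within 3
percentage points of the planted distribution.  ANI checks use a 60-kb,
55-gene genome at 0.5% planted divergence (expected ANI ≈ 99.5).  The
analysis drivers simulate a three-member consortium (130/136/165 kb at
GC 26/19/18.5%) mirroring the two studied host species' consortia.

## Known limitations

- Split-gene detection on real annotations inherits PGAP's CDS calls; a
  second half re-annotated from an internal ATG at a distance > `max_gap`
  is missed, and abutting in-frame ORF pairs can be false positives
  (mitigable with the homology-table hook).
- Presence calling requires gene symbols in the annotation; unannotated
  or divergently named genes score absent.  The catalog transcription,
  not the code, carries the curation burden — disputes are data edits.
- ANI and RBH use edit-distance scoring, not substitution matrices; they
  are meant for the high-identity regime (> 90%) where the difference is
  negligible.
- The consortium union model is purely presence-based: no expression,
  flux, or metabolite exchange is modelled.
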