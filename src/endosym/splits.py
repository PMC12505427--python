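"""Split-gene detection and stop-codon usage statistics.

In heavily eroded endosymbiont genomes, annotation pipelines frequently
report a gene as two adjacent CDS because a single in-frame internal stop
codon interrupts the ORF.  Merging the two halves restores one reading frame
whose translation contains exactly one internal stop — the geometric
signature this module detects, without recourse to homology searches.

Stop codons are then tallied for three groups of genes: (1) terminal stops
of intact genes, (2) the internal stop of each split gene (the first half's
terminal stop), and (3) the terminal stop of each split gene's second half.
A shift toward TGA among internal stops relative to intact genes bears on
the question of stop-codon repurposing in AT-rich reduced genomes; this
module reports the frequencies and draws no inference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .genome_io import (
    CdsFeature,
    FeatureSet,
    NucleotideGenome,
    STOP_CODONS,
    extract_cds,
    translate,
)

logger = logging.getLogger(__name__)

DEFAULT_MAX_GAP = 30         # nt between halves in coding orientation
DEFAULT_MIN_HALF = 10        # codons per half

_STOP_ORDER = ("TAA", "TAG", "TGA")


class AnnotationError(ValueError):
    pass


@dataclass
class SplitCandidate:
    """An adjacent same-strand CDS pair whose merged span is one ORF with
    exactly one internal stop."""

    first: CdsFeature
    second: CdsFeature
    gap_nt: int
    merged_interval: tuple[int, int]       # genomic span, 0-based half-open
    internal_stop_codon: str
    internal_stop_codon_index: int         # 0-based codon index in merged ORF
    merged_locus_tag: str

    @property
    def strand(self) -> str:
        return self.first.strand


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (matching printed integer percentages)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _merged_feature(first: CdsFeature, second: CdsFeature) -> CdsFeature:
    lo = min(first.start, second.start)
    hi = max(first.end, second.end)
    return CdsFeature(
        genome_id=first.genome_id, segments=[(lo, hi)], strand=first.strand,
        locus_tag=first.locus_tag + "_merged",
        gene_symbol=first.gene_symbol or second.gene_symbol,
        product=first.product,
    )


def _evaluate_pair(genome: NucleotideGenome, a: CdsFeature, b: CdsFeature,
                   max_gap: int, min_half: int) -> SplitCandidate | None:
    """Test pair (a, b) where b is the next CDS downstream of a in coding
    orientation; return a candidate or None."""
    if a.strand != b.strand:
        return None
    if len(a.segments) != 1 or len(b.segments) != 1:
        return None
    if a.strand == "+":
        gap = b.start - a.end
    else:
        gap = a.start - b.end
    if gap < 0 or gap > max_gap:
        return None
    span = a.length + gap + b.length
    if span % 3:
        return None

    merged = _merged_feature(a, b)
    protein, internal = translate(extract_cds(genome, merged))
    if len(internal) != 1:
        return None
    idx, codon = internal[0]
    # The single internal stop must sit at/after a's annotated stop codon and
    # before b's first codon (all in merged-frame codon coordinates).
    lo = (a.length - 3) // 3
    hi = (a.length + gap) // 3
    if not (lo <= idx < max(hi, lo + 1)):
        return None
    first_half_codons = idx + 1
    second_half_codons = span // 3 - first_half_codons
    if first_half_codons < min_half or second_half_codons < min_half:
        return None
    return SplitCandidate(
        first=a, second=b, gap_nt=gap,
        merged_interval=(merged.start, merged.end),
        internal_stop_codon=codon, internal_stop_codon_index=idx,
        merged_locus_tag=merged.locus_tag,
    )


def _check_annotation(cds: list[CdsFeature]) -> None:
    by_strand: dict[str, list[CdsFeature]] = {"+": [], "-": []}
    for f in cds:
        if len(f.segments) == 1:
            by_strand[f.strand].append(f)
    offenders = []
    for strand, feats in by_strand.items():
        feats.sort(key=lambda f: f.start)
        for prev, cur in zip(feats, feats[1:]):
            if cur.start < prev.end:
                offenders.append((prev.locus_tag, cur.locus_tag))
    if offenders:
        raise AnnotationError(f"overlapping same-strand CDS: {offenders}")


def find_split_candidates(
    genome: NucleotideGenome,
    features: FeatureSet,
    max_gap: int = DEFAULT_MAX_GAP,
    min_half_length: int = DEFAULT_MIN_HALF,
) -> list[SplitCandidate]:
    """Detect adjacent CDS pairs that merge into a single in-frame ORF
    interrupted by exactly one internal stop.

    Pairing is a greedy left-to-right partial matching in coding
    orientation; when a middle fragment could pair either way the smaller
    gap wins.  Each CDS participates in at most one candidate.  Chains of
    three or more fragments are reduced to successive pairs and logged.
    """
    cds = [f for f in features.cds() if len(f.segments) == 1]
    _check_annotation(cds)

    candidates: list[SplitCandidate] = []
    for strand in ("+", "-"):
        feats = [f for f in cds if f.strand == strand]
        feats.sort(key=lambda f: f.start, reverse=(strand == "-"))
        used: set[str] = set()
        i = 0
        while i + 1 < len(feats):
            a, b = feats[i], feats[i + 1]
            if a.locus_tag in used:
                i += 1
                continue
            cand = _evaluate_pair(genome, a, b, max_gap, min_half_length)
            if cand is None:
                i += 1
                continue
            if i + 2 < len(feats):
                nxt = _evaluate_pair(genome, b, feats[i + 2], max_gap, min_half_length)
                if nxt is not None and nxt.gap_nt < cand.gap_nt:
                    logger.info(
                        "fragment chain at %s: preferring smaller-gap pair %s",
                        b.locus_tag, nxt.merged_locus_tag)
                    i += 1
                    continue
            candidates.append(cand)
            used.update({a.locus_tag, b.locus_tag})
            i += 2
    candidates.sort(key=lambda c: c.merged_interval)
    return candidates


MERGED_COLUMNS = [
    "merged_locus_tag", "start", "end", "strand",
    "internal_stop_codon", "internal_stop_codon_index",
    "first_locus_tag", "second_locus_tag",
]


def write_merged_annotation(candidates: list[SplitCandidate]) -> pd.DataFrame:
    """Merged-gene annotation table (1-based inclusive coordinates, 1-based
    internal-stop codon index), one row per merged gene."""
    rows = []
    for c in candidates:
        lo, hi = c.merged_interval
        rows.append({
            "merged_locus_tag": c.merged_locus_tag,
            "start": lo + 1,
            "end": hi,
            "strand": c.strand,
            "internal_stop_codon": c.internal_stop_codon,
            "internal_stop_codon_index": c.internal_stop_codon_index + 1,
            "first_locus_tag": c.first.locus_tag,
            "second_locus_tag": c.second.locus_tag,
        })
    return pd.DataFrame(rows, columns=MERGED_COLUMNS)


@dataclass
class StopUsageTable:
    """Stop-codon counts and rounded integer percentages for the three
    gene groups."""

    counts: dict[str, dict[str, int]]
    n_excluded_no_stop: int = 0
    excluded_tags: list[str] = field(default_factory=list)

    GROUPS = ("group1_intact_terminal", "group2_internal", "group3_second_half_terminal")

    def percent(self, group: str) -> dict[str, int]:
        total = sum(self.counts[group].values())
        if total == 0:
            return {c: 0 for c in _STOP_ORDER}
        return {
            c: int(round_half_up(100.0 * self.counts[group][c] / total))
            for c in _STOP_ORDER
        }

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.GROUPS:
            pct = self.percent(g)
            for c in _STOP_ORDER:
                rows.append({"group": g, "codon": c,
                             "count": self.counts[g][c], "percent": pct[c]})
        return pd.DataFrame(rows)


def stop_usage(
    genome: NucleotideGenome,
    features: FeatureSet,
    candidates: list[SplitCandidate],
    include_pseudo: bool = False,
) -> StopUsageTable:
    """Tally terminal/internal stop codons for intact genes (group 1), split
    genes' internal stops (group 2) and split genes' second-half terminal
    stops (group 3).

    CDS not ending in a stop codon (annotation truncations) are excluded
    from group 1 and counted in ``n_excluded_no_stop``.  Features flagged
    pseudo are excluded from group 1 unless ``include_pseudo``.
    """
    in_candidate = {c.first.locus_tag for c in candidates} | \
                   {c.second.locus_tag for c in candidates}
    counts = {g: {c: 0 for c in _STOP_ORDER} for g in StopUsageTable.GROUPS}
    table = StopUsageTable(counts=counts)

    for f in features.cds(include_pseudo=include_pseudo):
        if f.locus_tag in in_candidate:
            continue
        seq = extract_cds(genome, f)
        if len(seq) % 3:
            table.n_excluded_no_stop += 1
            table.excluded_tags.append(f.locus_tag)
            continue
        last = seq[-3:]
        if last in STOP_CODONS:
            counts["group1_intact_terminal"][last] += 1
        else:
            table.n_excluded_no_stop += 1
            table.excluded_tags.append(f.locus_tag)

    for c in candidates:
        counts["group2_internal"][c.internal_stop_codon] += 1
        second_seq = extract_cds(genome, c.second)
        last = second_seq[-3:]
        if len(second_seq) % 3 == 0 and last in STOP_CODONS:
            counts["group3_second_half_terminal"][last] += 1
        else:
            table.n_excluded_no_stop += 1
            table.excluded_tags.append(c.second.locus_tag)
    return table
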