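"""Pairwise genome and marker comparisons.

Covers the comparisons used to characterise near-identical endosymbiont
genome pairs and their taxonomic placement: circularity-aware SNP counting
(rotation-normalized global alignment), 16S rRNA percent identity
(end-gap-free global alignment), an OrthoANI-style average nucleotide
identity over reciprocal best 1020-nt fragments, reciprocal-best-hit
orthologue sharing between proteomes, and per-genome summary statistics.

Alignment machinery: edlib (edit-distance alignments with extended CIGAR)
for genome-scale work, Biopython's PairwiseAligner for the scored 16S
global alignment.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import edlib
from Bio import Align

from .genome_io import (
    FeatureSet,
    NucleotideGenome,
    UNAMBIGUOUS,
    extract_cds,
    translate,
)
from .splits import round_half_up

_COMP = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


class ComparisonError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Rotation normalization for circular genomes

def _unique_kmers(seq: str, k: int) -> dict[str, int]:
    pos: dict[str, int] = {}
    dup: set[str] = set()
    for i in range(len(seq) - k + 1):
        km = seq[i:i + k]
        if km in dup:
            continue
        if km in pos:
            del pos[km]
            dup.add(km)
        else:
            pos[km] = i
    return pos


def rotate_align(a: NucleotideGenome, b: NucleotideGenome, anchor_k: int = 17) -> int:
    """Rotation offset of ``b`` relative to ``a``: the modal diagonal of
    shared unique anchor k-mers on the circle (the longest collinear chain
    for substitution-only divergence).  ``rotate(a, offset)`` aligns with
    ``b``; ties break to the smallest offset."""
    if abs(len(a) - len(b)) > 0.1 * max(len(a), len(b)):
        raise ComparisonError("genomes differ in length by more than 10%")
    ka = _unique_kmers(a.sequence, anchor_k)
    kb = _unique_kmers(b.sequence, anchor_k)
    L = len(a.sequence)
    votes = Counter()
    for km, ia in ka.items():
        ib = kb.get(km)
        if ib is not None:
            votes[(ia - ib) % L] += 1
    if not votes:
        raise ComparisonError(
            "no shared anchor k-mers; genomes may be unrelated or linear "
            "alignment mode is needed")
    best = max(votes.values())
    return min(off for off, v in votes.items() if v == best)


def rotate(seq: str, n: int) -> str:
    n %= len(seq)
    return seq[n:] + seq[:n]


def _orient(a: str, b: str, k: int = 15) -> tuple[str, bool]:
    """Return b in the orientation sharing more unique k-mers with a."""
    ka = set(_unique_kmers(a, k))
    fwd = len(ka & set(_unique_kmers(b, k)))
    rc = revcomp(b)
    rev = len(ka & set(_unique_kmers(rc, k)))
    return (rc, True) if rev > fwd else (b, False)


# ---------------------------------------------------------------------------
# SNP counting

@dataclass
class SnpReport:
    n_substitutions: int
    positions: list[int]
    n_indel_events: int
    n_ambiguous_columns: int
    rotation_offset: int


def count_snps(a: NucleotideGenome, b: NucleotideGenome, anchor_k: int = 17) -> SnpReport:
    """Substitutions between a closed genome pair.

    Both genomes are rotation-normalized first (circular pairs may be
    deposited at different start coordinates).  Substitutions are aligned
    columns with differing unambiguous bases; gap runs are counted as indel
    events; columns involving an ambiguity code are tallied separately."""
    if abs(len(a) - len(b)) > 0.1 * max(len(a), len(b)):
        raise ComparisonError(
            f"length difference {abs(len(a) - len(b))} exceeds 10%: not a closed pair")
    bseq, _ = _orient(a.sequence, b.sequence)
    offset = 0
    if a.circular and b.circular:
        b_g = NucleotideGenome(b.id, bseq, circular=True)
        offset = rotate_align(a, b_g, anchor_k)
        bseq = rotate(bseq, -offset % len(bseq))

    if len(bseq) == len(a.sequence):
        # Equal-length closed pair: column-wise comparison is exact and free
        # of the substitution/indel ambiguity of minimum-edit alignments.
        qa, ta = bseq, a.sequence
    else:
        res = edlib.align(bseq, a.sequence, mode="NW", task="path")
        nice = edlib.getNiceAlignment(res, bseq, a.sequence)
        qa, ta = nice["query_aligned"], nice["target_aligned"]

    positions: list[int] = []
    n_ambig = 0
    n_indel = 0
    in_gap = False
    apos = 0
    for cb, ca in zip(qa, ta):
        if cb == "-" or ca == "-":
            if not in_gap:
                n_indel += 1
                in_gap = True
            if ca != "-":
                apos += 1
            continue
        in_gap = False
        if ca != cb:
            if ca in UNAMBIGUOUS and cb in UNAMBIGUOUS:
                positions.append(apos)
            else:
                n_ambig += 1
        apos += 1
    return SnpReport(
        n_substitutions=len(positions), positions=positions,
        n_indel_events=n_indel, n_ambiguous_columns=n_ambig,
        rotation_offset=offset,
    )


# ---------------------------------------------------------------------------
# 16S identity

@dataclass
class IdentityResult:
    matches: int
    aligned_columns: int
    identity_percent: float
    identity_rounded: int


def identity_16s(x: str, y: str, min_length: int = 1200) -> IdentityResult:
    """Percent identity between two (near-complete) 16S rRNA genes.

    Global alignment with free terminal gaps; identity = matches over
    aligned columns with terminal gap columns excluded and internal gap
    columns counted in the denominator.  Orientation is auto-detected.
    Sequences shorter than ``min_length`` are still compared (warning-level
    situation left to the caller's logging)."""
    x, y = x.upper(), y.upper()
    y, _ = _orient(x, y, k=11)
    aligner = Align.PairwiseAligner(
        mode="global", match_score=1, mismatch_score=-1,
        open_gap_score=-2, extend_gap_score=-0.5,
    )
    aligner.end_insertion_score = 0  # terminal gaps free (semi-global)
    aligner.end_deletion_score = 0
    aln = aligner.align(x, y)[0]
    sx, sy = str(aln[0]), str(aln[1])
    start = 0
    end = len(sx)
    while start < end and (sx[start] == "-" or sy[start] == "-"):
        start += 1
    while end > start and (sx[end - 1] == "-" or sy[end - 1] == "-"):
        end -= 1
    matches = sum(1 for i in range(start, end) if sx[i] == sy[i] and sx[i] != "-")
    cols = end - start
    pct = 100.0 * matches / cols if cols else 0.0
    return IdentityResult(matches, cols, pct, int(round_half_up(pct)))


# ---------------------------------------------------------------------------
# ANI

@dataclass
class AniResult:
    ani_percent: float | None
    n_fragment_pairs: int
    fragment_length: int

    @property
    def defined(self) -> bool:
        return self.ani_percent is not None


def _fragment_hits(frags: list[str], target: str, circular: bool,
                   fragment_length: int) -> list[tuple[int, float, float]]:
    """Best semi-global hit of each fragment in the target genome: returns
    (target fragment index, identity fraction, coverage fraction)."""
    search = target + target[:fragment_length] if circular else target
    hits = []
    for frag in frags:
        res = edlib.align(frag, search, mode="HW", task="locations")
        loc = res["locations"][0]
        hit_len = loc[1] - loc[0] + 1
        aln_len = max(len(frag), hit_len)
        ident = 1.0 - res["editDistance"] / aln_len
        cov = min(len(frag), hit_len) / max(len(frag), hit_len)
        center = ((loc[0] + loc[1]) // 2) % len(target)
        hits.append((center // fragment_length, ident, cov))
    return hits


def ani(a: NucleotideGenome, b: NucleotideGenome,
        fragment_length: int = 1020, min_coverage: float = 0.7) -> AniResult:
    """OrthoANI-style average nucleotide identity.

    Both genomes are chopped into non-overlapping fragments (the trailing
    remainder is discarded); each fragment is placed in the other genome by
    best semi-global alignment, and identity is averaged over reciprocal
    best fragment pairs with coverage >= ``min_coverage``.  Undefined (not
    zero) when no pair qualifies."""
    if fragment_length > min(len(a), len(b)):
        raise ComparisonError("fragment_length exceeds a genome length")
    bseq, _ = _orient(a.sequence, b.sequence)
    frags_a = [a.sequence[i:i + fragment_length]
               for i in range(0, len(a) - fragment_length + 1, fragment_length)]
    frags_b = [bseq[i:i + fragment_length]
               for i in range(0, len(b) - fragment_length + 1, fragment_length)]
    if len(frags_a) < 5 or len(frags_b) < 5:
        raise ComparisonError("fewer than 5 fragments per genome")
    hits_ab = _fragment_hits(frags_a, bseq, b.circular, fragment_length)
    hits_ba = _fragment_hits(frags_b, a.sequence, a.circular, fragment_length)

    identities = []
    for i, (j, id_ab, cov_ab) in enumerate(hits_ab):
        if j >= len(frags_b):
            continue
        j_back, id_ba, cov_ba = hits_ba[j]
        if j_back == i and cov_ab >= min_coverage and cov_ba >= min_coverage:
            identities.append((id_ab + id_ba) / 2)
    if not identities:
        return AniResult(None, 0, fragment_length)
    return AniResult(100.0 * sum(identities) / len(identities),
                     len(identities), fragment_length)


# ---------------------------------------------------------------------------
# Reciprocal best hits

@dataclass
class RbhResult:
    pairs: list[tuple[str, str]]
    unique_a: list[str]
    unique_b: list[str]

    @property
    def n_shared(self) -> int:
        return len(self.pairs)


def _best_hits(pa: dict[str, str], pb: dict[str, str]) -> dict[str, str]:
    best: dict[str, str] = {}
    for ta, sa in pa.items():
        scored = []
        for tb, sb in pb.items():
            d = edlib.align(sa, sb, mode="NW", task="distance")["editDistance"]
            sim = 1.0 - d / max(len(sa), len(sb), 1)
            scored.append((-sim, tb))
        scored.sort()  # highest similarity, then lexicographic tag
        best[ta] = scored[0][1]
    return best


def rbh_orthologues(proteome_a: dict[str, str], proteome_b: dict[str, str]) -> RbhResult:
    """Reciprocal best hits between two proteomes (similarity = 1 - edit
    distance / max length; ties break to the lexicographically smaller
    locus_tag).  A proxy for 1:1 orthology; no graph clustering."""
    if not proteome_a or not proteome_b:
        raise ComparisonError("empty proteome")
    ab = _best_hits(proteome_a, proteome_b)
    ba = _best_hits(proteome_b, proteome_a)
    pairs = sorted((ta, tb) for ta, tb in ab.items() if ba.get(tb) == ta)
    in_a = {ta for ta, _ in pairs}
    in_b = {tb for _, tb in pairs}
    return RbhResult(
        pairs=pairs,
        unique_a=sorted(set(proteome_a) - in_a),
        unique_b=sorted(set(proteome_b) - in_b),
    )


def proteome(genome: NucleotideGenome, features: FeatureSet) -> dict[str, str]:
    """Translate all non-pseudo CDS (internal stops rendered as ``*``)."""
    out = {}
    for f in features.cds(include_pseudo=False):
        seq = extract_cds(genome, f)
        if len(seq) % 3:
            continue
        out[f.locus_tag] = translate(seq)[0]
    return out


# ---------------------------------------------------------------------------
# Genome statistics

@dataclass
class GenomeStats:
    length: int
    gc_percent: float
    n_cds: int
    n_pseudo: int
    n_rrna: int
    n_trna: int


def genome_stats(genome: NucleotideGenome, features: FeatureSet) -> GenomeStats:
    """Summary statistics as printed in genome tables: length, GC% over
    unambiguous bases to one decimal, and feature counts."""
    cds = [f for f in features.features if f.kind == "CDS"]
    return GenomeStats(
        length=len(genome),
        gc_percent=round_half_up(100.0 * genome.gc_fraction, 1),
        n_cds=sum(1 for f in cds if not f.pseudo),
        n_pseudo=sum(1 for f in cds if f.pseudo),
        n_rrna=sum(1 for f in features.features if f.kind == "rRNA"),
        n_trna=sum(1 for f in features.features if f.kind == "tRNA"),
    )
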