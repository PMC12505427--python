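"""Genome and annotation I/O for reduced bacterial genomes.

Sequences are held as plain uppercase IUPAC-DNA strings.  All internal
coordinates are 0-based half-open; the GFF3/GenBank/TSV readers and writers
convert from/to the 1-based inclusive convention at the file boundary.
Circular genomes are first-class: a feature spanning the replication origin
is normalized to a two-segment representation.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

from Bio import SeqIO
from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import reverse_complement

IUPAC_DNA = frozenset("ACGTRYSWKMBDHVN")
UNAMBIGUOUS = frozenset("ACGT")
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

_CODON_TABLE_CACHE: dict[int, dict[str, str]] = {}


class FormatError(ValueError):
    """Malformed input file (names the record and offset where possible)."""


@dataclass
class NucleotideGenome:
    """A (possibly circular) DNA sequence with identity and provenance."""

    id: str
    sequence: str
    circular: bool = False
    description: str = ""

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if len(self.sequence) < 1:
            raise FormatError(f"genome {self.id!r}: empty sequence")
        bad = set(self.sequence) - IUPAC_DNA
        if bad:
            offset = next(i for i, c in enumerate(self.sequence) if c in bad)
            raise FormatError(
                f"genome {self.id!r}: non-IUPAC character {self.sequence[offset]!r} "
                f"at offset {offset}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def gc_fraction(self) -> float:
        """GC over unambiguous bases only (ambiguity codes excluded from
        numerator and denominator)."""
        gc = sum(self.sequence.count(b) for b in "GC")
        at = sum(self.sequence.count(b) for b in "AT")
        if gc + at == 0:
            return 0.0
        return gc / (gc + at)


@dataclass
class CdsFeature:
    """A stranded coding interval; may span the origin as two segments.

    ``segments`` are ordered 5'→3' in coding orientation: for a minus-strand
    feature the first segment is the genomically rightmost one.
    """

    genome_id: str
    segments: list[tuple[int, int]]
    strand: str
    locus_tag: str
    gene_symbol: str | None = None
    product: str | None = None
    pseudo: bool = False
    kind: str = "CDS"

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.locus_tag}: strand must be '+' or '-'")
        if not self.segments:
            raise ValueError(f"{self.locus_tag}: no segments")
        for s, e in self.segments:
            if not s < e:
                raise ValueError(f"{self.locus_tag}: segment ({s},{e}) has start >= end")
        if self.kind == "CDS" and self.length < 3:
            raise ValueError(f"{self.locus_tag}: coding length {self.length} < 3")

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.segments)

    @property
    def start(self) -> int:
        """Leftmost genomic coordinate."""
        return min(s for s, _ in self.segments)

    @property
    def end(self) -> int:
        """Rightmost genomic coordinate (exclusive)."""
        return max(e for _, e in self.segments)


@dataclass
class FeatureSet:
    genome_id: str
    features: list[CdsFeature] = field(default_factory=list)
    source: str = "memory"

    def __post_init__(self) -> None:
        tags = [f.locus_tag for f in self.features]
        if len(tags) != len(set(tags)):
            dup = sorted({t for t in tags if tags.count(t) > 1})
            raise FormatError(f"duplicate locus_tags in feature set: {dup}")
        for f in self.features:
            if f.genome_id != self.genome_id:
                raise FormatError(
                    f"feature {f.locus_tag} references genome {f.genome_id!r}, "
                    f"set is for {self.genome_id!r}"
                )

    def cds(self, include_pseudo: bool = True) -> list[CdsFeature]:
        return [
            f for f in self.features
            if f.kind == "CDS" and (include_pseudo or not f.pseudo)
        ]


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[NucleotideGenome]:
    """Read a multi-record FASTA; circularity from a ``circular=true`` header
    keyword (default linear).  Ids must be unique."""
    path = Path(path)
    genomes: list[NucleotideGenome] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip()
        circular = "circular=true" in desc.lower()
        genomes.append(
            NucleotideGenome(rec.id, str(rec.seq), circular=circular, description=desc)
        )
    if not genomes:
        raise FormatError(f"{path}: no FASTA records")
    return genomes


def write_fasta(genomes: Iterable[NucleotideGenome], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for g in genomes:
            desc = g.description
            if g.circular and "circular=true" not in desc:
                desc = ("circular=true " + desc).strip()
            header = f">{g.id} {desc}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(g.sequence), width):
                fh.write(g.sequence[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Feature tables

TSV_COLUMNS = ["genome_id", "locus_tag", "start", "end", "strand", "gene", "product", "pseudo"]


def _wrap_segments(start0: int, end0: int, genome_length: int | None,
                   circular: bool, tag: str) -> list[tuple[int, int]]:
    """Normalize a possibly origin-spanning interval to explicit segments."""
    if genome_length is None or end0 <= genome_length:
        return [(start0, end0)]
    if not circular:
        raise FormatError(
            f"feature {tag}: end {end0} beyond linear genome length {genome_length}"
        )
    return [(start0, genome_length), (0, end0 - genome_length)]


def read_features(path: str | Path, dialect: str,
                  genome_length: int | None = None,
                  circular: bool = False) -> FeatureSet:
    """Read CDS (and rRNA/tRNA where the format carries them) annotations.

    ``dialect`` is one of ``gff3``, ``genbank``, ``tsv``.  File coordinates
    are 1-based inclusive and converted to 0-based half-open here.
    """
    path = Path(path)
    if dialect == "tsv":
        return _read_tsv(path, genome_length, circular)
    if dialect == "gff3":
        return _read_gff3(path, genome_length, circular)
    if dialect == "genbank":
        return _read_genbank(path)
    raise ValueError(f"unsupported feature dialect {dialect!r}")


def _read_tsv(path: Path, genome_length: int | None, circular: bool) -> FeatureSet:
    features: list[CdsFeature] = []
    genome_id = None
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            gid = row["genome_id"]
            genome_id = genome_id or gid
            start0 = int(row["start"]) - 1
            end0 = int(row["end"])
            strand = row["strand"]
            segs = _wrap_segments(start0, end0, genome_length, circular, row["locus_tag"])
            if strand == "-":
                segs = segs[::-1]
            features.append(CdsFeature(
                genome_id=gid,
                segments=segs,
                strand=strand,
                locus_tag=row["locus_tag"],
                gene_symbol=row.get("gene") or None,
                product=row.get("product") or None,
                pseudo=str(row.get("pseudo", "")).strip().lower() in {"true", "1", "yes"},
                kind=row.get("kind", "CDS") or "CDS",
            ))
    if genome_id is None:
        raise FormatError(f"{path}: no feature rows")
    return FeatureSet(genome_id=genome_id, features=features, source="tsv")


def write_features_tsv(fs: FeatureSet, path: str | Path) -> None:
    """Write the TSV dialect (1-based inclusive coordinates).

    Origin-wrapped two-segment features are written as a single row whose end
    exceeds the genome length, mirroring how they are read back."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(TSV_COLUMNS + ["kind"])
        for f in fs.features:
            segs = f.segments if f.strand == "+" else f.segments[::-1]
            if len(segs) == 2 and segs[1][0] == 0:  # origin wrap
                start0, end0 = segs[0][0], segs[0][1] + segs[1][1]
            else:
                start0, end0 = segs[0][0], segs[-1][1]
            writer.writerow([
                f.genome_id, f.locus_tag, start0 + 1, end0, f.strand,
                f.gene_symbol or "", f.product or "",
                "true" if f.pseudo else "false", f.kind,
            ])


_GFF_KIND = {"CDS": "CDS", "rRNA": "rRNA", "tRNA": "tRNA"}


def _read_gff3(path: Path, genome_length: int | None, circular: bool) -> FeatureSet:
    features: list[CdsFeature] = []
    genome_id = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF3 columns")
            seqid, _src, ftype, start, end, _score, strand, _phase, attrs = cols
            if ftype not in _GFF_KIND:
                continue
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            tag = attr.get("locus_tag") or attr.get("ID") or f"{path.stem}_{lineno}"
            segs = _wrap_segments(int(start) - 1, int(end), genome_length, circular, tag)
            if strand == "-":
                segs = segs[::-1]
            genome_id = genome_id or seqid
            features.append(CdsFeature(
                genome_id=seqid, segments=segs, strand=strand, locus_tag=tag,
                gene_symbol=attr.get("gene"), product=attr.get("product"),
                pseudo="pseudo" in attr or attr.get("pseudogene") is not None,
                kind=_GFF_KIND[ftype],
            ))
    if genome_id is None:
        raise FormatError(f"{path}: no CDS/rRNA/tRNA features")
    return FeatureSet(genome_id=genome_id, features=features, source="gff3")


def _read_genbank(path: Path) -> FeatureSet:
    """GenBank flat-file parsing limited to CDS/rRNA/tRNA features."""
    recs = list(SeqIO.parse(str(path), "genbank"))
    if not recs:
        raise FormatError(f"{path}: no GenBank records")
    rec = recs[0]
    features: list[CdsFeature] = []
    counter = 0
    for feat in rec.features:
        if feat.type not in _GFF_KIND:
            continue
        counter += 1
        strand = "-" if feat.location.strand == -1 else "+"
        segs = [(int(p.start), int(p.end)) for p in feat.location.parts]
        # Biopython lists parts 5'→3' already; ensure coding orientation.
        if strand == "-" and len(segs) > 1 and segs[0][0] < segs[-1][0]:
            segs = segs[::-1]
        q = feat.qualifiers
        features.append(CdsFeature(
            genome_id=rec.id,
            segments=segs,
            strand=strand,
            locus_tag=q.get("locus_tag", [f"{rec.id}_{counter}"])[0],
            gene_symbol=q.get("gene", [None])[0],
            product=q.get("product", [None])[0],
            pseudo="pseudo" in q or "pseudogene" in q,
            kind=feat.type,
        ))
    return FeatureSet(genome_id=rec.id, features=features, source="genbank")


# ---------------------------------------------------------------------------
# Sequence operations

def extract_cds(genome: NucleotideGenome, f: CdsFeature) -> str:
    """Concatenated, strand-oriented coding sequence of a feature."""
    if f.genome_id != genome.id:
        raise ValueError(f"feature {f.locus_tag} does not reference genome {genome.id}")
    parts = []
    for s, e in (f.segments if f.strand == "+" else f.segments[::-1]):
        if e > len(genome.sequence):
            raise ValueError(
                f"feature {f.locus_tag}: segment ({s},{e}) outside genome of "
                f"length {len(genome.sequence)}"
            )
        parts.append(genome.sequence[s:e])
    seq = "".join(parts)
    if f.strand == "-":
        seq = reverse_complement(seq)
    return seq


class InternalStop(NamedTuple):
    codon_index: int  # 0-based within the ORF
    codon: str        # TAA / TAG / TGA


class TranslationError(ValueError):
    def __init__(self, remainder: int):
        self.remainder = remainder
        super().__init__(f"CDS length not divisible by 3 (remainder {remainder})")


def _codon_map(table_id: int) -> dict[str, str]:
    if table_id not in _CODON_TABLE_CACHE:
        _CODON_TABLE_CACHE[table_id] = dict(unambiguous_dna_by_id[table_id].forward_table)
    return _CODON_TABLE_CACHE[table_id]


def translate(cds: str, table: int = 11) -> tuple[str, list[InternalStop]]:
    """Translate a CDS under the bacterial code (table 11 by default).

    Returns the protein (internal stops shown as ``*``, terminal stop
    omitted) and the list of internal stops with their 0-based codon index.
    Codons containing ambiguity codes translate to ``X``.
    """
    cds = cds.upper()
    if len(cds) % 3:
        raise TranslationError(len(cds) % 3)
    fwd = _codon_map(table)
    n_codons = len(cds) // 3
    aa: list[str] = []
    internal: list[InternalStop] = []
    for i in range(n_codons):
        codon = cds[3 * i: 3 * i + 3]
        if codon in STOP_CODONS:
            if i == n_codons - 1:
                continue  # terminal stop, not part of the protein
            internal.append(InternalStop(i, codon))
            aa.append("*")
        else:
            aa.append(fwd.get(codon, "X"))
    return "".join(aa), internal
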