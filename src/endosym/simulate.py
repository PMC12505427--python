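"""Truth-tracked synthetic endosymbiont genomes.

Emulates the genomic regime of obligate planthopper endosymbionts: small
(130-500 kb) circular chromosomes, extreme AT richness (18-27% GC), densely
packed single-exon CDS, genes split in two halves by a single in-frame
internal stop codon, near-identical genome pairs differing by a known number
of substitutions, and 16S rRNA pairs at a target percent identity.  Every
planted artifact is recorded in a :class:`SimulatedTruth` so the analysis
modules can be tested for exact recovery.

Codons are sampled position-independently with nucleotide weights matching
the GC target; in-frame stops are rejected and resampled.  No indels,
recombination or tree-based evolution are simulated.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .genome_io import (
    CdsFeature,
    FeatureSet,
    NucleotideGenome,
    STOP_CODONS,
    extract_cds,
    write_fasta,
    write_features_tsv,
)

BASES = np.array(list("ACGT"))
_STOPS = ("TAA", "TAG", "TGA")
# Terminal stop usage of intact genes defaults to the distribution observed
# in AT-rich reduced genomes (TAA-dominated).
DEFAULT_TERMINAL_STOP_DIST = (0.80, 0.07, 0.13)
# Internal stops of split genes are planted, by default, at the frequencies
# observed for split-gene internal stops (TAA 55%, TAG 9%, TGA 36%).
DEFAULT_SPLIT_STOP_DIST = (0.55, 0.09, 0.36)


class SimulationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Parameters of one synthetic genome.

    Lengths are nucleotides except ``mean_gene_length`` (codons).  Defaults
    mirror a mid-sized reduced endosymbiont chromosome: 150 kb, 20% GC,
    150 genes averaging 250 codons (~85% coding density).
    """

    seed: int = 0
    genome_length: int = 150_000
    gc_target: float = 0.20
    n_genes: int = 150
    mean_gene_length: int = 250
    intergenic_mean: int = 120
    n_split_genes: int = 0
    split_stop_distribution: tuple[float, float, float] = DEFAULT_SPLIT_STOP_DIST
    pathway_assignment: dict[str, list[str]] = field(default_factory=dict)
    n_snps_pair: int = 0
    target_16s_identity: float = 1.0
    genome_id: str = "sim"
    min_gene_length: int = 60   # codons; keeps every gene splittable
    # Minimum intergenic spacer.  Two complete ORFs separated by a short
    # in-frame spacer are geometrically indistinguishable from a split gene
    # (the paper-style resolution is homology evidence, which is out of
    # scope), so spacers stay above the detector's default max_gap.
    intergenic_min: int = 40

    def validate(self) -> None:
        if not 0 < self.gc_target < 1:
            raise SimulationError("gc_target must be in (0,1)")
        if abs(sum(self.split_stop_distribution) - 1.0) > 1e-9:
            raise SimulationError("split_stop_distribution must sum to 1")
        if self.n_split_genes > self.n_genes:
            raise SimulationError("n_split_genes exceeds n_genes")
        if not 0 < self.target_16s_identity <= 1:
            raise SimulationError("target_16s_identity must be in (0,1]")


@dataclass
class SimulatedTruth:
    """Ground truth of planted artifacts, for recovery tests."""

    split_records: list[tuple[str, str, int]] = field(default_factory=list)
    snp_positions: list[int] = field(default_factory=list)
    planted_genes: dict[str, set[str]] = field(default_factory=dict)
    achieved_gc: float = 0.0

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["planted_genes"] = {k: sorted(v) for k, v in self.planted_genes.items()}
        return json.dumps(d, indent=1)


def _nt_weights(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def _random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    return "".join(BASES[rng.choice(4, size=n, p=_nt_weights(gc))])


def _random_codons(rng: np.random.Generator, n: int, gc: float) -> str:
    """n sense codons, AT-biased, stop codons rejected and resampled."""
    out: list[str] = []
    w = _nt_weights(gc)
    while len(out) < n:
        batch = BASES[rng.choice(4, size=(n - len(out) + 8, 3), p=w)]
        for row in batch:
            codon = "".join(row)
            if codon not in STOP_CODONS:
                out.append(codon)
                if len(out) == n:
                    break
    return "".join(out)


def _sample_stop(rng: np.random.Generator, dist) -> str:
    return _STOPS[rng.choice(3, p=np.asarray(dist, dtype=float))]


def simulate_genome(config: SimulationConfig) -> tuple[NucleotideGenome, FeatureSet, SimulatedTruth]:
    """Generate a circular genome with densely packed intact ORFs.

    Deterministic given ``config.seed``.  Gene symbols listed in
    ``config.pathway_assignment`` are attached to distinct genes.  Split
    genes and SNP pairs are planted afterwards with
    :func:`plant_split_genes` / :func:`mutate_pair`.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    # Draw the layout first so infeasible packing fails before any output.
    lengths = np.maximum(
        rng.gamma(shape=6.0, scale=config.mean_gene_length / 6.0, size=config.n_genes),
        config.min_gene_length,
    ).astype(int)
    tail_mean = max(config.intergenic_mean - config.intergenic_min, 1)
    gaps = config.intergenic_min + rng.geometric(1.0 / tail_mean, size=config.n_genes + 1)
    needed = int(3 * lengths.sum() + gaps.sum())
    if needed > config.genome_length:
        raise SimulationError(
            f"infeasible packing: {config.n_genes} genes need {needed} nt "
            f"but genome_length is {config.genome_length}"
        )

    symbols = [s for genes in config.pathway_assignment.values() for s in genes]
    if len(symbols) > config.n_genes:
        raise SimulationError("more pathway gene symbols than genes")
    symbol_slots = rng.choice(config.n_genes, size=len(symbols), replace=False)
    slot_to_symbol = dict(zip(symbol_slots.tolist(), symbols))

    parts: list[str] = []
    features: list[CdsFeature] = []
    pos = 0
    for i in range(config.n_genes):
        parts.append(_random_dna(rng, int(gaps[i]), config.gc_target))
        pos += int(gaps[i])
        n_codons = int(lengths[i])
        body = _random_codons(rng, n_codons - 2, config.gc_target)
        cds = "ATG" + body + _sample_stop(rng, DEFAULT_TERMINAL_STOP_DIST)
        strand = "+" if rng.random() < 0.5 else "-"
        ins = cds if strand == "+" else _revcomp(cds)
        parts.append(ins)
        sym = slot_to_symbol.get(i)
        features.append(CdsFeature(
            genome_id=config.genome_id,
            segments=[(pos, pos + len(cds))],
            strand=strand,
            locus_tag=f"{config.genome_id.upper()}_{i + 1:04d}",
            gene_symbol=sym,
            product=f"{sym} protein" if sym else "hypothetical protein",
        ))
        pos += len(cds)
    parts.append(_random_dna(rng, config.genome_length - pos, config.gc_target))

    genome = NucleotideGenome(
        id=config.genome_id, sequence="".join(parts), circular=True,
        description="synthetic endosymbiont genome",
    )
    truth = SimulatedTruth(
        planted_genes={config.genome_id: set(symbols)},
        achieved_gc=genome.gc_fraction,
    )
    return genome, FeatureSet(config.genome_id, features, source="simulated"), truth


_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def plant_split_genes(
    genome: NucleotideGenome,
    features: FeatureSet,
    n: int,
    stop_dist=DEFAULT_SPLIT_STOP_DIST,
    seed: int = 0,
    min_half: int = 10,
    truth: SimulatedTruth | None = None,
) -> tuple[NucleotideGenome, FeatureSet, SimulatedTruth]:
    """Rewrite one mid-gene codon of ``n`` genes to a stop drawn from
    ``stop_dist`` and split each annotation into two CDS halves, mirroring
    what an annotation pipeline reports for a pseudogenized gene.

    The first half ends at (and includes) the internal stop; the second half
    starts at the next codon.  Frame is never shifted.  Returns the modified
    genome, annotation, and a truth object recording (first-half locus_tag,
    stop codon, 0-based codon index in the original ORF).
    """
    rng = np.random.default_rng(seed)
    eligible = [
        f for f in features.cds(include_pseudo=False)
        if len(f.segments) == 1 and f.length // 3 >= max(2 * min_half + 1, 60)
    ]
    if n > len(eligible):
        raise SimulationError(
            f"cannot plant {n} splits: only {len(eligible)} eligible genes"
        )
    chosen_idx = sorted(rng.choice(len(eligible), size=n, replace=False).tolist())
    chosen = {eligible[i].locus_tag for i in chosen_idx}

    seq = list(genome.sequence)
    new_features: list[CdsFeature] = []
    truth = truth or SimulatedTruth(achieved_gc=genome.gc_fraction)
    for f in features.features:
        if f.locus_tag not in chosen:
            new_features.append(f)
            continue
        n_codons = f.length // 3
        k = int(rng.integers(min_half, n_codons - min_half))  # internal stop codon index
        stop = _sample_stop(rng, stop_dist)
        (s, e) = f.segments[0]
        if f.strand == "+":
            seq[s + 3 * k: s + 3 * k + 3] = list(stop)
            first = dataclasses.replace(
                f, segments=[(s, s + 3 * (k + 1))], locus_tag=f.locus_tag + "_1")
            second = dataclasses.replace(
                f, segments=[(s + 3 * (k + 1), e)], locus_tag=f.locus_tag + "_2")
        else:
            seq[e - 3 * (k + 1): e - 3 * k] = list(_revcomp(stop))
            first = dataclasses.replace(
                f, segments=[(e - 3 * (k + 1), e)], locus_tag=f.locus_tag + "_1")
            second = dataclasses.replace(
                f, segments=[(s, e - 3 * (k + 1))], locus_tag=f.locus_tag + "_2")
        new_features.extend([first, second])
        truth.split_records.append((first.locus_tag, stop, k))

    genome2 = NucleotideGenome(genome.id, "".join(seq), genome.circular, genome.description)
    truth.achieved_gc = genome2.gc_fraction
    return genome2, FeatureSet(features.genome_id, new_features, features.source), truth


def mutate_pair(
    genome: NucleotideGenome,
    n_snps: int,
    seed: int = 0,
    avoid_stop_creation: bool = True,
    features: FeatureSet | None = None,
    max_retries_factor: int = 50,
) -> tuple[NucleotideGenome, list[int]]:
    """Copy ``genome`` with exactly ``n_snps`` substitutions at distinct
    positions (no indels).

    With ``avoid_stop_creation`` and an annotation, substitutions that would
    create or destroy an in-frame stop codon inside a CDS are re-drawn, so
    split-gene detection on the mutated copy stays consistent with the
    original truth.
    """
    L = len(genome.sequence)
    if n_snps > L:
        raise SimulationError(f"n_snps {n_snps} exceeds genome length {L}")
    rng = np.random.default_rng(seed)
    seq = list(genome.sequence)

    codon_of: dict[int, tuple[int, int, str]] = {}
    if avoid_stop_creation and features is not None:
        for f in features.cds():
            if len(f.segments) != 1:
                continue
            s, e = f.segments[0]
            for ci in range((e - s) // 3):
                for off in range(3):
                    codon_of[s + 3 * ci + off] = (s + 3 * ci, off, f.strand)

    positions: set[int] = set()
    budget = max_retries_factor * max(n_snps, 1)
    while len(positions) < n_snps:
        if budget <= 0:
            raise SimulationError(
                f"could not place {n_snps} substitutions without touching stop "
                f"codons; placed {len(positions)}"
            )
        budget -= 1
        p = int(rng.integers(0, L))
        if p in positions:
            continue
        old = seq[p]
        if old not in "ACGT":
            continue
        alt = [b for b in "ACGT" if b != old]
        new = alt[int(rng.integers(0, 3))]
        if p in codon_of:
            cs, off, strand = codon_of[p]
            codon = "".join(seq[cs:cs + 3])
            mutated = codon[:off] + new + codon[off + 1:]
            if strand == "-":
                codon, mutated = _revcomp(codon), _revcomp(mutated)
            if (codon in STOP_CODONS) != (mutated in STOP_CODONS):
                continue
        seq[p] = new
        positions.add(p)

    genome2 = NucleotideGenome(
        genome.id + "_v2", "".join(seq), genome.circular, genome.description)
    return genome2, sorted(positions)


def simulate_16s_pair(
    length: int = 1500,
    target_identity: float = 0.96,
    seed: int = 0,
    gc: float = 0.52,
) -> tuple[str, str]:
    """A 16S-like sequence pair diverged by substitutions only, realizing
    ``target_identity`` exactly (to the resolution of one site)."""
    if not 0 < target_identity <= 1:
        raise SimulationError("target_identity must be in (0,1]")
    rng = np.random.default_rng(seed)
    s1 = _random_dna(rng, length, gc)
    n_diff = round(length * (1 - target_identity))
    pos = rng.choice(length, size=n_diff, replace=False)
    s2 = list(s1)
    for p in pos:
        alt = [b for b in "ACGT" if b != s2[p]]
        s2[p] = alt[int(rng.integers(0, 3))]
    return s1, "".join(s2)


# ---------------------------------------------------------------------------
# Consortium-level simulation driven by one YAML config

def simulate_consortium(config_path: str | Path, out_dir: str | Path) -> dict[str, dict]:
    """Simulate several genomes with distinct pathway assignments.

    The YAML maps genome ids to :class:`SimulationConfig` fields.  Emits, per
    genome: ``<id>.fasta``, ``<id>.features.tsv`` and ``<id>.truth.json``.
    Returns {genome_id: {"genome", "features", "truth"}}.
    """
    with open(config_path) as fh:
        spec = yaml.safe_load(fh)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results: dict[str, dict] = {}
    for gid, params in spec["genomes"].items():
        params = dict(params)
        n_split = params.pop("n_split_genes", 0)
        cfg = SimulationConfig(genome_id=gid, **params)
        genome, features, truth = simulate_genome(cfg)
        if n_split:
            genome, features, truth = plant_split_genes(
                genome, features, n_split, cfg.split_stop_distribution,
                seed=cfg.seed + 1, truth=truth)
        write_fasta([genome], out_dir / f"{gid}.fasta")
        write_features_tsv(features, out_dir / f"{gid}.features.tsv")
        entry: dict = {"genome": genome, "features": features, "truth": truth,
                       "config": cfg}
        if cfg.n_snps_pair > 0:
            pair, snps = mutate_pair(genome, cfg.n_snps_pair, seed=cfg.seed + 2,
                                     features=features)
            truth.snp_positions = snps
            write_fasta([pair], out_dir / f"{gid}_v2.fasta")
            entry["pair_genome"] = pair
        if cfg.target_16s_identity < 1:
            s1, s2 = simulate_16s_pair(
                target_identity=cfg.target_16s_identity, seed=cfg.seed + 3)
            write_fasta([
                NucleotideGenome(f"{gid}_16s_a", s1),
                NucleotideGenome(f"{gid}_16s_b", s2),
            ], out_dir / f"{gid}.16s.fasta")
            entry["s16"] = (s1, s2)
        (out_dir / f"{gid}.truth.json").write_text(truth.to_json())
        results[gid] = entry
    return results
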