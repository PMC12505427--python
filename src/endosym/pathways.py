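"""Nutritional pathway completeness and consortium complementarity.

Obligate endosymbiont consortia of sap-feeding insects divide the labour of
provisioning the host with the 10 essential amino acids (EAAs) and
B vitamins: each highly reduced genome retains only a subset of pathway
genes, and the union across consortium members restores (near-)complete
pathways.  This module scores per-genome gene presence against a curated
pathway catalog and computes per-pathway completeness and consortium-level
union coverage.

Presence calling is by annotated gene symbol with a synonym table — not by
homology search — which keeps the scoring exactly testable; an externally
produced symbol table can be supplied for real genomes.  Genes retained only
as a split gene (two CDS halves with one internal stop) count toward
coverage with the distinct status ``present_split``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .genome_io import FeatureSet

PRESENT = "present"
PRESENT_SPLIT = "present_split"
ABSENT = "absent"

PATHWAY_CLASSES = ("EAA", "non-essential AA", "B-vitamin", "cofactor")


class CatalogError(ValueError):
    pass


@dataclass
class Pathway:
    pathway_id: str
    display_name: str
    klass: str
    steps: list[frozenset[str]]


@dataclass
class PathwayCatalog:
    pathways: list[Pathway]
    synonym_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [p.pathway_id for p in self.pathways]
        if len(ids) != len(set(ids)):
            raise CatalogError("duplicate pathway_id in catalog")
        for p in self.pathways:
            if p.klass not in PATHWAY_CLASSES:
                raise CatalogError(f"{p.pathway_id}: unknown class {p.klass!r}")
            if not p.steps or any(not s for s in p.steps):
                raise CatalogError(f"{p.pathway_id}: empty step")
        for syn, canon in self.synonym_map.items():
            if canon in self.synonym_map:
                raise CatalogError(f"synonym chain/cycle at {syn!r} -> {canon!r}")

    @property
    def vocabulary(self) -> frozenset[str]:
        return frozenset(s for p in self.pathways for step in p.steps for s in step)

    def get(self, pathway_id: str) -> Pathway:
        for p in self.pathways:
            if p.pathway_id == pathway_id:
                return p
        raise KeyError(pathway_id)

    def canonical(self, symbol: str) -> str | None:
        """Case-insensitive symbol normalization through the synonym map;
        None when the symbol is outside the catalog vocabulary."""
        lower = {s.lower(): s for s in self.vocabulary}
        lower.update({k.lower(): v for k, v in self.synonym_map.items()})
        return lower.get(symbol.lower())

    def signature(self) -> tuple:
        return tuple((p.pathway_id, tuple(map(tuple, map(sorted, p.steps))))
                     for p in self.pathways)


def default_catalog_path() -> Path:
    return Path(str(resources.files("endosym").joinpath("data/pathway_catalog.tsv")))


def load_catalog(path: str | Path | None = None) -> PathwayCatalog:
    """Load a pathway catalog (TSV or YAML by extension).

    TSV columns: pathway_id, display_name, class, step_index, alternatives
    (comma-separated gene symbols).  An optional ``synonym`` / ``canonical``
    pair of columns (rows with empty pathway_id) carries the synonym map.
    The shipped default covers the 10 EAA pathways plus cysteine, riboflavin
    and biotin.
    """
    path = Path(path) if path is not None else default_catalog_path()
    if path.suffix in {".yaml", ".yml"}:
        return _load_catalog_yaml(path)
    return _load_catalog_tsv(path)


def _load_catalog_tsv(path: Path) -> PathwayCatalog:
    order: list[str] = []
    meta: dict[str, tuple[str, str]] = {}
    steps: dict[str, list[tuple[int, frozenset[str]]]] = {}
    synonyms: dict[str, str] = {}
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            pid = row["pathway_id"].strip()
            if not pid:
                if row.get("synonym") and row.get("canonical"):
                    synonyms[row["synonym"].strip()] = row["canonical"].strip()
                continue
            if pid not in meta:
                order.append(pid)
                meta[pid] = (row["display_name"], row["class"])
                steps[pid] = []
            alts = frozenset(a.strip() for a in row["alternatives"].split(",") if a.strip())
            steps[pid].append((int(row["step_index"]), alts))
    pathways = []
    for pid in order:
        name, klass = meta[pid]
        ordered = [alts for _, alts in sorted(steps[pid], key=lambda t: t[0])]
        pathways.append(Pathway(pid, name, klass, ordered))
    return PathwayCatalog(pathways, synonyms)


def _load_catalog_yaml(path: Path) -> PathwayCatalog:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    pathways = [
        Pathway(p["pathway_id"], p.get("display_name", p["pathway_id"]),
                p["class"], [frozenset(step) for step in p["steps"]])
        for p in doc["pathways"]
    ]
    return PathwayCatalog(pathways, doc.get("synonyms", {}))


def save_catalog(catalog: PathwayCatalog, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["pathway_id", "display_name", "class", "step_index",
                    "alternatives", "synonym", "canonical"])
        for p in catalog.pathways:
            for i, step in enumerate(p.steps):
                w.writerow([p.pathway_id, p.display_name, p.klass, i,
                            ",".join(sorted(step)), "", ""])
        for syn, canon in sorted(catalog.synonym_map.items()):
            w.writerow(["", "", "", "", "", syn, canon])


# ---------------------------------------------------------------------------
# Presence

@dataclass
class PresenceMatrix:
    """genome x canonical gene symbol -> present / present_split / absent
    (absent entries are implicit)."""

    data: dict[str, dict[str, str]] = field(default_factory=dict)

    def set(self, genome: str, symbol: str, status: str) -> None:
        self.data.setdefault(genome, {})[symbol] = status

    def status(self, genome: str, symbol: str) -> str:
        return self.data.get(genome, {}).get(symbol, ABSENT)

    def covered(self, genome: str, step: frozenset[str]) -> bool:
        return any(self.status(genome, s) in (PRESENT, PRESENT_SPLIT) for s in step)

    @property
    def genomes(self) -> list[str]:
        return sorted(self.data)


def profile_presence(
    features: FeatureSet,
    merged: pd.DataFrame | None,
    catalog: PathwayCatalog,
) -> PresenceMatrix:
    """Catalog-symbol presence for one genome from its annotation.

    A symbol is ``present`` when a non-pseudo CDS carries it (gene qualifier,
    or product prefix, normalized through the synonym map) and
    ``present_split`` when the carrying CDS is a half of a merged split gene
    from the merged-annotation table."""
    split_halves: set[str] = set()
    if merged is not None and len(merged):
        split_halves = set(merged["first_locus_tag"]) | set(merged["second_locus_tag"])

    pm = PresenceMatrix()
    for f in features.cds(include_pseudo=False):
        raw = f.gene_symbol or (f.product.split()[0] if f.product else None)
        if not raw:
            continue
        symbol = catalog.canonical(raw)
        if symbol is None:
            continue
        status = PRESENT_SPLIT if f.locus_tag in split_halves else PRESENT
        # present_split never downgrades an intact copy
        if pm.status(features.genome_id, symbol) != PRESENT:
            pm.set(features.genome_id, symbol, status)
    pm.data.setdefault(features.genome_id, {})
    return pm


def load_presence_fixture(path: str | Path | None = None) -> PresenceMatrix:
    """Load a presence-list TSV (columns: genome, gene, status[, source]).

    The shipped fixture transcribes the per-symbiont nutritional gene
    repertoires of the two studied planthopper consortia; rows marked
    ``source=figure`` are figure-derived rather than named in the text."""
    if path is None:
        path = Path(str(resources.files("endosym").joinpath("data/figure3_presence.tsv")))
    pm = PresenceMatrix()
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            pm.set(row["genome"], row["gene"], row.get("status") or PRESENT)
    return pm


# ---------------------------------------------------------------------------
# Completeness

@dataclass
class PathwayCompleteness:
    pathway_id: str
    covered_steps: int
    total_steps: int
    completeness: float
    missing: list[frozenset[str]]
    covered_mask: list[bool]
    split_steps: list[frozenset[str]] = field(default_factory=list)


@dataclass
class CompletenessReport:
    genome_id: str
    per_pathway: dict[str, PathwayCompleteness]
    catalog_signature: tuple

    def to_frame(self) -> pd.DataFrame:
        rows = [{
            "genome": self.genome_id, "pathway": pc.pathway_id,
            "covered_steps": pc.covered_steps, "total_steps": pc.total_steps,
            "completeness": pc.completeness,
            "missing": ";".join(",".join(sorted(m)) for m in pc.missing),
        } for pc in self.per_pathway.values()]
        return pd.DataFrame(rows)


def completeness(presence: PresenceMatrix, catalog: PathwayCatalog,
                 genome: str | None = None) -> CompletenessReport | list[CompletenessReport]:
    """Per-pathway step coverage: a step is covered iff at least one of its
    alternative genes is present or present_split."""
    if genome is None:
        return [completeness(presence, catalog, g) for g in presence.genomes]
    per: dict[str, PathwayCompleteness] = {}
    for p in catalog.pathways:
        mask = [presence.covered(genome, step) for step in p.steps]
        missing = [step for step, ok in zip(p.steps, mask) if not ok]
        split_steps = [
            step for step in p.steps
            if any(presence.status(genome, s) == PRESENT_SPLIT for s in step)
        ]
        per[p.pathway_id] = PathwayCompleteness(
            pathway_id=p.pathway_id,
            covered_steps=sum(mask),
            total_steps=len(p.steps),
            completeness=sum(mask) / len(p.steps),
            missing=missing,
            covered_mask=mask,
            split_steps=split_steps,
        )
    return CompletenessReport(genome, per, catalog.signature())


DEFAULT_WHITELIST = frozenset({"ilvA", "hisN", "yigB"})


@dataclass
class ConsortiumPathway:
    pathway_id: str
    union_completeness: float
    providers: list[set[str]]          # per step, genomes covering it
    sole_provider_steps: list[frozenset[str]]
    jointly_complete: bool


@dataclass
class ConsortiumReport:
    members: list[str]
    per_pathway: dict[str, ConsortiumPathway]

    def jointly_complete_ids(self, klass: str | None = None,
                             catalog: PathwayCatalog | None = None) -> set[str]:
        ids = {pid for pid, cp in self.per_pathway.items() if cp.jointly_complete}
        if klass is not None and catalog is not None:
            ids &= {p.pathway_id for p in catalog.pathways if p.klass == klass}
        return ids


def consortium_union(
    reports: list[CompletenessReport],
    catalog: PathwayCatalog,
    whitelist: frozenset[str] = DEFAULT_WHITELIST,
) -> ConsortiumReport:
    """Step-wise union of coverage across consortium members.

    ``jointly_complete`` holds when every step not fully covered by the
    whitelist (genes treated as host-complemented or consistently absent in
    the clade) is covered by at least one member.  Union completeness is
    computed without the whitelist, so it is comparable across consortia."""
    if not reports:
        raise ValueError("no reports")
    sig = catalog.signature()
    for r in reports:
        if r.catalog_signature != sig:
            raise CatalogError(f"report for {r.genome_id} uses a different catalog")
    members = [r.genome_id for r in reports]
    per: dict[str, ConsortiumPathway] = {}
    for p in catalog.pathways:
        providers: list[set[str]] = []
        for i, step in enumerate(p.steps):
            providers.append({
                r.genome_id for r in reports
                if r.per_pathway[p.pathway_id].covered_mask[i]
            })
        covered = [len(pr) > 0 for pr in providers]
        exempt = [step <= whitelist for step in p.steps]
        per[p.pathway_id] = ConsortiumPathway(
            pathway_id=p.pathway_id,
            union_completeness=sum(covered) / len(p.steps),
            providers=providers,
            sole_provider_steps=[
                step for step, pr in zip(p.steps, providers) if len(pr) == 1
            ],
            jointly_complete=all(c or e for c, e in zip(covered, exempt)),
        )
    return ConsortiumReport(members, per)


def pathways_retained(presence: PresenceMatrix, catalog: PathwayCatalog,
                      genome: str, klass: str | None = None) -> set[str]:
    """Pathways for which the genome retains at least one catalog gene."""
    out = set()
    for p in catalog.pathways:
        if klass is not None and p.klass != klass:
            continue
        if any(presence.covered(genome, step) for step in p.steps):
            out.add(p.pathway_id)
    return out
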