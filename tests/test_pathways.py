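"""Pathway catalog, presence calling, completeness and consortium union."""

import itertools

import pandas as pd
import pytest

from endosym.genome_io import CdsFeature, FeatureSet
from endosym.pathways import (
    ABSENT,
    PRESENT,
    PRESENT_SPLIT,
    CatalogError,
    CompletenessReport,
    Pathway,
    PathwayCatalog,
    PresenceMatrix,
    completeness,
    consortium_union,
    load_catalog,
    pathways_retained,
    profile_presence,
    save_catalog,
)


class TestCatalog:
    def test_default_catalog_shape(self, catalog):
        assert len(catalog.pathways) == 13
        classes = {p.klass for p in catalog.pathways}
        assert classes == {"EAA", "non-essential AA", "B-vitamin"}
        assert sum(p.klass == "EAA" for p in catalog.pathways) == 10

    def test_alternative_steps_present(self, catalog):
        lysine = catalog.get("lysine")
        assert frozenset({"dapC", "argD"}) in lysine.steps
        arginine = catalog.get("arginine")
        assert [sorted(s)[0] for s in arginine.steps[:2]] == ["carA", "carB"]

    def test_duplicate_pathway_id_rejected(self):
        p = Pathway("x", "X", "EAA", [frozenset({"a"})])
        with pytest.raises(CatalogError, match="duplicate"):
            PathwayCatalog([p, p])

    def test_empty_step_rejected(self):
        with pytest.raises(CatalogError, match="empty"):
            PathwayCatalog([Pathway("x", "X", "EAA", [frozenset()])])

    def test_unknown_class_rejected(self):
        with pytest.raises(CatalogError, match="class"):
            PathwayCatalog([Pathway("x", "X", "vitamin Q", [frozenset({"a"})])])

    def test_synonym_cycle_rejected(self):
        with pytest.raises(CatalogError, match="chain"):
            PathwayCatalog([Pathway("x", "X", "EAA", [frozenset({"a"})])],
                           {"b": "c", "c": "b"})

    def test_roundtrip_save_load(self, catalog, tmp_path):
        out = tmp_path / "cat.tsv"
        save_catalog(catalog, out)
        again = load_catalog(out)
        assert again.signature() == catalog.signature()
        assert again.synonym_map == catalog.synonym_map


def _features(genome_id, genes, split_tags=(), pseudo_tags=()):
    feats = []
    pos = 0
    for i, g in enumerate(genes):
        tag = f"t{i}"
        feats.append(CdsFeature(genome_id, [(pos, pos + 90)], "+", tag,
                                gene_symbol=g, pseudo=tag in pseudo_tags))
        pos += 120
    return FeatureSet(genome_id, feats)


class TestProfilePresence:
    def test_symbol_presence_and_split_status(self, catalog):
        fs = _features("gA", ["bioB", "bioA", None])
        merged = pd.DataFrame([{"first_locus_tag": "t1", "second_locus_tag": "t9"}])
        pm = profile_presence(fs, merged, catalog)
        assert pm.status("gA", "bioB") == PRESENT
        assert pm.status("gA", "bioA") == PRESENT_SPLIT
        assert pm.status("gA", "bioH") == ABSENT

    def test_pseudo_cds_do_not_count(self, catalog):
        fs = _features("gA", ["bioB"], pseudo_tags={"t0"})
        pm = profile_presence(fs, None, catalog)
        assert pm.status("gA", "bioB") == ABSENT

    def test_synonym_and_case_normalization(self, catalog):
        fs = _features("gA", ["RibG", "ARGD"])  # ribG -> ribD; case-folded argD
        pm = profile_presence(fs, None, catalog)
        assert pm.status("gA", "ribD") == PRESENT
        assert pm.covered("gA", frozenset({"dapC", "argD"}))

    def test_alternative_gene_covers_step(self, catalog):
        fs = _features("gA", ["argD"])
        pm = profile_presence(fs, None, catalog)
        rep = completeness(pm, catalog, "gA")
        lysine = rep.per_pathway["lysine"]
        assert lysine.covered_steps == 1
        assert frozenset({"dapC", "argD"}) not in lysine.missing


class TestCompleteness:
    def test_empty_presence_all_zero(self, catalog):
        pm = PresenceMatrix({"gA": {}})
        rep = completeness(pm, catalog, "gA")
        assert all(pc.completeness == 0 for pc in rep.per_pathway.values())
        assert all(pc.covered_steps + len(pc.missing) == pc.total_steps
                   for pc in rep.per_pathway.values())

    def test_split_counts_toward_coverage(self, catalog, presence):
        rep = completeness(presence, catalog, "Mirabilia_CW")
        biotin = rep.per_pathway["biotin"]
        assert biotin.covered_steps == 5  # bioA covered though split
        assert frozenset({"bioA"}) in biotin.split_steps


class TestConsortiumUnion:
    def test_single_member_equals_own_report(self, catalog, presence):
        rep = completeness(presence, catalog, "Vidania_PL")
        un = consortium_union([rep], catalog)
        for pid, cp in un.per_pathway.items():
            assert cp.union_completeness == rep.per_pathway[pid].completeness

    def test_mismatched_catalogs_rejected(self, catalog, presence):
        other = PathwayCatalog([Pathway("x", "X", "EAA", [frozenset({"a"})])])
        rep = completeness(presence, catalog, "Vidania_PL")
        with pytest.raises(CatalogError, match="different catalog"):
            consortium_union([rep], other)

    def test_union_against_brute_force_oracle_exhaustive(self):
        """All 2^15 presence patterns of 3 genomes x 5 single-gene steps."""
        steps = [frozenset({f"g{i}"}) for i in range(5)]
        cat = PathwayCatalog([Pathway("p", "P", "EAA", steps)])
        genomes = ["A", "B", "C"]
        for bits in itertools.product([0, 1], repeat=15):
            pm = PresenceMatrix()
            grid = {}
            for gi, g in enumerate(genomes):
                pm.data[g] = {}
                for si in range(5):
                    present = bits[gi * 5 + si]
                    grid[(g, si)] = present
                    if present:
                        pm.set(g, f"g{si}", PRESENT)
            reports = [completeness(pm, cat, g) for g in genomes]
            un = consortium_union(reports, cat, frozenset())
            # oracle: direct set union over the grid
            expected = sum(
                1 for si in range(5) if any(grid[(g, si)] for g in genomes)
            ) / 5
            assert un.per_pathway["p"].union_completeness == expected
            assert un.per_pathway["p"].union_completeness >= max(
                r.per_pathway["p"].completeness for r in reports)

    def test_monotone_in_members(self, catalog, presence):
        members = ["Karelsulcia_PL", "Vidania_PL", "Purcelliella_PL"]
        reports = [completeness(presence, catalog, m) for m in members]
        partial = consortium_union(reports[:2], catalog)
        full = consortium_union(reports, catalog)
        for pid in full.per_pathway:
            assert full.per_pathway[pid].union_completeness >= \
                partial.per_pathway[pid].union_completeness

    def test_idempotent_under_duplication(self, catalog, presence):
        rep = completeness(presence, catalog, "Vidania_PL")
        once = consortium_union([rep], catalog)
        twice = consortium_union([rep, rep], catalog)
        for pid in once.per_pathway:
            assert once.per_pathway[pid].union_completeness == \
                twice.per_pathway[pid].union_completeness
            assert once.per_pathway[pid].jointly_complete == \
                twice.per_pathway[pid].jointly_complete

    def test_whitelist_enlargement_never_unflips(self, catalog, presence):
        members = ["Karelsulcia_PL", "Vidania_PL", "Purcelliella_PL"]
        reports = [completeness(presence, catalog, m) for m in members]
        small = consortium_union(reports, catalog, frozenset({"ilvA"}))
        big = consortium_union(reports, catalog,
                               frozenset({"ilvA", "hisN", "yigB", "bioH"}))
        for pid in small.per_pathway:
            if small.per_pathway[pid].jointly_complete:
                assert big.per_pathway[pid].jointly_complete

    def test_sole_provider_steps(self, catalog, presence):
        members = ["Karelsulcia_PL", "Vidania_PL", "Purcelliella_PL"]
        reports = [completeness(presence, catalog, m) for m in members]
        un = consortium_union(reports, catalog)
        trp = un.per_pathway["tryptophan"]
        assert len(trp.sole_provider_steps) == 5  # only Vidania encodes trp


class TestRetained:
    def test_branched_chain_vs_other_eaa_split(self, catalog, presence):
        k = pathways_retained(presence, catalog, "Karelsulcia_PL", "EAA")
        v = pathways_retained(presence, catalog, "Vidania_PL", "EAA")
        assert k == {"isoleucine", "leucine", "valine"}
        assert len(v) == 7 and not (k & v)
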