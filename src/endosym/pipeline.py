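"""End-to-end pipeline: simulate → detect splits → stop usage → pathway
complementarity → comparisons, with a provenance record.

One YAML config drives everything; every output table is TSV with a fixed
column order and the bundle carries a ``provenance.json`` (package version,
seed, parameters, input checksums) plus a MANIFEST listing the files
written.  Re-running with an identical config reproduces identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .compare import ani, count_snps, genome_stats, identity_16s
from .genome_io import read_fasta, read_features
from .pathways import (
    DEFAULT_WHITELIST,
    completeness,
    consortium_union,
    load_catalog,
    load_presence_fixture,
)
from .simulate import simulate_consortium
from .splits import find_split_candidates, stop_usage, write_merged_annotation

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (see README for the YAML schema)."""

    out_dir: Path
    seed: int = 0
    simulate: dict | None = None
    genomes: dict[str, dict] = field(default_factory=dict)  # id -> {fasta, features, dialect}
    max_gap: int = 30
    min_half_length: int = 10
    catalog_path: str | None = None
    presence_fixture: str | None = None
    consortia: dict[str, list[str]] = field(default_factory=dict)
    whitelist: list[str] = field(default_factory=lambda: sorted(DEFAULT_WHITELIST))
    snp_pairs: list[list[str]] = field(default_factory=list)
    ani_pairs: list[list[str]] = field(default_factory=list)
    fragment_length: int = 1020
    anchor_k: int = 17
    raw: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if "out_dir" not in doc:
            raise ConfigError("config must set out_dir")
        cfg = cls(
            out_dir=Path(doc["out_dir"]),
            seed=int(doc.get("seed", 0)),
            simulate=doc.get("simulate"),
            genomes=doc.get("genomes", {}),
            max_gap=int(doc.get("max_gap", 30)),
            min_half_length=int(doc.get("min_half_length", 10)),
            catalog_path=doc.get("catalog"),
            presence_fixture=doc.get("presence_fixture"),
            consortia=doc.get("consortia", {}),
            whitelist=list(doc.get("whitelist", sorted(DEFAULT_WHITELIST))),
            snp_pairs=doc.get("snp_pairs", []),
            ani_pairs=doc.get("ani_pairs", []),
            fragment_length=int(doc.get("fragment_length", 1020)),
            anchor_k=int(doc.get("anchor_k", 17)),
            raw=doc,
        )
        for gid, spec in cfg.genomes.items():
            for key in ("fasta", "features"):
                if key in spec and not Path(spec[key]).exists():
                    raise ConfigError(f"genome {gid}: missing file {spec[key]}")
        if cfg.catalog_path and not Path(cfg.catalog_path).exists():
            raise ConfigError(f"catalog not found: {cfg.catalog_path}")
        return cfg

    def checksum(self) -> str:
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _sha(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all configured stages; returns a summary dict.

    A stage failure aborts with the failing stage named; files already
    written stay on disk and the MANIFEST marks the bundle incomplete."""
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []
    summary: dict = {"config_checksum": config.checksum()}
    stage = "init"
    try:
        loaded: dict[str, tuple] = {}
        sim_16s: dict[str, tuple[str, str]] = {}

        if config.simulate:
            stage = "simulate"
            sim_yaml = out / "simulation.yaml"
            sim_yaml.write_text(yaml.safe_dump(config.simulate))
            sim = simulate_consortium(sim_yaml, out / "simulated")
            for gid, entry in sim.items():
                loaded[gid] = (entry["genome"], entry["features"])
                if "pair_genome" in entry:
                    loaded[gid + "_v2"] = (entry["pair_genome"], entry["features"])
                if "s16" in entry:
                    sim_16s[gid] = entry["s16"]
            manifest += sorted(str(p.relative_to(out)) for p in (out / "simulated").iterdir())

        stage = "load"
        for gid, spec in config.genomes.items():
            genome = read_fasta(spec["fasta"])[0]
            feats = None
            if "features" in spec:
                feats = read_features(
                    spec["features"], spec.get("dialect", "tsv"),
                    genome_length=len(genome), circular=genome.circular)
            loaded[gid] = (genome, feats)

        stage = "splits"
        split_counts = {}
        for gid, (genome, feats) in loaded.items():
            if feats is None or gid.endswith("_v2"):
                continue
            cands = find_split_candidates(genome, feats, config.max_gap,
                                          config.min_half_length)
            logger.info("%s: %d CDS, %d split candidates",
                        gid, len(feats.cds()), len(cands))
            merged = write_merged_annotation(cands)
            merged.to_csv(out / f"{gid}.merged.tsv", sep="\t", index=False)
            usage = stop_usage(genome, feats, cands)
            usage.to_frame().to_csv(out / f"{gid}.stop_usage.tsv", sep="\t", index=False)
            manifest += [f"{gid}.merged.tsv", f"{gid}.stop_usage.tsv"]
            split_counts[gid] = len(cands)
        summary["split_candidates"] = split_counts

        stage = "pathways"
        catalog = load_catalog(config.catalog_path)
        presence = load_presence_fixture(config.presence_fixture)
        reports = {r.genome_id: r for r in completeness(presence, catalog)}
        frames = [r.to_frame() for r in reports.values()]
        if frames:
            import pandas as pd
            pd.concat(frames).to_csv(out / "completeness.tsv", sep="\t", index=False)
            manifest.append("completeness.tsv")
        consortium_out = {}
        for name, members in config.consortia.items():
            rep = consortium_union([reports[m] for m in members], catalog,
                                   frozenset(config.whitelist))
            consortium_out[name] = {
                pid: {"union_completeness": cp.union_completeness,
                      "jointly_complete": cp.jointly_complete}
                for pid, cp in rep.per_pathway.items()
            }
        (out / "consortium.json").write_text(json.dumps(consortium_out, indent=1))
        manifest.append("consortium.json")
        summary["consortia"] = consortium_out

        stage = "comparisons"
        comp_rows = []
        for pair in config.snp_pairs:
            a, b = loaded[pair[0]][0], loaded[pair[1]][0]
            rep = count_snps(a, b, config.anchor_k)
            comp_rows.append({"comparison": "snps", "a": pair[0], "b": pair[1],
                              "value": rep.n_substitutions,
                              "detail": f"indels={rep.n_indel_events}"})
        for pair in config.ani_pairs:
            a, b = loaded[pair[0]][0], loaded[pair[1]][0]
            rep = ani(a, b, config.fragment_length)
            comp_rows.append({"comparison": "ani", "a": pair[0], "b": pair[1],
                              "value": rep.ani_percent,
                              "detail": f"pairs={rep.n_fragment_pairs}"})
        for gid, (s1, s2) in sim_16s.items():
            res = identity_16s(s1, s2)
            comp_rows.append({"comparison": "16s_identity", "a": gid, "b": gid,
                              "value": res.identity_rounded,
                              "detail": f"exact={res.identity_percent:.2f}"})
        for gid, (genome, feats) in loaded.items():
            if feats is None:
                continue
            st = genome_stats(genome, feats)
            comp_rows.append({"comparison": "stats", "a": gid, "b": "",
                              "value": st.length,
                              "detail": f"gc={st.gc_percent} cds={st.n_cds}"})
        if comp_rows:
            import pandas as pd
            pd.DataFrame(comp_rows).to_csv(out / "comparisons.tsv", sep="\t", index=False)
            manifest.append("comparisons.tsv")
        summary["comparisons"] = comp_rows

        stage = "provenance"
        provenance = {
            "package_version": __version__,
            "seed": config.seed,
            "config_checksum": config.checksum(),
            "parameters": {k: v for k, v in config.raw.items() if k != "simulate"},
            "input_checksums": {
                gid: _sha(Path(spec["fasta"]))
                for gid, spec in config.genomes.items()
            },
        }
        (out / "provenance.json").write_text(json.dumps(provenance, indent=1))
        manifest.append("provenance.json")
        (out / "MANIFEST").write_text("\n".join(["status: complete"] + manifest) + "\n")
        return summary
    except Exception:
        (out / "MANIFEST").write_text(
            "\n".join([f"status: INCOMPLETE (failed at stage: {stage})"] + manifest) + "\n")
        logger.error("pipeline failed at stage %r", stage)
        raise
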