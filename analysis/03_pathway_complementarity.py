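#!/usr/bin/env python
"""Score nutritional pathway completeness and consortium complementarity.

Uses the shipped presence fixture (per-symbiont nutritional gene repertoires
of the two studied host species) to compute per-genome pathway completeness
and the step-wise union across each host's consortium, writing
results/completeness.tsv and results/consortium.json.
"""

import json
from pathlib import Path

import pandas as pd

from endosym.pathways import (
    completeness,
    consortium_union,
    load_catalog,
    load_presence_fixture,
    pathways_retained,
)

ROOT = Path(__file__).resolve().parents[1]

CONSORTIA = {
    "C_wagneri": ["Karelsulcia_CW", "Vidania_CW", "Mirabilia_CW"],
    "P_leporinus": ["Karelsulcia_PL", "Vidania_PL", "Purcelliella_PL"],
}


def main() -> None:
    catalog = load_catalog()
    presence = load_presence_fixture()
    out = ROOT / "results"
    out.mkdir(exist_ok=True)

    reports = {g: completeness(presence, catalog, g) for g in presence.genomes}
    pd.concat([r.to_frame() for r in reports.values()]).to_csv(
        out / "completeness.tsv", sep="\t", index=False)

    for genome in presence.genomes:
        eaa = pathways_retained(presence, catalog, genome, "EAA")
        others = pathways_retained(presence, catalog, genome) - eaa
        print(f"{genome}: {len(eaa)} EAA pathway(s) "
              f"({', '.join(sorted(eaa)) or '-'}); other: "
              f"{', '.join(sorted(others)) or '-'}")

    doc = {}
    for host, members in CONSORTIA.items():
        union = consortium_union([reports[m] for m in members], catalog)
        complete_eaa = union.jointly_complete_ids("EAA", catalog)
        doc[host] = {
            pid: {"union_completeness": cp.union_completeness,
                  "jointly_complete": cp.jointly_complete}
            for pid, cp in union.per_pathway.items()
        }
        print(f"\n{host} consortium ({', '.join(members)}):")
        print(f"  EAA pathways jointly complete: {len(complete_eaa)}/10")
        for pid, cp in union.per_pathway.items():
            if not cp.jointly_complete:
                missing = [",".join(sorted(s)) for s, pr in
                           zip(catalog.get(pid).steps, cp.providers) if not pr]
                print(f"  {pid}: union {cp.union_completeness:.2f}, "
                      f"uncovered steps: {'; '.join(missing)}")
    (out / "consortium.json").write_text(json.dumps(doc, indent=1))
    print(f"\nwrote {out}/completeness.tsv and {out}/consortium.json")


if __name__ == "__main__":
    main()
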