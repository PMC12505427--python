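#!/usr/bin/env python
"""Pairwise genome comparisons on the simulated consortium.

SNP counts of the near-identical genome pairs (recovered under an arbitrary
rotation of the circular genome), 16S identity of the diverged pair,
OrthoANI-style ANI, reciprocal-best-hit orthologue sharing and per-genome
statistics.  Requires scratch/simulated/ from 01_simulate_consortium.py.
"""

import json
from pathlib import Path

import pandas as pd

from endosym.compare import (
    ani,
    count_snps,
    genome_stats,
    identity_16s,
    proteome,
    rbh_orthologues,
    rotate,
)
from endosym.genome_io import NucleotideGenome, read_fasta, read_features

ROOT = Path(__file__).resolve().parents[1]
SIM = ROOT / "scratch" / "simulated"


def main() -> None:
    rows = []
    for gid in ("karelsulcia_sim", "vidania_sim", "mirabilia_sim"):
        genome = read_fasta(SIM / f"{gid}.fasta")[0]
        features = read_features(SIM / f"{gid}.features.tsv", "tsv",
                                 genome_length=len(genome), circular=True)
        st = genome_stats(genome, features)
        rows.append({"comparison": "stats", "a": gid, "b": "",
                     "value": st.length, "detail": f"gc={st.gc_percent}"})
        print(f"{gid}: {st.length:,} bp, GC {st.gc_percent}%")

        pair_path = SIM / f"{gid}_v2.fasta"
        if pair_path.exists():
            truth = json.loads((SIM / f"{gid}.truth.json").read_text())
            pair = read_fasta(pair_path)[0]
            # deposit the second genome at a different origin to exercise
            # rotation normalization
            shifted = NucleotideGenome(pair.id, rotate(pair.sequence, 10_000),
                                       circular=True)
            rep = count_snps(genome, shifted)
            print(f"  SNPs vs pair: {rep.n_substitutions} "
                  f"(planted {len(truth['snp_positions'])}, "
                  f"rotation {rep.rotation_offset})")
            rows.append({"comparison": "snps", "a": gid, "b": pair.id,
                         "value": rep.n_substitutions,
                         "detail": f"rotation={rep.rotation_offset}"})
            res = ani(genome, pair)
            print(f"  ANI vs pair: {res.ani_percent:.2f}% "
                  f"over {res.n_fragment_pairs} fragment pairs")
            rows.append({"comparison": "ani", "a": gid, "b": pair.id,
                         "value": round(res.ani_percent, 2),
                         "detail": f"fragments={res.n_fragment_pairs}"})

        s16_path = SIM / f"{gid}.16s.fasta"
        if s16_path.exists():
            r1, r2 = read_fasta(s16_path)
            res = identity_16s(r1.sequence, r2.sequence)
            print(f"  16S pair identity: {res.identity_rounded}% "
                  f"({res.identity_percent:.2f}% over {res.aligned_columns} columns)")
            rows.append({"comparison": "16s_identity", "a": r1.id, "b": r2.id,
                         "value": res.identity_rounded,
                         "detail": f"exact={res.identity_percent:.2f}"})

    # orthologue sharing between the two most reduced simulated genomes
    ga = read_fasta(SIM / "karelsulcia_sim.fasta")[0]
    fa = read_features(SIM / "karelsulcia_sim.features.tsv", "tsv")
    gb = read_fasta(SIM / "vidania_sim.fasta")[0]
    fb = read_features(SIM / "vidania_sim.features.tsv", "tsv")
    res = rbh_orthologues(proteome(ga, fa), proteome(gb, fb))
    print(f"karelsulcia_sim vs vidania_sim: {res.n_shared} RBH pairs, "
          f"{len(res.unique_a)}/{len(res.unique_b)} unique proteins")
    rows.append({"comparison": "rbh_shared", "a": "karelsulcia_sim",
                 "b": "vidania_sim", "value": res.n_shared,
                 "detail": f"unique={len(res.unique_a)},{len(res.unique_b)}"})

    out = ROOT / "results" / "comparisons.tsv"
    pd.DataFrame(rows).to_csv(out, sep="\t", index=False)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
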