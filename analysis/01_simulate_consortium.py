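#!/usr/bin/env python
"""Simulate the synthetic endosymbiont consortium.

Generates three truth-tracked genomes in the regimes of a planthopper's
co-primary endosymbionts (small, AT-rich, densely coding), including planted
split genes, near-identical SNP pairs and a diverged 16S pair, and writes
FASTA + feature tables + truth files under scratch/simulated/ (regenerable
intermediates consumed by the later drivers).
"""

from pathlib import Path

from endosym.compare import genome_stats
from endosym.simulate import simulate_consortium

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    out = ROOT / "scratch" / "simulated"
    results = simulate_consortium(ROOT / "analysis" / "consortium_config.yaml", out)
    print(f"wrote {out}/")
    for gid, entry in results.items():
        st = genome_stats(entry["genome"], entry["features"])
        truth = entry["truth"]
        print(f"  {gid}: {st.length:,} bp, GC {st.gc_percent}%, "
              f"{st.n_cds} CDS, {len(truth.split_records)} planted splits, "
              f"{len(truth.snp_positions)} planted SNPs")


if __name__ == "__main__":
    main()
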