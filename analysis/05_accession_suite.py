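#!/usr/bin/env python
"""Re-run the analyses on the deposited endosymbiont genomes (user-supplied).

This driver takes local paths to genomes and annotations downloaded from the
public archives (BioProjects PRJNA1100464 and PRJNA1100466; 16S accession
OQ099687.1) and recomputes, on real data, what the other drivers compute on
simulations: split-gene candidates and the three-group stop-codon usage on
the eroding Gammaproteobacteria symbiont genome, SNP counts for the
near-identical genome pairs, 16S identities, and genome statistics.  It
performs no downloads itself.

Example:
    python analysis/05_accession_suite.py \
        --genome mirabilia.fasta --features mirabilia.gff3 --dialect gff3 \
        --snp-pair vidania_plfr.fasta vidania_plch.fasta \
        --rrna-pair cnervosus_16s.fasta mirabilia_16s.fasta
"""

import argparse

from endosym.compare import count_snps, genome_stats, identity_16s
from endosym.genome_io import read_fasta, read_features
from endosym.splits import find_split_candidates, stop_usage, write_merged_annotation


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--genome", help="FASTA of the genome to scan for split genes")
    ap.add_argument("--features", help="its annotation")
    ap.add_argument("--dialect", default="gff3",
                    choices=["gff3", "genbank", "tsv"])
    ap.add_argument("--max-gap", type=int, default=30)
    ap.add_argument("--min-half", type=int, default=10)
    ap.add_argument("--merged-out", default="merged_annotation.tsv")
    ap.add_argument("--snp-pair", nargs=2, action="append", default=[],
                    metavar=("A", "B"))
    ap.add_argument("--rrna-pair", nargs=2, action="append", default=[],
                    metavar=("A", "B"))
    args = ap.parse_args()

    if args.genome and args.features:
        genome = read_fasta(args.genome)[0]
        features = read_features(args.features, args.dialect,
                                 genome_length=len(genome),
                                 circular=genome.circular)
        st = genome_stats(genome, features)
        print(f"{genome.id}: {st.length:,} bp, GC {st.gc_percent}%, "
              f"{st.n_cds} CDS, {st.n_pseudo} pseudogenes")
        cands = find_split_candidates(genome, features, args.max_gap,
                                      args.min_half)
        write_merged_annotation(cands).to_csv(args.merged_out, sep="\t",
                                              index=False)
        print(f"split candidates: {len(cands)} (merged annotation -> "
              f"{args.merged_out})")
        usage = stop_usage(genome, features, cands)
        for group in usage.GROUPS:
            pct = usage.percent(group)
            n = sum(usage.counts[group].values())
            print(f"  {group} (n={n}): "
                  + ", ".join(f"{c} {pct[c]}%" for c in ("TAA", "TAG", "TGA")))

    for a_path, b_path in args.snp_pair:
        a, b = read_fasta(a_path)[0], read_fasta(b_path)[0]
        rep = count_snps(a, b)
        print(f"{a.id} vs {b.id}: {rep.n_substitutions} SNPs, "
              f"{rep.n_indel_events} indel events")

    for a_path, b_path in args.rrna_pair:
        a, b = read_fasta(a_path)[0], read_fasta(b_path)[0]
        res = identity_16s(a.sequence, b.sequence)
        print(f"{a.id} vs {b.id}: 16S identity {res.identity_rounded}% "
              f"({res.identity_percent:.2f}%)")


if __name__ == "__main__":
    main()
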