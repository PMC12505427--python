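# endosym

Comparative analyses for the highly reduced genomes of co-obligate
endosymbiont consortia in sap-feeding insects (planthoppers and their
relatives), written for microbial genomicists studying genome erosion and
nutritional symbiosis.

Long-term host-restricted endosymbionts have tiny (130–500 kb), extremely
AT-rich (18–27% GC) circular chromosomes.  This package implements the
analyses that characterise such genomes and the division of nutritional
labour within a symbiont consortium:

- **Split-gene detection** — find adjacent CDS pairs (A, B) on one strand
  whose merged span translates, in A's frame, to a single ORF with exactly
  one internal stop codon located between A's terminal codon and B's first
  codon; emit a merged annotation.  These "genes split in two halves" are a
  hallmark of pseudogenization (or, possibly, stop-codon repurposing).
- **Stop-codon usage statistics** — TAA/TAG/TGA frequencies for three gene
  groups: (1) terminal stops of intact genes, (2) internal stops of split
  genes, (3) terminal stops of split genes' second halves.
- **Pathway completeness & consortium complementarity** — per-genome
  coverage of the 10 essential amino-acid (EAA) pathways plus cysteine,
  riboflavin and biotin, scored against a curated step catalog
  (steps = sets of alternative genes), and the step-wise union across
  consortium members: completeness `= |covered steps| / |steps|`, a
  consortium is *jointly complete* for a pathway when every
  non-whitelisted step is covered by at least one member.
- **Pairwise genome comparisons** — circularity-aware SNP counting
  (rotation-normalized), 16S rRNA percent identity (end-gap-free global
  alignment), OrthoANI-style ANI over reciprocal best 1020-nt fragments,
  reciprocal-best-hit orthologue sharing, and genome summary statistics.
- **Synthetic consortium generator** — truth-tracked simulations of the
  above regimes (planted split genes, SNP pairs, 16S pairs at a target
  identity, pathway gene repertoires) so every analysis is tested for
  exact recovery.

See `docs/methods.md` for the models, defaults and their rationale.

## Layout

```
src/endosym/        library: genome_io, simulate, splits, pathways,
                    compare, pipeline, cli; shipped data files
                    (pathway catalog, consortium presence fixture)
analysis/           numbered drivers reproducing the study-style analyses
results/            tables written by the drivers
scratch/            regenerable simulated genomes (not tracked)
scripts/acceptance.py   recomputes the headline numbers from scratch
```

## Worked example

```bash
python analysis/01_simulate_consortium.py
python analysis/02_split_genes_and_stop_usage.py
```

prints (abridged):

```
  mirabilia_sim: 165,000 bp, GC 19.2%, 200 CDS, 20 planted splits, 0 planted SNPs
split genes: 20 detected / 20 planted (20 with matching internal stop codon and position)
  group1_intact_terminal (n=160): TAA 83%, TAG 7%, TGA 11%
  group2_internal (n=20): TAA 60%, TAG 0%, TGA 40%
  group3_second_half_terminal (n=20): TAA 75%, TAG 10%, TGA 15%
```

The eroding simulated genome carries 20 genes each split in two halves by a
planted internal stop; the detector recovers all 20 with their exact stop
codons and positions, and the usage table shows the TAA-dominated terminal
stops of intact genes (group 1) beside the internal stops of split genes
(group 2), which were planted TGA-enriched.  Then

```bash
python analysis/03_pathway_complementarity.py
python analysis/04_genome_comparisons.py
```

reports the division of labour and the pair comparisons (abridged):

```
Karelsulcia_PL: 3 EAA pathway(s) (isoleucine, leucine, valine); other: -
Vidania_PL: 7 EAA pathway(s) (arginine, histidine, lysine, methionine,
            phenylalanine, threonine, tryptophan); other: -
P_leporinus consortium (Karelsulcia_PL, Vidania_PL, Purcelliella_PL):
  EAA pathways jointly complete: 10/10
  vidania_sim:  SNPs vs pair: 68 (planted 68, rotation 10000)
                ANI vs pair: 99.95% over 133 fragment pairs
  mirabilia_sim: 16S pair identity: 96% (96.00% over 1500 columns)
```

One symbiont retains exactly the three branched-chain EAA pathways, a
second the seven others, and their union — under the default whitelist of
host-complemented genes (`ilvA`, `hisN`, `yigB`) — covers all 10 EAA
pathways: the consortium-complementarity signature.  The 68 planted
substitutions are recovered exactly even when the circular pair is
deposited at a different origin.

The same machinery is scriptable via the `endosym` CLI
(`endosym simulate|splits|pathways|compare|run`), e.g.
`endosym splits detect genome.fasta features.tsv --max-gap 30 --min-half 10`.
Real deposited assemblies can be analysed with
`analysis/05_accession_suite.py`, which takes local file paths
(GFF3/GenBank/TSV annotations) and performs no downloads.

Output tables have fixed column orders: merged annotations
(`merged_locus_tag, start, end, strand, internal_stop_codon,
internal_stop_codon_index, first_locus_tag, second_locus_tag`; 1-based
inclusive coordinates), stop usage (`group, codon, count, percent`),
completeness (`genome, pathway, covered_steps, total_steps, completeness,
missing`), comparisons (`comparison, a, b, value, detail`).  The feature
TSV dialect uses 1-based inclusive coordinates with columns `genome_id,
locus_tag, start, end, strand, gene, product, pseudo` plus an optional
`kind` column (CDS/rRNA/tRNA, default CDS).

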