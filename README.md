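# kmersig

Alignment-free comparison of metagenomic samples through k-tuple sequence
signatures. Reads from each sample (FASTA/FASTQ, optionally gzipped) are
supplemented with their reverse complements and summarized as the vector of
counts of all 4^k nucleotide words; samples are then compared with a
battery of dissimilarity measures and analyzed for group structure or
environmental gradients.

## What's inside

- **signatures** — read loading, complement supplementation, k-tuple
  counting (k = 2–12), frequency vectors, TSV export.
- **background** — Markov models of order 0–3 (and k−2 for the Hao
  measure) fitted per sample, giving expected tuple frequencies and
  centralized counts.
- **measures** — the 14-measure roster: `d2`; `d2S|M0..M3` and
  `d2star|M0..M3` on centralized counts; Manhattan/Euclidean/Chebyshev on
  frequency vectors; `Hao` (composition-vector correlation distance);
  `Willner` di/tri/tetranucleotide odds-ratio distances (k = 2–4).
- **community_sim** — synthetic order-1 Markov genomes (or user-supplied
  FASTA genomes), Zipf and perturbation-based abundance designs
  (`sim1`–`sim4`: two grouped and two gradient layouts), and an error-free
  read sampler.
- **beta_eval** — UPGMA clustering with Newick export, Fitch parsimony
  score with a Monte Carlo permutation test, classical-MDS PCoA, and
  |Pearson| correlation of PC1 against a gradient.
- **cli / experiments** — command-line pipeline and canned benchmark
  experiments.

## CLI

```sh
# simulate a 20-sample gradient community (5 synthetic genomes)
kmersig simulate --design sim2 --depth 10000 --seed 1 --out-dir sim2/

# signature TSVs (one per sample) at k=5
kmersig count sim2/S*.fasta --k 5 --out-dir sigs/

# pairwise dissimilarity matrix, d2S with an order-0 background
kmersig dist sim2/S*.fasta --measure d2S --k 5 --order 0 --out d.tsv

# gradient evaluation: PCoA + |PCC| between PC1 and the gradient
awk 'NR>1{print $1"\t"$2}' sim2/manifest.tsv > grad.tsv
kmersig eval --matrix d.tsv --metadata grad.tsv --mode gradient --out-prefix run1

# group evaluation: UPGMA tree + parsimony test (1000 permutations)
kmersig eval --matrix d.tsv --metadata groups.tsv --mode cluster --seed 1 --out-prefix run2
```

`--matrix-format phylip` writes a PHYLIP-dialect distance matrix for
external tree tools.

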