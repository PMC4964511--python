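# codonbias

Codon usage bias analysis for coding sequences, built for genome-scale
studies of the kind run on fungal genomes such as the grass endophyte
*Epichloë festucae*: which synonymous codons a genome prefers, and how much
of that preference is explained by mutational GC pressure versus
translational selection.

From a CDS FASTA the package computes, per gene and pooled:

- **QC filtering** — ATG start, terminal stop, length strictly > 300 nt,
  triplet structure, exact-duplicate removal, with a full rejection tally;
- **composition** — GC, GC1/GC2/GC3, GC12, GC3s and A3s/T3s/C3s/G3s over
  synonymous third positions;
- **bias indices** — RSCU, Wright's effective number of codons (ENC), the
  codon adaptation index (CAI), GRAVY and aromaticity;
- **ENC-plot analytics** — the mutation-only expectation
  `ENC_exp = 2 + s + 29/(s² + (1−s)²)` at `s = GC3s`, the per-gene ENC
  ratio `(ENC_exp − ENC_obs)/ENC_exp` and its frequency distribution;
- **neutrality plot** — ordinary least squares of GC12 on GC3; the slope
  is the conventional mutational share of codon-usage variation;
- **correspondence analysis** of the genes × 59-codon RSCU matrix, with
  correlations (Spearman or Pearson) between axis coordinates and all
  indices;
- **optimal codons** — genes ranked by ENC ratio, the 5% extremes pooled,
  and codons with `ΔRSCU = RSCU_high − RSCU_low > 0.08` called optimal
  (stops, Met and Trp excluded).

A synthetic CDS generator with a per-gene GC3 mutation kernel and an
`exp(s)` selection tilt toward a planted preferred-codon set makes the
entire pipeline testable end-to-end without any external genome, including
exact recovery of the planted optimal codons. The package also ships the
published genome-wide codon usage table of *E. festucae* (4870 filtered
CDS) as a ready-made reference dataset.

## Worked example

```python
from codonbias import (
    count_codons, ending_base_tally, filter_cds, neutrality_fit,
    optimal_codon_table, pool_counts, profile_genes, select_bias_subsets,
)
from codonbias.synthetic import SyntheticSpec, generate_genes

records, truth = generate_genes(SyntheticSpec(n_genes=500, seed=42))
kept, report = filter_cds(records)            # retained 500/500
profiles = profile_genes(kept)

fit = neutrality_fit(list(zip(profiles["gc3"], profiles["gc12"])))
print(f"slope {fit.slope:.4f}, r {fit.pearson_r:.3f}")
# slope 0.0093, r 0.104  -> composition barely drags positions 1-2:
# codon usage here is selection-dominated, not mutation-dominated

counts = {r.id: count_codons(r) for r in kept}
subsets = select_bias_subsets(profiles["enc_ratio"], 0.05)  # 25 genes/side
table = optimal_codon_table(
    pool_counts([counts[g] for g in subsets.high_ids]),
    pool_counts([counts[g] for g in subsets.low_ids]),
)
optimal = table[table["optimal"]]
print(len(optimal), ending_base_tally(table))
# 18 {'U': 0, 'C': 15, 'A': 0, 'G': 3}
```

The 18 recovered optimal codons are exactly the generator's planted
preferred set (all C/G-ending), and per-gene ENC spans 20.6–61.0 with the
selection-tilted genes sitting far below the mutation-only ENC curve.

The same analysis runs from the shell:

```sh
codonbias simulate --n 500 --seed 42 --out synth.fasta --truth truth.tsv
codonbias run --input synth.fasta --outdir results/ --plots
```

`run` writes the filter report, per-gene index table, pooled RSCU table,
ENC/neutrality reports, correspondence-analysis coordinates, the
correlation matrix with significance stars, the optimal-codon table, the
three standard figures, and a manifest with per-artifact checksums
(reruns are byte-identical).

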