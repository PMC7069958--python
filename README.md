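# bioidflow

Lineage-resolved analysis of proximity-labelling (BioID) interactomes for
transcription factors, built around the experimental design that contrasts a
wild-type bait, a DNA-binding-deficient bait (homeodomain N51A mutation) and
a nuclear GFP control, each quantified label-free in four biological
replicates per tissue.

The package is aimed at proteomics analysts who have a protein-group
quantification table (one LFQ intensity column per sample, `Reverse` /
`Potential contaminant` / `Only identified by site` flags) and want a tested,
scriptable re-implementation of the enrichment-calling and downstream
comparisons usually done interactively:

- **Enrichment calling.** Per replicate, the bait/control ratio on the log2
  scale, `log2(LFQ_case / LFQ_control)`. Ratios with a quantified case but an
  unquantified control ("infinite" ratios) are imputed; finite values are
  centred on their per-replicate median; the enrichment cutoff is
  `median + k · SD₉₀`, where `SD₉₀` is the standard deviation of the central
  90% of the ratio distribution (default `k = 2`). A protein joins the
  interactome when it exceeds the cutoff in ≥ 2 of 4 replicates.
- **Compartment classification.** With `W` = wild-type interactome and `M` =
  DNA-binding-deficient interactome of the same tissue: chromatin partners
  `W \ M`, general nuclear partners `W ∩ M`, nucleoplasm partners `M \ W`.
- **Multi-tissue comparison.** Exact Venn partition over any number of tissue
  interactomes, pairwise-complete Pearson QC of replicates on log10 LFQ, and
  a downshifted-normal imputed matrix for PCA/heat maps.
- **TF co-binding.** Peaks of two factors resized to 1-kb midpoint windows;
  co-bound loci are connected components of overlapping windows containing
  both factors; loci are assigned to genes (promoter −2 kb, gene body,
  nearest TSS ≤ 5 kb), classified promoter/gene body/intergenic, compared
  between TF pairs (shared loci, % exclusivity), and overlaid with an
  expressed-gene list.
- **Category enrichment.** One-sided Fisher exact test (hypergeometric upper
  tail) with Benjamini–Hochberg FDR over user-supplied category maps.
- **Synthetic data.** Generators for LFQ experiments with planted interactors
  of the three compartment classes (log-normal baselines, logistic
  intensity-dependent dropout, flagged decoy/contaminant rows) and for toy
  genomes with a planted co-binding fraction — every downstream stage is
  testable against known truth without any download.

## Worked example

```python
import bioidflow as bf

cfg = bf.LfqSimConfig(n_proteins=1000, n_chromatin=25, n_nucleus=25, n_nucleoplasm=25,
                      effect_size=3.0, seed=0)
matrix, truth = bf.generate_lfq_experiment(cfg)
filtered = bf.filter_canonical(matrix)

wt, ratios, threshold = bf.call_interactome(filtered, ("WT", "GFP"), "mesoderm")
n51a, _, _ = bf.call_interactome(filtered, ("N51A", "GFP"), "mesoderm")
print(threshold.per_replicate.round(3))
print(f"WT interactome: {len(wt.members)} proteins; N51A interactome: {len(n51a.members)}")
print("compartments:", bf.classify_compartment(wt, n51a).counts())
print(bf.call_metrics(wt.members, truth, ("chromatin", "nucleus")))
```

prints

```
           median  trimmed_sd  upper
replicate
1             0.0       0.650  1.299
2             0.0       0.665  1.329
3             0.0       0.671  1.342
4            -0.0       0.656  1.313
WT interactome: 57 proteins; N51A interactome: 52
compartments: {'chromatin': 32, 'nucleus': 25, 'nucleoplasm': 27}
{'tp': 50, 'fp': 7, 'fn': 0, 'precision': 0.877..., 'recall': 1.0}
```

The per-replicate cutoffs sit at `median + 2·SD₉₀ ≈ 1.3` log2 units; the 57
proteins called in the WT contrast recover all 50 planted chromatin + nucleus
interactors (recall 1.0) with 7 background false calls (precision 0.88), and
the WT/N51A set logic recovers the three planted compartment classes almost
exactly. For real data, replace the generator with
`bf.read_protein_groups(path, bf.SampleDesign.from_yaml(design_yaml))`.

On the genomic side:

```python
cfg = bf.GenomeSimConfig(planted_cobind_fraction=0.3, seed=5)
genes, peaks_a, peaks_b, expressed = bf.generate_genome_fixture(cfg)
result = bf.cobind(peaks_a, peaks_b, window=1000)
result.summary()                      # {'n_cobound': 60, 'n_A_only': 140, 'n_B_only': 140}
```

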