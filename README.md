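# gsikit

Genetic stock identification (GSI) for mixed-stock fisheries from small SNP
panels, built around the Atlantic herring populations of the west of Scotland
and northwest Ireland shelf (the autumn-spawning `6aN_Aut`, winter-spawning
`6aS` and spring-spawning `6aN_Sp` groups, which mix outside the spawning
season). The toolkit covers the full path from amplicon read counts to stock
composition tables:

- **Amplicon genotyping** — dual-barcode demultiplexing (96 combinatorial
  11 bp barcodes, Levenshtein matching, five hierarchical read categories)
  and genotype calling from the allele-1/allele-2 read-count ratio *r*:
  hom1 for *r* ≥ 5.0, hom2 for *r* ≤ 0.2, het for 0.3 ≤ *r* ≤ 3.33, no call
  in the gap zones or below 10 reads; individuals need ≥ 40/45 genotypes.
- **Baseline population genetics** — exact Hardy–Weinberg tests (Levene
  conditional distribution), genotypic LD G-tests with permutation nulls,
  multi-locus pairwise Weir–Cockerham (1984) F<sub>ST</sub>
  (θ = Σa / Σ(a+b+c)) with permutation p-values and locus-bootstrap CIs,
  Holm correction, and PCoA of the distance matrix.
- **DAPC and cluster discovery** — PCA → LDA with cross-validated PC
  selection, and K-means over PC scores scored by
  BIC(K) = n·ln(W_K/n) + K·ln(n), with clusters relabelled as population
  proxies from their known-origin composition.
- **Hierarchical SVM assignment** — balanced training sets, top-F<sub>ST</sub>
  or random locus subsampling, PCA → radial-kernel SVM with Platt-calibrated
  probabilities, Monte Carlo and K-fold cross-validation, and a two-level
  decision table (Level 1: `6aN_Aut` vs `6aS`+`6aN_Sp`; Level 2: `6aS` vs
  `6aN_Sp`) with a 0.67 probability threshold and threshold sweeps.
- **Synthetic data** — block-structured allele-frequency simulation
  (45 markers in 14 linked blocks on 8 chromosomes), HWE genotype draws,
  negative-binomial read depths with per-read error, and mixed samples with
  known origins, so the whole pipeline is testable with known truth.

## Worked example

```python
from gsikit.panel import default_panel
from gsikit.simulate import (simulate_allele_frequencies,
                             simulate_baseline_genotypes,
                             simulate_mixed_sample, MixtureSpec)
from gsikit.assignment import (AssignerConfig, hierarchical_self_assignment,
                               train_assigner, assign_unknowns, level_labels,
                               composition_estimate)

panel = default_panel()                      # 45 SNPs, 14 locus blocks
specs = simulate_allele_frequencies(3, panel, 0.5, seed=1,
                                    pop_names=["6aN_Aut", "6aS", "6aN_Sp"],
                                    n_individuals=300)
baseline = simulate_baseline_genotypes(specs, missing_rate=0.01, seed=2)

cfg = AssignerConfig(level=1, n_train_per_group=200, n_pcs=20,
                     n_iterations=10, seed=5)
acc, _ = hierarchical_self_assignment(baseline, cfg)
print(f"self-assignment accuracy: {acc:.3f}")

mix, truth = simulate_mixed_sample(
    specs, MixtureSpec({"6aN_Aut": 0.6, "6aS": 0.3, "6aN_Sp": 0.1}, 500), seed=9)
m1 = train_assigner(baseline.genotypes, level_labels(baseline.labels(), 1), cfg)
lab2 = level_labels(baseline.labels(), 2); keep = lab2.notna()
m2 = train_assigner(baseline.genotypes.subset(individuals=lab2.index[keep]),
                    lab2[keep], AssignerConfig(level=2, n_pcs=20,
                                               svm_gamma=0.5, seed=5))
print(composition_estimate(assign_unknowns(m1, m2, mix, threshold=0.67)))
```

Output:

```
self-assignment accuracy: 0.982
6aN_Aut    321
6aS        136
6aN_Sp      38
NA           5
```

98.2% of held-out baseline individuals receive a final call consistent with
their true origin at the 0.67 threshold, and the 60/30/10 mixture is
recovered as 321/136/38 of 500 against realized true origin counts of
325/137/38 — five individuals stay unassigned rather than being guessed.

A command-line interface mirrors the library
(`gsi simulate | demux | call | qc | fst | dapc | clusters | assign | sweep | run`);
`gsi run --out-dir artifacts/` drives the whole synthetic pipeline from one
YAML config and writes deterministic, hash-stamped CSVs.

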