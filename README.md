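# rnamotifs

Tools for asking how much of the repertoire of RNA secondary structures
found in nature is explained by the bias of the sequence→structure map
itself — and whether the small differences that remain are enough to tell
natural(-like) RNA from random RNA.

The package folds ensembles of RNA sequences to single minimum-free-energy
secondary structures, coarse-grains them to level-5 abstract shapes
(`[]`-notation helix arrangements), counts five structural motifs per
structure — bulges, hairpin loops, junctions, helices and bonds — and
compares ensembles three ways:

1. **Shape frequencies.** For an ensemble, each shape p gets a probability
   f_p (its fraction of the sample) and a rank. Random genotype sampling
   (G-sampling) yields f_pG; the correlation of log10 f_p with log10 f_pG
   and the fraction of natural shapes recovered by sampling measure
   phenotype bias. The analytic number of possible level-5 shapes,
   s5(L) ≈ 2.44 · 1.32^L · L^(−3/2), calibrates how surprising any overlap
   is (≈10^9 shapes at L = 100, ≈10^45 at L = 400).
2. **Motif trends.** Per-structure motif counts m grow linearly with
   length, m = a·L + b; ordinary least squares over a 50–3000 nt grid with
   percentile-bootstrap 95% CIs gives a five-number summary per ensemble.
3. **Classification.** Stratified 5-fold cross-validated kNN and PLSDA on
   the five motif counts, summarised by ROC AUC with a bootstrap CI;
   PLSDA additionally reports signed variable importances.

It is aimed at researchers in RNA evolution, genotype–phenotype maps and
ncRNA bioinformatics. Natural sequence sets are ingested from user-supplied
FASTA; a synthetic "pseudo-natural" generator (GC-composition bias plus
Boltzmann selection on motif counts) makes every downstream stage testable
without a database download.

## Worked example

Fold 30,000 uniform random 100-nt sequences with ViennaRNA and count the
distinct level-5 shapes that appear:

```python
from rnamotifs.experiments import unique_shape_count
from rnamotifs.shape_stats import shape_space_size

print(unique_shape_count(n=30_000, L=100, seed=1))   # -> 40
print(f"{shape_space_size(100).estimate:.2e}")       # -> 2.79e+09
```

Thirty thousand random sequences produce only 40 distinct shapes out of
~2.8 × 10^9 possible ones — the sequence→shape map concentrates almost all
probability on a tiny set of shapes (strong phenotype bias).

Fit the motif-count trends for the same kind of random ensemble
(25 sequences per length over the 50–3000 nt grid):

```python
from rnamotifs.experiments import random_trend_slopes
slopes = random_trend_slopes(seed=1, n_per_length=25)
print({k: round(v, 4) for k, v in slopes.items()})
```

```
{'bulges': 0.0181, 'loops': 0.0177, 'junctions': 0.0083, 'helices': 0.0724, 'bonds': 0.3134}
```

Read: a random 1000-nt RNA carries on the order of 313 base pairs in ~72
helices, with ~18 hairpin loops and ~8 multiloop junctions; every motif
accumulates linearly with length.

Classify a pseudo-natural ensemble (fewer bulges/bonds, more loops) against
random sequences:

```python
from rnamotifs.folding import ViennaEngine
from rnamotifs.synthetic import PseudoNaturalSpec, generate_pseudo_natural, make_feature_dataset
from rnamotifs.classification import knn_cv

spec = PseudoNaturalSpec(L=200, n=200)
structures, labels = generate_pseudo_natural(spec, ViennaEngine(), seed=1)
df = make_feature_dataset(structures, labels)
result = knn_cv(df.drop(columns="label").to_numpy(float),
                df["label"].to_numpy(int), k=5, seed=1)
print(round(result.auc, 2), [round(c, 2) for c in result.ci])
```

```
0.64 [0.59, 0.69]
```

An AUC near 0.5 would mean the ensembles are indistinguishable from motif
counts alone; 1.0 would be perfect separation. The default effect sizes
inject a modest natural-minus-random contrast, so a 200-nt ensemble is
separable but far from cleanly — separation grows with the effect-size
vector δ and with sequence length.

A `rnamotifs` console script exposes the same steps as subcommands
(`sample`, `fold`, `shapes`, `motifs`, `trends`, `classify`, `simulate`,
`run-all`); see `rnamotifs --help`.

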