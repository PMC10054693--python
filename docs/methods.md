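# Methods

`rnamotifs` analyses how strongly the RNA sequence→secondary-structure
(genotype→phenotype) map biases the repertoire of structures, and whether
the residual differences between natural-like and random RNA are large
enough to classify the two. This note records the models, parameter
choices and numerical conventions the package commits to.

## Structures, loop decomposition and motifs

A secondary structure is a nested set of base pairs written in dot-bracket
notation. Parsing is stack-based over the plain `()` alphabet; pseudoknot
alphabets are out of scope. Every valid structure decomposes uniquely into
loop faces, which the package represents as a tree rooted at the exterior
region: maximal runs of stacked pairs are HELIX nodes, and each helix's
interior face is classified by the number of helices it encloses and the
sidedness of its unpaired runs — HAIRPIN (0 enclosed helices), BULGE (1,
unpaired on one strand), INTERNAL (1, unpaired on both strands), MULTILOOP
(≥ 2). A face with zero unpaired bases between two stacked pairs cannot
occur (it would be one helix); the tree builder asserts this.

The five analysis features per structure are:

* **bonds** — base pairs;
* **helices** — HELIX nodes (maximal stacks);
* **loops** — hairpin loops;
* **bulges** — one-sided single-helix faces;
* **junctions** — multiloops.

Internal loops are counted as an auxiliary sixth quantity and enter none of
the five features (a `internal_as_bulge` switch folds them into bulges for
sensitivity analysis). The bulge/internal boundary is convention-sensitive
across the literature — some counting schemes reserve "bulge" for short
(even single-nucleotide) one-sided runs and call the rest internal loops —
and the split materially changes the per-length bulge rate (roughly 0.018
vs 0.011 per nt for random uniform sequences) while leaving the combined
single-helix-face rate unchanged. This package commits to the sidedness
definition above, with no size threshold. This assignment is the only one consistent with the
observed trend magnitudes: helix counts grow at roughly 0.073 per nt while
hairpins + bulges + junctions together grow at ~0.04 per nt, and each helix
terminates in exactly one loop-type face (the tree identity
`helices == loops + bulges + junctions + internals`, tested exhaustively
for all structures of length ≤ 14). The exterior region contributes to no
count: its helices are already counted, and trend intercepts near zero
support excluding it as a "loop".

A second, tree-free motif counter (`motif_counts_scan`) recomputes all six
counts by direct pair-table scanning and serves as an independent oracle in
the test suite.

## Shape abstraction

Abstract shapes coarse-grain a structure to its helix arrangement in
square-bracket notation. Level 5 — the level used for all frequency
analyses — is defined operationally: collapse every maximal chain of
helices connected only through bulges or internal loops into a single
`[...]`; a chain ending in a hairpin renders `[]`; a chain ending in a
multiloop wraps the concatenation of its branch shapes; the exterior
concatenates its branches; a pair-free structure renders the sentinel `_`
(distinct from the empty string so frequency tables stay well-defined).
Levels 1–4 are provided for illustration following the published RNAshapes
abstraction ladder (level 4 merges across bulges only; level 3 keeps every
helix; levels 2 and 1 add `_` markers for unpaired runs) and are not used
by any analysis. The level-5 invariant
`#'[' == loops + junctions` is tested exhaustively at small lengths. No
external shape program is called; the collapse rule is unambiguous for
nested structures.

## Folding engines

The analysis engine is ViennaRNA's single minimum-free-energy structure at
package defaults (37 °C, default dangles, no constraints); the engine
version string is recorded in every run's provenance sidecar. The
simplification of treating the MFE structure as "the" phenotype ignores
the Boltzmann ensemble and co-transcriptional kinetics; abstract shapes
are relatively insensitive to suboptimal-fold fluctuation, which is why
level-5 analyses tolerate it.

A built-in Nussinov-style engine (maximise Watson–Crick + GU wobble pairs,
minimum hairpin length 3, deterministic traceback preferring unpaired
positions and then smallest partners) provides a dependency-free baseline
used by unit tests and toy pipelines. Its bond counts are verified against
an exhaustive-enumeration maximiser for short sequences. It is never used
for headline numbers.

## Sampling and the pseudo-natural generator

Random sequences draw residues i.i.d. from a composition specification
(uniform by default, or a GC fraction split evenly between G/C and A/U).
Scrambling permutes a sequence uniformly, preserving its exact residue
multiset — the standard control for composition-driven differences. FASTA
ingestion normalises T→U and skips records with ambiguity codes (random
resolution would perturb folding); length filtering is exact by default
because the analyses stratify by exact length.

Natural sequence databases cannot ship with the package, so the
`synthetic` module generates a labelled stand-in with the two properties
the downstream analysis needs:

* per-sequence GC fractions drawn from Beta(gc_alpha, gc_beta)
  (default Beta(2, 2): mean 0.5, realistic spread ~0.22 — natural ncRNA
  GC content varies widely around a near-central mean);
* a motif-count shift δ injected by selection-by-resampling: for each
  pseudo-natural slot, `candidates_per_accept` (default 5) candidate
  sequences are folded and one is kept with Boltzmann weight
  ∝ exp(motif vector · δ).

Boltzmann (softmax) selection was chosen over a hard argmax deliberately:
an argmax is invariant to the scale of δ, so "effect size" would be a
direction only; the Boltzmann weight makes selection strength grow
smoothly with ‖δ‖, is a uniform draw at δ = 0, and converges to the argmax
in the strong-selection limit. With δ = 0 *and* the GC law disabled
(`gc_alpha = gc_beta = None`) both classes are generated by the identical
process, giving an exactly exchangeable null — the configuration used to
calibrate classifier AUC against a label-permutation band. Note that
δ = 0 with a Beta GC law is *not* exchangeable: composition spread alone
changes motif-count distributions.

The default δ evaluates the natural-minus-random contrast of the reference
linear trends at the configured length (fewer bulges and bonds, more
loops); these magnitudes are configuration, not claims about nature. The
generator does not simulate phylogenetic relatedness or family structure,
so classifier results on synthetic data speak to the pipeline's
sensitivity, not to performance on real databases.

## Shape statistics

Frequency tables assign each distinct shape its count, probability
(count/total) and rank (1 = most probable; ties broken lexicographically
on the shape string for determinism). Coverage is the fraction of unique
natural shapes also present in the sampled ensemble. The frequency
correlation between two ensembles is Pearson's r on log10 probabilities
over the intersection of shapes (zeros have no logarithm; an optional
add-one pseudocount mode uses the union instead), with the two-sided
p-value from the standard t transform and no multiple-testing correction
(a handful of length strata at most). Base 10 matches log-scale plotting
conventions; r itself is base-invariant.

The analytic size of level-5 shape space is 2.44 · 1.32^L · L^(−3/2)
(minimum hairpin length 3, 'min' ladder convention matching MFE folding):
about 10^9 shapes at L = 100 and 10^45 at L = 400, which is what makes the
observed tiny sampled shape sets evidence of strong phenotype bias.

## Motif trends

Per-structure motif counts are regressed on length by ordinary least
squares, m = a·L + b, over structure-level points (not per-length means:
the bootstrap is only meaningful with structure-level replication). The
default grid {50, 100, 200, 300, 400, 600, 800, 1000, 1500, 2000, 2500,
3000} spans the 50–3000 nt analysis range with affordable cost at the
cubic-time large lengths. Confidence intervals are nonparametric
percentile bootstrap (B = 1000 by default), resampling points with
replacement; noiseless data collapse the intervals to zero width, and the
width tracks the analytic OLS standard error within a factor of two in
tests.

## Classification

Features are the five motif counts; labels are binary
(natural/pseudo-natural = 1). Evaluation is stratified five-fold
cross-validation with a single repetition; features are z-scored with
statistics fit on the training folds only (bond counts dwarf junction
counts, and both kNN distances and PLS weights are scale-sensitive).

* **kNN** — k = 5 by default (the neighbour count is exposed as
  configuration); the out-of-fold score is the fraction of the k nearest
  training neighbours labelled 1.
* **PLSDA** — labels encoded ±1, PLS regression with 2 components by
  default; the out-of-fold continuous prediction is the score. Signed
  variable importances are the fold-averaged regression coefficients on
  standardised features; unsigned VIP scores are also reported since the
  two conventions are both in circulation.

ROC AUC is computed on the pooled out-of-fold scores with the
Mann–Whitney tie convention; its 95% CI is a percentile bootstrap over
(score, label) pairs, redrawing (and logging) single-class resamples.

## Problem sizes and determinism

Headline computations run at fixed sizes chosen to finish in minutes on a
single core: shape diversity folds 30,000 uniform random L = 100
sequences; the random-ensemble trend study folds 25 sequences per grid
length (300 structures, 1500 motif points). All randomness flows through
numpy Generators; pipelines derive independent per-stage substreams from
one run seed, so a single seed and config fully determine every output
byte. Each run directory carries a `provenance.json` with the config hash
and folding-engine version.

## Known limitations

Single MFE structure per sequence (no Boltzmann ensemble, no kinetics);
no pseudoknots, noncanonical pairs or tertiary contacts; exact-length
stratification assumes the relevant functional length is known; the
synthetic ensemble is i.i.d. (no families); level 1–4 shape strings are
best-effort illustrations, not analysis surfaces.
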