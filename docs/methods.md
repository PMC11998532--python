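# Methods

## The problem

Plus-strand RNA plant viruses engineered as VIGS (virus-induced gene
silencing) vectors tend to delete foreign inserts within weeks. The working
model behind this package is that viral genomes have evolved substructures
with tuned *plasticity* — a balance of thermodynamic stability (MFE free
energy, ΔG) and conformational ambiguity (positional entropy) — and that an
insert is retained only when its own thermodynamic profile matches that of
the natural hairpins of the backbone. `rnaplast` operationalizes that model:
it computes the plasticity metrics, mines the structural statistics of
genomes, simulates random hairpin populations to map the ΔG–length–entropy
landscape, and turns the resulting regression into a design rule for
candidate inserts.

## Plasticity metrics

All thermodynamics come from the ViennaRNA nearest-neighbor (Turner-style)
energy model at 37 °C (configurable): the MFE structure and its free energy
ΔG (kcal/mol, ≤ 0; a sequence with no favorable pairs reports the open
chain at 0), and the partition-function base-pair probability matrix
p_ij with per-residue unpaired probability q_i = 1 − Σ_j p_ij.

Positional entropy (PE) of residue i is the Shannon entropy of its
pairing-state distribution:

    S_i = −[ Σ_j p_ij log p_ij + q_i log q_i ] / log(base)

with 0·log 0 := 0. **The default log base is 2**, matching the convention
of the folding engine's own positional-entropy output (the source of
published PE color maps); with base 2 our recomputation from p_ij agrees
with the engine per residue to better than 1e−3 (the residual comes only
from the engine's sparsity cutoff on tiny probabilities). The base is a
parameter so natural-log sensitivity checks are one keyword away; the
closed-form oracles in the test suite exercise base e (S = ln k for k
equiprobable states, exactly).

APE (average positional entropy) is the arithmetic mean of S_i over a
1-based inclusive span; it is exactly additive, so the APE of a
concatenation is the length-weighted mean of span APEs. For structure
drawings, PE maps to a clear-to-red scale as min(S_i, cap)/cap with
cap = 2.6, the highest per-residue value observed across the study's
structures (in bits); larger values clip to full red.

## Structure mining

Structures are pseudoknot-free pair tables parsed from dot-bracket (one
bracket family; additional families are rejected — a documented
representation limit) or standard 6-column CT text. Coordinates are 1-based
inclusive throughout, matching genome-position conventions.

A *simple hairpin* is a stem-loop with exactly one apical loop: starting
from each hairpin loop's closing pair, the stem grows outward through
stacked pairs, bulges and internal loops of any size, and stops at a
multiloop branch or the exterior loop. Growth through arbitrarily large
internal loops is deliberate (the mined genomes contain hairpins with big
bulges); a `max_loop_size` cap is available when a stricter definition is
wanted. Motifs with fewer than `min_stem_pairs` pairs (default 3) are
dropped so that incidental 1–2-pair stems in unstructured sequence are not
counted as hairpins; the default is a package choice, configurable. The
miner is verified exhaustively against an independent nesting-forest
decomposition on every balanced dot-bracket string of length ≤ 14
(180,339 structures).

Supporting statistics: apical-loop count (pairs with no pairs strictly
inside), maximal unpaired runs of at least `min_run` residues (default 11,
i.e. "more than 10 consecutive unpaired"), and the longest uninterrupted
helix (consecutive stacked pairs).

## Random-hairpin population

`random_hairpin` draws a 5' arm of uniform random ACGU (stem lengths 10,
15, 30, 45, 60, 75 or 90 nt), a 5-nt uniform random apical loop, and a 3'
arm in which each position mirroring 5' position i is forced to the
Watson-Crick complement of residue i with probability c/100
(complementarity c ∈ {0, 10, …, 100}), otherwise drawn uniformly — so at
0% the arms are independent and a mirrored position still matches by
chance 1/4 of the time, and at 100% the 3' arm is the exact reverse
complement. G:U wobble never counts as complementary in the generator,
though the energy model may still pair it. An exact-count mode (forcing
⌊c·L/100⌋ positions chosen uniformly) is available behind a flag for
sensitivity checks; the Bernoulli semantics is the default because the
population-level complementarity is then only guaranteed in expectation,
matching how the populations this emulates were described.

Each hairpin is folded and characterized (ΔG, APE, apical-loop count,
simple-hairpin topology). Randomness: one root seed; each
(stem, complementarity, replicate) cell derives its own stream from the
tuple, so catalogs are byte-identical across runs and independent of
iteration order. The default analysis size is 100 replicates per cell
(7,700 hairpins, a few minutes on one core); the full-scale population of
38,577 corresponds to 501 replicates per cell and scales linearly.

What the generator does *not* emulate: real-genome nucleotide composition,
dinucleotide structure, or selection — so passing population-level tests
shows the thermodynamic relationships are properties of the energy model
over random sequence, not evidence about any particular genome.

`synth_backbone` builds a genome-like folding context for insertion-site
experiments: fully complementary 15-bp stems with 5-nt loops joined by
random C/U linkers (pyrimidines cannot pair with each other, keeping the
linkers effectively single-stranded); the intended reference structure is
returned alongside, and refolding recovers ≥ 90% of designed pairs.

## Regression and population statistics

`DeltaGLengthRegressor` is a scikit-learn estimator for the OLS fit of ΔG
on length, reporting slope, intercept, R², F(1, n−2), p, and residual SE,
plus the *prediction* interval for a new hairpin at length x:

    ŷ(x) ± t_{1−α/2, n−2} · s · sqrt(1 + 1/n + (x − x̄)² / Sxx)

A prediction-type band (not a confidence band for the mean) is used because
the design question is about a single new insert; its construction is
validated by Monte-Carlo coverage (95% ± 3% over 2,000 trials, and at the
4-point natural-hairpin design specifically). `RegressionFit.from_summary`
reconstructs a fit from published summaries (slope, intercept, the x
design, and F) via s² = slope²·Sxx/F, so a published regression can serve
as a reference band without the raw responses; reconstruction from rounded
summaries reproduces a published 95% band at 160 nt to within a few
kcal/mol, which is expected rounding-level disagreement.

Population summaries over a catalog: per-complementarity ΔG-vs-length
slopes with mean-SE bands; binned APE against the ratio r = ΔG/length with
a descriptive curve APE = a + b·ln(r_max − r + ε) (ε = 0.01, r_max = 0 —
the curve is descriptive only; the Spearman correlation of bin ratio vs
bin-mean APE is the primary monotonicity diagnostic); and apical-loop
mean ± SE per complementarity level, pooled over stem lengths (SE =
sd/√n).

## Retention assessment

`assess_retention` applies four checks to a characterized hairpin:

* **dg_in_band** — ΔG ≥ the lower bound of the level-0.95 prediction
  interval of the natural regression at the hairpin's length. The check is
  one-sided at the bottom: hairpins *more* stable than natural ones are
  the documented failure mode, while a ΔG above the upper bound only
  warns, because weakly structured inserts are caught by the entropy and
  topology checks.
* **ape_global** — whole-hairpin APE ≤ 0.25. Natural hairpins sit at
  0.11–0.19 and the loosest retained designed exemplar at 0.23; 0.25 is
  the smallest round bound accepting all retained exemplars.
* **ape_window** — every sliding 15-nt window mean PE ≤ 0.60. This
  operationalizes "no hot region": documented failures carry apical
  regions at APE 0.75–1.17 while successes stay ≤ 0.23, and a window
  maximum is a stricter statistic than a regional mean (the maximum
  window over a hot region always reaches at least the region's mean).
  Skipped with a warning when no per-residue profile is available.
* **topology** — the MFE structure is a single simple hairpin.

Verdict is retained-likely iff all enabled checks pass. The thresholds are
explicit heuristics calibrated to the nine published retained/lost
exemplars (9/9 concordance) and are all configurable; they are not claims
about other backbones.

`regional_ape_change` folds a context without and with an insert placed
immediately after a 1-based position ("insert at N" interrupts after
residue N — the convention is stated here because usage elsewhere is
ambiguous) and compares the mean PE of the context residues within a
30-nt radius of the site (plus the insert residues, after insertion). The
empty insert returns a delta of exactly 0.

`design_mimic` is greedy stochastic local search over a hairpin's 3' side
toward a target ΔG: start from the exact reverse complement of the fixed
5' arm plus a tetraloop; proposals are mismatch substitutions,
single-residue deletions (bulges), loop edits, and re-complementation
moves; a proposal is kept iff it reduces |ΔG − target|. Success requires
landing within tolerance *and* passing the global-APE and topology checks,
re-verified by refolding; exhausting the budget raises an explicit error
with the search trace rather than returning a best effort. The search is
deterministic given its generator state. The achievable ΔG is bounded by
full pairing of the arm, so far-off targets fail fast and honestly.

## Numerical and interface choices

* ΔG values are rounded to 0.01 kcal/mol (the engine's printed precision).
* Base-pair probability rows are validated to Σ ≤ 1 + 1e−6; entropy
  tolerances (1e−3 vs the engine) absorb the engine's sparsity cutoff.
* Degenerate regressions (single point, zero length-variance) raise;
  exactly collinear data report R² = 1 with zero residual SE and an
  infinite F rather than dividing by zero.
* One tabular dialect everywhere: UTF-8 TSV, '.' decimals, '#' header
  lines recording tool version, config digest and seed, so reruns are
  byte-comparable.
* The CLI (`rnaplast fold | pe-colors | mine | simulate | regress |
  assess | design | insert-scan | fig11`) is a thin layer over the library;
  all stochastic subcommands take `--seed`.

## Limitations

* No pseudoknots or tertiary interactions; the plasticity metrics describe
  the secondary-structure ensemble only.
* Printed ΔG reproductions depend on the energy-parameter version of the
  folding engine; small drift across engine versions is expected.
* The retention thresholds are calibrated to nine exemplars from one viral
  backbone; they are decision heuristics, not biophysical constants.
* The synthetic backbone is a folding testbed, not a model of any real
  genome's sequence composition.
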