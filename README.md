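# rnaplast

RNA plasticity analysis and hairpin-insert design for viral VIGS vectors.

Foreign sequences inserted into plant-virus VIGS (virus-induced gene
silencing) vectors are usually deleted within weeks. A thermodynamic
explanation is that viral genomes have evolved substructures with tuned
*plasticity*, and inserts are retained only when they match: each natural
hairpin's minimum-free-energy ΔG scales almost perfectly linearly with its
length (for the reference umbravirus-like backbone, ΔG = −0.42·L − 2.84
kcal/mol, R² = 0.988), every residue keeps low positional entropy, and each
substructure folds as a single simple stem-loop. `rnaplast` implements the
computational side of that story for people designing or analyzing hairpin
inserts:

* **Plasticity metrics** — MFE ΔG, partition-function base-pair
  probabilities, per-residue positional entropy
  S_i = −[Σ_j p_ij log₂ p_ij + q_i log₂ q_i], span-averaged APE, and the
  clear-to-red color normalization min(S_i, 2.6)/2.6 used for structure
  drawings (ViennaRNA backend, Turner nearest-neighbor model, 37 °C).
* **Structure mining** — dot-bracket and CT parsing; simple-hairpin
  extraction (one apical loop, bulges/internal loops allowed, stopping at
  multiloops); apical-loop counts; maximal unpaired runs; longest helix.
* **Random-hairpin simulation** — seeded populations over stem lengths
  10–90 nt and Watson-Crick complementarity 0–100%, folded and
  characterized, reproducing the ΔG–length–entropy landscape.
* **Statistics** — `DeltaGLengthRegressor`, a scikit-learn estimator for
  the OLS fit of ΔG on length with F/R²/residual-SE inference and
  prediction intervals ("retention bands"); per-complementarity slope
  tables; binned APE vs ΔG/length; apical-loop summaries.
* **Design tools** — retention assessment of candidate hairpins, regional
  APE change at an insertion site, and stochastic mimic design of a hairpin
  toward a target ΔG.

## Worked example

Assess a fully base-paired GC-rich 60-nt hairpin, then redesign it to match
the natural thermodynamics:

```python
import numpy as np
from rnaplast import (RegressionFit, predict_dg, recommended_dg, RnaSequence,
                      characterize_hairpin, assess_retention, design_mimic)

# the natural-hairpin regression, reconstructed from its published summary
ref = RegressionFit.from_summary(slope=-0.42, intercept=-2.84,
                                 x_values=[197, 32, 83, 61], f_stat=237.7)
print(predict_dg(ref, 160))

candidate = RnaSequence("candidate",
    "GCGGCCGCAUGGCCGGAUCCGGCACGGCUAACGCCGUGCCGGAUCCGGCCAUGCGGCCGC")
rec = characterize_hairpin(candidate)
assessment = assess_retention(rec, ref)
print(assessment.verdict)
for line in assessment.reasons:
    print(" ", line)
```

```
target dG at 160 nt: -70.04 kcal/mol (95% band -88.2 to -51.9)
candidate: 60 nt, dG -70.1 kcal/mol, APE 0.009, simple hairpin: True
verdict: retained-unlikely
  dg_in_band: FAIL (measured -70.100 vs bound -44.896) — 95% band (-44.9, -11.2) at 60 nt
  ape_global: pass (measured 0.009 vs bound 0.250)
  ape_window: pass (measured 0.013 vs bound 0.600) — max 15-nt window mean PE
  topology: pass (measured 1.000 vs bound 1.000) — MFE structure must be a single simple hairpin
```

The candidate folds beautifully and has almost no positional entropy, but at
−70.1 kcal/mol it is far *too stable* for a 60-nt hairpin — exactly the
profile of inserts that get deleted. Redesigning the 3' side toward the
recommended ΔG while keeping the 5' targeting arm fixed:

```python
arm = RnaSequence("arm", "GCGGCCGCAUGGCCGGAUCCGGCACGGC")
target = recommended_dg(60, ref)                  # -28.04 kcal/mol
rec, trace = design_mimic(arm, target_dg=target.point, tolerance=2.0,
                          rng=np.random.default_rng(11), max_iter=400)
print(rec.delta_g, rec.ape, assess_retention(rec, ref).verdict)
```

```
designed 56 nt hairpin: dG -28.3, APE 0.249, 15 accepted moves
verdict: retained-likely
GCGGCCGCAUGGCCGGAUCCGGCACGGCAAAUGCCCGCCGGCUCCCGAAUCGGCCU
..(((((.((..(.(((.(((((..(((....))).))))).))).).))))))).
```

Fifteen accepted mismatch/bulge moves bring the hairpin inside the
prediction band at its length while keeping a single apical loop and low
entropy — the profile of inserts that are retained.

The same stages are scriptable from the shell:

```sh
rnaplast fold hairpins.fasta
rnaplast simulate --replicates 100 --seed 1 --out catalog.tsv
rnaplast fig11 --replicates 100 --seed 1 --outdir report/
rnaplast assess candidates.fasta --fit-tsv natural_points.tsv --out report.tsv
```

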