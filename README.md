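# skullroof

Phylogenetic comparative analysis of skull-roof microanatomy in burrowing
(fossorial) lepidosaurs — lizards, snakes and their relatives.

Fully fossorial lepidosaurs dig head-first, and their skull roofs respond:
the bone becomes highly compact (osteosclerotic), the skull diameter small,
the cranium elongate, and the frontal short relative to the parietal.
`skullroof` implements the full measurement-to-inference chain needed to
test whether such traits evolved convergently with lifestyle:

1. **Morphometry** — six traits per specimen from binary μCT cross-section
   masks of the four roofing bones (premaxilla, nasal, frontal, parietal),
   two sections per bone:
   - compactness *c* = bone pixels / pixels inside the outer bone boundary;
   - mean local thickness (Hildebrand–Rüegsegger largest-inscribed-disc
     construction in 2D, after cavity filling), summarised as the integral
     *d* of relative thickness over the anterior half of the cranial
     profile, *d* = ∫₀^0.5 d_rel(s) ds with d_rel = thickness / dia × 100;
   - anteroposterior bone overlap
     *ovl* [%] = 100 (2/3 − 2Δ/(L_A + L_B)), where Δ is the signed distance
     between the flanking cross-sections of neighbouring bones (100 % =
     centred alignment, 0 % = exact abutment);
   - *rfp* = L_frontal / L_parietal, *dia* = √(w·h), *elo* = l / dia;
   - the resolving transform c_log = −log₁₀((105 − c)/105) for compactness
     values crowded against 100 %.
2. **Lifestyle signal** — phylogenetically informed ANOVA: Pagel's-λ GLS
   whitening plus residual-randomization permutation (RRPP) inference, with
   pairwise least-squares-mean contrasts and Holm adjustment.
3. **Ancestral lifestyle** — ML Mk models, stochastic character mapping
   with uniformized branch histories, branch-wise posterior profiles and
   >50 % acquisition calls; Retention Index and phylogeny–lifestyle
   two-block PLS for clade clustering.
4. **Convergence** — Stayton's univariate C1 (1 − D_tip/D_max over focal
   clade pairs) and C5 (lineages entering the focal morphospace: interval
   in 1-D, minimum-area enclosing ellipse in 2-D), with p-values from
   Brownian-motion simulation nulls; mean converging vectors; PCA.
5. **Synthetic studies** — a generator producing complete studies (tree,
   Mk lifestyle history, regime-switching OU traits with a fossorial
   optimum, PNG section masks of controlled compactness) with full ground
   truth, so every stage is testable without scan data.

## Worked example

```python
from skullroof.synthetic import SimConfig, gen_dataset
from skullroof.pipeline import load_dataset, run_full_pipeline, results_summary

gen_dataset(SimConfig(n_tips=40, seed=42), "demo_study")
cfg = {"seed": 1, "n_perm": 999, "n_sim": 999, "n_maps": 200}
summary = results_summary(run_full_pipeline(load_dataset("demo_study", cfg)))
```

which prints (formatted):

```
ANOVA (trait c): F=14.3, lambda=1.00, p=0.0010
  fully vs non: d=0.157, p_holm=0.0030
  fully vs semi: d=0.105, p_holm=0.0030
  non vs semi: d=0.052, p_holm=0.2640
lambda(c)=1.00  RI=0.82  r-PLS=0.69  acquisitions=4
c        C1=0.84 (p=0.0010)  C5=4 (p=0.0630)
dia      C1=0.51 (p=0.0120)  C5=2 (p=0.3140)
control  C1=0.40 (p=0.0980)  C5=1 (p=1.0000)
PC1 share = 85.1%
```

Reading: mean compactness measured back from the generated masks separates
the fully fossorial class from both other classes (Holm-adjusted p ≈ 0.003)
but the two non-fully classes do not differ; the trait carries a strong
phylogenetic signal (λ ≈ 1); stochastic mapping recovers the four planted
independent acquisitions of the fully fossorial lifestyle; compactness is
strongly convergent across those clades (C1 = 0.84, p ≈ 0.001) while the
neutral control trait is not; and compactness dominates the first principal
component of the converging traits.

The same chain is available from the shell:

```sh
skullroof simulate demo_study --n-tips 40 --seed 42
skullroof all demo_study demo_out --seed 1 --n-perm 999 --n-sim 999 --n-maps 200
```

Full-scale defaults (10 000 permutations and maps, 30 000 convergence
simulations) are used when counts are not reduced; reduced runs are
labelled in the log.

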