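# fairgen

Synthetic-data augmentation for fairer diagnostic imaging models, at desk
scale.  Medical image classifiers inherit the skews of their training data:
when a demographic subgroup or an acquisition site is underrepresented —
especially in combination with particular diagnoses — models lean on
spurious shortcuts and their performance splits across subgroups, most
visibly under distribution shift.  `fairgen` implements, end to end and on a
single CPU, the generative recipe for countering this:

1. **Train** a conditional denoising-diffusion model (DDPM) on labeled *and*
   unlabeled images, with blockwise conditioning on the diagnostic label and
   optionally a sensitive attribute or site id; an all-zero block means
   "unknown", which is how unlabeled images participate.
2. **Sample** a synthetic pool under a *fair policy*: attribute values drawn
   uniformly, labels drawn from the empirical prevalence p(y), so
   p̂(a, y) = Uniform(a) × p(y).  Classifier-free guidance
   ε̂ = (1+w) ε(x,t,c) − w ε(x,t,∅) sharpens samples toward canonical
   exemplars of the conditioned cell.
3. **Mix and train**: each training example comes from the real labeled set
   with probability α, else from the synthetic pool, and a diagnostic
   classifier is fit by empirical risk minimisation on the mixture —
   targeting the fair risk E_{p_f}[L(f(x), y, a)] instead of the skewed one.

Around this core the package provides the audit instruments used to judge
the result: subgroup best–worst gaps, AUC parity, high-risk sensitivity,
balanced/top-k accuracy, a Beta-posterior spread for small-sample fairness
differences, MMD domain-shift estimates with a cubic polynomial kernel and a
Mann–Whitney replicate protocol, PCA variance-retention compression counts,
and consistently-misclassified-individual analysis.  A seeded synthetic
cohort generator with planted label/attribute/domain structure (blob radius
= label, corner hue = attribute, colour cast = site) plus multi-rater
soft-label aggregation stand in for clinical datasets, so every stage is
testable without any downloads.

Intended users: researchers studying fairness interventions and
distribution shift in medical ML who want a small, fully controlled,
reproducible sandbox in which the ground truth (the planted rule and the
Bayes optimum) is known exactly.

## Worked example

`examples/fair_mixture_theory.py` demonstrates the core property on a
closed-form two-Gaussian toy (class signal on one axis, attribute signal on
the orthogonal axis, Bayes fair accuracy Φ(1) ≈ 0.841):

```
Bayes-optimal fair accuracy : 0.841
skewed training set         : acc=0.799  subgroup gap=0.033
fair mixture (alpha=0)      : acc=0.855  subgroup gap=0.002
```

A classifier trained on the skewed set (attribute strongly correlated with
the label) sits well below the Bayes bound and carries a subgroup gap; the
same classifier trained on the α=0 fair mixture from a perfect generator
recovers the bound and closes the gap.

`examples/soft_labels.py` shows the rater-aggregation rule on its canonical
two-rater input:

```
soft label : [0.5, 0.167, 0.0, 0.333]
```

Rater 1 reports (A,4),(B,3); rater 2 reports (A,3),(D,4).  Per rater,
conditions are ranked by descending confidence and weighted 1/rank; weights
are summed across raters and normalised — A ends up with half the mass, and
the case fails a strict t=0.9 canonical-case filter on every condition.

Other examples: `generate_cohort.py` (planted-structure cohorts, skewing),
`diffusion_sampling.py` (label-conditional generation with fidelity check),
`shift_diagnostics.py` (MMD replicates + U-test, PCA compression),
`end_to_end_experiment.py` (the full three-step pipeline with baseline and
synthetic arms; prints per-arm OOD accuracy and subgroup gap).

A thin CLI mirrors the common workflows:

```bash
fairgen cohort generate --config cohort.yaml --seed 1 --out data/
fairgen run --config experiment.yaml --out results/
```

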