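# ppsi — polynomial progression subtype inference

`ppsi` infers **disease stages and subtypes from purely cross-sectional
data**. Given an observation-by-feature table of biomarkers (z-scored
against a confounder-adjusted control model), it learns, for each of S
subtypes, one polynomial trajectory per feature over a latent pseudotime
axis t ∈ [0, 1] discretized into K+1 stages (stage 0 is the control
anchor, where every trajectory is pinned at 0). Each observation is
hard-assigned to the subtype and stage whose multivariate Gaussian
"stage-cluster" explains it best, and the trajectories are trained by
gradient descent on the resulting likelihood.

It is aimed at researchers modelling progressive conditions
(neurodegeneration, cancer protein expression, organ decline) who have a
single measurement per subject and want a data-driven ordering of
disease severity plus a partition into differently-progressing subtypes —
the problem family of event-based models and SuStaIn, but with
continuous, possibly non-monotonic polynomial trajectories and a much
cheaper fit.

## Model

With stages t_k = k/K, basis matrix T ∈ R^{(K+1)×D}, T[k, d] = t_k^d,
and per-subtype coefficients Θ_s ∈ R^{D×P}, the stage-cluster centroids
are M_s = T·Θ_s. An observation x_n scores

φ_{s,k}(x_n) = Σ_p [ ln α − (x_{n,p} − μ_{k,p,s})² / β ],   α = 1/(σ√2π), β = 2σ²

with fixed σ, and is assigned to (s, k) = argmax φ. The training loss is

L(Θ) = − Σ_n max_{s,k} φ_{s,k}(x_n) + λ Σ |θ|

minimized by Adam with a warmup-plus-cosine learning-rate schedule, with
gradients flowing only through each record's current argmax cell
(hard-assignment subgradient, as in k-means / hard EM). One loss
evaluation is O(S·K·P·N).

The package also includes the surrounding workflow: normative z-scoring
(`ppsi.preprocess`), a ground-truth progression simulator
(`ppsi.simulate`), a cross-validated order × subtype-count sweep with six
evaluation metrics (`ppsi.model_selection`), feature-dropout importance
(`ppsi.feature_reduction`), recovery and longitudinal validation
statistics (`ppsi.validation`), and dataset/model IO, plotting and a thin
`ppsi` command-line interface.

## Worked example

```python
from ppsi import (FitConfig, GeneratorParams, adjusted_rand_index, fit,
                  predict, simulate_dataset, staging_correlation)

data, truth = simulate_dataset(GeneratorParams(
    n_polynomials=20, n_subtypes=2, dimensions=2, record_count=400,
    noise_min=0.2, noise_max=0.4, subtype_class_imbalance_index=0.0, seed=7))
model = fit(data, FitConfig(D=2, S=2, seed=0))
assignments = predict(model, data)
print(adjusted_rand_index(truth.record_subtype, [a.subtype for a in assignments]))
print(staging_correlation(truth.record_stage, [a.stage for a in assignments]).abs_r)
```

Running `python examples/simulate_and_recover.py` (this scenario) prints:

```
simulated 400 records x 20 features, true subtype counts: [193 207]
final loss: 7778.2
subtyping ARI: 1.000  (1 = perfect partition recovery, 0 = chance)
staging Pearson |r|: 0.992  (axis inverted: false)
```

ARI of 1.0 means the two latent subtypes were recovered exactly;
staging |r| of 0.99 means assigned stages track the latent pseudotime up
to discretization. The other scripts under `examples/` walk through
normative z-scoring, the subtype sweep, feature dropout and longitudinal
validation, each printing and explaining its numbers.

The same workflow is available from the shell:

```sh
ppsi simulate --seed 7 --out data.csv --truth truth.csv
ppsi fit --data data.csv --subtypes 2 --order 2 --out model.json
ppsi predict --model model.json --data data.csv --out assignments.csv
```

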