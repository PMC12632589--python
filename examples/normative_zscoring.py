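"""Normative z-scoring against a control sample.

Builds a toy control table where a biomarker drifts with age, fits the
confounder model on controls, and expresses patient values as z-scores
relative to what a control of the same age would show.
"""

import numpy as np

from ppsi import fit_normative, zscore

rng = np.random.default_rng(0)

# controls: biomarker = 0.8 * age + noise
age_controls = rng.uniform(55, 85, size=120)
biomarker_controls = 0.8 * age_controls + rng.normal(scale=3.0, size=120)

normative = fit_normative(
    biomarker_controls[:, None],
    age_controls[:, None],
    feature_names=["biomarker"],
    confounder_names=["age"],
)
print(f"control model: biomarker = {normative.coefficients[0, 0]:.2f} "
      f"+ {normative.coefficients[1, 0]:.3f} * age, "
      f"residual sd = {normative.residual_std[0]:.2f}")

# two patients of the same age, one at the control expectation, one far above
age_patients = np.array([[70.0], [70.0]])
values = np.array([[0.8 * 70.0], [0.8 * 70.0 + 9.0]])
z = zscore(normative, values, age_patients)
print(f"patient z-scores: {z.X.ravel().round(2)}")
# ~0 for the first patient (at the age-expected control value) and ~3 for
# the second (three control residual SDs above expectation) -- the scale
# the progression model's stage-0 anchor assumes.
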