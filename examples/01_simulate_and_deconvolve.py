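"""Simulate a bulk melanoma-like cohort and recover cell fractions.

Builds a 22-cell-type signature matrix, mixes it into 60 bulk samples with
three planted immune subtypes, deconvolves the bulk profiles by nu-SVR, and
reports how close the estimated fractions come to the planted truth.
"""

import numpy as np

from iciscope import svr_deconvolve
from iciscope.simulate import simulate_cohort

cohort = simulate_cohort(n_samples=60, seed=42)
fractions = svr_deconvolve(cohort.expression, cohort.signature)

mae = np.abs(fractions.data.to_numpy() - cohort.true_fractions.data.to_numpy()).mean()
print(f"samples: {len(fractions.data)}, cell types: {len(fractions.cell_types)}")
print(f"mean absolute error vs planted fractions: {mae:.4f}")
print(f"median reconstruction RMSE: {fractions.diagnostics['rmse'].median():.4f}")
# an MAE well under 0.05 means the deconvolution tracks the planted immune
# composition despite the multiplicative expression noise
print(fractions.data.iloc[:3, :4].round(3))
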