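"""How many axes are nontrivial? Bootstrap eigenvalue bands vs the scree.

Replicate eigenvalue bands from 1000 resamples are compared rank by rank:
retain another axis only while the min of rank k clears the max of rank k+1
(the non-overlap criterion at trim level 0). A one-factor structure with a
weak beta-vs-theta contrast lands at m* = 2, the classical result for
strongly inter-correlated EEG features.
"""

from pcaboot import (
    fit_pca,
    make_resample_plan,
    nonoverlap_dimension,
    replicate_eigenvalues,
    standardize,
    synth_feature_matrix,
)
from pcaboot.simulate import two_factor_spec

X = synth_feature_matrix(two_factor_spec(seed=42))
model = fit_pca(standardize(X))
plan = make_resample_plan(X.n, R=1000, seed=42)
bands = replicate_eigenvalues(X, plan)
report = nonoverlap_dimension(bands, model=model)
print(report.summary())
print(
    "\n'separated' is True while the rank's eigenvalue band clears the next"
    "\nband entirely; m* counts the leading separations plus one."
)
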