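"""Normalize one array and build the imputed M-value matrix.

Shows the effect of MA-loess normalization on a dye-biased array: the raw
M values curve with intensity A; after global loess the residual trend is
near zero.  Then runs the full pre-processing chain (filter, impute,
collapse duplicates, drop unlabeled samples).
"""

import numpy as np

import maclust as mc

exp = mc.generate_experiment(mc.SimConfig(dye_bias_amplitude=0.8, seed=2))
scan = exp.scans[0]

raw = mc.compute_ma(scan, background_correct=False)
norm = mc.apply_normalization(scan, "norm.glob")
ok = ~raw.missing

# size of the intensity-dependent trend before and after normalization
# (mean |trend| over the observed spots; the tails of A are sparse, so the
# residual trend there is noisier than in the dense center)
trend_raw = mc.loess_fit(raw.M[ok], raw.A[ok])
trend_norm = mc.loess_fit(norm.M[ok], norm.A[ok])
print(f"mean |loess trend| raw:        {np.mean(np.abs(trend_raw(raw.A[ok]))):.3f} (log2 units)")
print(f"mean |loess trend| normalized: {np.mean(np.abs(trend_norm(norm.A[ok]))):.3f}")
print(f"missing spots on this array:  {raw.missing.sum()} of {scan.n_spots}")

matrix, labels = mc.preprocess_scans(exp.scans, exp.labels_mapping(),
                                     normalization="norm.pt.bkg",
                                     imputation="SVD")
info = matrix.provenance["imputation"]
print(f"matrix after preprocessing:   {matrix.n_genes} genes x "
      f"{matrix.n_samples} samples, no missing values")
print(f"SVD imputation: k={info['k']}, {info['iterations']} iterations, "
      f"converged={info['converged']}")
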