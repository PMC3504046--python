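"""Independent reference computations used to validate the implementation.

These deliberately take a different route from the package code: per-voxel
regression goes through statsmodels' OLS, and sphere membership is found by
exhaustive lattice enumeration.
"""

import numpy as np
import statsmodels.api as sm


def ols_tmap_oracle(Y, X, weights):
    """Per-voxel OLS via statsmodels: betas, t values, two-sided p values."""
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    betas, tvals, pvals = [], [], []
    for v in range(Y.shape[1]):
        res = sm.OLS(Y[:, v], X).fit()
        tt = res.t_test(np.asarray(weights, dtype=float))
        betas.append(res.params)
        tvals.append(float(np.squeeze(tt.tvalue)))
        pvals.append(float(np.squeeze(tt.pvalue)))
    return np.array(betas).T, np.array(tvals), np.array(pvals)


def sphere_lattice_count(radius_mm, voxel_mm):
    """Number of lattice points (spacing voxel_mm) within radius_mm of origin."""
    reach = int(np.ceil(radius_mm / voxel_mm))
    count = 0
    for i in range(-reach, reach + 1):
        for j in range(-reach, reach + 1):
            for k in range(-reach, reach + 1):
                if (i * i + j * j + k * k) * voxel_mm**2 <= radius_mm**2:
                    count += 1
    return count
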