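"""Numba inner loops for the single-site Gibbs sampler.

All randomness is drawn outside (numpy Generator) and passed in as arrays,
so chains are bit-reproducible given a seed and the loops stay pure
compute. Coefficient matrices are expected in Fortran order for contiguous
column access.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def update_effects_gaussian(W, csum, a, e, var_a, sigma2_e, normals):
    """One sweep of Gaussian (BRR / BayesA) effect updates.

    var_a is per-effect prior variance (a constant vector under BRR).
    Residual e is updated in place.
    """
    n = e.shape[0]
    L = a.shape[0]
    for z in range(L):
        c = csum[z]
        if c < 1e-12:
            a[z] = 0.0
            continue
        az = a[z]
        col = W[:, z]
        r = np.dot(col, e) + c * az
        lam = sigma2_e / var_a[z]
        v = c + lam
        anew = r / v + normals[z] * np.sqrt(sigma2_e / v)
        diff = anew - az
        for i in range(n):
            e[i] -= col[i] * diff
        a[z] = anew


@njit(cache=True)
def update_effects_spike_slab(W, csum, a, incl, e, var_a, sigma2_e, logit_pi,
                              normals, uniforms):
    """One sweep of spike-and-slab (BayesB / BayesC) effect updates.

    Each effect is either excluded (point mass at zero) or drawn from its
    Gaussian slab; the inclusion indicator is sampled from the exact
    single-site marginal odds with the effect integrated out.
    """
    n = e.shape[0]
    L = a.shape[0]
    for z in range(L):
        c = csum[z]
        if c < 1e-12:
            a[z] = 0.0
            incl[z] = 0
            continue
        az = a[z]
        col = W[:, z]
        r = np.dot(col, e) + c * az
        v0 = c * sigma2_e
        v1 = v0 + c * c * var_a[z]
        logodds = logit_pi + 0.5 * np.log(v0 / v1) + 0.5 * r * r * (1.0 / v0 - 1.0 / v1)
        if logodds > 35.0:
            p_in = 1.0
        elif logodds < -35.0:
            p_in = 0.0
        else:
            p_in = 1.0 / (1.0 + np.exp(-logodds))
        if uniforms[z] < p_in:
            lam = sigma2_e / var_a[z]
            v = c + lam
            anew = r / v + normals[z] * np.sqrt(sigma2_e / v)
            incl[z] = 1
        else:
            anew = 0.0
            incl[z] = 0
        diff = anew - az
        if diff != 0.0:
            for i in range(n):
                e[i] -= col[i] * diff
        a[z] = anew


@njit(cache=True)
def update_eigen_effects(U, eigval, delta, e, sigma2_u, sigma2_e, normals):
    """One sweep over the eigen-coordinates of a kernel random effect.

    The effect is u = U delta with delta_j ~ N(0, eigval_j * sigma2_u);
    U columns are orthonormal so each coordinate has unit sum of squares.
    """
    n = e.shape[0]
    m = delta.shape[0]
    for j in range(m):
        dj = delta[j]
        col = U[:, j]
        r = np.dot(col, e) + dj
        lam = sigma2_e / (eigval[j] * sigma2_u)
        v = 1.0 + lam
        dnew = r / v + normals[j] * np.sqrt(sigma2_e / v)
        diff = dnew - dj
        for i in range(n):
            e[i] -= col[i] * diff
        delta[j] = dnew
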