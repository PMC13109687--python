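"""Independent WHAM reference used as a cross-implementation oracle.

Solves the same estimator as popswitch.wham but by a different numerical
route: direct minimization of the WHAM negative log-likelihood

    A(g) = sum_j M_j ln( sum_i N_i exp(g_i - b_ij/kT) ) - sum_i N_i g_i

over the reduced window free energies g_i = F_i/kT, with the analytic
gradient, via L-BFGS. The minimizer's stationarity conditions are exactly
the WHAM self-consistency equations, so the two routes must agree at their
common fixed point; the code paths share nothing beyond numpy.
"""

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from popswitch.constants import kt


def reference_wham(windows, bin_width, temperature=298.15):
    """Return (bin_centers, W, occupied_mask) for the anchored PMF."""
    kbt = kt(temperature)
    windows = sorted(windows, key=lambda w: w.center)
    lo = min(w.samples.min() for w in windows)
    hi = max(w.samples.max() for w in windows)
    first = np.floor(lo / bin_width) * bin_width
    n_bins = int(np.ceil((hi - first) / bin_width)) + 1
    edges = first + bin_width * np.arange(n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])

    counts = np.stack([np.histogram(w.samples, bins=edges)[0]
                       for w in windows]).astype(float)
    n_i = counts.sum(axis=1)
    m_j = counts.sum(axis=0)
    occ = m_j > 0
    log_n = np.log(n_i)
    bias = np.stack([0.5 * w.force_constant * (centers - w.center) ** 2
                     for w in windows]) / kbt

    def objective(g):
        # log sum_i N_i exp(g_i - b_ij) per occupied bin
        z = log_n[:, None] + g[:, None] - bias[:, occ]
        log_denom = logsumexp(z, axis=0)
        a = float(m_j[occ] @ log_denom - n_i @ g)
        # gradient: sum_j M_j softmax_i(z) - N_i
        soft = np.exp(z - log_denom)
        grad = soft @ m_j[occ] - n_i
        return a, grad

    res = minimize(objective, np.zeros(len(windows)), jac=True,
                   method="L-BFGS-B",
                   options={"maxiter": 5000, "ftol": 1e-15, "gtol": 1e-10})
    g = res.x
    z = log_n[:, None] + g[:, None] - bias[:, occ]
    log_p = np.log(m_j[occ]) - logsumexp(z, axis=0)
    w = np.full(centers.size, np.nan)
    w[occ] = -kbt * log_p
    w -= np.nanmin(w)
    return centers, w, occ
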