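"""Independent reference oracles used only by the test suite.

The reference WHAM solves the same statistical problem as the package's
self-consistent iteration but by a different route: direct minimization of
the convex WHAM negative log-likelihood with L-BFGS (analytic gradient,
log-sum-exp stabilized).  Agreement between the two is a genuine
cross-check of the fixed-point implementation.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp


def reference_wham(bin_centers, counts, z0s, ks, kT):
    """Maximum-likelihood WHAM on precomputed histograms.

    Parameters: shared bin centers (B,), per-window counts (W, B), window
    reference positions and force constants, and kT.  Returns ``(G, mask)``
    where G (kJ/mol) is defined on sampled bins (NaN elsewhere) with an
    arbitrary constant.
    """
    counts = np.asarray(counts, dtype=float)
    z = np.asarray(bin_centers, dtype=float)
    N = counts.sum(axis=1)
    M = counts.sum(axis=0)
    sampled = M > 0
    u = 0.5 * np.asarray(ks)[:, None] \
        * (z[None, :] - np.asarray(z0s)[:, None]) ** 2 / kT  # (W, B)
    logN = np.log(N)

    zs = u[:, sampled]
    Ms = M[sampled]

    def objective(g):
        # log D_b = logsumexp_i (log N_i + g_i - u_ib)
        logD = logsumexp(logN[:, None] + g[:, None] - zs, axis=0)
        F = float(np.sum(Ms * logD) - np.sum(N * g))
        w = np.exp(logN[:, None] + g[:, None] - zs - logD[None, :])
        grad = w @ Ms - N
        return F, grad

    res = minimize(objective, np.zeros(len(N)), jac=True, method="L-BFGS-B",
                   options={"maxiter": 20000, "ftol": 1e-15, "gtol": 1e-8})
    g = res.x
    logD = logsumexp(logN[:, None] + g[:, None] - zs, axis=0)
    logp = np.log(Ms) - logD
    G = np.full(z.shape, np.nan)
    G[sampled] = -kT * logp
    return G, sampled
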