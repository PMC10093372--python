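"""Single-site Gibbs sweep over SNP effects.

The sweep is shared by the whole Bayesian alphabet: conditional on the
per-SNP effect variance (and, for spike-and-slab priors, the prior
inclusion probability 1−π), each SNP's indicator is sampled from the
normal likelihood ratio with the effect integrated out, then the effect
from its normal full conditional. All randomness is passed in as
pre-drawn uniform/normal arrays so the chain is a pure function of the
caller's RNG stream; numba only accelerates the loop.
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        def wrap(f):
            return f
        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True)
def snp_sweep(Wt, wtw, r, m, delta, var_m, sigma_e2, pi, z, u):
    """One Gibbs pass over all SNPs, updating effects and the residual
    vector in place.

    Wt: (p, n) transposed centered marker matrix (C-contiguous rows);
    wtw: per-SNP sum of squares; r: residual y − Xb − Σ w_j m_j; m, delta:
    current effects and inclusion indicators; var_m: per-SNP effect
    variance; z, u: standard-normal and uniform draws, one per SNP.
    """
    p, n = Wt.shape
    for j in range(p):
        c = wtw[j]
        old = m[j]
        if c <= 0.0 or var_m[j] <= 0.0:
            if old != 0.0:
                for t in range(n):
                    r[t] += Wt[j, t] * old
            m[j] = 0.0
            delta[j] = 0 if pi > 0.0 else 1
            continue
        rhs = c * old
        for t in range(n):
            rhs += Wt[j, t] * r[t]
        include = True
        if pi > 0.0:
            v0 = c * sigma_e2
            v1 = c * c * var_m[j] + v0
            logr = (
                math.log((1.0 - pi) / pi)
                + 0.5 * math.log(v0 / v1)
                + 0.5 * rhs * rhs * (1.0 / v0 - 1.0 / v1)
            )
            if logr > 35.0:
                include = True
            elif logr < -35.0:
                include = False
            else:
                include = u[j] < 1.0 / (1.0 + math.exp(-logr))
        if include:
            lhs = c + sigma_e2 / var_m[j]
            mean = rhs / lhs
            new = mean + z[j] * math.sqrt(sigma_e2 / lhs)
            delta[j] = 1
        else:
            new = 0.0
            delta[j] = 0
        d = new - old
        if d != 0.0:
            for t in range(n):
                r[t] -= Wt[j, t] * d
        m[j] = new
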