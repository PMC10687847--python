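"""Numba kernels for the Gibbs location sweeps.

Two sweep strategies over an effect group's levels:

* blocked — all k components of a level are drawn jointly from their k-variate
  normal full conditional. Valid only when components never share a record
  (direct/indirect incidences are disjoint because focal != opponent); joint
  draws mix far better than scalar ones when components are strongly
  negatively correlated, which is exactly the regime the dominance model
  lives in.
* scalar — one component at a time, correct regardless of shared records
  (used for herd effects, contemporary groups and fixed effects).

Both maintain the residual vector e = obs - (full linear predictor) in place.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["sweep_block", "sweep_scalar"]


@njit(cache=True)
def sweep_block(e, tau, u, colptr, rows, vals, prec, use_rel,
                a_indptr, a_indices, a_data, a_diag, z):  # pragma: no cover
    k, nlev = u.shape
    zi = 0
    M = np.empty((k, k))
    b = np.empty(k)
    x = np.empty(k)
    v = np.empty(k)
    for i in range(nlev):
        for c in range(k):
            b[c] = 0.0
            for c2 in range(k):
                M[c, c2] = 0.0
        for c in range(k):
            sl = 0.0
            sr = 0.0
            for p in range(colptr[c, i], colptr[c, i + 1]):
                r = rows[p]
                w = vals[p]
                t = tau[r]
                sl += w * w * t
                sr += w * t * (e[r] + w * u[c, i])
            M[c, c] += sl
            b[c] += sr
        if use_rel:
            di = a_diag[i]
            for c in range(k):
                for c2 in range(k):
                    M[c, c2] += prec[c, c2] * di
            for c2 in range(k):
                dot = 0.0
                for q in range(a_indptr[i], a_indptr[i + 1]):
                    dot += a_data[q] * u[c2, a_indices[q]]
                dot -= di * u[c2, i]
                for c in range(k):
                    b[c] -= prec[c, c2] * dot
        else:
            for c in range(k):
                for c2 in range(k):
                    M[c, c2] += prec[c, c2]
        # x ~ N(M^-1 b, M^-1) via Cholesky M = L L'
        L = np.linalg.cholesky(M)
        # mean: solve L y = b, then L' m = y
        for c in range(k):
            s = b[c]
            for c2 in range(c):
                s -= L[c, c2] * x[c2]
            x[c] = s / L[c, c]
        for c in range(k - 1, -1, -1):
            s = x[c]
            for c2 in range(c + 1, k):
                s -= L[c2, c] * x[c2]
            x[c] = s / L[c, c]
        # noise: solve L' v = z
        for c in range(k - 1, -1, -1):
            s = z[zi + c]
            for c2 in range(c + 1, k):
                s -= L[c2, c] * v[c2]
            v[c] = s / L[c, c]
        zi += k
        for c in range(k):
            newv = x[c] + v[c]
            delta = newv - u[c, i]
            if delta != 0.0:
                for p in range(colptr[c, i], colptr[c, i + 1]):
                    e[rows[p]] -= vals[p] * delta
                u[c, i] = newv


@njit(cache=True)
def sweep_scalar(e, tau, u, colptr, rows, vals, prec, z):  # pragma: no cover
    k, nlev = u.shape
    zi = 0
    for c in range(k):
        for i in range(nlev):
            lhs = prec[c, c]
            rhs = 0.0
            for p in range(colptr[c, i], colptr[c, i + 1]):
                r = rows[p]
                w = vals[p]
                t = tau[r]
                lhs += w * w * t
                rhs += w * t * (e[r] + w * u[c, i])
            for c2 in range(k):
                if c2 != c:
                    rhs -= prec[c, c2] * u[c2, i]
            if lhs <= 0.0:
                # no data and no prior: leave at current value (dropped column)
                zi += 1
                continue
            newv = rhs / lhs + z[zi] / np.sqrt(lhs)
            zi += 1
            delta = newv - u[c, i]
            if delta != 0.0:
                for p in range(colptr[c, i], colptr[c, i + 1]):
                    e[rows[p]] -= vals[p] * delta
                u[c, i] = newv
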