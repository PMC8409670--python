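"""Compiled inner loop of iterative proportional scaling.

Each edge update matches one 2x2 marginal covariance to the target S by a
rank-2 precision update; the covariance iterate is maintained with a
Woodbury identity so a sweep costs O(|E| p^2) instead of O(|E| p^3).
Status codes: 0 converged, 1 sweep budget exhausted, -1 lost positive
definiteness (a required 2x2 marginal of S or of the iterate is singular).
"""

from __future__ import annotations

import numpy as np
from numba import njit

OK = 0
NO_CONVERGENCE = 1
NOT_PD = -1


@njit(cache=True)
def ips_sweeps(
    S: np.ndarray,
    edges: np.ndarray,  # (m, 2) int64
    K: np.ndarray,      # precision iterate, modified in place
    Sigma: np.ndarray,  # its inverse, modified in place
    tol: float,
    max_sweeps: int,
) -> int:
    p = S.shape[0]
    m = edges.shape[0]
    vi = np.empty(p)
    vj = np.empty(p)
    for _ in range(max_sweeps):
        for t in range(m):
            i = edges[t, 0]
            j = edges[t, 1]
            a = S[i, i]
            b = S[i, j]
            c = S[j, j]
            det_s = a * c - b * b
            if det_s <= 0.0 or a <= 0.0:
                return NOT_PD
            A = Sigma[i, i]
            B = Sigma[i, j]
            C = Sigma[j, j]
            det_t = A * C - B * B
            if det_t <= 0.0 or A <= 0.0:
                return NOT_PD
            # D = inv(S_ee) - inv(Sigma_ee)
            d11 = c / det_s - C / det_t
            d12 = -b / det_s + B / det_t
            d22 = a / det_s - A / det_t
            # M = D (I + Sigma_ee D)^{-1}
            e11 = 1.0 + A * d11 + B * d12
            e12 = A * d12 + B * d22
            e21 = B * d11 + C * d12
            e22 = 1.0 + B * d12 + C * d22
            det_e = e11 * e22 - e12 * e21
            if det_e <= 0.0:
                return NOT_PD
            ie11 = e22 / det_e
            ie12 = -e12 / det_e
            ie21 = -e21 / det_e
            ie22 = e11 / det_e
            m11 = d11 * ie11 + d12 * ie21
            m12 = d11 * ie12 + d12 * ie22
            m21 = d12 * ie11 + d22 * ie21
            m22 = d12 * ie12 + d22 * ie22
            K[i, i] += d11
            K[i, j] += d12
            K[j, i] += d12
            K[j, j] += d22
            for r in range(p):
                vi[r] = Sigma[r, i]
                vj[r] = Sigma[r, j]
            # Sigma <- Sigma - [vi vj] M [vi vj]^T
            for r in range(p):
                wi = vi[r] * m11 + vj[r] * m21
                wj = vi[r] * m12 + vj[r] * m22
                for s in range(p):
                    Sigma[r, s] -= wi * vi[s] + wj * vj[s]
        # convergence: Sigma must match S on the diagonal and on the edges
        err = 0.0
        for r in range(p):
            d = abs(Sigma[r, r] - S[r, r])
            if d > err:
                err = d
        for t in range(m):
            i = edges[t, 0]
            j = edges[t, 1]
            d = abs(Sigma[i, j] - S[i, j])
            if d > err:
                err = d
        if err < tol:
            return OK
    return NO_CONVERGENCE
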