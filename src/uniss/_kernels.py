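"""Numba kernels for the simulator hot path."""

from __future__ import annotations

import numba
import numpy as np


@numba.njit(cache=True)
def ar1_inplace(eps, rho):  # pragma: no cover - exercised via simdata
    """Turn i.i.d. N(0,1) draws (p x n, variants first) into a stationary
    AR(1) sequence along variants, in place."""
    p, n = eps.shape
    c = np.sqrt(1.0 - rho * rho)
    for j in range(1, p):
        for i in range(n):
            eps[j, i] = rho * eps[j - 1, i] + c * eps[j, i]


@numba.njit(cache=True)
def top_k_alleles(z, k_per_variant, out):  # pragma: no cover - exercised via simdata
    """Add 1 to ``out`` for the ``k`` samples with the largest latent value
    per variant (p x n layout).

    Equivalent to thresholding the within-variant descending-rank fraction
    strictly below MAF: exactly k = #{r : r/n < MAF} samples carry the allele.
    """
    p, n = z.shape
    for j in range(p):
        k = k_per_variant[j]
        if k <= 0:
            continue
        if k >= n:
            for i in range(n):
                out[j, i] += 1
            continue
        thr = np.partition(z[j], n - k - 1)[n - k - 1]
        for i in range(n):
            if z[j, i] > thr:
                out[j, i] += 1
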