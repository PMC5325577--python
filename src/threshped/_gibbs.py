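"""Numba kernel for the animal-effect scan of the threshold-model sampler.

One call performs a Gibbs sweep over all animal effects, conditionally on
the current latent liabilities, fixed effects, genetic covariance G0 and
residual covariance R0 (fixed effects are drawn jointly in numpy by the
caller — their dimension is small — while the ``n_animals`` sparse scan
lives here).  The per-record residual precision is ``1/r_m`` when one
trait is observed and the inverse of the 2x2 residual covariance when both
are; the caller passes the precomputed weights (``w00b``, ``w01b``,
``w11b`` for doubly-observed records, ``w0s``, ``w1s`` for singly-observed
ones).

Animal effects are updated in per-animal blocks across traits (T<=2),
using the animal's row of the sparse A-inverse: conditional precision
C_i = sum_rec W_rec + A^-1_ii * G0^-1 and mean C_i^-1 (sum_rec W_rec *
(e_rec + a_i) - G0^-1 sum_{j!=i} A^-1_ij a_j).

The residual array ``e = liability - eta`` is maintained incrementally and
is both input and output.  Standard-normal innovations are pre-drawn by
the caller (``z_anim``) so all randomness flows from one generator.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def animal_scan(obs, e, a,
                ai_indptr, ai_indices, ai_data,
                ar_ptr, ar_idx, g0inv,
                w00b, w01b, w11b, w0s, w1s,
                z_anim):
    T = a.shape[1]
    n_ped = a.shape[0]
    for i in range(n_ped):
        c00 = 0.0
        c01 = 0.0
        c11 = 0.0
        r0 = 0.0
        r1 = 0.0
        for k in range(ar_ptr[i], ar_ptr[i + 1]):
            rr = ar_idx[k]
            if T == 2:
                if obs[rr, 0] == 1 and obs[rr, 1] == 1:
                    et0 = e[rr, 0] + a[i, 0]
                    et1 = e[rr, 1] + a[i, 1]
                    c00 += w00b
                    c11 += w11b
                    c01 += w01b
                    r0 += w00b * et0 + w01b * et1
                    r1 += w11b * et1 + w01b * et0
                elif obs[rr, 0] == 1:
                    c00 += w0s
                    r0 += w0s * (e[rr, 0] + a[i, 0])
                elif obs[rr, 1] == 1:
                    c11 += w1s
                    r1 += w1s * (e[rr, 1] + a[i, 1])
            else:
                if obs[rr, 0] == 1:
                    c00 += w0s
                    r0 += w0s * (e[rr, 0] + a[i, 0])
        dii = 0.0
        for k in range(ai_indptr[i], ai_indptr[i + 1]):
            j = ai_indices[k]
            v = ai_data[k]
            if j == i:
                dii = v
            elif T == 2:
                r0 -= v * (g0inv[0, 0] * a[j, 0] + g0inv[0, 1] * a[j, 1])
                r1 -= v * (g0inv[1, 0] * a[j, 0] + g0inv[1, 1] * a[j, 1])
            else:
                r0 -= v * g0inv[0, 0] * a[j, 0]
        c00 += dii * g0inv[0, 0]
        if T == 2:
            c01 += dii * g0inv[0, 1]
            c11 += dii * g0inv[1, 1]
            l00 = np.sqrt(c00)
            l10 = c01 / l00
            l11 = np.sqrt(c11 - l10 * l10)
            y0 = r0 / l00
            y1 = (r1 - l10 * y0) / l11
            mu1 = y1 / l11
            mu0 = (y0 - l10 * mu1) / l00
            u1 = z_anim[i, 1] / l11
            u0 = (z_anim[i, 0] - l10 * u1) / l00
            new0 = mu0 + u0
            new1 = mu1 + u1
            d0 = new0 - a[i, 0]
            d1 = new1 - a[i, 1]
            a[i, 0] = new0
            a[i, 1] = new1
            for k in range(ar_ptr[i], ar_ptr[i + 1]):
                rr = ar_idx[k]
                if obs[rr, 0] == 1:
                    e[rr, 0] -= d0
                if obs[rr, 1] == 1:
                    e[rr, 1] -= d1
        else:
            new0 = r0 / c00 + z_anim[i, 0] / np.sqrt(c00)
            d0 = new0 - a[i, 0]
            a[i, 0] = new0
            for k in range(ar_ptr[i], ar_ptr[i + 1]):
                rr = ar_idx[k]
                if obs[rr, 0] == 1:
                    e[rr, 0] -= d0
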