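"""Compiled inner loops for the blocked screen.

Every reduction here is a plain sequential loop over the n observations, so
the floating-point accumulation order for one (x, z, y) triple is fixed by
construction — independent of how the matrices are partitioned into files,
how many other columns are present, and how work is split across threads.
That is what makes chunked runs bit-identical to whole-matrix runs.  The
kernels release the GIL so thread-based workers scale.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# smallest positive normal double: guards relative tolerance tests at zero
_TINY = 2.2250738585072014e-308


@njit(nogil=True, cache=True)
def _col_means_sumsq(values):
    """Per-column mean and centered sum of squares with sequential sums.

    The accumulation order per column depends only on the row count, never on
    how many other columns the matrix happens to hold.
    """
    n, p = values.shape
    means = np.empty(p)
    sumsq = np.empty(p)
    for j in range(p):
        s = 0.0
        for i in range(n):
            s += values[i, j]
        m = s / n
        means[j] = m
        ss = 0.0
        for i in range(n):
            d = values[i, j] - m
            ss += d * d
        sumsq[j] = ss
    return means, sumsq


@njit(nogil=True, cache=True)
def _col_sumsq(values):
    """Per-column raw sum of squares, sequential accumulation."""
    n, p = values.shape
    out = np.empty(p)
    for j in range(p):
        s = 0.0
        for i in range(n):
            v = values[i, j]
            s += v * v
        out[j] = s
    return out


@njit(nogil=True, cache=True)
def _outer_column_sweep(o_raw, q2, I_raw, Ic, ss_i, raw_ss_i, Yc, ssy, tol,
                        r_out, ok_out):
    """Screen one outer covariate column against all inner columns and outcomes.

    Writes the partial correlation into r_out[y, inner] with ok_out marking
    testable combinations; returns (degenerate pair count, skipped outcome
    count).  q2 is the normalized centered outer column.
    """
    n = q2.shape[0]
    p_in = Ic.shape[1]
    p_y = Yc.shape[1]

    degenerate = 0
    skipped = 0

    # <y, q2> hoisted out of the inner-column loop
    d2 = np.empty(p_y)
    for yj in range(p_y):
        s = 0.0
        for i in range(n):
            s += Yc[i, yj] * q2[i]
        d2[yj] = s

    q3 = np.empty(n)
    q4 = np.empty(n)
    for ii in range(p_in):
        if ss_i[ii] <= tol * max(raw_ss_i[ii], _TINY):
            degenerate += 1
            continue

        # q3: inner column residualized against q2
        proj = 0.0
        for i in range(n):
            proj += Ic[i, ii] * q2[i]
        ss3 = 0.0
        for i in range(n):
            v = Ic[i, ii] - proj * q2[i]
            q3[i] = v
            ss3 += v * v
        if ss3 <= tol * max(ss_i[ii], _TINY):
            degenerate += 1
            continue
        inv3 = 1.0 / math.sqrt(ss3)
        for i in range(n):
            q3[i] *= inv3

        # q4: interaction product of the raw columns, centered, then
        # residualized against q2 and q3
        mean_p = 0.0
        for i in range(n):
            v = o_raw[i] * I_raw[i, ii]
            q4[i] = v
            mean_p += v
        mean_p /= n
        ssp = 0.0
        for i in range(n):
            q4[i] -= mean_p
            ssp += q4[i] * q4[i]
        a2 = 0.0
        for i in range(n):
            a2 += q4[i] * q2[i]
        for i in range(n):
            q4[i] -= a2 * q2[i]
        a3 = 0.0
        for i in range(n):
            a3 += q4[i] * q3[i]
        ss4 = 0.0
        for i in range(n):
            q4[i] -= a3 * q3[i]
            ss4 += q4[i] * q4[i]
        if ssp <= 0.0 or ss4 <= tol * ssp:
            degenerate += 1
            continue
        inv4 = 1.0 / math.sqrt(ss4)
        for i in range(n):
            q4[i] *= inv4

        # two inner products per outcome; d2 already hoisted
        for yj in range(p_y):
            d3 = 0.0
            d4 = 0.0
            for i in range(n):
                yv = Yc[i, yj]
                d3 += yv * q3[i]
                d4 += yv * q4[i]
            denom_sq = ssy[yj] - d2[yj] * d2[yj] - d3 * d3
            if denom_sq <= tol * max(ssy[yj], _TINY):
                skipped += 1
                continue
            rv = d4 / math.sqrt(denom_sq)
            if rv > 1.0:
                rv = 1.0
            elif rv < -1.0:
                rv = -1.0
            r_out[yj, ii] = rv
            ok_out[yj, ii] = True

    return degenerate, skipped
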