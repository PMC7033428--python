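"""Independent brute-force oracles used by the tests.

These deliberately avoid the library code paths (and numpy's FFT): Fourier
coefficients are computed by direct summation and the band-limited signal is
resynthesized by direct summation, so agreement with the fast implementation
is evidence, not tautology.
"""

import numpy as np


def dft_bandpass_oracle(x, fs, f_low, f_high, pad_to):
    """Direct-summation DFT projection onto the half-open band [f_low, f_high).

    Mirrors the contract of the fast path: demean, append zeros, keep every
    bin whose |frequency| lies in the band (DC always dropped), resynthesize,
    truncate to the original length.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    xp = np.zeros(pad_to)
    xp[:n] = x - x.mean()
    N = pad_to
    m = np.arange(N)
    out = np.zeros(N, dtype=complex)
    for k in range(N):
        f_signed = k * fs / N if k <= N // 2 else (k - N) * fs / N
        f_abs = abs(f_signed)
        if k == 0 or not (f_low <= f_abs < f_high):
            continue
        coeff = np.sum(xp * np.exp(-2j * np.pi * k * m / N))
        out += coeff * np.exp(2j * np.pi * k * m / N) / N
    return out.real[:n]


def ols_slope_intercept(x, y):
    """Closed-form ordinary least squares line fit."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    slope = (xc * (y - y.mean())).sum() / (xc ** 2).sum()
    return slope, y.mean() - slope * x.mean()


def welch_t_pvalue(a, b):
    """Welch two-sample t-test by the textbook formulas."""
    from scipy.stats import t as t_dist

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t_stat = (a.mean() - b.mean()) / np.sqrt(va + vb)
    dof = (va + vb) ** 2 / (va ** 2 / (len(a) - 1) + vb ** 2 / (len(b) - 1))
    return 2 * t_dist.sf(abs(t_stat), dof)
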