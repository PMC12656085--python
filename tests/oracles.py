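"""Independent brute-force oracles for the feature catalogue and metrics.

Everything here is written directly from the defining formulas with plain
Python loops / naive transforms, deliberately sharing no code with the
package implementation.
"""

from __future__ import annotations

import math

import numpy as np


# -- time-domain ------------------------------------------------------------

def o_aav(x):
    return sum(abs(v) for v in x) / len(x)


def o_mmav(x):
    n = len(x)
    total = 0.0
    for i, v in enumerate(x, start=1):
        w = 1.0 if 0.25 * n <= i <= 0.75 * n else 0.5
        total += w * abs(v)
    return total / n


def o_mmav3(x):
    n = len(x)
    total = 0.0
    for i, v in enumerate(x, start=1):
        w = 1.0 if i <= 0.25 * n else 0.5
        total += w * abs(v)
    return total / n


def o_smav(x, fs):
    return o_aav(x) / (len(x) / fs)


def o_mavs(x, k=3):
    m = len(x) // k
    subs = [sum(abs(v) for v in x[j * m : (j + 1) * m]) / m for j in range(k)]
    return [subs[j + 1] - subs[j] for j in range(k - 1)]


def o_lssi(x):
    return math.log(sum(v * v for v in x) + 1e-12)


def o_rmsv2(x):
    return (sum(v * v for v in x) / len(x)) ** 0.5


def o_ewl(x):
    n = len(x)
    total = 0.0
    for i in range(2, n + 1):
        d = abs(x[i - 1] - x[i - 2])
        p = 0.75 if 0.2 * n <= i <= 0.8 * n else 0.5
        total += d**p
    return total


def o_perc2(x):
    a = sorted(abs(v) for v in x)
    n = len(a)
    mid = n // 2
    return a[mid] if n % 2 else 0.5 * (a[mid - 1] + a[mid])


def o_lpc3(x, order=3):
    """LPC via naive autocorrelation and a direct Toeplitz solve (no
    Levinson recursion)."""
    x = np.asarray(x, float)
    n = len(x)
    r = [float(np.dot(x[: n - k], x[k:]) / n) for k in range(order + 1)]
    R = np.array([[r[abs(i - j)] for j in range(order)] for i in range(order)])
    return np.linalg.solve(R, -np.array(r[1 : order + 1]))


# -- spectral ---------------------------------------------------------------

def o_power_spectrum(x, fs):
    """Naive one-sided DFT power spectrum (arbitrary overall scale)."""
    x = np.asarray(x, float)
    n = len(x)
    k = np.arange(n // 2 + 1)
    dft = np.exp(-2j * np.pi * np.outer(k, np.arange(n)) / n) @ x
    p = np.abs(dft) ** 2
    return k * fs / n, p


def o_ftht4(x, fs, band=(20.0, 300.0)):
    f, p = o_power_spectrum(x, fs)
    edges = np.linspace(band[0], band[1], 5)
    powers = np.array([p[(f >= edges[j]) & (f < edges[j + 1])].sum() for j in range(4)])
    return powers / powers.sum()


def o_psr(x, fs, band=(20.0, 300.0), halfwidth=10.0):
    f, p = o_power_spectrum(x, fs)
    m = (f >= band[0]) & (f < band[1])
    fb, pb = f[m], p[m]
    f0 = fb[int(np.argmax(pb))]
    return float(pb[np.abs(fb - f0) <= halfwidth].sum() / pb.sum())


# -- wavelet packets --------------------------------------------------------

def _periodized_halfband(x, filt):
    """One periodized analysis step: circular convolution + dyadic
    downsampling (odd lengths padded by repeating the last sample)."""
    x = list(x)
    if len(x) % 2:
        x = x + [x[-1]]
    n = len(x)
    L = len(filt)
    out = []
    for m in range(n // 2):
        acc = 0.0
        for k in range(L):
            acc += filt[k] * x[(2 * m + L // 2 - k) % n]
        out.append(acc)
    return out


def o_wp_energies(x, dec_lo, dec_hi, level=3):
    """Terminal-node energies of the full wavelet-packet tree via naive
    recursive filter-bank decomposition (signal wrapped to a multiple of
    2**level first, per the feature definition)."""
    x = list(np.asarray(x, float))
    pad = (-len(x)) % (2**level)
    x = x + x[:pad]
    nodes = [x]
    for _ in range(level):
        nxt = []
        for node in nodes:
            nxt.append(_periodized_halfband(node, dec_lo))
            nxt.append(_periodized_halfband(node, dec_hi))
        nodes = nxt
    return np.array([sum(v * v for v in node) for node in nodes])


# -- correlation / ranking --------------------------------------------------

def o_pearson(a, b):
    n = len(a)
    ma = sum(a) / n
    mb = sum(b) / n
    cov = sum((x - ma) * (y - mb) for x, y in zip(a, b))
    va = sum((x - ma) ** 2 for x in a)
    vb = sum((y - mb) ** 2 for y in b)
    return cov / math.sqrt(va * vb)


def o_ccs(samples):
    y = [[math.sqrt(v) for v in ch] for ch in samples]
    out = []
    for i in range(len(y)):
        for j in range(i + 1, len(y)):
            out.append(o_pearson(y[i], y[j]))
    return np.array(out)


def o_concordance_auc(labels, scores):
    """AUC as the Mann-Whitney concordance probability (ties count 1/2)."""
    pos = [s for l, s in zip(labels, scores) if l == 1]
    neg = [s for l, s in zip(labels, scores) if l == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))
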