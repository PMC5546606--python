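"""Independent brute-force reference implementations used by the tests.

Every function here is written as plain nested loops (or a dense full-system
solve) directly from the model's defining formulas, deliberately sharing no
code path with the package's vectorised implementations.
"""

import numpy as np


def estep_brute(t, ctf, a, beta_bar):
    """Responsibilities via direct per-(k, i) evaluation of exp(-delta/2)."""
    n, j = t.shape
    k = a.shape[0]
    r = np.zeros((k, n))
    for i in range(n):
        w = np.zeros(k)
        for kk in range(k):
            d = 0.0
            for jj in range(j):
                d += beta_bar * (t[i, jj] - ctf[i, jj] * a[kk, jj]) ** 2
            w[kk] = d
        w = np.exp(-(w - w.min()) / 2.0)
        r[:, i] = w / w.sum()
    return r


def weights_brute(t, ctf, r, phi, beta_bar, alpha):
    """Solve the full dense normal equations over all (m, j) unknowns.

    Unknown vector x stacks W columns j-major: x[j * M + m] = W[m, j].
    """
    n, j = t.shape
    k, m = phi.shape
    size = m * j
    big_c = np.zeros((size, size))
    big_b = np.zeros(size)
    for jj in range(j):
        for mm in range(m):
            row = jj * m + mm
            for mm2 in range(m):
                col = jj * m + mm2
                acc = 0.0
                for i in range(n):
                    for kk in range(k):
                        acc += (
                            r[kk, i]
                            * beta_bar
                            * phi[kk, mm]
                            * phi[kk, mm2]
                            * ctf[i, jj] ** 2
                        )
                big_c[row, col] = acc + (alpha if mm == mm2 else 0.0)
            acc = 0.0
            for i in range(n):
                for kk in range(k):
                    acc += r[kk, i] * beta_bar * phi[kk, mm] * ctf[i, jj] * t[i, jj]
            big_b[row] = acc
    x = np.linalg.solve(big_c, big_b)
    return x.reshape(j, m).T


def loss_brute(t, ctf, r, a):
    """Triple-loop responsibility-weighted squared-residual loss."""
    n, j = t.shape
    k = a.shape[0]
    total = 0.0
    for i in range(n):
        for jj in range(j):
            for kk in range(k):
                total += r[kk, i] * (t[i, jj] - ctf[i, jj] * a[kk, jj]) ** 2
    return total


def beta_brute(t, ctf, r, a):
    """Componentwise 1/beta_ij and the pooled mean precision."""
    n, j = t.shape
    k = a.shape[0]
    inv_beta = np.zeros((n, j))
    for i in range(n):
        for jj in range(j):
            for kk in range(k):
                inv_beta[i, jj] += r[kk, i] * (t[i, jj] - ctf[i, jj] * a[kk, jj]) ** 2
    return inv_beta, n * j / inv_beta.sum()


def averages_brute(t, ctf, r, beta_bar, alpha):
    """Scalar evaluation of the Wiener-type class-average formula."""
    n, j = t.shape
    k = r.shape[0]
    a = np.zeros((k, j))
    for kk in range(k):
        for jj in range(j):
            num = 0.0
            den = alpha
            for i in range(n):
                num += r[kk, i] * beta_bar * ctf[i, jj] * t[i, jj]
                den += r[kk, i] * beta_bar * ctf[i, jj] ** 2
            a[kk, jj] = num / den
    return a
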