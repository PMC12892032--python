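"""Independent oracles used by the test suite.

These deliberately avoid the package's own algorithms: the wear-time oracle
enumerates candidate non-wear intervals exhaustively over run boundaries, the
WLS oracle accumulates raw normal equations row by row, and the REML oracle
builds each couple's full covariance matrix densely.
"""

from __future__ import annotations

import numpy as np


def runs_of(values):
    """Run-length encoding: list of (start, length, is_zero)."""
    out = []
    i = 0
    n = len(values)
    while i < n:
        j = i
        zero = values[i] == 0
        while j < n and (values[j] == 0) == zero:
            j += 1
        out.append((i, j - i, zero))
        i = j
    return out


def choi_nonwear_oracle(counts, min_len=90, spike_tol=2, flank=30):
    """Exhaustive scan: mark the union of all valid non-wear intervals.

    A candidate interval runs from the start of one zero run to the end of a
    later (or the same) zero run.  It is valid when every non-zero run inside
    has length <= spike_tol and is flanked inside the interval by >= flank
    zeros on each side, and the total length is >= min_len.
    """
    counts = np.asarray(counts)
    n = len(counts)
    nonwear = np.zeros(n, dtype=bool)
    rle = runs_of(counts)
    zero_idx = [k for k, (_, _, z) in enumerate(rle) if z]
    for a_pos, a in enumerate(zero_idx):
        for b in zero_idx[a_pos:]:
            start = rle[a][0]
            end = rle[b][0] + rle[b][1]
            if end - start < min_len:
                continue
            ok = True
            for k in range(a, b + 1):
                _, length, zero = rle[k]
                if zero:
                    continue
                if length > spike_tol:
                    ok = False
                    break
                if rle[k - 1][1] < flank or rle[k + 1][1] < flank:
                    ok = False
                    break
            if ok:
                nonwear[start:end] = True
    return nonwear


def random_block_day(rng, n_minutes=1440):
    """A synthetic day built from alternating zero and activity blocks,
    giving realistic run structure for the wear-time oracle."""
    counts = []
    while len(counts) < n_minutes:
        zero_len = int(rng.integers(1, 200))
        counts.extend([0] * zero_len)
        act_len = int(rng.integers(1, 60))
        counts.extend(rng.integers(1, 6000, size=act_len).tolist())
    return np.asarray(counts[:n_minutes], dtype=float)


def normal_equation_wls(X, y, w=None):
    """Row-by-row accumulation of the weighted normal equations."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.ones(len(y)) if w is None else np.asarray(w, dtype=float)
    p = X.shape[1]
    A = np.zeros((p, p))
    b = np.zeros(p)
    for i in range(len(y)):
        A += w[i] * np.outer(X[i], X[i])
        b += w[i] * X[i] * y[i]
    return np.linalg.solve(A, b)


def dense_reml_loglik(work, outcome, fixed_cols, random_cols, sd, sigma, phi, rho=0.0):
    """REML log-likelihood via dense per-couple covariance matrices."""
    from scipy.linalg import block_diag

    sd = np.asarray(sd, dtype=float)
    Xs, ys, Vs = [], [], []
    for _, g in work.groupby("couple", sort=True):
        g = g.sort_values(["member", "day"])
        X = g[fixed_cols].to_numpy(dtype=float)
        Z = g[random_cols].to_numpy(dtype=float) if random_cols else np.zeros((len(g), 0))
        y = g[outcome].to_numpy(dtype=float)
        m = g["member"].to_numpy()
        d = g["day"].to_numpy()
        same_member = m[:, None] == m[None, :]
        C = np.where(
            same_member,
            np.power(phi, np.abs(d[:, None] - d[None, :])),
            np.where(d[:, None] == d[None, :], rho, 0.0),
        )
        V = Z @ np.diag(sd**2) @ Z.T + sigma**2 * C
        Xs.append(X)
        ys.append(y)
        Vs.append(V)
    X = np.vstack(Xs)
    y = np.concatenate(ys)
    V = block_diag(*Vs)
    Vi = np.linalg.inv(V)
    A = X.T @ Vi @ X
    beta = np.linalg.solve(A, X.T @ Vi @ y)
    r = y - X @ beta
    n, p = X.shape
    return -0.5 * (
        np.linalg.slogdet(V)[1]
        + np.linalg.slogdet(A)[1]
        + r @ Vi @ r
        + (n - p) * np.log(2 * np.pi)
    )


def swap_members(table):
    """Relabel member 1 <-> 2 within every couple (indistinguishability checks)."""
    out = table.copy()
    out["member"] = 3 - out["member"]
    return out.sort_values(["couple", "member", "day"]).reset_index(drop=True)
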