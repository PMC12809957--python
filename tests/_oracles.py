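"""Independent brute-force oracles used by the test suite.

Every function here recomputes a quantity by a different route than the
package (explicit tabular recursions, path enumeration, naive loops,
log-space dynamic programming) so the tests compare two independent
implementations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def tabular_A(ped) -> np.ndarray:
    """Additive relationship matrix by the tabular method."""
    n = ped.n_animals
    s, d = ped.sire_idx, ped.dam_idx
    A = np.zeros((n, n))
    for i in range(n):
        row = np.zeros(n)
        if s[i] >= 0:
            row += 0.5 * A[s[i]]
        if d[i] >= 0:
            row += 0.5 * A[d[i]]
        A[i, :i] = row[:i]
        A[:i, i] = row[:i]
        if s[i] >= 0 and d[i] >= 0:
            A[i, i] = 1.0 + 0.5 * A[s[i], d[i]]
        else:
            A[i, i] = 1.0
    return A


def equivalent_generations_bruteforce(ped, i: int) -> float:
    """Sum of (1/2)^n over all known-ancestor occurrences, by explicit
    path enumeration."""
    s, d = ped.sire_idx, ped.dam_idx
    total = 0.0
    stack = [(i, 0)]
    while stack:
        j, depth = stack.pop()
        for p in (s[j], d[j]):
            if p >= 0:
                total += 0.5 ** (depth + 1)
                stack.append((p, depth + 1))
    return total


def founder_contribution_paths(ped, i: int) -> dict[int, float]:
    """Founder contributions to animal i by explicit path enumeration:
    each founder accumulates (1/2)^len over all ancestor paths."""
    s, d = ped.sire_idx, ped.dam_idx
    out: dict[int, float] = {}
    stack = [(i, 1.0)]
    while stack:
        j, wt = stack.pop()
        if s[j] < 0 and d[j] < 0:
            out[j] = out.get(j, 0.0) + wt
            continue
        for p in (s[j], d[j]):
            if p >= 0:
                stack.append((p, wt / 2.0))
            # unknown-parent share is simply lost here (phantom slot)
    return out


def roh_bruteforce(geno_row: np.ndarray, pos: np.ndarray, params):
    """ROH segments for one animal on one chromosome by naive loops."""
    L = len(pos)
    w = params.window_snps
    if L < w:
        return []
    nwin = L - w + 1
    compliant = []
    for k in range(nwin):
        win = geno_row[k:k + w]
        compliant.append(int(np.sum(win == 1)) <= params.max_het_in_window and
                         int(np.sum(win < 0)) <= params.max_missing_in_window)
    eligible = []
    for j in range(L):
        n_ok = n_all = 0
        for k in range(max(0, j - w + 1), min(j, nwin - 1) + 1):
            n_all += 1
            n_ok += compliant[k]
        eligible.append(n_ok / n_all > params.window_threshold)
    segs = []
    j = 0
    while j < L:
        if not eligible[j]:
            j += 1
            continue
        k = j
        while (k + 1 < L and eligible[k + 1] and
               pos[k + 1] - pos[k] <= params.max_gap_bp):
            k += 1
        length = int(pos[k] - pos[j])
        if length >= params.min_length_bp and (k - j + 1) >= params.min_snps:
            segs.append((int(pos[j]), int(pos[k]), k - j + 1, length))
        j = k + 1
    return segs


def hmm_posterior_logspace(g: np.ndarray, freqs: np.ndarray,
                           d_morgan: np.ndarray, rate: float, mixing: float,
                           error: float):
    """Two-state HBD posteriors and log-likelihood for one animal, by a
    scalar log-space forward-backward recursion."""
    from scipy.special import logsumexp

    L = len(g)
    logB = np.empty((L, 2))
    for l in range(L):
        p = min(max(freqs[l], 1e-4), 1 - 1e-4)
        if g[l] == 2:
            logB[l] = np.log([(1 - error) * p, p ** 2])
        elif g[l] == 1:
            logB[l] = np.log([error, 2 * p * (1 - p)])
        elif g[l] == 0:
            logB[l] = np.log([(1 - error) * (1 - p), (1 - p) ** 2])
        else:
            logB[l] = 0.0
    logpi = np.log([mixing, 1 - mixing])
    logT = []
    for l in range(L - 1):
        s = np.exp(-rate * d_morgan[l])
        T = s * np.eye(2) + (1 - s) * np.tile(np.exp(logpi), (2, 1))
        logT.append(np.log(T))
    la = logpi + logB[0]
    alphas = [la]
    for l in range(1, L):
        la = np.array([logsumexp(la + logT[l - 1][:, j]) for j in range(2)]) \
            + logB[l]
        alphas.append(la)
    loglik = logsumexp(alphas[-1])
    lb = np.zeros(2)
    betas = [lb]
    for l in range(L - 2, -1, -1):
        lb = np.array([logsumexp(logT[l][i, :] + logB[l + 1] + lb)
                       for i in range(2)])
        betas.append(lb)
    betas = betas[::-1]
    post = np.array([np.exp(a + b - loglik) for a, b in zip(alphas, betas)])
    return post[:, 0], float(loglik)


def random_pedigree(rng: np.random.Generator, n: int,
                    p_known: float = 0.8) -> pd.DataFrame:
    """Random acyclic pedigree frame with consistent sexes and years."""
    rows = []
    males, females = [], []
    for i in range(n):
        aid = f"R{i:04d}"
        sex = "M" if rng.random() < 0.5 else "F"
        sire = dam = None
        if males and rng.random() < p_known:
            sire = males[int(rng.integers(len(males)))]
        if females and rng.random() < p_known:
            dam = females[int(rng.integers(len(females)))]
        rows.append((aid, sire, dam, sex, 2000 + i, "1"))
        (males if sex == "M" else females).append(aid)
    return pd.DataFrame(rows, columns=["id", "sire", "dam", "sex",
                                       "birth_year", "flock"])
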