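"""Independent oracles for the test suite.

Everything here is deliberately naive — exhaustive enumeration of secondary
structures, double loops, per-interval recomputation from scratch — so that
it shares no code path with the implementations it checks.
"""

from __future__ import annotations

import math

import numpy as np

from rnasnip.folding import DEFAULT_PAIR_ENERGIES

MIN_HAIRPIN = 3


def can_pair(a: str, b: str) -> bool:
    return (a, b) in DEFAULT_PAIR_ENERGIES


def enumerate_structures(res: str, min_hairpin: int = MIN_HAIRPIN):
    """All non-crossing sets of canonical pairs with hairpin loops >= min size.

    Pairs are 0-based (i, j) tuples; structures are yielded as frozensets.
    """
    n = len(res)
    pairs = [(i, j) for i in range(n) for j in range(i + min_hairpin + 1, n)
             if can_pair(res[i], res[j])]

    def compatible(p, used):
        i, j = p
        for a, b in used:
            if len({a, b, i, j}) < 4:
                return False
            if (a < i < b < j) or (i < a < j < b):
                return False
        return True

    def rec(used, lo):
        yield frozenset(used)
        for idx in range(lo, len(pairs)):
            if compatible(pairs[idx], used):
                yield from rec(used + [pairs[idx]], idx + 1)

    yield from rec([], 0)


def structure_energy(struct, res: str, energies=DEFAULT_PAIR_ENERGIES) -> float:
    return sum(energies[(res[i], res[j])] for i, j in struct)


def boltzmann_distribution(res: str, min_hairpin: int = MIN_HAIRPIN,
                           energy_scale: float = 1.0) -> tuple:
    """({structure: probability}, Z) by direct summation."""
    weights = {}
    for s in enumerate_structures(res, min_hairpin):
        weights[s] = math.exp(-energy_scale * structure_energy(s, res))
    z = sum(weights.values())
    return {s: w / z for s, w in weights.items()}, z


def pair_matrix_enumeration(res: str, min_hairpin: int = MIN_HAIRPIN) -> np.ndarray:
    """0-based upper-triangular P matrix by enumeration."""
    probs, _ = boltzmann_distribution(res, min_hairpin)
    n = len(res)
    P = np.zeros((n, n))
    for s, p in probs.items():
        for i, j in s:
            P[i, j] += p
    return P


def profile_marginals_enumeration(res: str) -> dict:
    """pi / xi marginals by summing over enumerated structures."""
    probs, _ = boltzmann_distribution(res)
    n = len(res)
    pi = np.zeros(n)
    up = np.zeros(n)
    down = np.zeros(n)
    for s, p in probs.items():
        for i, j in s:
            pi[i] += p
            pi[j] += p
            down[i] += p
            up[j] += p
    return {"pi": pi, "xi_up": up, "xi_down": down, "xi_un": 1.0 - pi}


def delta_enumeration(res_x: str, res_y: str) -> float:
    """Ensemble distance by enumeration over the union of structure sets."""
    px, _ = boltzmann_distribution(res_x)
    py, _ = boltzmann_distribution(res_y)
    union = set(px) | set(py)
    return math.sqrt(sum((px.get(s, 0.0) - py.get(s, 0.0)) ** 2 for s in union))


# ---------------------------------------------------------------------------
# naive measure recomputation on matrices

def naive_euclid_matrix(A: np.ndarray, B: np.ndarray) -> float:
    n = A.shape[0]
    total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            total += (A[i, j] - B[i, j]) ** 2
    return math.sqrt(total)


def naive_pearson(x, y) -> float:
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    mx, my = x.mean(), y.mean()
    num = float(((x - mx) * (y - my)).sum())
    den = math.sqrt(float(((x - mx) ** 2).sum()) * float(((y - my) ** 2).sum()))
    return num / den


def restricted_vectors(P_upper: np.ndarray, k: int, l: int, basis: str):
    """Interval-restricted profile vectors from scratch (1-based k, l)."""
    S = P_upper + P_upper.T
    sub = S[k - 1:l, k - 1:l]
    if basis == "pi":
        return sub.sum(axis=1)
    if basis == "xi":
        return np.concatenate([np.tril(sub, -1).sum(axis=1),
                               np.triu(sub, 1).sum(axis=1)])
    iu = np.triu_indices(l - k + 1, 1)
    return P_upper[k - 1:l, k - 1:l][iu]


def brute_force_optimize(P_upper: np.ndarray, Q_upper: np.ndarray, measure: str,
                         basis: str, min_len: int, alpha: float,
                         p_thr: float):
    """Exhaustive per-interval recomputation; returns (score, k, l) or None."""
    X = P_upper.copy()
    X[X < p_thr] = 0.0
    Y = Q_upper.copy()
    Y[Y < p_thr] = 0.0
    n = X.shape[0]
    Sx, Sy = X + X.T, Y + Y.T
    best = None
    for k in range(1, n + 2 - min_len):
        for l in range(k + min_len - 1, n + 1):
            admissible = False
            for S, U in ((Sx, X), (Sy, Y)):
                w_in = U[k - 1:l, k - 1:l].sum()
                w_cross = S[k - 1:l, :].sum() - 2 * w_in
                if w_in >= alpha * w_cross - 1e-9:
                    admissible = True
            if not admissible:
                continue
            a = restricted_vectors(X, k, l, basis)
            b = restricted_vectors(Y, k, l, basis)
            if measure == "d":
                s = math.sqrt(float(((a - b) ** 2).sum()))
                if best is None or s > best[0] + 1e-12:
                    best = (s, k, l)
            else:
                if ((a - a.mean()) ** 2).sum() < 1e-14 or \
                        ((b - b.mean()) ** 2).sum() < 1e-14:
                    continue
                r = naive_pearson(a, b)
                if best is None or r < best[0] - 1e-12:
                    best = (r, k, l)
    return best


def brute_force_reoptimize(P_upper: np.ndarray, Q_upper: np.ndarray,
                           k_star: int, h_prime: int, h_dprime: int):
    """Max of the restricted pi-distance over l in (k*, k* + h'' + h']."""
    n = P_upper.shape[0]
    best = (0.0, k_star)
    for l in range(k_star + 1, min(n, k_star + h_dprime + h_prime) + 1):
        a = restricted_vectors(P_upper, k_star, l, "pi")
        b = restricted_vectors(Q_upper, k_star, l, "pi")
        d = math.sqrt(float(((a - b) ** 2).sum()))
        if d > best[0] + 1e-15:
            best = (d, l)
    return best


def random_bpm_array(n: int, rng: np.random.Generator,
                     n_pairs: int | None = None) -> np.ndarray:
    """A random valid pair-probability matrix (row sums <= 1)."""
    P = np.zeros((n, n))
    m = n_pairs if n_pairs is not None else max(4, n // 2)
    for _ in range(m):
        i = int(rng.integers(0, n - 5))
        j = int(rng.integers(i + 4, n))
        P[i, j] += float(rng.uniform(0.0, 0.6))
    S = P + P.T
    worst = S.sum(axis=1).max()
    if worst > 1.0:
        P /= worst * 1.0001
    return np.triu(P)


def ks_statistic_direct(values: np.ndarray, cdf) -> float:
    """sup |ECDF - CDF| computed from first principles."""
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    F = cdf(x)
    ecdf_hi = np.arange(1, n + 1) / n
    ecdf_lo = np.arange(0, n) / n
    return float(max(np.abs(ecdf_hi - F).max(), np.abs(F - ecdf_lo).max()))
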