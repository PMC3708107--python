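"""Exact partition-function folding under the builtin pair-additive energy model.

The builtin model assigns each canonical base pair a fixed energy in RT units
(E(structure) = sum of pair energies) and forbids hairpin loops shorter than a
minimum size.  For this model the McCaskill inside/outside recursions compute
the partition function Z and every pair probability P_ij exactly, which makes
the engine verifiable against exhaustive structure enumeration at small n.

All arrays here are 1-based with one row/column of padding on either side;
``Z[a, a-1] == 1`` encodes the empty region, entries further below the
diagonal are 0 so that matrix products silently drop impossible splits.

Partition functions are rescaled per nucleotide by a factor ``kappa`` to keep
them inside double-precision range for long sequences: every unpaired base
carries weight 1/kappa and every pair weight exp(-e)/kappa^2, so that the true
log partition function is ``log(Zhat) + n*log(kappa)``.
"""

from __future__ import annotations

import math

import numpy as np

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3}


def encode(residues: str) -> np.ndarray:
    return np.array([_BASE_INDEX[b] for b in residues], dtype=np.intp)


def energy_lut(pair_energies: dict) -> np.ndarray:
    """4x4 matrix of pair energies (RT units); +inf marks a disallowed pair."""
    lut = np.full((4, 4), np.inf)
    for (a, b), e in pair_energies.items():
        lut[_BASE_INDEX[a], _BASE_INDEX[b]] = e
    return lut


def pair_weights(codes: np.ndarray, lut: np.ndarray, min_hairpin: int) -> np.ndarray:
    """Padded (n+2, n+2) matrix of Boltzmann pair weights exp(-e_ij)."""
    n = len(codes)
    energy = lut[codes[:, None], codes[None, :]]
    q = np.zeros((n + 2, n + 2))
    with np.errstate(over="ignore"):
        w = np.exp(-energy)
    w[~np.isfinite(w)] = 0.0
    ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    w[jj - ii < min_hairpin + 1] = 0.0
    q[1:n + 1, 1:n + 1] = w
    return q


def default_kappa(residues: str, pair_energies: dict) -> float:
    """Per-base rescaling factor from a crude lower bound on the ground-state energy."""
    counts = {b: residues.count(b) for b in "ACGU"}
    gc = min(counts["G"], counts["C"])
    au = min(counts["A"], counts["U"])
    e_gc = abs(pair_energies.get(("G", "C"), -3.0))
    e_au = abs(pair_energies.get(("A", "U"), -2.0))
    bound = e_gc * gc + e_au * au
    n = max(len(residues), 1)
    return math.exp(bound / n)


def inside(q: np.ndarray, kappa: float) -> np.ndarray:
    """Inside partition functions Zhat(i, j) over all subintervals."""
    n = q.shape[0] - 2
    Z = np.zeros((n + 2, n + 2))
    idx = np.arange(1, n + 2)
    Z[idx, idx - 1] = 1.0
    inv = 1.0 / kappa
    Zb = np.zeros((n + 2, n + 2))
    for i in range(n, 0, -1):
        # Zb[i, k] = q[i, k] * Z(i+1, k-1)
        Zb[i, 1:n + 1] = q[i, 1:n + 1] * Z[i + 1, 0:n]
        # sum_k Zb[i, k] * Z(k+1, j); rows with Zb == 0 contribute nothing
        term = Zb[i, 1:n + 1] @ Z[2:n + 2, 1:n + 1]
        Z[i, i:n + 1] = Z[i + 1, i:n + 1] * inv + term[i - 1:n]
    return Z


def outside(q: np.ndarray, Z: np.ndarray, kappa: float) -> np.ndarray:
    """Outside values Yhat(i, j): scaled partition function over everything
    exterior to the blocked interval [i, j], including pairs that enclose it."""
    n = q.shape[0] - 2
    Y = np.zeros((n + 2, n + 2))
    inv = 1.0 / kappa
    Y[1, 1:n + 1] = Z[2:n + 2, n]
    Zt = Z.T
    for i in range(2, n + 1):
        t = Y[i - 1, i:n + 1] * inv
        if i > 2:
            # position i-1 pairs with k < i-1 inside the left segment
            c = q[1:i - 1, i - 1] * Z[2:i, i - 2]
            t = t + c @ Y[1:i - 1, i:n + 1]
        # position i-1 pairs with m > j, enclosing the blocked interval
        d = q[i - 1, 1:n + 1] * Y[i - 1, 1:n + 1]
        t = t + d @ Zt[0:n, i + 1:n + 2]
        Y[i, i:n + 1] = t
    return Y


def pair_probabilities(q: np.ndarray, Z: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """0-based upper-triangular (n, n) matrix of pair probabilities."""
    n = q.shape[0] - 2
    ztot = Z[1, n]
    P = q[1:n + 1, 1:n + 1] * Z[2:n + 2, 0:n] * Y[1:n + 1, 1:n + 1] / ztot
    np.clip(P, 0.0, 1.0, out=P)
    return np.triu(P)


def fold(residues: str, pair_energies: dict, min_hairpin: int,
         kappa: float | None = None) -> tuple[np.ndarray, float]:
    """Base pair probability matrix and log partition function.

    Retries with an adjusted rescaling factor if the scaled partition
    function leaves double-precision range.
    """
    codes = encode(residues)
    lut = energy_lut(pair_energies)
    kap = kappa if kappa is not None else default_kappa(residues, pair_energies)
    n = len(residues)
    q = pair_weights(codes, lut, min_hairpin)
    for _ in range(8):
        qs = q / kap ** 2
        Z = inside(qs, kap)
        ztot = Z[1, n]
        if not np.isfinite(ztot):
            kap *= math.e
            continue
        if ztot <= 0.0:
            kap /= math.e
            continue
        Y = outside(qs, Z, kap)
        if not np.isfinite(Y[1:n + 1, 1:n + 1]).all():
            kap *= math.e
            continue
        P = pair_probabilities(qs, Z, Y)
        return P, math.log(ztot) + n * math.log(kap)
    raise FloatingPointError("partition function rescaling failed to converge")


def log_partition_function(residues: str, pair_energies: dict, min_hairpin: int,
                           energy_scale: float = 1.0,
                           residues_other: str | None = None) -> float:
    """log Z with all pair energies multiplied by ``energy_scale``.

    With ``residues_other`` set, computes the cross partition function over
    structures formable by both sequences, each pair contributing the mean of
    its two energies (both scaled).
    """
    codes = encode(residues)
    lut = energy_lut(pair_energies)
    n = len(residues)
    if residues_other is None:
        e1 = lut[codes[:, None], codes[None, :]]
        energy = e1
    else:
        other = encode(residues_other)
        energy = 0.5 * (lut[codes[:, None], codes[None, :]]
                        + lut[other[:, None], other[None, :]])
    energy = energy * energy_scale
    with np.errstate(over="ignore", invalid="ignore"):
        w = np.exp(-energy)
    w[~np.isfinite(w)] = 0.0
    ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    w[jj - ii < min_hairpin + 1] = 0.0
    kap = math.exp(np.log(w[w > 0]).max() / 2.0) if (w > 0).any() else 1.0
    for _ in range(8):
        q = np.zeros((n + 2, n + 2))
        q[1:n + 1, 1:n + 1] = w / kap ** 2
        Z = inside(q, kap)
        ztot = Z[1, n]
        if not np.isfinite(ztot):
            kap *= math.e
            continue
        if ztot <= 0.0:
            kap /= math.e
            continue
        return math.log(ztot) + n * math.log(kap)
    raise FloatingPointError("partition function rescaling failed to converge")
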