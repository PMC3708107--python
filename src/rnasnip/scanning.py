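"""Screening approximation d# and the peak-anchored exact re-optimization.

For long sequences the exact interval search is replaced by a cheap scan:
pair probabilities come from a scanning fold with maximal pair span h''
(matching the span cap L of the fold), the squared profile differences are
integrated over a short window of h' positions starting at k, and the peak
position k* of the resulting profile d#(k) anchors one exact restricted
optimization d_[k*, l] over l.  h' = 20 reflects the size of typical
cis-regulatory elements (e.g. miRNA binding sites); h'' = 120 reflects the
span below which most base pairs of structured mRNA elements fall.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .folding import BasePairMatrix
from .localization import Interval, IntervalScore, build_mn

DEFAULT_H_PRIME = 20
DEFAULT_H_DPRIME = 120


@dataclass(frozen=True)
class ScanParams:
    h_prime: int = DEFAULT_H_PRIME    # integration window length (nt)
    h_dprime: int = DEFAULT_H_DPRIME  # maximal base-pair span (nt)

    def __post_init__(self):
        if not (0 < self.h_prime <= self.h_dprime):
            raise ParameterError(
                f"require 0 < h' <= h'' (got h'={self.h_prime}, h''={self.h_dprime})")


@dataclass(frozen=True)
class ScanProfile:
    """d#(k) over the scanned start positions, and the peak position k*."""

    positions: np.ndarray  # 1-based start positions k
    values: np.ndarray     # d#(k) >= 0
    k_star: int

    def max_value(self) -> float:
        return float(self.values.max()) if len(self.values) else 0.0


def span_limited_profiles(P: BasePairMatrix, h_dprime: int) -> np.ndarray:
    """pi-hat_i = sum over partners within span h'' (0-based vector).

    Equals the plain marginal pi when the matrix is already span-capped at
    L <= h'' or when h'' >= n.
    """
    if P.span_cap is not None and P.span_cap <= h_dprime:
        return P.row_marginals()
    if h_dprime >= P.n - 1:
        return P.row_marginals()
    S = P.sym()
    ii, jj = np.meshgrid(np.arange(P.n), np.arange(P.n), indexing="ij")
    return np.where(np.abs(jj - ii) <= h_dprime, S, 0.0).sum(axis=1)


def d_sharp_profile(P: BasePairMatrix, Ps: BasePairMatrix,
                    params: ScanParams = ScanParams(),
                    k_range: tuple | None = None) -> ScanProfile:
    """Sliding-window distance profile d#(k).

    d#(k)^2 integrates the squared difference of the span-limited marginals
    over the h' positions [k, k+h'-1]; successive values are obtained by the
    sliding recursion d#(k+1)^2 = d#(k)^2 - delta_k + delta_{k+h'} (realised
    here with a prefix sum).  Ties for the peak go to the smallest k.
    """
    n = P.n
    if n != Ps.n:
        raise ParameterError("matrices must have equal size")
    h = min(params.h_prime, n)
    pih_x = span_limited_profiles(P, params.h_dprime)
    pih_y = span_limited_profiles(Ps, params.h_dprime)
    delta2 = (pih_x - pih_y) ** 2
    csum = np.concatenate([[0.0], np.cumsum(delta2)])
    lo, hi = 1, n - h + 1
    if k_range is not None:
        lo = max(lo, int(k_range[0]))
        hi = min(hi, int(k_range[1]))
        if lo > hi:
            raise ParameterError(f"empty scan range [{k_range[0]},{k_range[1]}]")
    ks = np.arange(lo, hi + 1)
    vals = np.sqrt(np.clip(csum[ks - 1 + h] - csum[ks - 1], 0.0, None))
    k_star = int(ks[int(np.argmax(vals))])
    return ScanProfile(positions=ks, values=vals, k_star=k_star)


def reoptimize_at_peak(P: BasePairMatrix, Ps: BasePairMatrix, k_star: int,
                       params: ScanParams = ScanParams()) -> IntervalScore:
    """Exact restricted distance d_[k*, l] maximized over the right end l.

    l ranges over (k*, min(n, k* + h'' + h')], capping the exact
    re-optimization at the span the scanning fold could see.  Uses the pi
    marginals through the M/N tables.
    """
    n = P.n
    if not (1 <= k_star <= n):
        raise ParameterError(f"peak position {k_star} outside [1,{n}]")
    mn_x, mn_y = build_mn(P), build_mn(Ps)
    a = mn_x.M[:, k_star] - mn_y.M[:, k_star]     # (i,) at fixed k
    dN = mn_x.N - mn_y.N
    l_max = min(n, k_star + params.h_dprime + params.h_prime)
    best_l, best = k_star + 1 if k_star < n else k_star, -1.0
    for l in range(k_star + 1, l_max + 1):
        idx = slice(k_star, l + 1)
        v = a[idx] + dN[idx, l]
        d = float(np.sqrt(np.sum(v * v)))
        if d > best + 1e-15:
            best, best_l = d, l
    if best < 0.0:  # k* at the last position: only the singleton interval
        best = 0.0
        best_l = k_star
    return IntervalScore(Interval(k_star, best_l), best, "d_max", "pi")
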