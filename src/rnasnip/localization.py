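"""Interval-restricted dissimilarity measures and their exact optimization.

The structural effect of a substitution is usually confined to a local
region, so the informative quantity is not the global distance between the
wild-type and mutant ensembles but its restriction to the sequence interval
[k, l] where the two ensembles differ most: d_max (maximal restricted
Euclidean distance) and r_min (minimal restricted Pearson correlation).

Two devices make the O(n^2)-interval search practical and robust:

* M/N tables: M[i, k] is the probability that position i pairs somewhere in
  [k, i-1] and N[i, l] the probability that it pairs in [i+1, l].  They obey
  M[i, k] = M[i, k+1] + P_ki and N[i, l] = N[i, l-1] + P_il, and give the
  restricted marginal pi_i[k, l] = M[i, k] + N[i, l] in constant time.
* a self-containedness filter: an interval is admissible only if the expected
  number of base pairs inside it outweighs (by a factor alpha) the expected
  number of pairs crossing its boundary, for the wild-type or the mutant.

The grid evaluation below scores every interval at once with prefix sums and
three matrix products per cross term, so the full exact search stays cheap
even for windows of several hundred nucleotides.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError, UndefinedCorrelationError
from .folding import BasePairMatrix
from .measures import euclid_distance, pearson_correlation

_VAR_EPS = 1e-14
_ADM_EPS = 1e-9

DEFAULT_MIN_LEN = 50
DEFAULT_ALPHA = 1.0
DEFAULT_P_THR = 0.01

BASES = ("P", "pi", "xi")
MEASURES = ("d", "r")


@dataclass(frozen=True)
class Interval:
    """1-based inclusive sequence interval."""

    k: int
    l: int

    def __post_init__(self):
        if not (1 <= self.k <= self.l):
            raise ParameterError(f"invalid interval [{self.k},{self.l}]")

    def __len__(self):
        return self.l - self.k + 1

    def shifted(self, offset: int) -> "Interval":
        return Interval(self.k + offset, self.l + offset)


@dataclass(frozen=True)
class IntervalScore:
    interval: Interval
    score: float
    measure: str  # "d_max" | "r_min" | "d_sharp"
    basis: str    # "P" | "pi" | "xi"


@dataclass(frozen=True)
class MNTables:
    """Padded (n+1, n+1) tables; index 0 is unused.

    M[i, k] = sum_{j in [k, i-1]} P_ji   (pairing partner left of i, right of k)
    N[i, l] = sum_{j in [i+1, l]} P_ij
    """

    M: np.ndarray
    N: np.ndarray
    n: int

    def pi_restricted(self, i: int, k: int, l: int) -> float:
        """pi_i[k, l], the probability that i pairs within [k, l]."""
        if not (k <= i <= l):
            raise ParameterError(f"position {i} outside interval [{k},{l}]")
        return float(self.M[i, k] + self.N[i, l])


def threshold_filter(P: BasePairMatrix, p_thr: float) -> BasePairMatrix:
    """Zero out pairs less likely than p_thr (noise filter)."""
    if not (0.0 <= p_thr < 1.0):
        raise ParameterError("p_thr must be in [0, 1)")
    if p_thr == 0.0:
        return P
    q = P.p.copy()
    q[q < p_thr] = 0.0
    return BasePairMatrix(q, backend=P.backend, span_cap=P.span_cap,
                          engine=P.engine, validate=False)


def build_mn(P: BasePairMatrix) -> MNTables:
    n = P.n
    S = np.zeros((n + 1, n + 1))
    S[1:, 1:] = P.sym()
    lower = np.tril(S, -1)
    M = lower[:, ::-1].cumsum(axis=1)[:, ::-1]  # M[i, k] = sum_{j >= k, j < i}
    upper = np.triu(S, 1)
    N = upper.cumsum(axis=1)                    # N[i, l] = sum_{j <= l, j > i}
    return MNTables(M=M, N=N, n=n)


# ---------------------------------------------------------------------------
# grid helpers: all produce (n+1, n+1) arrays G[k, l] (rows k, columns l)

def _colcum(X: np.ndarray) -> np.ndarray:
    return np.cumsum(X, axis=0)


def _range_colk(C: np.ndarray) -> np.ndarray:
    """G[k, l] = C[l, k] - C[k-1, k] for a column cumsum C of an (i, k) array."""
    n = C.shape[0] - 1
    v = np.zeros(n + 1)
    v[1:] = np.diagonal(C, offset=1)
    return C.T - v[:, None]


def _range_coll(C: np.ndarray) -> np.ndarray:
    """G[k, l] = C[l, l] - C[k-1, l] for a column cumsum C of an (i, l) array."""
    d = np.diagonal(C)
    shifted = np.zeros_like(C)
    shifted[1:, :] = C[:-1, :]
    return d[None, :] - shifted


def _cross(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """G[k, l] = sum_{i=k}^{l} A[i, k] * B[i, l] via three matrix products."""
    full = A.T @ B
    below = np.triu(A, 1).T @ B      # contributions with i < k
    above = A.T @ np.tril(B, -1)     # contributions with i > l
    return full - below - above


def _boxsum_grid(X: np.ndarray) -> np.ndarray:
    """G[k, l] = sum over k <= i, j <= l of a padded (n+1, n+1) array X."""
    C = X.cumsum(axis=0).cumsum(axis=1)
    d = np.diagonal(C)
    rowshift = np.zeros_like(C)
    rowshift[1:, :] = C[:-1, :]          # C[k-1, l]
    colshift = np.zeros_like(C)
    colshift[1:, :] = C.T[:-1, :]        # C[l, k-1] indexed [k, l]
    dk = np.zeros(C.shape[0])
    dk[1:] = d[:-1]                      # C[k-1, k-1]
    return d[None, :] - rowshift - colshift + dk[:, None]


def _pad_ut(P: BasePairMatrix) -> np.ndarray:
    n = P.n
    X = np.zeros((n + 1, n + 1))
    X[1:, 1:] = P.p
    return X


def admissibility_grid(P: BasePairMatrix, Ps: BasePairMatrix,
                       alpha: float) -> np.ndarray:
    """Boolean grid: interval [k, l] has self-contained pairing in P or P*."""
    ok = None
    for mat in (P, Ps):
        X = _pad_ut(mat)
        w_in = _boxsum_grid(X)
        pi = np.zeros(mat.n + 1)
        pi[1:] = mat.row_marginals()
        c1 = np.cumsum(pi)
        seg = c1[None, :] - np.concatenate([[0.0], c1[:-1]])[:, None]
        w_cross = seg - 2.0 * w_in
        this = w_in >= alpha * w_cross - _ADM_EPS
        ok = this if ok is None else (ok | this)
    return ok


def self_contained(P: BasePairMatrix, Ps: BasePairMatrix, ival: Interval,
                   alpha: float = DEFAULT_ALPHA) -> bool:
    """True iff expected pairing inside [k, l] outweighs pairing across its
    boundary by a factor alpha, in the wild-type or the mutant ensemble."""
    k, l = ival.k, ival.l
    for mat in (P, Ps):
        sub = mat.p[k - 1:l, k - 1:l]
        w_in = float(sub.sum())
        w_cross = float(mat.sym()[k - 1:l, :].sum()) - 2.0 * w_in
        if w_in >= alpha * w_cross - _ADM_EPS:
            return True
    return False


# ---------------------------------------------------------------------------
# score grids

def _grids_pi(P, Ps, want_d: bool, want_r: bool) -> dict:
    mn_x, mn_y = build_mn(P), build_mn(Ps)
    Mx, Nx, My, Ny = mn_x.M, mn_x.N, mn_y.M, mn_y.N
    out = {}
    nc = _len_grid(P.n)
    if want_r:
        x1 = _cross(Mx, Nx)
        x2 = _cross(My, Ny)
        x3 = _cross(Mx, Ny)
        x4 = _cross(My, Nx)
        cross_dd = x1 - x3 - x4 + x2
        sx = _range_colk(_colcum(Mx)) + _range_coll(_colcum(Nx))
        sy = _range_colk(_colcum(My)) + _range_coll(_colcum(Ny))
        sxx = _range_colk(_colcum(Mx * Mx)) + 2.0 * x1 + _range_coll(_colcum(Nx * Nx))
        syy = _range_colk(_colcum(My * My)) + 2.0 * x2 + _range_coll(_colcum(Ny * Ny))
        sxy = _range_colk(_colcum(Mx * My)) + x3 + x4 + _range_coll(_colcum(Nx * Ny))
        out["r"] = _r_from_sums(sx, sy, sxx, syy, sxy, nc)
    else:
        cross_dd = _cross(Mx - My, Nx - Ny)
    if want_d:
        dM, dN = Mx - My, Nx - Ny
        d2 = (_range_colk(_colcum(dM * dM)) + 2.0 * cross_dd
              + _range_coll(_colcum(dN * dN)))
        out["d"] = np.sqrt(np.clip(d2, 0.0, None))
    return out


def _grids_xi(P, Ps, want_d: bool, want_r: bool) -> dict:
    mn_x, mn_y = build_mn(P), build_mn(Ps)
    Mx, Nx, My, Ny = mn_x.M, mn_x.N, mn_y.M, mn_y.N
    out = {}
    if want_d:
        dM, dN = Mx - My, Nx - Ny
        d2 = _range_colk(_colcum(dM * dM)) + _range_coll(_colcum(dN * dN))
        out["d"] = np.sqrt(np.clip(d2, 0.0, None))
    if want_r:
        nc = 2.0 * _len_grid(P.n)
        sx = _range_colk(_colcum(Mx)) + _range_coll(_colcum(Nx))
        sy = _range_colk(_colcum(My)) + _range_coll(_colcum(Ny))
        sxx = _range_colk(_colcum(Mx * Mx)) + _range_coll(_colcum(Nx * Nx))
        syy = _range_colk(_colcum(My * My)) + _range_coll(_colcum(Ny * Ny))
        sxy = _range_colk(_colcum(Mx * My)) + _range_coll(_colcum(Nx * Ny))
        out["r"] = _r_from_sums(sx, sy, sxx, syy, sxy, nc)
    return out


def _grids_P(P, Ps, want_d: bool, want_r: bool) -> dict:
    X, Y = _pad_ut(P), _pad_ut(Ps)
    out = {}
    if want_d:
        D = X - Y
        out["d"] = np.sqrt(np.clip(_boxsum_grid(D * D), 0.0, None))
    if want_r:
        nc = _len_grid(P.n)
        npairs = nc * (nc - 1) / 2.0
        out["r"] = _r_from_sums(_boxsum_grid(X), _boxsum_grid(Y),
                                _boxsum_grid(X * X), _boxsum_grid(Y * Y),
                                _boxsum_grid(X * Y), npairs)
    return out


def _len_grid(n: int) -> np.ndarray:
    idx = np.arange(n + 1, dtype=float)
    return idx[None, :] - idx[:, None] + 1.0


def _r_from_sums(sx, sy, sxx, syy, sxy, nc) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        nc_safe = np.maximum(nc, 1.0)
        cov = sxy - sx * sy / nc_safe
        vx = sxx - sx * sx / nc_safe
        vy = syy - sy * sy / nc_safe
        r = cov / np.sqrt(np.clip(vx, 0.0, None) * np.clip(vy, 0.0, None))
    r = np.clip(r, -1.0, 1.0)
    r[(vx < _VAR_EPS) | (vy < _VAR_EPS)] = np.nan  # undefined correlation
    return r


_GRIDS = {"pi": _grids_pi, "xi": _grids_xi, "P": _grids_P}


def restricted_measure(P: BasePairMatrix, Ps: BasePairMatrix, ival: Interval,
                       measure: str = "d", basis: str = "pi") -> float:
    """d_[k,l] or r_[k,l] on the interval-restricted profiles.

    The pi and xi bases are evaluated through the M/N tables; the matrix
    basis restricts to pairs with both ends inside the interval.
    """
    _check_measure_basis(measure, basis)
    k, l = ival.k, ival.l
    if l > P.n:
        raise ParameterError(f"interval [{k},{l}] outside sequence of length {P.n}")
    if basis == "P":
        x = P.p[k - 1:l, k - 1:l][np.triu_indices(l - k + 1, 1)]
        y = Ps.p[k - 1:l, k - 1:l][np.triu_indices(l - k + 1, 1)]
    else:
        mnx, mny = build_mn(P), build_mn(Ps)
        idx = np.arange(k, l + 1)
        if basis == "pi":
            x = mnx.M[idx, k] + mnx.N[idx, l]
            y = mny.M[idx, k] + mny.N[idx, l]
        else:
            x = np.concatenate([mnx.M[idx, k], mnx.N[idx, l]])
            y = np.concatenate([mny.M[idx, k], mny.N[idx, l]])
    if measure == "d":
        return euclid_distance(x, y)
    return pearson_correlation(x, y)


def _check_measure_basis(measure: str, basis: str):
    if measure not in MEASURES:
        raise ParameterError(f"unknown measure {measure!r}")
    if basis not in BASES:
        raise ParameterError(f"unknown profile basis {basis!r}")


def optimize_interval_multi(P: BasePairMatrix, Ps: BasePairMatrix,
                            measures=("d",), basis: str = "pi",
                            min_len: int = DEFAULT_MIN_LEN,
                            alpha: float = DEFAULT_ALPHA,
                            p_thr: float = DEFAULT_P_THR) -> dict:
    """Best admissible interval for each requested measure, sharing all
    precomputation.  Returns ``{measure: IntervalScore}``.

    The noise filter p_thr is applied to both matrices before the M/N tables
    and before the self-containedness sums.  Ties are broken toward the
    smallest k, then the smallest l.
    """
    for m in measures:
        _check_measure_basis(m, basis)
    n = P.n
    if n != Ps.n:
        raise ParameterError("matrices must have equal size")
    if n < min_len:
        raise ParameterError(f"sequence length {n} below minimum interval length {min_len}")
    Pf = threshold_filter(P, p_thr)
    Psf = threshold_filter(Ps, p_thr)
    admissible = admissibility_grid(Pf, Psf, alpha)
    lengths = _len_grid(n)
    valid = admissible & (lengths >= min_len)
    valid[0, :] = False
    valid[:, 0] = False
    grids = _GRIDS[basis](Pf, Psf, want_d="d" in measures, want_r="r" in measures)
    out = {}
    for m in measures:
        g = grids[m]
        if m == "d":
            masked = np.where(valid, g, -1.0)
            flat = int(np.argmax(masked))
            best = masked.ravel()[flat]
            if best < 0.0:
                out[m] = _fallback(Pf, Psf, n, m, basis)
                continue
            k, l = divmod(flat, n + 1)
            out[m] = IntervalScore(Interval(k, l), float(g[k, l]), "d_max", basis)
        else:
            masked = np.where(valid & ~np.isnan(g), g, 2.0)
            flat = int(np.argmin(masked))
            best = masked.ravel()[flat]
            if best > 1.0:
                out[m] = _fallback(Pf, Psf, n, m, basis)
                continue
            k, l = divmod(flat, n + 1)
            out[m] = IntervalScore(Interval(k, l), float(g[k, l]), "r_min", basis)
    return out


def _fallback(Pf, Psf, n, measure, basis) -> IntervalScore:
    # the full interval [1, n] is always self-contained (nothing can cross
    # the sequence ends); reached only if every interval had an undefined
    # correlation, in which case [1, n] decides
    ival = Interval(1, n)
    score = restricted_measure(Pf, Psf, ival, measure, basis)
    return IntervalScore(ival, score, "d_max" if measure == "d" else "r_min", basis)


def optimize_interval(P: BasePairMatrix, Ps: BasePairMatrix, measure: str = "d",
                      basis: str = "pi", min_len: int = DEFAULT_MIN_LEN,
                      alpha: float = DEFAULT_ALPHA,
                      p_thr: float = DEFAULT_P_THR) -> IntervalScore:
    """The admissible interval of length >= min_len that maximizes the
    restricted distance (or minimizes the restricted correlation)."""
    return optimize_interval_multi(P, Ps, (measure,), basis, min_len, alpha,
                                   p_thr)[measure]
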