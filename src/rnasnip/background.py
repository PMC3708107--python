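"""Null score distributions, parametric fits and empirical P-values.

An observed dissimilarity is meaningful only against the distribution of the
same score for random substitutions in random sequences.  Shuffling-based
backgrounds would require a cubic-time fold per shuffle; instead the null is
simulated once per condition (sequence length, GC content, substitution
position) and summarized by a parametric fit:

* distances d (d_max, d#): the transform x = 1 - log(d) is fitted by a
  Gumbel distribution (maximum likelihood, parameters mu and sigma); because
  the transform is decreasing, the upper tail P(D >= d) equals the Gumbel
  CDF at x.
* correlations r (r_min): y = (r + 1)/2 is fitted by a beta distribution;
  P = F_beta(y) is small for strongly disrupted (very negative) r.

Zero distances (no structural change at all) are excluded from fitting and
assigned P = 1 by convention.  Fitted parameters are tabulated on a grid of
(length, GC bin, relative substitution position) and persisted as JSON; a
query clamps to the nearest grid cell.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from . import _score
from .config import DEFAULT_CONFIG, RnaSnpConfig
from .errors import DistributionFitError, ParameterError, TableError
from .folding import RnaSequence, Substitution, SubstitutionSet

#: GC-content grid of the precomputed tables (fraction G+C)
GC_GRID = (0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8)
#: full-scale sequence-length grid; any subset may be tabulated
LENGTH_GRID_FULL = tuple(range(400, 1601, 100))

DEFAULT_MIN_SAMPLES = 200

DISTANCE_MEASURES = ("d_max", "d_sharp")
MEASURE_BACKENDS = {
    "d_max": ("global", "scanning"),
    "d_sharp": ("scanning",),
    "r_min": ("global",),
}


def random_sequence(length: int, gc_target: float, rng: np.random.Generator,
                    seq_id: str = "random") -> RnaSequence:
    """I.i.d. residues with Pr(G) = Pr(C) = gc/2, Pr(A) = Pr(U) = (1-gc)/2."""
    if not (0.0 < gc_target < 1.0):
        raise ParameterError("gc_target must be in (0, 1)")
    p = np.array([(1 - gc_target) / 2, gc_target / 2, gc_target / 2,
                  (1 - gc_target) / 2])
    res = "".join(rng.choice(np.array(list("ACGU")), size=length, p=p))
    return RnaSequence(seq_id, res)


def random_substitution(seq: RnaSequence, position: int,
                        rng: np.random.Generator) -> SubstitutionSet:
    ref = seq.residues[position - 1]
    alts = [b for b in "ACGU" if b != ref]
    alt = alts[int(rng.integers(len(alts)))]
    return SubstitutionSet([Substitution(position, ref, alt)])


@dataclass(frozen=True)
class NullSample:
    """Scores of one measure for random variants under one grid condition."""

    scores: np.ndarray
    measure: str
    backend: str   # "global" | "scanning"
    length: int
    gc: float
    position: int
    meta: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.scores)


def _score_draw(seq, snps, measures, cfg: RnaSnpConfig) -> dict:
    """Full mode-1/mode-2 scoring of one variant; {(measure, backend): score}."""
    out = {}
    want_global = [m for m in ("d_max", "r_min")
                   if (m, "global") in measures]
    if want_global:
        fold = _score.fold_variant_window(seq, snps, cfg)
        keys = tuple("d" if m == "d_max" else "r" for m in want_global)
        scores = _score.score_exact(fold, cfg, measures=keys)
        for m in want_global:
            out[(m, "global")] = scores["d" if m == "d_max" else "r"].score
    if ("d_max", "scanning") in measures or ("d_sharp", "scanning") in measures:
        scan = _score.score_scanning(seq, snps, cfg)
        if ("d_sharp", "scanning") in measures:
            out[("d_sharp", "scanning")] = scan.d_sharp.score
        if ("d_max", "scanning") in measures:
            out[("d_max", "scanning")] = scan.d_max.score
    return out


def sample_null_joint(measures, length: int, gc, position: int,
                      n_samples: int, rng: np.random.Generator,
                      config: RnaSnpConfig = DEFAULT_CONFIG,
                      min_samples: int = DEFAULT_MIN_SAMPLES) -> dict:
    """Draw one null sample and score several measures per draw.

    ``measures`` is an iterable of (measure, backend) pairs, e.g.
    ``[("d_max", "global"), ("r_min", "global")]``.  ``gc`` is either a
    target fraction or a (lo, hi) range sampled uniformly per draw.
    Each draw places one random substitution at ``position``.
    """
    measures = [tuple(m) for m in measures]
    for m, b in measures:
        if b not in MEASURE_BACKENDS.get(m, ()):
            raise ParameterError(f"unsupported measure/backend pair ({m}, {b})")
    if n_samples < min_samples:
        raise ParameterError(
            f"n_samples={n_samples} below min_samples={min_samples}")
    if not (1 <= position <= length):
        raise ParameterError("substitution position outside the sequence")
    lo, hi = (gc, gc) if np.isscalar(gc) else gc
    collected = {m: [] for m in measures}
    for i in range(n_samples):
        gc_i = lo if lo == hi else float(rng.uniform(lo, hi))
        seq = random_sequence(length, gc_i, rng, seq_id=f"null{i}")
        snps = random_substitution(seq, position, rng)
        scores = _score_draw(seq, snps, measures, config)
        for m in measures:
            collected[m].append(scores[m])
    mid = (lo + hi) / 2.0
    return {
        m: NullSample(scores=np.array(collected[m]), measure=m[0], backend=m[1],
                      length=length, gc=mid, position=position,
                      meta={"n_samples": n_samples, "gc_range": (lo, hi)})
        for m in measures
    }


def sample_null(measure: str, backend: str, length: int, gc, position: int,
                n_samples: int, rng: np.random.Generator,
                config: RnaSnpConfig = DEFAULT_CONFIG,
                min_samples: int = DEFAULT_MIN_SAMPLES) -> NullSample:
    """Null sample of one measure via the full scoring path."""
    return sample_null_joint([(measure, backend)], length, gc, position,
                             n_samples, rng, config, min_samples)[(measure, backend)]


# ---------------------------------------------------------------------------
# parametric fits

def distance_transform(d: np.ndarray) -> np.ndarray:
    """x = 1 - log(d); decreasing, so large distances map to the lower tail."""
    d = np.asarray(d, dtype=float)
    return 1.0 - np.log(d)


def fit_gumbel(sample) -> tuple:
    """ML Gumbel parameters (mu, sigma) of x = 1 - log(d), zeros dropped."""
    d = np.asarray(sample.scores if isinstance(sample, NullSample) else sample,
                   dtype=float)
    d = d[d > 0.0]
    if len(d) < 10:
        raise DistributionFitError("too few nonzero distances to fit")
    x = distance_transform(d)
    if np.ptp(x) < 1e-12:
        raise DistributionFitError("degenerate distance sample (all equal)")
    mu, sigma = stats.gumbel_r.fit(x)
    if not (sigma > 0.0 and np.isfinite(mu)):
        raise DistributionFitError("Gumbel fit did not converge")
    return float(mu), float(sigma)


def fit_beta(sample) -> tuple:
    """ML beta parameters (a, b) of y = (r + 1)/2."""
    r = np.asarray(sample.scores if isinstance(sample, NullSample) else sample,
                   dtype=float)
    if len(r) < 10:
        raise DistributionFitError("too few correlation values to fit")
    if r.min() < -1.0 - 1e-9 or r.max() > 1.0 + 1e-9:
        raise ParameterError("correlation values outside [-1, 1]")
    y = np.clip((r + 1.0) / 2.0, 1e-9, 1.0 - 1e-9)
    if np.ptp(y) < 1e-12:
        raise DistributionFitError("degenerate correlation sample (all equal)")
    a, b, _, _ = stats.beta.fit(y, floc=0.0, fscale=1.0)
    if not (a > 0.0 and b > 0.0):
        raise DistributionFitError("beta fit did not converge")
    return float(a), float(b)


def fitted_pvalues(scores, family: str, params) -> np.ndarray:
    scores = np.asarray(scores, dtype=float)
    if family == "gumbel":
        p = np.ones_like(scores)
        pos = scores > 0.0
        p[pos] = stats.gumbel_r.cdf(distance_transform(scores[pos]), *params)
        return p
    if family == "beta":
        return stats.beta.cdf((scores + 1.0) / 2.0, *params)
    raise ParameterError(f"unknown distribution family {family!r}")


def rank_pvalues(scores, kind: str = "distance") -> np.ndarray:
    """Empirical tail probability of each score within its own sample."""
    s = np.asarray(scores, dtype=float)
    n = len(s)
    if kind == "distance":
        order = (s[:, None] <= s[None, :]).sum(axis=1)  # count >= each
        return order / n
    order = (s[:, None] >= s[None, :]).sum(axis=1)      # count <= each
    return order / n


@dataclass(frozen=True)
class KsResult:
    statistic: float
    pvalue: float
    ok: bool  # False is a warning, not a failure


def ks_check(sample, family: str, params, warn_stat: float = 0.1) -> KsResult:
    """Kolmogorov-Smirnov agreement between a null sample and its fit.

    Imperfect tails are expected for the most extreme discrepancies, so a
    large statistic is reported as a warning rather than an error.
    """
    scores = np.asarray(sample.scores if isinstance(sample, NullSample) else sample,
                        dtype=float)
    if family == "gumbel":
        x = distance_transform(scores[scores > 0.0])
        res = stats.kstest(x, "gumbel_r", args=params)
    elif family == "beta":
        y = np.clip((scores + 1.0) / 2.0, 1e-9, 1 - 1e-9)
        res = stats.kstest(y, "beta", args=params)
    else:
        raise ParameterError(f"unknown distribution family {family!r}")
    return KsResult(statistic=float(res.statistic), pvalue=float(res.pvalue),
                    ok=float(res.statistic) <= warn_stat)


# ---------------------------------------------------------------------------
# tables

def _family_for(measure: str) -> str:
    return "beta" if measure == "r_min" else "gumbel"


@dataclass
class BackgroundTable:
    """Fitted null-distribution parameters on a (length, GC, position) grid.

    Cells are keyed by (length, gc_bin, relative-position bin); lookups clamp
    to the nearest tabulated cell.  ``gc_bin`` values follow the generation
    targets of the grid (0.2 .. 0.8 in steps of 0.1 at full scale).
    """

    measure: str
    backend: str
    engine: str
    family: str
    cells: dict  # (length, gc, relpos) -> {"params": tuple, "n": int, "ks": float}
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    @classmethod
    def build(cls, measure: str, backend: str, lengths, gc_bins, pos_bins,
              n_samples: int, rng: np.random.Generator,
              config: RnaSnpConfig = DEFAULT_CONFIG,
              min_samples: int = DEFAULT_MIN_SAMPLES,
              seed: int | None = None) -> "BackgroundTable":
        """Simulate and fit every grid cell.

        ``pos_bins`` are relative positions in (0, 1); each cell simulates
        substitutions at the corresponding absolute position.
        """
        family = _family_for(measure)
        cells = {}
        for length in lengths:
            for gc in gc_bins:
                for rel in pos_bins:
                    pos = min(length, max(1, int(round(rel * length))))
                    sample = sample_null(measure, backend, length, gc, pos,
                                         n_samples, rng, config, min_samples)
                    params = (fit_gumbel(sample) if family == "gumbel"
                              else fit_beta(sample))
                    ks = ks_check(sample, family, params)
                    cells[(int(length), round(float(gc), 3), round(float(rel), 3))] = {
                        "params": params, "n": len(sample), "ks": ks.statistic}
        return cls(measure=measure, backend=backend, engine=config.backend,
                   family=family, cells=cells, seed=seed,
                   meta={"n_samples": n_samples})

    def _nearest_cell(self, length: int, gc: float, relpos: float) -> dict:
        if not self.cells:
            raise TableError("empty background table")
        gc = min(max(gc, GC_GRID[0]), GC_GRID[-1])
        key = min(self.cells,
                  key=lambda c: (abs(c[0] - length) / 100.0) ** 2
                  + ((c[1] - gc) / 0.1) ** 2 + (c[2] - relpos) ** 2)
        return self.cells[key]

    def pvalue(self, score: float, length: int, gc: float,
               position: float) -> float:
        """Empirical P-value of an observed score.

        ``position`` is the absolute substitution position within the folded
        window of length ``length``; ``gc`` is the GC fraction of that window.
        """
        relpos = min(max(position / max(length, 1), 0.0), 1.0)
        if self.family == "gumbel" and score <= 0.0:
            return 1.0  # no structural change: maximally non-significant
        cell = self._nearest_cell(length, gc, relpos)
        return float(fitted_pvalues([score], self.family, cell["params"])[0])

    # -- persistence --------------------------------------------------------

    def to_json(self) -> str:
        doc = {
            "measure": self.measure, "backend": self.backend,
            "engine": self.engine, "family": self.family, "seed": self.seed,
            "meta": self.meta,
            "cells": [
                {"length": k[0], "gc": k[1], "relpos": k[2],
                 "params": list(v["params"]), "n": v["n"], "ks": v.get("ks")}
                for k, v in sorted(self.cells.items())
            ],
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "BackgroundTable":
        doc = json.loads(text)
        cells = {
            (int(c["length"]), float(c["gc"]), float(c["relpos"])): {
                "params": tuple(c["params"]), "n": int(c["n"]), "ks": c.get("ks")}
            for c in doc["cells"]
        }
        return cls(measure=doc["measure"], backend=doc["backend"],
                   engine=doc["engine"], family=doc["family"], cells=cells,
                   seed=doc.get("seed"), meta=doc.get("meta", {}))

    def save(self, path):
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path) -> "BackgroundTable":
        path = Path(path)
        if not path.exists():
            raise TableError(
                f"background table {path} not found; generate it with "
                f"'rnasnip table build' or BackgroundTable.build()")
        return cls.from_json(path.read_text())


def pvalue(score: float, table: BackgroundTable, length: int, gc: float,
           position: float) -> float:
    """Module-level convenience wrapper around :meth:`BackgroundTable.pvalue`."""
    if table is None:
        raise TableError("no background table supplied; build one with "
                         "'rnasnip table build'")
    return table.pvalue(score, length, gc, position)


def table_filename(measure: str, backend: str) -> str:
    return f"rnasnip_table_{measure}_{backend}.json"


class TableSet(dict):
    """Mapping (measure, backend) -> BackgroundTable with directory I/O."""

    @classmethod
    def load_dir(cls, directory) -> "TableSet":
        out = cls()
        directory = Path(directory)
        for m, backends in MEASURE_BACKENDS.items():
            for b in backends:
                p = directory / table_filename(m, b)
                if p.exists():
                    out[(m, b)] = BackgroundTable.load(p)
        return out

    def save_dir(self, directory):
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for (m, b), table in self.items():
            table.save(directory / table_filename(m, b))

    def get_required(self, measure: str, backend: str) -> BackgroundTable:
        try:
            return self[(measure, backend)]
        except KeyError:
            raise TableError(
                f"missing background table for ({measure}, {backend}); "
                f"generate it with 'rnasnip table build'") from None
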