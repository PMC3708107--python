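"""Synthetic test constructs and reduced-scale methodological studies.

Everything here is generated programmatically so that the whole scoring
machinery can be exercised — and its calibration studies rerun — without any
external data: designed hairpins with known disruptive and neutral
substitutions, the rank-correlation comparison of the local (dis)similarity
measures, and the fit-quality study behind the tabulated null distributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import background, measures
from .config import DEFAULT_CONFIG, RnaSnpConfig
from .errors import ParameterError
from .folding import (BUILTIN_MODEL, EnergyModel, RnaSequence, Substitution,
                      SubstitutionSet, apply_substitutions, fold_global)
from .localization import Interval, optimize_interval_multi

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}


@dataclass(frozen=True)
class DesignedFixture:
    """A sequence with one strong designed hairpin and labelled substitutions.

    ``disruptive`` substitutions break a canonical pair of the designed stem;
    ``neutral`` substitutions sit in the loop and preserve every designed pair.
    """

    sequence: RnaSequence
    stem5: Interval
    loop: Interval
    stem3: Interval
    disruptive: list
    neutral: list

    def stem_pairs(self) -> list:
        """1-based (i, j) pairs of the designed stem."""
        length = len(self.stem5)
        return [(self.stem5.k + t, self.stem3.l - t) for t in range(length)]


def _stem_sequence(rng: np.random.Generator, length: int) -> str:
    # random G/C without triple runs: long same-letter runs create slipped
    # helix registers that let the stem ends fray
    s = []
    while len(s) < length:
        c = str(rng.choice(["G", "C"]))
        if len(s) >= 2 and s[-1] == s[-2] == c:
            c = "G" if c == "C" else "C"
        s.append(c)
    return "".join(s)


def make_hairpin_fixture(stem_len: int = 15, loop_len: int = 5,
                         context_len: int = 360,
                         rng: np.random.Generator | None = None) -> DesignedFixture:
    """A GC perfect hairpin embedded in random A/U context.

    The context is restricted to A and U so that the stem's G/C bases find no
    equally good partners outside the designed helix; this keeps every
    designed pair strongly occupied in the equilibrium ensemble.
    """
    if stem_len < 4:
        raise ParameterError("stem length must be >= 4")
    rng = rng if rng is not None else np.random.default_rng()
    left = context_len // 2
    right = context_len - left
    ctx = list("AU")
    left_ctx = "".join(rng.choice(ctx, size=left))
    right_ctx = "".join(rng.choice(ctx, size=right))
    stem5 = _stem_sequence(rng, stem_len)
    loop = "A" * max(loop_len, 3)
    stem3 = "".join(_COMPLEMENT[b] for b in reversed(stem5))
    seq = RnaSequence("hairpin", left_ctx + stem5 + loop + stem3 + right_ctx)
    s5 = Interval(left + 1, left + stem_len)
    lp = Interval(s5.l + 1, s5.l + len(loop))
    s3 = Interval(lp.l + 1, lp.l + stem_len)
    disruptive = []
    for off in (stem_len // 3, (2 * stem_len) // 3):
        pos = s5.k + off
        ref = seq.residues[pos - 1]
        # replace by the complement: turns a G-C pair into C-C (or G-G)
        disruptive.append(SubstitutionSet([Substitution(pos, ref, _COMPLEMENT[ref])]))
    neutral = []
    for off in range(min(2, len(lp))):
        pos = lp.k + off
        neutral.append(SubstitutionSet([Substitution(pos, "A", "C")]))
    return DesignedFixture(sequence=seq, stem5=s5, loop=lp, stem3=s3,
                           disruptive=disruptive, neutral=neutral)


#: measure columns of the correlation study
STUDY_MEASURES = ("d_max_P", "d_max_pi", "d_max_xi",
                  "r_min_P", "r_min_pi", "r_min_xi", "delta")


def measure_correlation_study(n_seqs: int, length: int, gc_grid=(0.2, 0.3, 0.4,
                                                                 0.5, 0.6, 0.7, 0.8),
                              rng: np.random.Generator | None = None,
                              model: EnergyModel = BUILTIN_MODEL,
                              config: RnaSnpConfig | None = None,
                              substitution_position: int | None = None):
    """Rank correlation of the local (dis)similarity measures and delta.

    Random sequences across the GC grid receive all three substitutions at
    the central position; every variant is scored by d_max and r_min on the
    P, pi and xi bases and by the ensemble distance delta.  Returns the
    per-variant score table and the Spearman correlation matrix.
    """
    import pandas as pd

    rng = rng if rng is not None else np.random.default_rng()
    cfg = config or RnaSnpConfig(backend="builtin",
                                 min_len=min(50, max(10, length // 4)))
    pos = substitution_position or (length // 2)
    rows = []
    for s in range(n_seqs):
        gc = gc_grid[s % len(gc_grid)]
        seq = background.random_sequence(length, gc, rng, seq_id=f"study{s}")
        wt = fold_global(seq, model)
        ref = seq.residues[pos - 1]
        for alt in "ACGU":
            if alt == ref:
                continue
            snps = SubstitutionSet([Substitution(pos, ref, alt)])
            mut_seq = apply_substitutions(seq, snps)
            mut = fold_global(mut_seq, model)
            row = {}
            for basis in ("P", "pi", "xi"):
                sc = optimize_interval_multi(wt, mut, measures=("d", "r"),
                                             basis=basis, min_len=cfg.min_len,
                                             alpha=cfg.alpha, p_thr=cfg.p_thr)
                row[f"d_max_{basis}"] = sc["d"].score
                row[f"r_min_{basis}"] = sc["r"].score
            row["delta"] = measures.ensemble_distance(seq, mut_seq, model)
            rows.append(row)
    frame = pd.DataFrame(rows, columns=list(STUDY_MEASURES))
    return frame, frame.corr(method="spearman")


def fit_quality_study(measure: str, backend: str, n_seqs: int,
                      rng: np.random.Generator | None = None,
                      length: int = 400, gc=(0.5, 0.6),
                      position: int | None = None,
                      config: RnaSnpConfig = DEFAULT_CONFIG,
                      split: bool = True) -> float:
    """Pearson correlation between fitted and rank-based null P-values.

    Simulates a null sample through the full scoring path, fits the
    parametric family (Gumbel for distances, beta for correlations) and
    correlates the fitted P-values with rank-based empirical P-values —
    either on a held-out half (``split=True``) or on the fitting sample
    itself.  High correlation certifies that the parametric tables can stand
    in for brute-force empirical P-values.
    """
    rng = rng if rng is not None else np.random.default_rng()
    pos = position or (length // 2)
    sample = background.sample_null(measure, backend, length, gc, pos,
                                    n_seqs, rng, config,
                                    min_samples=min(n_seqs, 200))
    scores = sample.scores
    family = "beta" if measure == "r_min" else "gumbel"
    if split:
        half = len(scores) // 2
        fit_part, eval_part = scores[:half], scores[half:]
    else:
        fit_part = eval_part = scores
    if family == "gumbel":
        params = background.fit_gumbel(fit_part)
        eval_part = eval_part[eval_part > 0]
        kind = "distance"
    else:
        params = background.fit_beta(fit_part)
        kind = "correlation"
    fitted = background.fitted_pvalues(eval_part, family, params)
    ranked = background.rank_pvalues(eval_part, kind)
    return float(np.corrcoef(fitted, ranked)[0, 1])
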