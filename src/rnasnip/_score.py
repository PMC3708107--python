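"""Shared scoring paths.

Mode 1 of the pipeline, the second screening stage of mode 3, and the
null-score sampler all run exactly this code, so that empirical P-values are
calibrated against the same computation that scores a real variant.
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import DEFAULT_CONFIG, RnaSnpConfig
from .folding import (BasePairMatrix, RnaSequence, SubstitutionSet,
                      apply_substitutions, fold_global, fold_scanning)
from .localization import Interval, IntervalScore, optimize_interval_multi, threshold_filter
from .scanning import d_sharp_profile, reoptimize_at_peak


@dataclass(frozen=True)
class WindowFold:
    """Folded window around a variant, in full-sequence coordinates."""

    window: Interval
    wt: BasePairMatrix
    mut: BasePairMatrix
    gc: float  # GC fraction of the folded wild-type window


def extract_window(seq: RnaSequence, snps: SubstitutionSet,
                   winsize_fold: int) -> Interval:
    """[center - winsize, center + winsize] clipped at the sequence ends.

    Clipping keeps the window one-sided rather than re-centering it; the
    P-value lookup later uses the actual folded length.  Multi-substitution
    variants are centred on their mean position.
    """
    c = snps.center()
    return Interval(max(1, c - winsize_fold), min(seq.n, c + winsize_fold))


def shift_into(snps: SubstitutionSet, window: Interval) -> SubstitutionSet:
    from .folding import Substitution

    return SubstitutionSet(
        Substitution(s.pos - window.k + 1, s.ref, s.alt) for s in snps)


def fold_variant_window(seq: RnaSequence, snps: SubstitutionSet,
                        cfg: RnaSnpConfig = DEFAULT_CONFIG,
                        wt_matrix: BasePairMatrix | None = None) -> WindowFold:
    """Global fold of the wild-type and mutant windows (mode-1 folding step).

    ``wt_matrix`` allows the screening mode to reuse one wild-type fold for
    every candidate variant sharing a window.
    """
    window = extract_window(seq, snps, cfg.winsize_fold)
    wt_sub = seq.subsequence(window.k, window.l)
    mut_sub = apply_substitutions(wt_sub, shift_into(snps, window))
    wt = wt_matrix if wt_matrix is not None else fold_global(wt_sub, cfg.model)
    mut = fold_global(mut_sub, cfg.model)
    return WindowFold(window=window, wt=wt, mut=mut, gc=wt_sub.gc_fraction())


def score_exact(fold: WindowFold, cfg: RnaSnpConfig = DEFAULT_CONFIG,
                measures=("d", "r")) -> dict:
    """Exact interval optimization on a folded window: {'d'|'r': IntervalScore},
    intervals in window coordinates."""
    return optimize_interval_multi(fold.wt, fold.mut, measures=measures,
                                   basis=cfg.basis, min_len=cfg.min_len,
                                   alpha=cfg.alpha, p_thr=cfg.p_thr)


@dataclass(frozen=True)
class ScanScore:
    """Mode-2 scoring result: the d# peak and the re-optimized exact distance."""

    d_sharp: IntervalScore
    d_max: IntervalScore
    gc: float
    n: int


def score_scanning(seq: RnaSequence, snps: SubstitutionSet,
                   cfg: RnaSnpConfig = DEFAULT_CONFIG,
                   wt_matrix: BasePairMatrix | None = None) -> ScanScore:
    """Scanning-fold scoring path (mode 2 and screening stage 1).

    Folds the whole sequence with the scanning backend, scans d# over start
    positions within h'' of the variant, and re-optimizes exactly at the d#
    peak k*.
    """
    mut_seq = apply_substitutions(seq, snps)
    wt = wt_matrix if wt_matrix is not None else fold_scanning(
        seq, cfg.window_w, cfg.span_l, cfg.model)
    mut = fold_scanning(mut_seq, cfg.window_w, cfg.span_l, cfg.model)
    wt_f = threshold_filter(wt, cfg.p_thr)
    mut_f = threshold_filter(mut, cfg.p_thr)
    n = seq.n
    pos = snps.center()
    h = min(cfg.h_prime, n)
    k_lo = max(1, pos - cfg.h_dprime)
    k_hi = min(n - h + 1, pos + cfg.h_dprime)
    k_hi = max(k_hi, k_lo)
    profile = d_sharp_profile(wt_f, mut_f, cfg.scan_params, (k_lo, k_hi))
    k_star = profile.k_star
    sharp = IntervalScore(Interval(k_star, min(n, k_star + h - 1)),
                          profile.max_value(), "d_sharp", "pi")
    dmax = reoptimize_at_peak(wt_f, mut_f, k_star, cfg.scan_params)
    return ScanScore(d_sharp=sharp, d_max=dmax, gc=seq.gc_fraction(), n=n)
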