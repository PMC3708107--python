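"""The three operating modes, variant parsing/formatting and TSV output.

Mode 1 (short sequences): extract a folding window of +/- winsizeFold around
the variant, fold wild-type and mutant globally, optimize d_max and r_min
over all admissible intervals and attach empirical P-values.

Mode 2 (long sequences): scanning fold (window W, span L), d# profile around
the variant, exact re-optimization anchored at the d# peak.

Mode 3 (screening): d# P-values for all 3n substitutions of the sequence;
candidates below the stage-1 threshold are re-scored through the mode-1 path
and reported if below the stage-2 threshold; reported intervals are merged
into regions with occurrence counts.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import numpy as np

from . import _score
from .background import TableSet
from .config import DEFAULT_CONFIG, RnaSnpConfig
from .errors import ParameterError, UndefinedCorrelationError, VariantFormatError
from .folding import (RnaSequence, Substitution, SubstitutionSet,
                      apply_substitutions, fold_global, fold_scanning)
from .localization import Interval

_VARIANT_RE = re.compile(r"^([ACGUTacgut])(\d+)([ACGUTacgut])$")


@dataclass(frozen=True)
class SnpResult:
    """Per-variant, per-measure record reported by every mode."""

    variant: str
    mode: int
    measure: str          # "d_max" | "r_min" | "d_sharp"
    window: Interval      # folded window, full-sequence coordinates
    interval: Interval    # best interval, full-sequence coordinates
    score: float
    pvalue: float | None
    length_used: int      # folded length entering the table lookup
    gc_used: float        # GC fraction of the folded window

    def row(self) -> dict:
        return {
            "variant": self.variant, "mode": self.mode, "measure": self.measure,
            "window_start": self.window.k, "window_end": self.window.l,
            "interval_start": self.interval.k, "interval_end": self.interval.l,
            "score": self.score,
            "pvalue": float("nan") if self.pvalue is None else self.pvalue,
        }


@dataclass(frozen=True)
class ScreeningRegion:
    """Maximal merged region of reported intervals, with occurrence count."""

    start: int
    end: int
    count: int


@dataclass(frozen=True)
class ScreeningResult:
    reported: list
    regions: list
    stage1_pvalues: np.ndarray  # P(d#) for every substitution tested
    n_variants: int


# ---------------------------------------------------------------------------
# variant I/O

def parse_variants(text: str, seq_len: int | None = None) -> list:
    """Parse variant lines into SubstitutionSets.

    Each non-empty line is one variant; simultaneous substitutions are
    comma-joined tokens of the form RefPosAlt (e.g. ``A51G,A54C,U57C``).
    """
    variants = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        subs = []
        for token in line.split(","):
            token = token.strip()
            m = _VARIANT_RE.match(token)
            if not m:
                raise VariantFormatError(
                    f"line {lineno}: cannot parse variant token {token!r} "
                    f"(expected RefPosAlt, e.g. G201C)")
            ref, pos, alt = m.group(1).upper(), int(m.group(2)), m.group(3).upper()
            if seq_len is not None and not (1 <= pos <= seq_len):
                raise VariantFormatError(
                    f"line {lineno}: position {pos} outside sequence of length {seq_len}")
            subs.append(Substitution(pos, ref, alt))
        variants.append(SubstitutionSet(subs))
    return variants


@dataclass(frozen=True)
class RegionContext:
    """Annotation for HGVS-style variant naming.

    ``coding``: cds_start/cds_end are the 1-based positions of the first and
    last CDS nucleotide; positions before/after get the ``-``/``*`` prefix.
    ``noncoding``: n. numbering relative to the transcription start.
    """

    kind: str = "noncoding"  # "coding" | "noncoding"
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self):
        if self.kind == "coding":
            if self.cds_start is None or self.cds_end is None:
                raise ParameterError("coding context requires cds_start and cds_end")
            if self.cds_end < self.cds_start:
                raise ParameterError("inconsistent CDS offsets (end before start)")
        elif self.kind != "noncoding":
            raise ParameterError(f"unknown region kind {self.kind!r}")


def _dna(base: str) -> str:
    return "T" if base == "U" else base


def format_variant(variant: SubstitutionSet,
                   region_context: RegionContext | None = None) -> str:
    """Plain RefPosAlt by default; HGVS-style c./n. numbering with a context."""
    if region_context is None:
        return str(variant)
    parts = []
    for sub in variant:
        ref, alt = _dna(sub.ref), _dna(sub.alt)
        if region_context.kind == "noncoding":
            parts.append(f"{sub.pos}{ref}>{alt}")
            prefix = "n."
        else:
            cs, ce = region_context.cds_start, region_context.cds_end
            if sub.pos < cs:
                num = f"-{cs - sub.pos}"
            elif sub.pos > ce:
                num = f"*{sub.pos - ce}"
            else:
                num = f"{sub.pos - cs + 1}"
            parts.append(f"{num}{ref}>{alt}")
            prefix = "c."
    if len(parts) == 1:
        return prefix + parts[0]
    return prefix + "[" + ";".join(parts) + "]"


# ---------------------------------------------------------------------------
# modes

def mode1(seq: RnaSequence, variant: SubstitutionSet,
          config: RnaSnpConfig = DEFAULT_CONFIG,
          tables: TableSet | None = None) -> list:
    """Global-folding assessment: d_max and r_min with P-values."""
    fold = _score.fold_variant_window(seq, variant, config)
    window = fold.window
    pos_in_window = variant.center() - window.k + 1
    results = []
    try:
        scores = _score.score_exact(fold, config, measures=("d", "r"))
    except UndefinedCorrelationError:
        scores = _score.score_exact(fold, config, measures=("d",))
    for key, measure in (("d", "d_max"), ("r", "r_min")):
        if key not in scores:
            # featureless ensembles: correlation undefined, no disruption
            results.append(SnpResult(
                variant=str(variant), mode=1, measure=measure, window=window,
                interval=window, score=math.nan,
                pvalue=1.0 if tables is not None else None,
                length_used=len(window), gc_used=fold.gc))
            continue
        sc = scores[key]
        p = None
        if tables is not None:
            table = tables.get_required(measure, "global")
            p = table.pvalue(sc.score, len(window), fold.gc, pos_in_window)
        results.append(SnpResult(
            variant=str(variant), mode=1, measure=measure, window=window,
            interval=sc.interval.shifted(window.k - 1), score=sc.score,
            pvalue=p, length_used=len(window), gc_used=fold.gc))
    return results


def mode2(seq: RnaSequence, variant: SubstitutionSet,
          config: RnaSnpConfig = DEFAULT_CONFIG,
          tables: TableSet | None = None) -> SnpResult:
    """Scanning-folding assessment: d# peak plus exact re-optimization."""
    scan = _score.score_scanning(seq, variant, config)
    window = Interval(1, seq.n)
    p = None
    if tables is not None:
        table = tables.get_required("d_max", "scanning")
        p = table.pvalue(scan.d_max.score, seq.n, scan.gc, variant.center())
    return SnpResult(
        variant=str(variant), mode=2, measure="d_max", window=window,
        interval=scan.d_max.interval, score=scan.d_max.score, pvalue=p,
        length_used=seq.n, gc_used=scan.gc)


def mode3_screen(seq: RnaSequence, config: RnaSnpConfig = DEFAULT_CONFIG,
                 tables: TableSet | None = None,
                 positions=None) -> ScreeningResult:
    """Two-stage screening of all substitutions at every position.

    Stage 1 scores every substitution by P(d#) against the scanning-fold
    table; candidates with P < t1 are re-scored through the exact mode-1
    path and reported when P(d_max) < t2.  ``positions`` restricts the scan
    (default: every position).
    """
    if tables is None:
        raise ParameterError("mode 3 requires background tables")
    sharp_table = tables.get_required("d_sharp", "scanning")
    dmax_table = tables.get_required("d_max", "global")
    n = seq.n
    gc_full = seq.gc_fraction()
    wt_scan = fold_scanning(seq, config.window_w, config.span_l, config.model)
    stage1_p = []
    candidates = []
    pos_iter = range(1, n + 1) if positions is None else positions
    for pos in pos_iter:
        ref = seq.residues[pos - 1]
        for alt in "ACGU":
            if alt == ref:
                continue
            snps = SubstitutionSet([Substitution(pos, ref, alt)])
            scan = _score.score_scanning(seq, snps, config, wt_matrix=wt_scan)
            p1 = sharp_table.pvalue(scan.d_sharp.score, n, gc_full, pos)
            stage1_p.append(p1)
            if p1 < config.t1:
                candidates.append(snps)
    reported = []
    wt_cache = {}
    for snps in candidates:
        window = _score.extract_window(seq, snps, config.winsize_fold)
        key = (window.k, window.l)
        if key not in wt_cache:
            wt_cache[key] = fold_global(seq.subsequence(*key), config.model)
        fold = _score.fold_variant_window(seq, snps, config,
                                          wt_matrix=wt_cache[key])
        sc = _score.score_exact(fold, config, measures=("d",))["d"]
        pos_in_window = snps.center() - window.k + 1
        p2 = dmax_table.pvalue(sc.score, len(window), fold.gc, pos_in_window)
        if p2 < config.t2:
            reported.append(SnpResult(
                variant=str(snps), mode=3, measure="d_max", window=window,
                interval=sc.interval.shifted(window.k - 1), score=sc.score,
                pvalue=p2, length_used=len(window), gc_used=fold.gc))
    regions = merge_regions(reported)
    return ScreeningResult(reported=reported, regions=regions,
                           stage1_pvalues=np.array(stage1_p),
                           n_variants=len(stage1_p))


def merge_regions(results) -> list:
    """Merge overlapping reported intervals into maximal regions with counts."""
    ivals = sorted((r.interval.k, r.interval.l) for r in results)
    regions = []
    for k, l in ivals:
        if regions and k <= regions[-1][1]:
            regions[-1][1] = max(regions[-1][1], l)
            regions[-1][2] += 1
        else:
            regions.append([k, l, 1])
    return [ScreeningRegion(start=k, end=l, count=c) for k, l, c in regions]


def run_variants(seq: RnaSequence, variants, mode: int,
                 config: RnaSnpConfig = DEFAULT_CONFIG,
                 tables: TableSet | None = None) -> list:
    """Score a list of variants in mode 1 or 2."""
    results = []
    for variant in variants:
        apply_substitutions(seq, variant)  # validate reference alleles early
        if mode == 1:
            results.extend(mode1(seq, variant, config, tables))
        elif mode == 2:
            results.append(mode2(seq, variant, config, tables))
        else:
            raise ParameterError("run_variants handles modes 1 and 2 only")
    return results


TSV_COLUMNS = ["variant", "mode", "measure", "window_start", "window_end",
               "interval_start", "interval_end", "score", "pvalue"]


def results_frame(results):
    import pandas as pd

    return pd.DataFrame([r.row() for r in results], columns=TSV_COLUMNS)


def write_tsv(results, path):
    results_frame(results).to_csv(path, sep="\t", index=False,
                                  float_format="%.6g")
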