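"""Sequences, substitutions and base-pair probability matrices.

Two folding engines produce the matrices that everything downstream consumes:

* ``builtin`` — an exact McCaskill partition function over a deliberately
  simple pair-additive energy model (fixed energy per GC/AU/GU pair, minimum
  hairpin size).  It has a nontrivial Boltzmann ensemble yet remains small
  enough to verify against exhaustive structure enumeration.
* ``thermodynamic`` — the ViennaRNA implementation of the Turner model
  (RNAfold / RNAplfold), used when realistic energetics matter.

Coordinates are 1-based and intervals inclusive throughout the public API.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from . import _mccaskill, _vienna
from .errors import ParameterError, ReferenceAlleleError, RnaSnipError

log = logging.getLogger(__name__)

_ALPHABET = set("ACGU")

#: builtin pair energies, RT units
DEFAULT_PAIR_ENERGIES = {
    ("G", "C"): -3.0, ("C", "G"): -3.0,
    ("A", "U"): -2.0, ("U", "A"): -2.0,
    ("G", "U"): -1.0, ("U", "G"): -1.0,
}

_warned_dna = False


@dataclass(frozen=True)
class RnaSequence:
    """An RNA sequence; DNA input is accepted and T is mapped to U."""

    id: str
    residues: str

    def __post_init__(self):
        global _warned_dna
        res = self.residues.upper()
        if "T" in res:
            if not _warned_dna:
                log.info("DNA input detected; mapping T to U")
                _warned_dna = True
            res = res.replace("T", "U")
        if not res:
            raise RnaSnipError(f"sequence {self.id!r} is empty")
        bad = set(res) - _ALPHABET
        if bad:
            raise RnaSnipError(
                f"sequence {self.id!r} contains non-nucleotide symbols: {sorted(bad)}")
        object.__setattr__(self, "residues", res)

    @property
    def n(self) -> int:
        return len(self.residues)

    def gc_fraction(self) -> float:
        return (self.residues.count("G") + self.residues.count("C")) / self.n

    def subsequence(self, start: int, end: int, id_suffix: str = "") -> "RnaSequence":
        """1-based inclusive slice."""
        if not (1 <= start <= end <= self.n):
            raise ParameterError(f"invalid subsequence bounds [{start},{end}]")
        return RnaSequence(self.id + id_suffix, self.residues[start - 1:end])


@dataclass(frozen=True)
class Substitution:
    pos: int  # 1-based
    ref: str
    alt: str

    def __post_init__(self):
        ref = self.ref.upper().replace("T", "U")
        alt = self.alt.upper().replace("T", "U")
        if ref not in _ALPHABET or alt not in _ALPHABET:
            raise RnaSnipError(f"invalid alleles {self.ref!r}>{self.alt!r}")
        if ref == alt:
            raise RnaSnipError(
                f"substitution at position {self.pos}: alternative allele equals reference")
        if self.pos < 1:
            raise RnaSnipError(f"substitution position {self.pos} is not positive")
        object.__setattr__(self, "ref", ref)
        object.__setattr__(self, "alt", alt)

    def __str__(self) -> str:
        return f"{self.ref}{self.pos}{self.alt}"


@dataclass(frozen=True)
class SubstitutionSet:
    """One variant: one or several simultaneous substitutions."""

    substitutions: tuple

    def __init__(self, substitutions: Iterable[Substitution]):
        subs = tuple(sorted(substitutions, key=lambda s: s.pos))
        if not subs:
            raise RnaSnipError("empty substitution set")
        positions = [s.pos for s in subs]
        if len(set(positions)) != len(positions):
            raise RnaSnipError(f"duplicate substitution positions in {positions}")
        object.__setattr__(self, "substitutions", subs)

    def __iter__(self):
        return iter(self.substitutions)

    def __len__(self):
        return len(self.substitutions)

    @property
    def positions(self) -> list:
        return [s.pos for s in self.substitutions]

    def center(self) -> int:
        """Mean substitution position, used for window placement."""
        pos = self.positions
        return int(round(sum(pos) / len(pos)))

    def __str__(self) -> str:
        return ",".join(str(s) for s in self.substitutions)


@dataclass(frozen=True)
class EnergyModel:
    """Folding model selector: builtin pair-additive or thermodynamic (Turner)."""

    mode: str = "builtin"  # "builtin" | "thermodynamic"
    pair_energies: dict = field(default_factory=lambda: dict(DEFAULT_PAIR_ENERGIES))
    min_hairpin: int = 3

    def __post_init__(self):
        if self.mode not in ("builtin", "thermodynamic"):
            raise ParameterError(f"unknown energy model mode {self.mode!r}")
        if self.min_hairpin < 3:
            raise ParameterError("minimum hairpin loop size must be >= 3")
        if self.mode == "builtin":
            for pair, e in self.pair_energies.items():
                if e >= 0:
                    raise ParameterError(f"pair energy for {pair} must be negative")


BUILTIN_MODEL = EnergyModel()
THERMO_MODEL = EnergyModel(mode="thermodynamic")


def model_for_backend(backend: str) -> EnergyModel:
    if backend in ("builtin",):
        return BUILTIN_MODEL
    if backend in ("thermo", "thermodynamic"):
        return THERMO_MODEL
    raise ParameterError(f"unknown backend {backend!r}")


class BasePairMatrix:
    """Upper-triangular matrix of pair probabilities P_ij (1 <= i < j <= n).

    ``backend`` records whether the matrix came from a global or a scanning
    (window-averaged) fold; ``span_cap`` is the maximal pair span L, if any.
    Consumers may read either (i, j) or (j, i); both return P_ij.
    """

    __slots__ = ("p", "n", "backend", "span_cap", "engine", "_sym")

    def __init__(self, p: np.ndarray, backend: str = "global",
                 span_cap: int | None = None, engine: str = "builtin",
                 validate: bool = True):
        p = np.asarray(p, dtype=float)
        if p.ndim != 2 or p.shape[0] != p.shape[1]:
            raise ParameterError("pair probability matrix must be square")
        self.p = np.triu(p, 1)
        self.n = p.shape[0]
        self.backend = backend
        self.span_cap = span_cap
        self.engine = engine
        self._sym = None
        if validate:
            self.validate()

    def validate(self, eps: float = 1e-9):
        if self.p.min() < -eps or self.p.max() > 1 + eps:
            raise RnaSnipError("pair probabilities outside [0, 1]")
        if self.backend == "global":
            # window-averaged (scanning) matrices may exceed 1 per position,
            # because each pair is averaged over its own set of windows
            sums = self.row_marginals()
            if sums.max() > 1 + 1e-6:
                raise RnaSnipError(
                    f"pairing probability sum exceeds 1 ({sums.max():.6g})")
        if self.span_cap is not None:
            ii, jj = np.nonzero(self.p)
            if len(jj) and (jj - ii).max() > self.span_cap:
                raise RnaSnipError("entry beyond the declared span cap")

    def sym(self) -> np.ndarray:
        """Symmetric view P_ij = P_ji (0-based)."""
        if self._sym is None:
            self._sym = self.p + self.p.T
        return self._sym

    def get(self, i: int, j: int) -> float:
        """1-based, order-insensitive accessor."""
        if i == j:
            return 0.0
        a, b = (i, j) if i < j else (j, i)
        return float(self.p[a - 1, b - 1])

    def row_marginals(self) -> np.ndarray:
        """pi_i = sum_j P_ij (0-based vector)."""
        return self.sym().sum(axis=1)


def apply_substitutions(seq: RnaSequence, snps: SubstitutionSet) -> RnaSequence:
    """Mutant sequence; every reference allele is checked against ``seq``."""
    residues = list(seq.residues)
    for sub in snps:
        if sub.pos > seq.n:
            raise ReferenceAlleleError(
                f"position {sub.pos} outside sequence {seq.id!r} of length {seq.n}")
        found = residues[sub.pos - 1]
        if found != sub.ref:
            raise ReferenceAlleleError(
                f"reference allele mismatch at position {sub.pos}: "
                f"expected {sub.ref}, found {found}")
        residues[sub.pos - 1] = sub.alt
    return RnaSequence(f"{seq.id}|{snps}", "".join(residues))


def fold_global(seq: RnaSequence, model: EnergyModel = BUILTIN_MODEL) -> BasePairMatrix:
    """Equilibrium pair probabilities of the full-length Boltzmann ensemble."""
    if model.mode == "thermodynamic":
        P = _vienna.fold_global(seq.residues, model.min_hairpin)
        return BasePairMatrix(P, backend="global", engine="thermo")
    P, _ = _mccaskill.fold(seq.residues, model.pair_energies, model.min_hairpin)
    return BasePairMatrix(P, backend="global", engine="builtin")


def log_partition_function(seq: RnaSequence, model: EnergyModel = BUILTIN_MODEL,
                           energy_scale: float = 1.0) -> float:
    if model.mode != "builtin":
        raise ParameterError("partition-function values are exposed for the builtin model only")
    return _mccaskill.log_partition_function(
        seq.residues, model.pair_energies, model.min_hairpin, energy_scale)


def _cap_span(P: np.ndarray, max_span: int) -> np.ndarray:
    n = P.shape[0]
    ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    out = P.copy()
    out[jj - ii > max_span] = 0.0
    return out


def fold_scanning(seq: RnaSequence, W: int = 200, L: int = 120,
                  model: EnergyModel = BUILTIN_MODEL) -> BasePairMatrix:
    """Pair probabilities averaged over all length-W windows, span capped at L.

    Each pair (i, j) is averaged over the windows that contain both ends; at
    the sequence ends the window set is simply truncated.  For n <= W this
    reduces to the global fold with spans above L removed.
    """
    if L > W:
        raise ParameterError(f"max pair span L={L} exceeds window size W={W}")
    if W < 1:
        raise ParameterError("window size must be positive")
    n = seq.n
    if model.mode == "thermodynamic":
        P = _vienna.fold_scanning(seq.residues, min(W, n), min(L, n))
        return BasePairMatrix(P, backend="scanning", span_cap=L, engine="thermo")
    if n <= W:
        P, _ = _mccaskill.fold(seq.residues, model.pair_energies, model.min_hairpin)
        return BasePairMatrix(_cap_span(P, L), backend="scanning", span_cap=L,
                              engine="builtin")
    acc = np.zeros((n, n))
    cnt = np.zeros((n, n))
    for start in range(0, n - W + 1):
        sub = seq.residues[start:start + W]
        Pw, _ = _mccaskill.fold(sub, model.pair_energies, model.min_hairpin)
        acc[start:start + W, start:start + W] += Pw
        cnt[start:start + W, start:start + W] += 1.0
    with np.errstate(invalid="ignore"):
        P = np.where(cnt > 0, acc / np.maximum(cnt, 1.0), 0.0)
    return BasePairMatrix(_cap_span(np.triu(P), L), backend="scanning",
                          span_cap=L, engine="builtin")


def read_fasta(path, record_id: str | None = None) -> RnaSequence:
    """Read one record from a (multi-)FASTA file; DNA is converted to RNA."""
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise RnaSnipError(f"no FASTA records in {path}")
    if record_id is None:
        rec = records[0]
    else:
        match = [r for r in records if r.id == record_id]
        if not match:
            raise RnaSnipError(f"record {record_id!r} not found in {path}")
        rec = match[0]
    return RnaSequence(rec.id, str(rec.seq))


def read_fasta_all(path) -> list:
    from Bio import SeqIO

    return [RnaSequence(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
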