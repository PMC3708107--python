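"""Global (dis)similarity measures between wild-type and mutant ensembles.

Wild-type and mutant sequences differ only by substitutions, so positions
correspond one-to-one and the base-pair probability matrices P and P* can be
compared directly: by Euclidean distance d, by Pearson correlation r, either
on the full matrices or on per-position marginals (Halvorsen-style pi vectors
or the upstream/downstream split xi).  The ensemble distance delta compares
the two Boltzmann distributions of structures themselves, via partition
functions evaluated at doubled energies plus a cross term over structures
formable by both sequences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ParameterError, UndefinedCorrelationError
from .folding import BasePairMatrix, EnergyModel, RnaSequence, log_partition_function

_VAR_EPS = 1e-14


@dataclass(frozen=True)
class PairingProfiles:
    """Per-position marginals of a base-pair probability matrix.

    pi_i       total pairing probability of position i
    xi_up_i    probability that i pairs upstream   (partner j < i)
    xi_down_i  probability that i pairs downstream (partner j > i)
    xi_un_i    probability that i is unpaired
    """

    pi: np.ndarray
    xi_up: np.ndarray
    xi_down: np.ndarray
    xi_un: np.ndarray

    @property
    def n(self) -> int:
        return len(self.pi)

    def xi_updown(self) -> np.ndarray:
        """Concatenated (xi_up, xi_down) vector of length 2n.

        xi_un is omitted: it is determined by the other two components.
        """
        return np.concatenate([self.xi_up, self.xi_down])


def profiles(P: BasePairMatrix) -> PairingProfiles:
    xi_down = P.p.sum(axis=1)
    xi_up = P.p.sum(axis=0)
    pi = xi_up + xi_down
    return PairingProfiles(pi=pi, xi_up=xi_up, xi_down=xi_down, xi_un=1.0 - pi)


def _as_vector(obj) -> np.ndarray:
    if isinstance(obj, BasePairMatrix):
        iu = np.triu_indices(obj.n, 1)
        return obj.p[iu]  # each unordered pair exactly once
    if isinstance(obj, PairingProfiles):
        return obj.pi
    return np.asarray(obj, dtype=float).ravel()


def euclid_distance(a, b) -> float:
    """Euclidean distance d = sqrt(sum (A - B)^2); matrices count each pair once."""
    va, vb = _as_vector(a), _as_vector(b)
    if va.shape != vb.shape:
        raise ParameterError(f"shape mismatch: {va.shape} vs {vb.shape}")
    return float(np.sqrt(np.sum((va - vb) ** 2)))


def pearson_correlation(a, b) -> float:
    va, vb = _as_vector(a), _as_vector(b)
    if va.shape != vb.shape:
        raise ParameterError(f"shape mismatch: {va.shape} vs {vb.shape}")
    va = va - va.mean()
    vb = vb - vb.mean()
    sxx = float(va @ va)
    syy = float(vb @ vb)
    if sxx < _VAR_EPS or syy < _VAR_EPS:
        raise UndefinedCorrelationError(
            "Pearson correlation undefined: input has zero variance")
    r = float(va @ vb) / math.sqrt(sxx * syy)
    return max(-1.0, min(1.0, r))


@dataclass(frozen=True)
class EnsembleDistanceTerms:
    """Log partition functions entering the ensemble distance delta."""

    log_z_x: float
    log_z_xs: float
    log_zhat_x: float      # doubled energies
    log_zhat_xs: float
    log_zhat_cross: float  # pairs formable by both, mean energies, doubled

    def delta_squared(self) -> float:
        d2 = (math.exp(self.log_zhat_x - 2.0 * self.log_z_x)
              + math.exp(self.log_zhat_xs - 2.0 * self.log_z_xs)
              - 2.0 * math.exp(self.log_zhat_cross - self.log_z_x - self.log_z_xs))
        return d2


def ensemble_distance_terms(x: RnaSequence, xs: RnaSequence,
                            model: EnergyModel) -> EnsembleDistanceTerms:
    if x.n != xs.n:
        raise ParameterError("ensemble distance requires equal-length sequences")
    if model.mode != "builtin":
        raise ParameterError(
            "the ensemble distance is implemented exactly for the builtin model only")
    from . import _mccaskill

    pe, mh = model.pair_energies, model.min_hairpin
    return EnsembleDistanceTerms(
        log_z_x=log_partition_function(x, model),
        log_z_xs=log_partition_function(xs, model),
        log_zhat_x=log_partition_function(x, model, energy_scale=2.0),
        log_zhat_xs=log_partition_function(xs, model, energy_scale=2.0),
        log_zhat_cross=_mccaskill.log_partition_function(
            x.residues, pe, mh, energy_scale=2.0, residues_other=xs.residues),
    )


def ensemble_distance(x: RnaSequence, xs: RnaSequence,
                      model: EnergyModel = None) -> float:
    """Euclidean distance delta between the two structure distributions.

    delta^2 = sum_psi (p_x(psi) - p_x*(psi))^2, evaluated through partition
    functions at doubled energies; always >= 0 by Cauchy-Schwarz, and tiny
    negative round-off is clipped.
    """
    from .folding import BUILTIN_MODEL

    terms = ensemble_distance_terms(x, xs, model or BUILTIN_MODEL)
    return math.sqrt(max(0.0, terms.delta_squared()))
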