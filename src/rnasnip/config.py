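"""Run configuration shared by the pipeline, the CLI and the null sampler."""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ParameterError
from .folding import EnergyModel, model_for_backend
from .scanning import ScanParams


@dataclass(frozen=True)
class RnaSnpConfig:
    """All tunables of the three operating modes.

    winsize_fold  half-width of the folding window around a variant (mode 1
                  and the screening re-scoring); the folded window is
                  [pos - winsize_fold, pos + winsize_fold], clipped at the
                  sequence ends.  Allowed range 200..800 in steps of 50 so
                  that folded windows stay within the background-table grid.
    window_w      scanning-fold window size W
    span_l        scanning-fold maximal pair span L
    h_prime       d# integration window h'
    h_dprime      d# maximal pair span h''
    alpha         self-containedness factor
    p_thr         pair-probability noise threshold
    min_len       minimum interval length of the exact search
    t1, t2        screening thresholds on P(d#) and P(d_max)
    basis         profile basis of the exact measures ("pi", "xi" or "P")
    """

    backend: str = "thermo"
    winsize_fold: int = 200
    window_w: int = 200
    span_l: int = 120
    h_prime: int = 20
    h_dprime: int = 120
    alpha: float = 1.0
    p_thr: float = 0.01
    min_len: int = 50
    t1: float = 0.4
    t2: float = 0.1
    basis: str = "pi"

    def __post_init__(self):
        if self.backend not in ("builtin", "thermo", "thermodynamic"):
            raise ParameterError(f"unknown backend {self.backend!r}")
        if not (200 <= self.winsize_fold <= 800) or self.winsize_fold % 50:
            raise ParameterError(
                "winsizeFold must lie between 200 and 800 in multiples of 50")
        if self.span_l > self.window_w:
            raise ParameterError("span L must not exceed window W")

    @property
    def scan_params(self) -> ScanParams:
        return ScanParams(h_prime=self.h_prime, h_dprime=self.h_dprime)

    @property
    def model(self) -> EnergyModel:
        return model_for_backend(self.backend)


DEFAULT_CONFIG = RnaSnpConfig()
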