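"""Thin wrapper around the ViennaRNA scripting interface.

Only two entry points are used: the global partition-function fold (RNAfold
behaviour) and the scanning, window-averaged fold (RNAplfold behaviour).
The import is lazy so the rest of the package works without the bindings.
"""

from __future__ import annotations

import numpy as np

from .errors import BackendMissingError

#: pair probabilities below this are dropped when extracting the matrix
PROB_CUTOFF = 1e-5


def _rna():
    try:
        import RNA
    except ImportError as exc:  # pragma: no cover - depends on environment
        raise BackendMissingError(
            "the thermodynamic backend requires the ViennaRNA python bindings "
            "(module 'RNA'); use the builtin energy model instead"
        ) from exc
    return RNA


def available() -> bool:
    try:
        import RNA  # noqa: F401
    except ImportError:  # pragma: no cover
        return False
    return True


def _plist_to_matrix(plist, n: int) -> np.ndarray:
    P = np.zeros((n, n))
    if plist:
        ii = np.fromiter((e.i for e in plist), dtype=np.intp, count=len(plist))
        jj = np.fromiter((e.j for e in plist), dtype=np.intp, count=len(plist))
        pp = np.fromiter((e.p for e in plist), dtype=float, count=len(plist))
        keep = (ii >= 1) & (jj >= 1)
        P[ii[keep] - 1, jj[keep] - 1] = pp[keep]
    np.clip(P, 0.0, 1.0, out=P)
    return np.triu(P)


def fold_global(residues: str, min_hairpin: int = 3) -> np.ndarray:
    """Equilibrium pair probabilities from the Turner-model partition function."""
    RNA = _rna()
    fc = RNA.fold_compound(residues)
    fc.pf()
    plist = fc.plist_from_probs(PROB_CUTOFF)
    return _plist_to_matrix(plist, len(residues))


def fold_scanning(residues: str, window: int, max_span: int) -> np.ndarray:
    """Window-averaged, span-limited pair probabilities (RNAplfold behaviour)."""
    RNA = _rna()
    plist = RNA.pfl_fold(residues, window, max_span, PROB_CUTOFF)
    return _plist_to_matrix(plist, len(residues))
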