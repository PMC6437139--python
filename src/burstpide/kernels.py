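"""Hill-type regulation input functions and the exponential burst kernel.

Protein production in bursting gene circuits is modulated by promoter
occupancy.  The probability that a promoter is inactive at protein level
``x`` is the Hill function ``rho(x) = x^H / (x^H + K^H)``, where ``K`` is
the equilibrium binding constant and ``H`` a nonzero integer Hill
coefficient (``H > 0``: negative feedback, ``H < 0``: positive feedback).
Transcription is then scaled by the input function
``c(x) = (1 - rho(x)) + rho(x) * eps``, which takes values in
``[eps, 1]``; ``eps`` is the leakage (basal transcription fraction).

Burst sizes are exponentially distributed with mean ``b``, so the
conditional density for the protein level to jump from ``y`` to
``x > y`` is ``omega(x - y) = exp(-(x-y)/b) / b``.

All Hill evaluations are done through logistic/log-space forms so that
negative exponents never require computing ``x**H`` at ``x = 0`` or for
extreme ``x/K`` ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

__all__ = [
    "HillFeedback1D",
    "BurstKernel",
    "CrossFeedback2D",
    "rho",
    "input_c",
    "input_c_nd",
    "omega",
]

# Floor for log(x): keeps x=0 limits exact after the softmax shift without
# generating nan from log(0) arithmetic.
_LOG_FLOOR = 1e-300


def _safe_log(x: np.ndarray) -> np.ndarray:
    return np.log(np.maximum(np.asarray(x, dtype=float), _LOG_FLOOR))


@dataclass(frozen=True)
class HillFeedback1D:
    """Self-regulation parameters of a single gene.

    Parameters
    ----------
    H : int
        Nonzero Hill coefficient.  Positive values encode negative
        feedback (the protein represses itself), negative values positive
        feedback.
    K : float
        Positive equilibrium binding constant, in protein units.
    epsilon : float
        Leakage fraction in ``(0, 1]``; ``epsilon = 1`` is the open loop.
    """

    H: int
    K: float
    epsilon: float

    def __post_init__(self) -> None:
        if int(self.H) != self.H or self.H == 0:
            raise ValueError(f"Hill coefficient must be a nonzero integer, got {self.H}")
        if not self.K > 0:
            raise ValueError(f"binding constant K must be positive, got {self.K}")
        if not 0 < self.epsilon <= 1:
            raise ValueError(f"leakage epsilon must lie in (0, 1], got {self.epsilon}")

    def rho(self, x):
        """Probability that the promoter is inactive at protein level ``x``.

        Evaluated as a logistic in log space,
        ``rho(x) = expit(H * (log x - log K))``, which equals
        ``x^H / (x^H + K^H)`` for ``x > 0`` and carries the limit values
        at ``x = 0`` (0 for ``H > 0``, 1 for ``H < 0``).
        """
        x = np.asarray(x, dtype=float)
        if np.any(x < 0):
            raise ValueError("protein level must be nonnegative")
        return expit(self.H * (_safe_log(x) - np.log(self.K)))

    def input_c(self, x):
        """Transcription input function ``c(x) = 1 - (1 - eps) * rho(x)``."""
        return 1.0 - (1.0 - self.epsilon) * self.rho(x)


@dataclass(frozen=True)
class BurstKernel:
    """Exponential burst-size kernel with mean burst size ``b`` (protein units)."""

    b: float

    def __post_init__(self) -> None:
        if not self.b > 0:
            raise ValueError(f"mean burst size b must be positive, got {self.b}")

    def omega(self, s):
        """Jump density ``omega(s) = exp(-s/b) / b`` for jump size ``s >= 0``."""
        s = np.asarray(s, dtype=float)
        if np.any(s < 0):
            raise ValueError("jump size must be nonnegative")
        return np.exp(-s / self.b) / self.b


def _softmax_combination(log_terms, weights):
    """Convex combination ``sum w_k exp(L_k) / sum exp(L_k)``, shift-stabilised.

    ``log_terms`` and ``weights`` are sequences of broadcast-compatible
    arrays/scalars.  The result always lies in ``[min w, max w]``.
    """
    L = np.stack([np.broadcast_arrays(*log_terms)[k] for k in range(len(log_terms))])
    m = np.max(L, axis=0)
    e = np.exp(L - m)
    num = sum(w * e[k] for k, w in enumerate(weights))
    return num / np.sum(e, axis=0)


@dataclass(frozen=True)
class CrossFeedback2D:
    """Input functions for two-gene networks.

    Three printed regulation variants are supported:

    ``product_of_1d``
        Two independently self-regulated genes; ``c_i`` depends only on
        ``x_i`` through a :class:`HillFeedback1D`.
    ``mutual_repression``
        A genetic toggle switch: each protein represses the *other* gene,
        ``c_1(x) = (K_1^{H12} + eps_1 x_2^{H12}) / (K_1^{H12} + x_2^{H12})``
        and symmetrically for ``c_2``.
    ``general_cross``
        A promoter with two binding sites (self and cross), whose four
        occupancy states each transcribe at their own leakage level; the
        input function is the softmax-weighted convex combination of
        ``{eps_i1, eps_i2, eps_i3, 1}``.

    No universal closed form exists for arbitrary promoter-state graphs;
    only these printed variants are implemented.
    """

    variant: str
    # product_of_1d
    factors: tuple[HillFeedback1D, ...] = ()
    # mutual_repression: per-gene (K_i, eps_i) and cross exponents H_12, H_21
    K: tuple[float, ...] = ()
    epsilon: tuple[float, ...] = ()
    H_cross: tuple[int, ...] = ()
    # general_cross: per-gene dicts of printed constants
    params: tuple[dict, ...] = field(default_factory=tuple)

    _VARIANTS = ("product_of_1d", "mutual_repression", "general_cross")

    def __post_init__(self) -> None:
        if self.variant not in self._VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; expected one of {self._VARIANTS}")
        if self.variant == "product_of_1d" and len(self.factors) != 2:
            raise ValueError("product_of_1d needs exactly two HillFeedback1D factors")
        if self.variant == "mutual_repression":
            if len(self.K) != 2 or len(self.epsilon) != 2 or len(self.H_cross) != 2:
                raise ValueError("mutual_repression needs K, epsilon and H_cross pairs")
            if any(k <= 0 for k in self.K):
                raise ValueError("binding constants must be positive")
            if any(not 0 < e <= 1 for e in self.epsilon):
                raise ValueError("leakages must lie in (0, 1]")
            if any(h == 0 for h in self.H_cross):
                raise ValueError("cross Hill coefficients must be nonzero")
        if self.variant == "general_cross":
            if len(self.params) != 2:
                raise ValueError("general_cross needs one parameter dict per gene")
            for prm in self.params:
                for key in ("H_self", "H_cross", "K_self", "K_cross", "eps1", "eps2", "eps3"):
                    if key not in prm:
                        raise ValueError(f"general_cross parameters missing {key!r}")
                if prm["K_self"] <= 0 or prm["K_cross"] <= 0:
                    raise ValueError("binding constants must be positive")

    @property
    def n(self) -> int:
        return 2

    def min_leakage(self) -> float:
        if self.variant == "product_of_1d":
            return min(f.epsilon for f in self.factors)
        if self.variant == "mutual_repression":
            return min(self.epsilon)
        return min(min(p["eps1"], p["eps2"], p["eps3"]) for p in self.params)

    def input_c(self, i: int, xs):
        """Evaluate ``c_i`` at coordinates ``xs = (x1, x2)`` (broadcastable arrays)."""
        if not 0 <= i < 2:
            raise IndexError(f"dimension index {i} out of range for a 2-gene network")
        x1, x2 = (np.asarray(x, dtype=float) for x in xs)
        if np.any(x1 < 0) or np.any(x2 < 0):
            raise ValueError("protein levels must be nonnegative")

        if self.variant == "product_of_1d":
            return self.factors[i].input_c(xs[i])

        if self.variant == "mutual_repression":
            other = x2 if i == 0 else x1
            H = self.H_cross[i]
            rho_cross = expit(H * (_safe_log(other) - np.log(self.K[i])))
            return 1.0 - (1.0 - self.epsilon[i]) * rho_cross

        prm = self.params[i]
        xs_self, xs_cross = (x1, x2) if i == 0 else (x2, x1)
        Ls = prm["H_self"] * _safe_log(xs_self)
        Lc = prm["H_cross"] * _safe_log(xs_cross)
        lKs = prm["H_self"] * np.log(prm["K_self"])
        lKc = prm["H_cross"] * np.log(prm["K_cross"])
        # states: (self+cross bound, cross bound, self bound, empty)
        log_terms = (Ls + Lc, lKs + Lc, Ls + lKc, lKs + lKc)
        weights = (prm["eps1"], prm["eps2"], prm["eps3"], 1.0)
        return _softmax_combination(log_terms, weights)


# ---------------------------------------------------------------------------
# thin functional surface

def rho(x, fb: HillFeedback1D):
    """Promoter-inactivity probability; see :meth:`HillFeedback1D.rho`."""
    return fb.rho(x)


def input_c(x, fb: HillFeedback1D):
    """1D transcription input function in ``[eps, 1]``."""
    return fb.input_c(x)


def input_c_nd(xs, fb: CrossFeedback2D, i: int):
    """``c_i`` of a two-gene network at coordinates ``xs``."""
    return fb.input_c(i, xs)


def omega(s, kernel: BurstKernel):
    """Exponential burst kernel density at jump size ``s``."""
    return kernel.omega(s)
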