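"""Grünwald-Letnikov (GL) fractional time derivative.

The GL approximation of the order-alpha derivative of a sampled signal g is

    D^alpha g(t_{n+1}) ~= dt^{-alpha} sum_{k=0}^{N} c_k g(t_{n+1-k}),

with generalised binomial weights c_k = (-1)^k C(alpha, k).  The weights
satisfy the recurrence

    c_0 = 1,   c_k = c_{k-1} (k - 1 - alpha) / k,

and for 0 < alpha < 1 they are negative and decay like k^(-1-alpha), which
justifies the short-memory principle: the sum may be truncated after L
terms (the effective memory length) with a controllable error.

Histories are stored newest-first: ``history[0]`` is the sample the weight
c_0 = 1 multiplies.  Pre-simulation samples are identically zero (quiescent
start), so early in a run the sum is naturally truncated at the number of
elapsed steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GLWeights", "gl_coefficients", "fractional_derivative", "memory_steps"]


def gl_coefficients(alpha: float, count: int) -> np.ndarray:
    """First ``count + 1`` GL binomial weights c_0 .. c_count for order alpha.

    Equivalent to (-1)^k * binomial(alpha, k), computed by the stable
    recurrence c_k = c_{k-1} (k - 1 - alpha) / k.  For alpha = 1 this is the
    backward first difference [1, -1, 0, ...]; for alpha = 0 the identity.
    """
    if count < 0:
        raise ValueError(f"count must be >= 0, got {count}")
    c = np.empty(count + 1)
    c[0] = 1.0
    for k in range(1, count + 1):
        c[k] = c[k - 1] * (k - 1 - alpha) / k
    return c


@dataclass(frozen=True)
class GLWeights:
    """Truncated GL coefficient sequence for a given (alpha, dt, L).

    ``scale = dt**-alpha`` multiplies the weighted history sum; L is the
    effective memory length in steps (L = 0 keeps only the newest sample).
    """

    alpha: float
    dt: float
    memory_length: int
    coefficients: np.ndarray = field(repr=False)

    def __init__(self, alpha: float, dt: float, memory_length: int):
        if dt <= 0:
            raise ValueError(f"dt must be > 0, got {dt}")
        if memory_length < 0:
            raise ValueError(f"memory_length must be >= 0, got {memory_length}")
        object.__setattr__(self, "alpha", float(alpha))
        object.__setattr__(self, "dt", float(dt))
        object.__setattr__(self, "memory_length", int(memory_length))
        object.__setattr__(
            self, "coefficients", gl_coefficients(alpha, memory_length)
        )

    @property
    def scale(self) -> float:
        """dt^(-alpha), units s^(-alpha)."""
        return self.dt**-self.alpha


def fractional_derivative(history, weights: GLWeights) -> float:
    """Evaluate the truncated GL derivative from a newest-first history.

    ``history[k]`` holds g(t_{n+1-k}); samples beyond the stored length are
    taken as zero (quiescent start).  Returns
    dt^(-alpha) * sum_k c_k history[k] over k <= min(L, len(history)-1).
    """
    h = np.asarray(history, dtype=float)
    if h.ndim != 1 or h.size == 0:
        raise ValueError("history must be a non-empty 1-D sequence")
    m = min(weights.memory_length + 1, h.size)
    return float(weights.scale * np.dot(weights.coefficients[:m], h[:m]))


def memory_steps(t_memory: float, dt: float) -> int:
    """Convert an effective memory time t_L (s) to a step count L.

    L = round(t_L / dt); during stepping the operative truncation is
    min(L, elapsed steps), so L larger than the run length reproduces the
    full-memory operator exactly.
    """
    if t_memory < 0:
        raise ValueError(f"t_memory must be >= 0, got {t_memory}")
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    return int(round(t_memory / dt))
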