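"""Adamax: the infinity-norm variant of Adam.

Per step, with gradient g:

    m_t = beta1 * m_{t-1} + (1 - beta1) * g          (first moment)
    u_t = max(beta2 * u_{t-1}, |g|)                  (infinity-norm moment)
    w_t = w_{t-1} - eta * (m_t / (1 - beta1^t)) / (u_t + eps)

Only the first moment is bias-corrected; the max recursion makes ``u``
unbiased by construction.  Defaults: eta = 0.01, beta1 = 0.9,
beta2 = 0.999, eps = 1e-8.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import NumericalError, ParameterError

__all__ = ["AdamaxState", "adamax_step", "AdamaxOptimizer"]


@dataclass
class AdamaxState:
    """Optimizer state for one parameter array."""

    m: np.ndarray
    u: np.ndarray
    t: int = 0
    lr: float = 0.01
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8

    @classmethod
    def zeros_like(cls, w: np.ndarray, lr: float = 0.01, beta1: float = 0.9,
                   beta2: float = 0.999, eps: float = 1e-8) -> "AdamaxState":
        if not (0 <= beta1 < 1 and 0 <= beta2 < 1):
            raise ParameterError("beta1, beta2 must lie in [0, 1)")
        w = np.asarray(w, dtype=np.float64)
        return cls(np.zeros_like(w), np.zeros_like(w), 0, lr, beta1, beta2, eps)


def adamax_step(state: AdamaxState, w: np.ndarray, g: np.ndarray,
                name: str = "parameters") -> tuple[AdamaxState, np.ndarray]:
    """One Adamax update; returns the advanced state and new weights."""
    w = np.asarray(w, dtype=np.float64)
    g = np.asarray(g, dtype=np.float64)
    if w.shape != g.shape or w.shape != state.m.shape:
        raise ParameterError(
            f"shape mismatch: w {w.shape}, g {g.shape}, state {state.m.shape}"
        )
    if not np.all(np.isfinite(g)):
        raise NumericalError(f"non-finite gradient in {name}")
    t = state.t + 1
    m = state.beta1 * state.m + (1.0 - state.beta1) * g
    u = np.maximum(state.beta2 * state.u, np.abs(g))
    m_hat = m / (1.0 - state.beta1 ** t)
    w_new = w - state.lr * m_hat / (u + state.eps)
    new_state = AdamaxState(m, u, t, state.lr, state.beta1, state.beta2, state.eps)
    return new_state, w_new


class AdamaxOptimizer:
    """Adamax over a dict of named parameter arrays (in-place convenience)."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 0.01,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.states = {
            k: AdamaxState.zeros_like(v, lr, beta1, beta2, eps)
            for k, v in params.items()
        }

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        for k in params:
            self.states[k], new_w = adamax_step(self.states[k], params[k], grads[k], name=k)
            params[k][...] = new_w
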