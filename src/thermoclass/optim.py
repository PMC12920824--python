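"""Adam optimizer, implemented from its moment-update equations.

State carries exponential moving averages of the gradient (first moment m)
and squared gradient (second moment v):

    m_t = β1 m_{t-1} + (1 − β1) g_t
    v_t = β2 v_{t-1} + (1 − β2) g_t²

bias-corrected as m̂_t = m_t / (1 − β1^t), v̂_t = v_t / (1 − β2^t), and the
parameter step is θ_t = θ_{t-1} − α m̂_t / (√v̂_t + ε).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class AdamState:
    """Optimizer state for one flat parameter vector.

    ``lr`` (α) defaults to 1e-3; β1/β2/ε use the customary 0.9/0.999/1e-8.
    """

    shape: tuple[int, ...]
    lr: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    t: int = 0
    m: np.ndarray = field(default=None)  # type: ignore[assignment]
    v: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.m is None:
            self.m = np.zeros(self.shape)
        if self.v is None:
            self.v = np.zeros(self.shape)
        if self.t < 0:
            raise ValueError("step counter must be non-negative")


def adam_step(params: np.ndarray, grads: np.ndarray, state: AdamState
              ) -> tuple[np.ndarray, AdamState]:
    """One Adam update; returns new parameters and the advanced state.

    The step counter is incremented before the bias corrections, so the
    first call uses t = 1 and m̂_1 = g_1 exactly.
    """
    params = np.asarray(params, dtype=np.float64)
    grads = np.asarray(grads, dtype=np.float64)
    if params.shape != grads.shape or params.shape != state.m.shape:
        raise ValueError("parameter, gradient and state shapes must agree")
    if not np.all(np.isfinite(grads)):
        raise FloatingPointError("non-finite gradients passed to adam_step")

    t = state.t + 1
    m = state.beta1 * state.m + (1.0 - state.beta1) * grads
    v = state.beta2 * state.v + (1.0 - state.beta2) * grads * grads
    m_hat = m / (1.0 - state.beta1 ** t)
    v_hat = v / (1.0 - state.beta2 ** t)
    new_params = params - state.lr * m_hat / (np.sqrt(v_hat) + state.eps)

    new_state = AdamState(shape=state.shape, lr=state.lr, beta1=state.beta1,
                          beta2=state.beta2, eps=state.eps, t=t, m=m, v=v)
    return new_params, new_state
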