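"""Shared integrator for the linear expression model dE/dt = K·E.

Both the synthetic ground-truth simulator and the fitted-model
simulator use the same matrix-exponential propagation so that a fitted
K is judged by exactly the dynamics used to generate data.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import expm

#: states with any |E| above this are treated as numerical blow-up
OVERFLOW_GUARD = 1e12


class UnstableSimulationError(RuntimeError):
    """Raised when the linear model blows up past the overflow guard."""


def integrate_linear_ode(K: np.ndarray, E0: np.ndarray,
                         times: np.ndarray) -> np.ndarray:
    """Solve dE/dt = K·E with E(times[0]) = E0 on the given time grid.

    Uses exact matrix-exponential steps (the solution of a linear
    time-invariant system), so accuracy is limited only by `expm`.

    Returns an array of shape (len(times), n) with E(t) per row.
    Raises :class:`UnstableSimulationError` on non-finite or
    guard-exceeding states.
    """
    K = np.asarray(K, dtype=float)
    E0 = np.asarray(E0, dtype=float)
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing 1-D")
    if K.shape[0] != K.shape[1] or K.shape[0] != E0.shape[0]:
        raise ValueError("K must be square and match E0")

    out = np.empty((times.size, E0.size))
    out[0] = E0
    # cache propagators: grids are usually uniform so expm runs once
    props: dict[float, np.ndarray] = {}
    state = E0
    for i in range(1, times.size):
        dt = float(times[i] - times[i - 1])
        key = round(dt, 12)
        if key not in props:
            props[key] = expm(K * dt)
        state = props[key] @ state
        if not np.all(np.isfinite(state)) or np.max(np.abs(state)) > OVERFLOW_GUARD:
            raise UnstableSimulationError(
                f"unstable simulation: state exceeded guard at t={times[i]:g}")
        out[i] = state
    return out
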