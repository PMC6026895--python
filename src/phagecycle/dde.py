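"""Fixed-parameter delayed infection model, solved by the method of steps.

This is the classical batch formulation with constant adsorption rate
``Ki``, latent period ``T`` and burst size ``b``:

    dS/dt  = -e * XS * mu(S)
    dXS/dt =  XS * mu(S) - Ki*XS*P - dX*XS
    dXI/dt =  Ki*XS*P - exp(-dX*T) * Ki*XS(t-T)*P(t-T) - dX*XI
    dP/dt  =  b * exp(-dX*T) * Ki*XS(t-T)*P(t-T) - Ki*XS*P - dP*P

where cells infected at time ``t - T`` lyse at time ``t`` (discounted by
endogenous decay over the latent period).  The delay makes this a DDE; it
serves here as the reference oracle against which the age-structured ODE
reformulation is validated, and as the engine of the phage-dosing case
study.

The solver advances in steps of length ``T``: on each step the delayed
terms are read from the dense interpolant of already-computed segments (or
from the prescribed history on ``[-T, 0]``), so each step is an ordinary
ODE initial value problem.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.integrate import solve_ivp

from .kinetics import KineticParameters

__all__ = ["DDETrajectory", "simulate_batch_dde"]

History = Callable[[float], tuple[float, float]]


@dataclass
class DDETrajectory:
    """Sampled DDE solution: substrate, susceptible, infected, phage."""

    t: np.ndarray
    S: np.ndarray
    XS: np.ndarray
    XI: np.ndarray
    P: np.ndarray


def simulate_batch_dde(
    initial: tuple[float, float, float, float],
    ki: float,
    latent: float,
    burst: float,
    params: KineticParameters,
    t_end: float,
    *,
    history: History | None = None,
    t_eval: np.ndarray | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-6,
) -> DDETrajectory:
    """Integrate the constant-parameter delayed batch model on ``[0, t_end]``.

    Parameters
    ----------
    initial : tuple
        ``(S, XS, XI, P)`` at ``t = 0``.
    ki, latent, burst : float
        Constant adsorption rate (mL/h), latent period (h, > 0) and burst
        size (phages/cell).
    history : callable, optional
        ``t -> (XS, P)`` for ``t in [-latent, 0)``.  The default keeps the
        pre-inoculation vessel phage-free: ``XS`` at its initial value and
        ``P = 0``, so no lysis occurs before ``t = latent``.
    """
    if latent <= 0:
        raise ValueError(f"latent period must be positive, got {latent}")
    if t_end <= 0:
        raise ValueError(f"t_end must be positive, got {t_end}")
    S0, XS0, XI0, P0 = (float(v) for v in initial)
    if min(S0, XS0, XI0, P0) < 0:
        raise ValueError("initial concentrations must be non-negative")

    if history is None:
        history = lambda t: (XS0, 0.0)  # noqa: E731 - phage-free pre-history

    survival = math.exp(-params.dX * latent)
    segments: list = []  # dense interpolants covering [0, t] so far

    def delayed(t: float) -> tuple[float, float]:
        td = t - latent
        if td <= 0.0:
            return history(td)
        for t_hi, sol in segments:
            if td <= t_hi:
                y = sol(td)
                return max(y[1], 0.0), max(y[3], 0.0)
        # round-off at a segment boundary: use the last interpolant
        y = segments[-1][1](td)
        return max(y[1], 0.0), max(y[3], 0.0)

    def rhs(t, y):
        S = max(y[0], 0.0)
        XS = max(y[1], 0.0)
        XI = max(y[2], 0.0)
        P = max(y[3], 0.0)
        mu = params.mu_max * S / (params.Km + S)
        XS_d, P_d = delayed(t)
        adsorb = ki * XS * P
        lysis_feed = ki * XS_d * P_d
        return [
            -params.e * XS * mu,
            XS * mu - adsorb - params.dX * XS,
            adsorb - survival * lysis_feed - params.dX * XI,
            burst * survival * lysis_feed - adsorb - params.dP * P,
        ]

    y0 = [S0, XS0, XI0, P0]
    t0 = 0.0
    while t0 < t_end - 1e-12:
        t1 = min(t0 + latent, t_end)
        sol = solve_ivp(
            rhs, (t0, t1), y0, method="LSODA", dense_output=True, rtol=rtol, atol=atol
        )
        if not sol.success:
            raise RuntimeError(f"DDE step [{t0:.4g}, {t1:.4g}] failed: {sol.message}")
        segments.append((t1, sol.sol))
        y0 = sol.y[:, -1]
        t0 = t1

    if t_eval is None:
        t_eval = np.linspace(0.0, t_end, 201)
    t_eval = np.asarray(t_eval, dtype=float)
    out = np.empty((4, t_eval.size))
    for j, t in enumerate(t_eval):
        for t_hi, dense in segments:
            if t <= t_hi + 1e-12:
                out[:, j] = dense(min(t, t_hi))
                break
    out = np.clip(out, 0.0, None)
    return DDETrajectory(t=t_eval, S=out[0], XS=out[1], XI=out[2], P=out[3])
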