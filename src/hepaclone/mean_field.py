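"""Deterministic mean-field oracle for the stochastic fate model.

In the large-population limit the expected counts obey linear ODEs.  After
the differentiation threshold is reached each hepatoblast division removes
one P and adds, in expectation, (p_hc + 2 p_hh) hepatocytes and
(p_hc + 2 p_cc) BECs, while differentiated cells grow exponentially at
their own rates:

    dP/dt = -rate_p * P
    dH/dt =  rate_p * P * (p_hc + 2 p_hh) + rate_h * H
    dC/dt =  rate_p * P * (p_hc + 2 p_cc) + rate_c * C

Phase I (pure hepatoblast expansion) only rescales time, never the final
H:C ratio, so integration starts at the differentiation onset
(P = n_diff_threshold, H = C = 0) and stops when the total population
first reaches n_final.  When hepatocytes and BECs divide at the same rate
the ratio is time-invariant once set and has the closed form
(p_hc + 2 p_hh) / (p_hc + 2 p_cc).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .fate_sim import FateModelParams

__all__ = ["MeanFieldTrajectory", "equal_rate_ratio", "integrate_mean_field"]


@dataclass
class MeanFieldTrajectory:
    """Expected counts from differentiation onset to the n_final stop."""

    time: np.ndarray
    p: np.ndarray
    h: np.ndarray
    c: np.ndarray
    t_final: float
    final_ratio: float  # hepatocytes per BEC at the stopping time; NaN if C=0

    @property
    def ratio_defined(self) -> bool:
        return np.isfinite(self.final_ratio)


def equal_rate_ratio(params: FateModelParams) -> float:
    """Closed-form expected final H:C ratio when rate_h == rate_c.

    Returns ``inf`` when no BECs are ever produced (p_hc + 2 p_cc = 0),
    marking the ratio as undefined.
    """
    if abs(params.rate_h - params.rate_c) > 1e-12:
        raise ValueError(
            "equal_rate_ratio requires rate_h == rate_c; use integrate_mean_field "
            "for unequal differentiated-cell rates"
        )
    h_flux = params.p_hc + 2 * params.p_hh
    c_flux = params.p_hc + 2 * params.p_cc
    if c_flux == 0:
        return float("inf")
    return h_flux / c_flux


def integrate_mean_field(
    params: FateModelParams,
    t_max: float = 1000.0,
    n_grid: int = 500,
) -> MeanFieldTrajectory:
    """Integrate the mean-field ODEs until the population reaches n_final.

    The stopping time is located by the integrator's event root-finding on
    P + H + C - n_final (absolute tolerance well below one cell).
    """
    rp, rh, rc = params.rate_p, params.rate_h, params.rate_c
    h_flux = params.p_hc + 2 * params.p_hh
    c_flux = params.p_hc + 2 * params.p_cc

    def rhs(_t, y):
        p, h, c = y
        return [-rp * p, rp * p * h_flux + rh * h, rp * p * c_flux + rc * c]

    def reached_final(_t, y):
        return float(np.sum(y)) - params.n_final

    reached_final.terminal = True
    reached_final.direction = 1

    y0 = [float(params.n_diff_threshold), 0.0, 0.0]
    sol = solve_ivp(
        rhs,
        (0.0, t_max),
        y0,
        events=reached_final,
        dense_output=True,
        rtol=1e-10,
        atol=1e-8,
    )
    if not sol.t_events[0].size:
        raise RuntimeError(
            f"population did not reach n_final={params.n_final} within t_max={t_max}"
        )
    t_final = float(sol.t_events[0][0])
    grid = np.linspace(0.0, t_final, n_grid)
    p, h, c = sol.sol(grid)
    h_final, c_final = float(h[-1]), float(c[-1])
    ratio = h_final / c_final if c_final > 1e-9 else float("nan")
    return MeanFieldTrajectory(time=grid, p=p, h=h, c=c, t_final=t_final, final_ratio=ratio)
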