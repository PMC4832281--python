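"""Delayed Hill-type gene expression driven by the active complex.

Transcription of a CAMTA-regulated gene responds to the nuclear-acting active
complex (4Ca2+-CaM-CAMTA, species M22X) through a Hill function, after a
fixed delay tau that lumps pre-initiation complex assembly and elongation.
Two regulation modes are supported:

    activation:  d[mRNA]/dt = k1 + k2 * (m/k4)^n / (1 + (m/k4)^n) - k3*[mRNA]
    repression:  d[mRNA]/dt = k1 + k2 / (1 + (m/k4)^n)            - k3*[mRNA]

with m the delayed active-complex concentration m22x(t - tau).  Because the
gene stage does not feed back on the binding network, the delay is implemented
by time-shifting the input rather than by a delay-differential solver.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GeneParams", "mrna_rhs", "mrna_steady_state", "potential_fold_curve", "simulate_gene"]


@dataclass(frozen=True)
class GeneParams:
    """Transcription parameters of one gene class.

    k1 : uM/s, basal transcription rate
    k2 : uM/s, maximal regulated transcription rate
    k3 : 1/s, first-order mRNA decay constant
    k4 : uM, DNA-binding affinity of the active complex (Hill half-point)
    n  : Hill coefficient (1, 2 or 3)
    tau: s, delay between the calcium-driven complex and transcription
    mode: "activation" or "repression"
    """

    k1: float = 5.0e-6
    k2: float = 5.0e-2
    k3: float = 3.75e-4
    k4: float = 1.1e-2
    n: int = 2
    tau: float = 600.0
    mode: str = "activation"

    def __post_init__(self) -> None:
        if min(self.k1, self.k2, self.k3, self.k4) <= 0:
            raise ValueError("k1..k4 must be strictly positive")
        if self.n not in (1, 2, 3):
            raise ValueError("Hill coefficient n must be 1, 2 or 3")
        if self.tau < 0:
            raise ValueError("tau must be non-negative")
        if self.mode not in ("activation", "repression"):
            raise ValueError("mode must be 'activation' or 'repression'")


def production_rate(m22x, params: GeneParams):
    """Transcription rate (uM/s) as a function of the active complex (uM)."""
    h = (np.asarray(m22x, dtype=float) / params.k4) ** params.n
    if params.mode == "activation":
        return params.k1 + params.k2 * h / (1.0 + h)
    return params.k1 + params.k2 / (1.0 + h)


def mrna_rhs(mrna: float, m22x: float, params: GeneParams) -> float:
    """d[mRNA]/dt (uM/s) at instantaneous active-complex concentration."""
    return float(production_rate(m22x, params)) - params.k3 * mrna


def mrna_steady_state(m22x, params: GeneParams, baseline_m22x: float | None = None):
    """Steady-state mRNA (uM) and fold change versus a baseline complex level.

    Closed form production/k3.  If ``baseline_m22x`` is given, also returns
    the fold of the steady state over the steady state at that baseline.
    """
    ss = production_rate(m22x, params) / params.k3
    if baseline_m22x is None:
        return ss
    ss0 = production_rate(baseline_m22x, params) / params.k3
    return ss, ss / ss0


def potential_fold_curve(m22x_grid, params: GeneParams, baseline_m22x: float):
    """Potential (steady-state) expression fold over a grid of complex levels.

    The "potential" fold is what expression would reach if the active-complex
    concentration were held indefinitely — monotone increasing in m22x for
    activation, decreasing for repression.
    """
    grid = np.asarray(m22x_grid, dtype=float)
    if grid.ndim != 1 or np.any(np.diff(grid) < 0):
        raise ValueError("m22x grid must be 1-D and sorted ascending")
    _, fold = mrna_steady_state(grid, params, baseline_m22x)
    return fold


def simulate_gene(
    times: np.ndarray,
    m22x: np.ndarray,
    params: GeneParams,
    control_m22x: float,
):
    """mRNA(t) and fold(t) for a given active-complex trajectory.

    The driving input is the delayed trajectory m22x(t - tau); before the
    trajectory start the input equals ``control_m22x``, so expression sits at
    its control steady state until the delayed signal arrives.

    Because the mRNA balance is linear in mRNA, it is solved exactly with an
    exponential (integrating-factor) step per sample interval, treating the
    production rate as piecewise linear between samples — no step-size
    control, no accuracy loss at square-wave switch times.  Returns
    ``(mrna, fold)`` sampled at ``times``.
    """
    times = np.asarray(times, dtype=float)
    m22x = np.asarray(m22x, dtype=float)
    if times.shape != m22x.shape:
        raise ValueError("times and m22x must have the same shape")
    if np.any(np.diff(times) < 0):
        raise ValueError("times must be non-decreasing")

    t0 = times[0]
    td = times - params.tau
    u = np.where(td <= t0, control_m22x, np.interp(td, times, m22x))
    p = np.asarray(production_rate(u, params), dtype=float)

    k3 = params.k3
    mrna0 = float(mrna_steady_state(control_m22x, params))
    h = np.diff(times)
    E = np.exp(-k3 * h)
    mrna = np.empty_like(times)
    mrna[0] = mrna0
    for i in range(h.size):
        if h[i] == 0.0:
            mrna[i + 1] = mrna[i]
            continue
        a = p[i]
        slope = (p[i + 1] - p[i]) / h[i]
        # exact convolution of a linear production ramp with exp(-k3 t)
        integral = a * (1.0 - E[i]) / k3 + slope * (h[i] / k3 - (1.0 - E[i]) / k3**2)
        mrna[i + 1] = mrna[i] * E[i] + integral
    mrna = np.clip(mrna, 0.0, None)
    return mrna, mrna / mrna0
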