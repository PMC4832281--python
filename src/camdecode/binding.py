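"""Ca2+-calmodulin-CAMTA binding network.

Calmodulin (CaM) carries two EF-hand pairs — an N-terminal and a C-terminal
lobe — each binding up to two Ca2+ ions sequentially.  Every CaM occupancy
state can additionally bind the transcription factor CAMTA.  The state space
is therefore a 3 x 3 x 2 lattice: 18 CaM species (free layer M{n}{c} and
CAMTA-bound layer M{n}{c}X, with n and c the N- and C-lobe Ca2+ counts) plus
free CAMTA, connected by 33 reversible mass-action reactions.

Only a subset of the rate constants has been measured: the four per-lobe Ca2+
binding steps, the affinity of any Ca2+-loaded CaM for CAMTA (one shared Kd),
and the weaker affinity of apo-CaM for CAMTA (weaker by the cooperativity
factor P < 1).  Every remaining constant is forced by thermodynamics: around
any closed reaction cycle the product of equilibrium constants must equal one
(the Wegscheider / detailed-balance condition).  :func:`derive_parameters`
performs that completion; :func:`wegscheider_check` verifies it cycle by
cycle.

Ca2+ itself is a clamped external input (a :class:`~camdecode.signatures.CalciumTrace`),
not a state variable: the network is driven, not autonomous.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq, root

from .signatures import CalciumTrace

__all__ = [
    "CaMSpecies",
    "ReactionSpec",
    "BaseParameters",
    "BindingModel",
    "enumerate_species",
    "derive_parameters",
    "wegscheider_check",
    "steady_state",
    "equilibrium_oracle",
    "simulate",
]

N_SPECIES = 19  # 9 free CaM + 9 CAMTA-bound CaM + free CAMTA


@dataclass(frozen=True)
class CaMSpecies:
    """One node of the occupancy lattice.

    ``n_occ``/``c_occ`` count Ca2+ ions on the N- and C-terminal lobes (0-2);
    ``camta_bound`` marks the CAMTA-bound layer.  The canonical name is
    ``M{n}{c}`` or ``M{n}{c}X``; free CAMTA is the sentinel ``X``.
    """

    n_occ: int
    c_occ: int
    camta_bound: bool

    @property
    def name(self) -> str:
        return f"M{self.n_occ}{self.c_occ}" + ("X" if self.camta_bound else "")

    @property
    def is_active(self) -> bool:
        """True for the fully loaded active complex M22X (4Ca2+-CaM-CAMTA)."""
        return self.camta_bound and self.n_occ == 2 and self.c_occ == 2


# canonical ordering: free layer M00..M22 ((n, c) lexicographic), bound layer
# M00X..M22X, then free CAMTA at index 18
_LATTICE = [(n, c) for n in range(3) for c in range(3)]
SPECIES: tuple[CaMSpecies, ...] = tuple(
    CaMSpecies(n, c, bound) for bound in (False, True) for n, c in _LATTICE
)
SPECIES_NAMES: tuple[str, ...] = tuple(s.name for s in SPECIES) + ("X",)
IDX = {name: i for i, name in enumerate(SPECIES_NAMES)}
ACTIVE_INDEX = IDX["M22X"]
CAMTA_INDEX = IDX["X"]


def enumerate_species() -> list[str]:
    """Canonical species ordering (length 19, apo-CaM M00 first, X last)."""
    return list(SPECIES_NAMES)


@dataclass(frozen=True)
class BaseParameters:
    """The anchored parameter subset from which the full network is derived.

    Per-lobe Ca2+ dissociation constants (uM) and on-rates (uM^-1 s^-1):
    first/second C-lobe site ``kc1``/``kc2``, first/second N-lobe site
    ``kn1``/``kn2``.  Lobes are independent: a site's constants do not depend
    on the other lobe's occupancy.

    ``kd_cam_camta`` / ``kon_cam_camta`` govern binding of any Ca2+-loaded CaM
    to CAMTA (all eight such reactions share them).  Apo-CaM binds CAMTA more
    weakly: its Kd is ``kd_cam_camta / p`` with cooperativity 0 < p <= 1, and
    its on-rate is ``kon_cam_camta / q`` (q = 1 puts the whole cooperativity
    into the off-rate).  ``cam_total`` / ``camta_total`` are conserved totals
    in uM.
    """

    kc1: float = 10.0
    kc2: float = 0.925
    kn1: float = 25.0
    kn2: float = 5.0
    kon_c1: float = 4.0
    kon_c2: float = 10.0
    kon_n1: float = 100.0
    kon_n2: float = 150.0
    kd_cam_camta: float = 1.2e-3
    kon_cam_camta: float = 1.0
    p: float = 0.1
    q: float = 1.0
    cam_total: float = 10.0
    camta_total: float = 10.0

    def __post_init__(self) -> None:
        for name in (
            "kc1", "kc2", "kn1", "kn2",
            "kon_c1", "kon_c2", "kon_n1", "kon_n2",
            "kd_cam_camta", "kon_cam_camta", "p", "q",
            "cam_total", "camta_total",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.p > 1.0:
            raise ValueError(
                "p must not exceed 1: Ca2+-loaded CaM binds CAMTA at least as "
                "tightly as apo-CaM"
            )


@dataclass(frozen=True)
class ReactionSpec:
    """One reversible reaction: reactant + ligand <-> product."""

    reaction_id: str
    reactant: str
    product: str
    ligand: str  # "Ca" or "CAMTA"
    kd: float
    k_on: float

    @property
    def k_off(self) -> float:
        return self.kd * self.k_on


# R-label layout of the lattice edges (lobe-independent grouping):
#   first C-lobe Ca2+:  R1 (n=0), R9 (n=1), R11 (n=2)
#   second C-lobe Ca2+: R2 (n=0), R10 (n=1), R12 (n=2)
#   first N-lobe Ca2+:  R3 (c=0), R5 (c=1), R7 (c=2)
#   second N-lobe Ca2+: R4 (c=0), R6 (c=1), R8 (c=2)
# CAMTA-bound layer edges carry the same labels + 20 (R21-R32).
_C_FIRST = {0: 1, 1: 9, 2: 11}
_C_SECOND = {0: 2, 1: 10, 2: 12}
_N_FIRST = {0: 3, 1: 5, 2: 7}
_N_SECOND = {0: 4, 1: 6, 2: 8}
# CaM+CAMTA binding labels for the eight Ca2+-loaded states, in lattice order
# (the measured shared affinity makes the exact assignment immaterial); apo
# binding is R15.
_BINDING_LABELS = {
    (0, 1): 13, (0, 2): 14, (1, 0): 16, (1, 1): 17,
    (1, 2): 18, (2, 0): 19, (2, 1): 20, (2, 2): 33,
}


def derive_parameters(base: BaseParameters) -> list[ReactionSpec]:
    """Complete the 33-reaction network from the anchored subset.

    Free-layer Ca2+ steps take the measured per-lobe constants.  All nine
    CaM-CAMTA binding reactions share the measured Kd and on-rate except the
    apo reaction, which is weaker by the cooperativity p (off-rate carries
    p*q of it, on-rate 1/q).  Bound-layer Ca2+ steps copy their free-layer
    counterparts — except the two edges leaving the apo-CaM-CAMTA state,
    whose Kd the Wegscheider condition forces down by the factor p; the
    correction is applied to the off-rate, keeping the on-rate shared.
    """
    b = base
    reactions: list[ReactionSpec] = []

    def ca_edge(rid: int, src: str, dst: str, kd: float, kon: float, koff_scale: float = 1.0):
        # koff_scale < 1 encodes the detailed-balance correction on k_off
        reactions.append(
            ReactionSpec(f"R{rid}", src, dst, "Ca", kd * koff_scale, kon)
        )

    for bound, off in ((False, 0), (True, 20)):
        sfx = "X" if bound else ""
        for n, c in _LATTICE:
            # apo·CAMTA's outgoing edges are tightened by p
            scale = b.p if bound and (n, c) == (0, 0) else 1.0
            if c < 2:
                kd, kon = (b.kc1, b.kon_c1) if c == 0 else (b.kc2, b.kon_c2)
                rid = (_C_FIRST if c == 0 else _C_SECOND)[n] + off
                ca_edge(rid, f"M{n}{c}{sfx}", f"M{n}{c + 1}{sfx}", kd, kon, scale)
            if n < 2:
                kd, kon = (b.kn1, b.kon_n1) if n == 0 else (b.kn2, b.kon_n2)
                rid = (_N_FIRST if n == 0 else _N_SECOND)[c] + off
                ca_edge(rid, f"M{n}{c}{sfx}", f"M{n + 1}{c}{sfx}", kd, kon, scale)

    # CaM + CAMTA binding
    for n, c in _LATTICE:
        if (n, c) == (0, 0):
            reactions.append(
                ReactionSpec(
                    "R15", "M00", "M00X", "CAMTA",
                    b.kd_cam_camta / b.p, b.kon_cam_camta / b.q,
                )
            )
        else:
            reactions.append(
                ReactionSpec(
                    f"R{_BINDING_LABELS[(n, c)]}", f"M{n}{c}", f"M{n}{c}X",
                    "CAMTA", b.kd_cam_camta, b.kon_cam_camta,
                )
            )
    assert len(reactions) == 33
    return reactions


@dataclass(frozen=True)
class CycleReport:
    """Wegscheider check of one elementary square cycle."""

    description: str
    kd_product: float  # forward/backward Kd ratio around the cycle; 1 if consistent
    ok: bool


def _reaction_map(reactions: Sequence[ReactionSpec]) -> dict[tuple[str, str], ReactionSpec]:
    out = {}
    for r in reactions:
        out[(r.reactant, r.product)] = r
    return out


def wegscheider_check(
    reactions: Sequence[ReactionSpec], rtol: float = 1e-9
) -> list[CycleReport]:
    """Check every elementary square cycle of the lattice for detailed balance.

    Covered cycles: (i) Ca2+ step x CAMTA binding step — the free-layer edge,
    the corresponding bound-layer edge and the two binding edges; (ii) N-lobe
    step x C-lobe step within each layer.  A cycle passes when the product of
    Kd's traversed forward equals the product traversed backward to ``rtol``.
    Raises ``ValueError`` for a malformed network (missing edges/species).
    """
    rmap = _reaction_map(reactions)
    names = set(SPECIES_NAMES)
    for r in reactions:
        ok_species = r.reactant in names and (r.product in names)
        if not ok_species:
            raise ValueError(f"{r.reaction_id}: dangling species "
                             f"{r.reactant!r} -> {r.product!r}")
    reports: list[CycleReport] = []

    def edge(src: str, dst: str) -> ReactionSpec:
        try:
            return rmap[(src, dst)]
        except KeyError:
            raise ValueError(f"malformed network: missing edge {src} -> {dst}") from None

    # Ca step x CAMTA binding squares: A -> B (free), A -> AX, B -> BX, AX -> BX
    for n, c in _LATTICE:
        for dn, dc in ((1, 0), (0, 1)):
            n2, c2 = n + dn, c + dc
            if n2 > 2 or c2 > 2:
                continue
            a, bnm = f"M{n}{c}", f"M{n2}{c2}"
            r_free = edge(a, bnm)
            r_bound = edge(a + "X", bnm + "X")
            r_bind_a = edge(a, a + "X")
            r_bind_b = edge(bnm, bnm + "X")
            prod = (r_free.kd * r_bind_b.kd) / (r_bind_a.kd * r_bound.kd)
            reports.append(
                CycleReport(
                    f"{a}/{bnm} Ca x CAMTA square "
                    f"({r_free.reaction_id},{r_bind_b.reaction_id},"
                    f"{r_bound.reaction_id},{r_bind_a.reaction_id})",
                    prod,
                    abs(prod - 1.0) <= rtol,
                )
            )
    # N x C squares within each layer
    for sfx in ("", "X"):
        for n in range(2):
            for c in range(2):
                r_n_low = edge(f"M{n}{c}{sfx}", f"M{n + 1}{c}{sfx}")
                r_c_high = edge(f"M{n + 1}{c}{sfx}", f"M{n + 1}{c + 1}{sfx}")
                r_c_low = edge(f"M{n}{c}{sfx}", f"M{n}{c + 1}{sfx}")
                r_n_high = edge(f"M{n}{c + 1}{sfx}", f"M{n + 1}{c + 1}{sfx}")
                prod = (r_n_low.kd * r_c_high.kd) / (r_c_low.kd * r_n_high.kd)
                reports.append(
                    CycleReport(
                        f"M{n}{c}{sfx} lobe square", prod, abs(prod - 1.0) <= rtol
                    )
                )
    return reports


class BindingModel:
    """The compiled 19-species mass-action network under clamped Ca2+.

    Built from :class:`BaseParameters` (constants completed by detailed
    balance) or directly from a reaction list.  Provides the vector field,
    its Jacobian, equilibrium solvers and trajectory simulation.
    """

    def __init__(
        self,
        base: BaseParameters | None = None,
        reactions: Sequence[ReactionSpec] | None = None,
        control_ca: float = 0.10,
    ):
        self.base = base if base is not None else BaseParameters()
        self.reactions = (
            list(reactions) if reactions is not None else derive_parameters(self.base)
        )
        if control_ca < 0:
            raise ValueError("control_ca must be non-negative")
        self.control_ca = control_ca
        self._compile()

    def _compile(self) -> None:
        ca_r, ca_p, ca_on, ca_off = [], [], [], []
        b_m, b_mx, b_on, b_off = [], [], [], []
        for r in self.reactions:
            if r.ligand == "Ca":
                ca_r.append(IDX[r.reactant])
                ca_p.append(IDX[r.product])
                ca_on.append(r.k_on)
                ca_off.append(r.k_off)
            else:
                b_m.append(IDX[r.reactant])
                b_mx.append(IDX[r.product])
                b_on.append(r.k_on)
                b_off.append(r.k_off)
        self._ca_r = np.array(ca_r)
        self._ca_p = np.array(ca_p)
        self._ca_on = np.array(ca_on)
        self._ca_off = np.array(ca_off)
        self._b_m = np.array(b_m)
        self._b_mx = np.array(b_mx)
        self._b_on = np.array(b_on)
        self._b_off = np.array(b_off)

    # ---- vector field -------------------------------------------------

    def rhs(self, state: np.ndarray, ca: float) -> np.ndarray:
        """d(state)/dt (uM/s) under clamped Ca2+ concentration ``ca``.

        Pure mass action; CaM and CAMTA totals are conserved exactly
        (the columns of the stoichiometry matrix sum to zero within each
        conservation class).
        """
        y = np.asarray(state, dtype=float)
        dy = np.zeros(N_SPECIES)
        flux = self._ca_on * ca * y[self._ca_r] - self._ca_off * y[self._ca_p]
        np.subtract.at(dy, self._ca_r, flux)
        np.add.at(dy, self._ca_p, flux)
        x = y[CAMTA_INDEX]
        bflux = self._b_on * y[self._b_m] * x - self._b_off * y[self._b_mx]
        np.subtract.at(dy, self._b_m, bflux)
        np.add.at(dy, self._b_mx, bflux)
        dy[CAMTA_INDEX] -= bflux.sum()
        return dy

    def jacobian(self, state: np.ndarray, ca: float) -> np.ndarray:
        y = np.asarray(state, dtype=float)
        J = np.zeros((N_SPECIES, N_SPECIES))
        for i, j, kon, koff in zip(self._ca_r, self._ca_p, self._ca_on, self._ca_off):
            J[i, i] -= kon * ca
            J[i, j] += koff
            J[j, i] += kon * ca
            J[j, j] -= koff
        x = y[CAMTA_INDEX]
        for i, j, kon, koff in zip(self._b_m, self._b_mx, self._b_on, self._b_off):
            # flux = kon*y[i]*x - koff*y[j]
            J[i, i] -= kon * x
            J[i, CAMTA_INDEX] -= kon * y[i]
            J[i, j] += koff
            J[j, i] += kon * x
            J[j, CAMTA_INDEX] += kon * y[i]
            J[j, j] -= koff
            J[CAMTA_INDEX, i] -= kon * x
            J[CAMTA_INDEX, CAMTA_INDEX] -= kon * y[i]
            J[CAMTA_INDEX, j] += koff
        return J

    # ---- conservation helpers -----------------------------------------

    def totals(self, state: np.ndarray) -> tuple[float, float]:
        """(total CaM, total CAMTA) implied by a state vector."""
        y = np.asarray(state, dtype=float)
        cam = float(y[:18].sum())
        camta = float(y[9:18].sum() + y[CAMTA_INDEX])
        return cam, camta

    def initial_state(self) -> np.ndarray:
        """All CaM apo and all CAMTA free — a valid pre-equilibration start."""
        y = np.zeros(N_SPECIES)
        y[IDX["M00"]] = self.base.cam_total
        y[CAMTA_INDEX] = self.base.camta_total
        return y


def steady_state(
    model: BindingModel,
    ca: float,
    tol: float = 1e-10,
    max_span: float = 1e8,
) -> np.ndarray:
    """Equilibrium of the clamped-Ca network, by relaxation plus Newton polish.

    Integrates the stiff ODE system from the apo/free start over successively
    longer spans, then polishes with a root find on the reduced system (apo-CaM
    and free CAMTA eliminated through the conservation laws so the totals are
    preserved exactly).  Convergence requires max |rhs| < ``tol`` uM/s.
    """
    if ca < 0:
        raise ValueError("ca must be non-negative")
    y = model.initial_state()
    span = 1e4
    while span <= max_span:
        sol = solve_ivp(
            lambda t, s: model.rhs(s, ca),
            (0.0, span),
            y,
            method="BDF",
            jac=lambda t, s: model.jacobian(s, ca),
            rtol=1e-10,
            atol=1e-14,
        )
        if not sol.success:
            raise RuntimeError(f"relaxation to equilibrium failed: {sol.message}")
        y = sol.y[:, -1]
        if np.max(np.abs(model.rhs(y, ca))) < tol:
            break
        span *= 10
    y = _polish(model, y, ca)
    res = float(np.max(np.abs(model.rhs(y, ca))))
    if res >= tol:
        raise RuntimeError(
            f"steady state did not converge at ca={ca}: max |rhs| = {res:.3e} uM/s"
        )
    return np.clip(y, 0.0, None)

def _polish(model: BindingModel, y0: np.ndarray, ca: float) -> np.ndarray:
    free_idx = [i for i in range(N_SPECIES) if i not in (IDX["M00"], CAMTA_INDEX)]

    def reduced(z):
        y = np.empty(N_SPECIES)
        y[free_idx] = z
        y[IDX["M00"]] = model.base.cam_total - z[:17][np.array(free_idx) < 18].sum()
        y[CAMTA_INDEX] = model.base.camta_total - y[9:18].sum()
        return model.rhs(y, ca)[free_idx]

    sol = root(reduced, y0[free_idx], method="hybr", tol=1e-14)
    if not sol.success:
        return y0
    y = np.empty(N_SPECIES)
    y[free_idx] = sol.x
    y[IDX["M00"]] = model.base.cam_total - sol.x[np.array(free_idx) < 18].sum()
    y[CAMTA_INDEX] = model.base.camta_total - y[9:18].sum()
    if np.any(y < -1e-12):
        return y0
    return y


def _state_weights(model: BindingModel, ca: float):
    """Boltzmann-like weights of every species relative to free apo-CaM.

    Each species' equilibrium concentration is [M00] (or [M00][X]) times a
    product of ca/Kd factors along any lattice path from apo; the Wegscheider
    condition makes the product path-independent.
    """
    b = model.base
    w_free = np.empty(9)
    w_bind = np.empty(9)  # [M{n}{c}X] = w_bind * [M00] * [X]
    for k, (n, c) in enumerate(_LATTICE):
        w = 1.0
        if n >= 1:
            w *= ca / b.kn1
        if n >= 2:
            w *= ca / b.kn2
        if c >= 1:
            w *= ca / b.kc1
        if c >= 2:
            w *= ca / b.kc2
        w_free[k] = w
        kd_bind = b.kd_cam_camta / b.p if (n, c) == (0, 0) else b.kd_cam_camta
        w_bind[k] = w / kd_bind
    return w_free, w_bind


def equilibrium_oracle(model: BindingModel, ca: float) -> np.ndarray:
    """Equilibrium state without integrating ODEs (partition-function route).

    Expresses every species through path products of ca/Kd factors and solves
    the two conservation equations for free apo-CaM and free CAMTA by
    bracketed root finding.  Serves as the independent cross-check of
    :func:`steady_state`.
    """
    if ca < 0:
        raise ValueError("ca must be non-negative")
    b = model.base
    w_free, w_bind = _state_weights(model, ca)
    sf, sb = w_free.sum(), w_bind.sum()
    cam_t, x_t = b.cam_total, b.camta_total

    def excess_camta(x):
        m0 = cam_t / (sf + x * sb)
        return x + m0 * x * sb - x_t

    x = brentq(excess_camta, 0.0, x_t, xtol=1e-300, rtol=8.9e-16)
    m0 = cam_t / (sf + x * sb)
    y = np.empty(N_SPECIES)
    y[:9] = m0 * w_free
    y[9:18] = m0 * x * w_bind
    y[CAMTA_INDEX] = x
    return y


def simulate(
    model: BindingModel,
    trace: CalciumTrace,
    t_out: np.ndarray | None = None,
    y0: np.ndarray | None = None,
    rtol: float = 1e-5,
    atol: float = 1e-5,
    method: str = "BDF",
):
    """Simulate the network driven by a clamped Ca2+ trace.

    The initial state defaults to the equilibrium at the model's control Ca.
    Integration restarts at every trace discontinuity (square-wave switch
    times) so the stiff solver never steps across a jump; between samples the
    trace is linearly interpolated, beyond its ends clamped.  ``atol`` is
    interpreted relative to the smaller conserved total, so dynamic range in
    the rare species is preserved.

    Returns ``(t_out, Y)`` with ``Y`` of shape (len(t_out), 19) in canonical
    species order.
    """
    if t_out is None:
        t_out = np.unique(trace.times)
    t_out = np.asarray(t_out, dtype=float)
    if y0 is None:
        y0 = steady_state(model, model.control_ca)
    y0 = np.asarray(y0, dtype=float)

    scale = min(model.base.cam_total, model.base.camta_total)
    atol_abs = atol * scale * 1e-6  # resolve species far below the totals

    breaks = trace.discontinuities()
    t0, t1 = t_out[0], t_out[-1]
    seg_edges = np.concatenate(
        [[t0], breaks[(breaks > t0) & (breaks < t1)], [t1]]
    )
    Y = np.empty((t_out.size, N_SPECIES))
    filled = 0
    if t_out[0] == t0:
        Y[0] = y0
        filled = 1
    y = y0
    for a, b_edge in zip(seg_edges[:-1], seg_edges[1:]):
        if b_edge <= a:
            continue
        mask = (t_out > a) & (t_out <= b_edge)
        t_eval = t_out[mask]
        sol = solve_ivp(
            lambda t, s: model.rhs(s, float(trace(t))),
            (a, b_edge),
            y,
            method=method,
            jac=lambda t, s: model.jacobian(s, float(trace(t))),
            rtol=rtol,
            atol=atol_abs,
            t_eval=t_eval if t_eval.size else None,
            dense_output=False,
        )
        if not sol.success:
            raise RuntimeError(
                f"integration failed on [{a:.6g}, {b_edge:.6g}] s: {sol.message}"
            )
        if t_eval.size:
            Y[filled : filled + t_eval.size] = sol.y.T
            filled += t_eval.size
        y = sol.y[:, -1]
    assert filled == t_out.size
    return t_out, np.clip(Y, 0.0, None)


def conservation_residual(model: BindingModel, Y: np.ndarray) -> float:
    """Worst relative drift of the CaM and CAMTA totals along a trajectory."""
    cam = Y[:, :18].sum(axis=1)
    camta = Y[:, 9:18].sum(axis=1) + Y[:, CAMTA_INDEX]
    r1 = np.max(np.abs(cam - model.base.cam_total)) / model.base.cam_total
    r2 = np.max(np.abs(camta - model.base.camta_total)) / model.base.camta_total
    return float(max(r1, r2))
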