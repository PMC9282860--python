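"""Two-compartment bifurcation analysis of the EGFR polarity network.

Projecting the membrane reaction-diffusion system onto a front and a back
compartment coupled by linear exchange gives a 4-ODE caricature that preserves
the full model's bifurcation structure: the homogeneous steady state (HSS)
loses stability to an odd (front-minus-back) perturbation at a pitchfork
bifurcation (PB), the emerging inhomogeneous steady state (IHSS) is subcritical
and is stabilized by a pair of saddle-node bifurcations (SN_PB).  Organization
of total receptor abundance ``Et`` just below the SN_PB ("criticality") is the
substrate for transient memory: after stimulus removal the trajectory is
trapped in the ghost of the vanished polarized state.

The module also performs the nondimensionalization and the weakly nonlinear
(Galerkin) reduction to a quintic Stuart-Landau amplitude equation, whose
cubic coefficient sign certifies subcriticality.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, fsolve

from .signaling import (SignalingParams, homogeneous_steady_state, n2a_qss,
                        reaction_terms, _rga_qss)

__all__ = [
    "CompartmentState",
    "DimensionlessParams",
    "AmplitudeCoeffs",
    "BifurcationDiagram",
    "compartment_rhs",
    "compartment_jacobian",
    "odd_mode_pb_test",
    "scan_bifurcation_diagram",
    "nondimensionalize",
    "stuart_landau_coeffs",
]

DEFAULT_EXCHANGE = (0.02, 0.02)  # scaled (Ep, RGa) front<->back exchange rates


@dataclass
class CompartmentState:
    """Front/back Ep-like and RGa-like variables (EEp optional under ligand)."""

    u1f: float
    u2f: float
    u1b: float
    u2b: float
    eepf: float = 0.0
    eepb: float = 0.0

    def as_vector(self, with_ligand: bool = False) -> np.ndarray:
        if with_ligand:
            return np.array([self.u1f, self.u2f, self.u1b, self.u2b,
                             self.eepf, self.eepb])
        return np.array([self.u1f, self.u2f, self.u1b, self.u2b])

    @classmethod
    def symmetric(cls, u1: float, u2: float, eep: float = 0.0
                  ) -> "CompartmentState":
        return cls(u1, u2, u1, u2, eep, eep)

    @property
    def asymmetry(self) -> float:
        return abs(self.u1f - self.u1b)


# ---------------------------------------------------------------------------
# right-hand side and Jacobian
# ---------------------------------------------------------------------------

def _single_rhs(ep, rga, eep, params, egf):
    """Single-compartment (Ep, RGa[, EEp]) rates with PTPN2 at QSS."""
    n2a = n2a_qss(max(ep, 0.0), max(eep, 0.0), params)
    f1, f2, f3, _ = reaction_terms(max(ep, 0.0), max(eep, 0.0),
                                   max(rga, 0.0), n2a, params, egf)
    return float(f1), float(f3), float(f2)


def compartment_rhs(state: CompartmentState, params: SignalingParams,
                    exchange: tuple[float, float] = DEFAULT_EXCHANGE,
                    egf_front: float = 0.0, egf_back: float = 0.0,
                    with_ligand: bool | None = None) -> np.ndarray:
    """Time derivatives of the front/back compartment system.

    Reaction terms are those of the membrane network with PTPN2 at quasi-steady
    state; diffusion becomes linear exchange ``-d*(front - back)``.  When
    ligand is present (or ``with_ligand`` is forced) the liganded receptor is
    carried as a dynamical variable per compartment, giving a 6-vector.
    """
    d1, d2 = exchange
    if with_ligand is None:
        with_ligand = (egf_front != 0.0 or egf_back != 0.0
                       or state.eepf != 0.0 or state.eepb != 0.0)
    f1f, f3f, f2f = _single_rhs(state.u1f, state.u2f, state.eepf, params,
                                egf_front)
    f1b, f3b, f2b = _single_rhs(state.u1b, state.u2b, state.eepb, params,
                                egf_back)
    du1f = f1f - d1 * (state.u1f - state.u1b)
    du2f = f3f - d2 * (state.u2f - state.u2b)
    du1b = f1b - d1 * (state.u1b - state.u1f)
    du2b = f3b - d2 * (state.u2b - state.u2f)
    if with_ligand:
        return np.array([du1f, du2f, du1b, du2b, f2f, f2b])
    return np.array([du1f, du2f, du1b, du2b])


def _single_jacobian(ep: float, rga: float, params: SignalingParams
                     ) -> np.ndarray:
    """Analytic 2x2 Jacobian of the ligand-free single compartment."""
    p = params
    E = p.Et - ep
    n2a = float(n2a_qss(ep, 0.0, p))
    dn2a = p.N2t * p.beta2 * p.k2 / (p.k1 + p.k2 + p.beta2 * ep) ** 2
    df1_dep = (-2 * p.alpha1 * E + p.alpha2 * (E - ep)
               - p.gamma1 * rga - p.gamma2 * (n2a + ep * dn2a))
    df1_drga = -p.gamma1 * ep
    df3_dep = -p.beta1 * rga
    df3_drga = -(p.k1 + p.k2) - p.beta1 * ep
    return np.array([[df1_dep, df1_drga], [df3_dep, df3_drga]])


def compartment_jacobian(state: CompartmentState, params: SignalingParams,
                         exchange: tuple[float, float] = DEFAULT_EXCHANGE
                         ) -> np.ndarray:
    """Analytic 4x4 Jacobian of the ligand-free front/back system."""
    d = np.diag(exchange)
    Af = _single_jacobian(state.u1f, state.u2f, params) - d
    Ab = _single_jacobian(state.u1b, state.u2b, params) - d
    J = np.zeros((4, 4))
    J[:2, :2] = Af
    J[2:, 2:] = Ab
    J[:2, 2:] = d
    J[2:, :2] = d
    return J


def numeric_jacobian(x: np.ndarray, params: SignalingParams,
                     exchange: tuple[float, float] = DEFAULT_EXCHANGE,
                     h: float = 1e-7) -> np.ndarray:
    """Central finite-difference Jacobian of the 4-ODE rhs (test oracle)."""
    def rhs(v):
        return compartment_rhs(CompartmentState(*v), params, exchange,
                               with_ligand=False)
    n = len(x)
    J = np.zeros((n, n))
    for j in range(n):
        e = np.zeros(n)
        e[j] = h
        J[:, j] = (rhs(x + e) - rhs(x - e)) / (2 * h)
    return J


# ---------------------------------------------------------------------------
# pitchfork test and diagram scan
# ---------------------------------------------------------------------------

def odd_mode_pb_test(params: SignalingParams, Et: float,
                     exchange: tuple[float, float] = DEFAULT_EXCHANGE,
                     branch: str = "low") -> float:
    """Odd-mode reduced determinant at the HSS.

    For a symmetric state the 4x4 Jacobian block-diagonalizes over even
    (front = back) and odd (front = -back) perturbations; the odd block is
    ``A - 2*diag(exchange)`` with ``A`` the single-compartment Jacobian.  Its
    determinant crosses zero exactly at the pitchfork bifurcation.
    """
    p = params.with_Et(Et)
    hss = homogeneous_steady_state(p, 0.0, branch=branch, n_bins=1)
    A = _single_jacobian(float(hss.Ep[0]), float(hss.RGa[0]), p)
    odd = A - 2 * np.diag(exchange)
    return float(np.linalg.det(odd))


@dataclass
class BifurcationDiagram:
    """HSS and IHSS branches of the front/back system versus ``Et``."""

    Et_hss: np.ndarray
    hss_Ep: np.ndarray            # uniform Ep along HSS points
    hss_stable: np.ndarray        # bool per HSS point (4-ODE stability)
    Et_ihss: np.ndarray
    ihss_front: np.ndarray        # high-branch Ep
    ihss_back: np.ndarray         # low-branch Ep
    ihss_stable: np.ndarray
    Et_pb: float | None = None
    Et_snpb: float | None = None
    meta: dict = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd
        rows = []
        for et, ep, st in zip(self.Et_hss, self.hss_Ep, self.hss_stable):
            rows.append(("HSS", et, ep, ep, bool(st)))
        for et, f, b, st in zip(self.Et_ihss, self.ihss_front,
                                self.ihss_back, self.ihss_stable):
            rows.append(("IHSS", et, f, b, bool(st)))
        return pd.DataFrame(rows, columns=["branch", "Et", "Ep_front",
                                           "Ep_back", "stable"])


def _hss_points(params: SignalingParams, Et: float) -> list[np.ndarray]:
    p = params.with_Et(Et)
    states = homogeneous_steady_state(p, 0.0, branch="all", n_bins=1)
    return [np.array([float(s.Ep[0]), float(s.RGa[0]),
                      float(s.Ep[0]), float(s.RGa[0])]) for s in states]


def _is_stable(x: np.ndarray, params: SignalingParams,
               exchange: tuple[float, float]) -> bool:
    J = compartment_jacobian(CompartmentState(*x), params, exchange)
    return bool(np.max(np.real(np.linalg.eigvals(J))) < 0)


def _continue_branch(x0: np.ndarray, Et0: float, params: SignalingParams,
                     exchange: tuple[float, float], Et_lo: float, Et_hi: float,
                     ds: float = 2e-3, max_steps: int = 6000):
    """Pseudo-arclength continuation of 4-ODE fixed points in ``Et``.

    Secant predictor, Newton (fsolve) corrector on the augmented system.
    Returns arrays of (Et, x) along the branch, traversing folds.
    """
    def F(x, Et):
        return compartment_rhs(CompartmentState(*x), params.with_Et(Et),
                               exchange, with_ligand=False)

    # converge the seed
    x0 = fsolve(lambda v: F(v, Et0), x0, xtol=1e-12)
    pts = [(Et0, x0)]
    # initial tangent: straight continuation in Et
    x1 = fsolve(lambda v: F(v, Et0 + ds), x0, xtol=1e-12)
    if np.max(np.abs(F(x1, Et0 + ds))) > 1e-8:
        return pts
    pts.append((Et0 + ds, x1))

    for direction in (+1, -1):
        work = list(pts) if direction > 0 else [pts[1], pts[0]]
        for _ in range(max_steps):
            (ea, xa), (eb, xb) = work[-2], work[-1]
            tang = np.append(xb - xa, eb - ea)
            norm = np.linalg.norm(tang)
            if norm == 0:
                break
            tang /= norm
            guess = np.append(xb, eb) + ds * tang

            def G(z):
                x, Et = z[:4], z[4]
                return np.append(F(x, Et),
                                 np.dot(z - np.append(xb, eb), tang) - ds)

            sol, info, ier, _ = fsolve(G, guess, full_output=True, xtol=1e-12)
            if ier != 1 or np.max(np.abs(F(sol[:4], sol[4]))) > 1e-8:
                break
            if np.any(sol[:4] < -1e-6) or not (Et_lo - 0.05 <= sol[4]
                                               <= Et_hi + 0.05):
                work.append((sol[4], sol[:4]))
                break
            work.append((sol[4], sol[:4]))
        if direction > 0:
            forward = work
        else:
            backward = work
    # stitch: backward (reversed, minus shared seed pair) + forward
    full = list(reversed(backward[2:])) + forward
    return full


def scan_bifurcation_diagram(params: SignalingParams,
                             Et_range: tuple[float, float] = (1.0, 2.0),
                             Et_step: float = 1e-3,
                             exchange: tuple[float, float] = DEFAULT_EXCHANGE,
                             ihss_seed_Et: float = 1.30
                             ) -> BifurcationDiagram:
    """Trace HSS and IHSS branches and locate the PB and SN_PB.

    The HSS branch comes from direct root finding per ``Et`` (all coexisting
    roots); its pitchfork is bracketed by the odd-mode determinant zero
    crossing on the low branch.  The IHSS branch is traced by pseudo-arclength
    continuation of asymmetric fixed points of the 4-ODE system, seeded by
    relaxation at ``ihss_seed_Et``; the SN_PB is the fold (minimal ``Et``)
    of that branch.
    """
    lo, hi = Et_range
    ets = np.arange(lo, hi + Et_step / 2, max(Et_step, 1e-4))
    # coarse HSS sampling for the diagram (fine scan only for PB bracketing)
    coarse = ets[::max(1, len(ets) // 400)]
    hss_et, hss_ep, hss_st = [], [], []
    for et in coarse:
        for x in _hss_points(params, et):
            hss_et.append(et)
            hss_ep.append(x[0])
            hss_st.append(_is_stable(x, params.with_Et(et), exchange))

    # PB: odd-mode determinant zero crossings along every HSS sub-branch.
    # The basal branch may stay symmetric all the way to its fold, in which
    # case the pitchfork sits on the middle (saddle) branch; the middle
    # branch is scanned over its full existence interval (the PB is a global
    # feature of the diagram, not confined to Et_range).
    pb_candidates = []
    for branch in ("low", "middle", "high"):
        grid = np.linspace(lo, hi + 0.5, 121)
        det_prev, et_prev = None, None
        for et in grid:
            try:
                det = odd_mode_pb_test(params, et, exchange, branch=branch)
            except RuntimeError:
                det_prev, et_prev = None, None
                continue
            if det_prev is not None and det * det_prev < 0:
                root = brentq(
                    lambda e: odd_mode_pb_test(params, e, exchange,
                                               branch=branch),
                    et_prev, et, xtol=1e-10)
                pb_candidates.append((root, branch))
            det_prev, et_prev = det, et
    # the PB from which the subcritical IHSS branch unfolds is the
    # largest-Et crossing (coexistence of HSS and IHSS extends below it)
    Et_pb = max((r for r, _ in pb_candidates), default=None)

    # IHSS: relax to an asymmetric state at the seed Et, then continue
    from scipy.integrate import solve_ivp
    p_seed = params.with_Et(ihss_seed_Et)
    hss = homogeneous_steady_state(p_seed, 0.0, branch="low", n_bins=1)
    x0 = np.array([float(hss.Ep[0]) + 0.5, float(hss.RGa[0]) * 0.5,
                   float(hss.Ep[0]), float(hss.RGa[0])])
    sol = solve_ivp(
        lambda t, v: compartment_rhs(CompartmentState(*np.clip(v, 0, None)),
                                     p_seed, exchange, with_ligand=False),
        (0.0, 600.0), x0, method="LSODA", rtol=1e-10, atol=1e-12)
    x = np.clip(sol.y[:, -1], 0, None)
    ih_et, ih_f, ih_b, ih_st = [], [], [], []
    Et_snpb = None
    if abs(x[0] - x[2]) > 1e-3:
        branch = _continue_branch(x, ihss_seed_Et, params, exchange, lo, hi)
        for et, xb in branch:
            if abs(xb[0] - xb[2]) < 1e-5:      # merged back into HSS (at PB)
                continue
            ih_et.append(et)
            ih_f.append(max(xb[0], xb[2]))
            ih_b.append(min(xb[0], xb[2]))
            ih_st.append(_is_stable(xb, params.with_Et(et), exchange))
        # SN_PB = fold of the IHSS branch where the asymmetric branch turns
        # and gains stability: the low-Et edge of the stable segment
        stable_ets = [et for et, st in zip(ih_et, ih_st) if st]
        if stable_ets:
            Et_snpb = float(np.min(stable_ets))
        elif ih_et:
            Et_snpb = float(np.min(ih_et))

    return BifurcationDiagram(
        np.array(hss_et), np.array(hss_ep), np.array(hss_st, dtype=bool),
        np.array(ih_et), np.array(ih_f), np.array(ih_b),
        np.array(ih_st, dtype=bool), Et_pb, Et_snpb,
        meta={"exchange": exchange, "Et_step": Et_step,
              "pb_candidates": pb_candidates,
              "params_hash": params.hash()})


# ---------------------------------------------------------------------------
# nondimensionalization and weakly nonlinear reduction
# ---------------------------------------------------------------------------

@dataclass
class DimensionlessParams:
    """Dimensionless groups of the two-variable (Ep, RGa) system.

    ``q7..q9t`` are the Taylor coefficients of the PTPN2 quasi-steady-state
    sink about the operating point ``Es``; ``q9, q10, q11`` are the recombined
    coefficients of the reduced quadratic kinetics.  Scalings: ``t0`` time,
    ``E0`` receptor, ``RG0`` phosphatase concentration, ``x0`` length.
    """

    q1: float
    q2: float
    q3: float
    q4: float
    q7: float
    q8: float
    q9t: float           # Taylor quadratic coefficient
    q9: float            # = q1 - q7
    q10: float           # = q2 - q8
    q11: float           # = q3 - q9t
    r1: float
    r2: float
    k: float             # k2/k1
    Dratio: float        # D_RGa / D_Ep
    Es: float            # dimensionless Ep operating point
    t0: float
    E0: float
    RG0: float
    x0: float


def nondimensionalize(params: SignalingParams,
                      Es: float | None = None) -> DimensionlessParams:
    """Dimensionless parameter groups for the weakly nonlinear analysis.

    ``Es`` is the dimensionless steady state of ``Ep`` about which the PTPN2
    sink is Taylor-expanded; when omitted it is computed from the
    low-phosphorylation homogeneous steady state.
    """
    p = params
    ks = p.k1 + p.k2
    if ks <= 0 or p.beta2 <= 0 or p.gamma1 <= 0 or p.D_Ep <= 0:
        raise ValueError("nondimensionalization requires k1+k2, beta2, "
                         "gamma1, D_Ep > 0")
    t0 = 1.0 / ks
    E0 = p.k1 / p.beta2
    RG0 = ks / p.gamma1
    x0 = float(np.sqrt(p.D_Ep * t0))
    if Es is None:
        hss = homogeneous_steady_state(p, 0.0, branch="low", n_bins=1)
        Es = float(hss.Ep[0]) / E0
    k = p.k2 / p.k1
    q1 = p.alpha1 * p.Et ** 2 / (ks * p.beta2)
    q2 = (p.alpha2 - 2 * p.alpha1) * p.Et / ks
    q3 = (p.alpha1 - p.alpha2) * p.k1 / (ks * p.beta2)
    q4 = p.gamma2 * p.N2t / ks
    c = 1 + k
    q7 = Es * q4 / (c + Es) - Es * q4 * c / (c + Es) ** 2
    q8 = Es * q4 / (c + Es) + q4 * c / (c + Es) ** 2 * (1 - Es)
    q9t = q4 * c / (c + Es) ** 2
    r1 = p.k1 * p.RGt * p.gamma1 / ks ** 2
    r2 = p.beta1 * p.k1 / (ks * p.beta2)
    return DimensionlessParams(
        q1=q1, q2=q2, q3=q3, q4=q4, q7=q7, q8=q8, q9t=q9t,
        q9=q1 - q7, q10=q2 - q8, q11=q3 - q9t,
        r1=r1, r2=r2, k=k, Dratio=p.D_RGa / p.D_Ep, Es=Es,
        t0=t0, E0=E0, RG0=RG0, x0=x0)


@dataclass
class AmplitudeCoeffs:
    """Stuart-Landau coefficients of the leading unstable mode.

    The amplitude obeys ``dphi/dt = c1*phi + c2*phi^3 - c3*phi^5``; with
    ``c2 > 0`` and ``c3 > 0`` the pitchfork is subcritical and the quintic
    saturation creates the stabilizing saddle-node pair (SN_PB).
    """

    c1: float
    c2: float
    c3: float
    km: float
    u2_2: float
    v2_2: float
    u3_3: float
    v3_3: float

    @property
    def subcritical(self) -> bool:
        return self.c2 > 0 and self.c3 > 0

    def fold_amplitude(self) -> float | None:
        """|phi| at the fold of the quintic amplitude equation (c1 -> 0-)."""
        if not self.subcritical:
            return None
        return float(np.sqrt(self.c2 / (2 * self.c3)))


def stuart_landau_coeffs(dp: DimensionlessParams, km: float | None = None
                         ) -> AmplitudeCoeffs:
    """Closed-form amplitude-equation coefficients at wavenumber ``km``.

    The Galerkin truncation requires the higher harmonics to be damped,
    i.e. ``q10 - (n*km)^2 < 0`` for n = 2, 3; wavenumbers below
    ``sqrt(q10)/2`` sit in a resonant band where the closed forms are
    meaningless (this includes the first ring mode ``x0/R`` of a
    2-um cell).  The default is therefore ``km = 1``: the intrinsic
    diffusion lengthscale of the activator in dimensionless units, the
    natural scale of the front-back pattern.  Raises when a harmonic
    resonates with the chosen mode (vanishing denominator).
    """
    if km is None:
        km = 1.0
    q10, q11, q9, r1, r2, D = dp.q10, dp.q11, dp.q9, dp.r1, dp.r2, dp.Dratio
    dens = [q10 - 4 * km ** 2, q10 - 9 * km ** 2,
            1 + 4 * D * km ** 2, 1 + 9 * D * km ** 2, q10]
    if any(abs(d) < 1e-12 for d in dens):
        raise ZeroDivisionError("resonant wavenumber: harmonic denominator "
                                "vanishes; choose a different km")
    u2_2 = (1 - q11) / (q10 - 4 * km ** 2)
    v2_2 = -r2 / (1 + 4 * D * km ** 2)
    u3_3 = (u2_2 + v2_2 - 2 * q11 * u2_2) / (q10 - 9 * km ** 2)
    v3_3 = -r2 * (u2_2 + v2_2) / (1 + 9 * D * km ** 2)
    c1 = q10 - km ** 2 - r1 + q9 * (1 - 2 * q11) / q10
    c2 = ((1 - q11) * (2 * q11 - 1) * (2 / q10 - 1 / (q10 - 4 * km ** 2))
          + r2 * (2 + 1 / (1 + 4 * D * km ** 2)))
    c3 = 2 * q11 * u2_2 * u3_3 - u2_2 * v3_3
    return AmplitudeCoeffs(c1=c1, c2=c2, c3=c3, km=float(km),
                           u2_2=u2_2, v2_2=v2_2, u3_3=u3_3, v3_3=v3_3)
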