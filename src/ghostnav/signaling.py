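"""Stochastic reaction-diffusion model of EGFR phosphorylation polarity.

The membrane of a single cell is represented as a one-dimensional periodic
domain of length ``L = 2*pi*R`` divided into equal bins.  Four species live on
it: ligandless phosphorylated receptor ``Ep``, liganded phosphorylated dimeric
receptor ``EEp``, active PTPRG ``RGa`` and active PTPN2 ``N2a``.  The receptor
activates autonomously, autocatalytically and through its liganded form, while
the two phosphatases provide a double-negative and a slow negative feedback.
Total receptor abundance ``Et`` is the control parameter: depending on its
value the network sits in a basal, critical (saddle-node ghost), stably
polarized, or pre-activated regime.

Simulation is explicit Euler-Maruyama with periodic central-difference
diffusion; additive white noise acts on the ``Ep`` equation only.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import brentq, fsolve

__all__ = [
    "SignalingParams",
    "MembraneGrid",
    "SignalingState",
    "GaussianComponent",
    "StimulusSegment",
    "StimulusProtocol",
    "Kymograph",
    "reaction_terms",
    "n2a_qss",
    "homogeneous_steady_state",
    "simulate_rd",
    "polarization_metrics",
]


# ---------------------------------------------------------------------------
# parameters and containers
# ---------------------------------------------------------------------------

@dataclass
class SignalingParams:
    """Rate constants and totals of the EGFR-PTPRG-PTPN2 network.

    Units: concentrations are normalized to the PTPRG total, time is minutes.
    ``epsilon`` is the timescale separation of the slow PTPN2 feedback.
    """

    alpha1: float = 0.001   # autonomous receptor activation
    alpha2: float = 0.3     # autocatalytic activation
    alpha3: float = 0.7     # liganded-receptor-induced activation
    beta1: float = 11.0     # receptor -> PTPRG inactivation
    beta2: float = 1.1      # receptor -> PTPN2 activation
    gamma1: float = 1.9     # PTPRG reactivity toward Ep
    gamma2: float = 0.1     # PTPN2 reactivity toward Ep
    k1: float = 0.5         # phosphatase activation
    k2: float = 0.5         # phosphatase inactivation
    kon: float = 0.05       # EGF binding
    koff: float = 0.28      # EGF unbinding
    epsilon: float = 0.01   # PTPN2 timescale separation
    Et: float = 1.26        # total EGFR (default: organization at criticality)
    RGt: float = 1.0        # total PTPRG
    N2t: float = 1.0        # total PTPN2
    D_Ep: float = 0.008     # um^2/min lateral diffusion of Ep
    D_RGa: float = 0.008    # um^2/min lateral diffusion of RGa
    D_EEp: float = 0.0      # liganded receptor is immobile
    sigma_noise: float = 0.02  # additive noise amplitude on Ep

    def __post_init__(self) -> None:
        rates = [self.alpha1, self.alpha2, self.alpha3, self.beta1, self.beta2,
                 self.gamma1, self.gamma2, self.k1, self.k2, self.kon,
                 self.koff, self.D_Ep, self.D_RGa, self.D_EEp,
                 self.sigma_noise]
        if any(r < 0 for r in rates):
            raise ValueError("all rate constants must be non-negative")
        if not 0 < self.epsilon <= 1:
            raise ValueError("epsilon must be in (0, 1]")
        if min(self.Et, self.RGt, self.N2t) <= 0:
            raise ValueError("totals Et, RGt, N2t must be positive")

    def with_Et(self, Et: float) -> "SignalingParams":
        return replace(self, Et=Et)

    def hash(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


@dataclass
class MembraneGrid:
    """Periodic 1-D discretization of the membrane contour."""

    radius: float = 2.0   # um
    n_bins: int = 20

    def __post_init__(self) -> None:
        if self.n_bins < 3:
            raise ValueError("need at least 3 bins for a periodic Laplacian")
        if self.radius <= 0:
            raise ValueError("radius must be positive")

    @property
    def bin_centers(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) * 2 * np.pi / self.n_bins

    @property
    def bin_length(self) -> float:
        return 2 * np.pi * self.radius / self.n_bins


@dataclass
class SignalingState:
    """Per-bin concentrations of the four species."""

    Ep: np.ndarray
    EEp: np.ndarray
    RGa: np.ndarray
    N2a: np.ndarray

    @classmethod
    def uniform(cls, n_bins: int, Ep: float, EEp: float, RGa: float,
                N2a: float) -> "SignalingState":
        f = np.full(n_bins, float(Ep))
        return cls(f, np.full(n_bins, float(EEp)),
                   np.full(n_bins, float(RGa)), np.full(n_bins, float(N2a)))

    def copy(self) -> "SignalingState":
        return SignalingState(self.Ep.copy(), self.EEp.copy(),
                              self.RGa.copy(), self.N2a.copy())

    def check_bounds(self, params: SignalingParams, atol: float = 1e-9) -> bool:
        p = params
        return bool(
            np.all(self.Ep >= -atol) and np.all(self.EEp >= -atol)
            and np.all(self.Ep + self.EEp <= p.Et + atol)
            and np.all((self.RGa >= -atol) & (self.RGa <= p.RGt + atol))
            and np.all((self.N2a >= -atol) & (self.N2a <= p.N2t + atol))
        )


# ---------------------------------------------------------------------------
# stimulus protocols
# ---------------------------------------------------------------------------

Schedule = float | tuple[float, float] | Callable[[float], float]


def _eval_schedule(s: Schedule, t: float, t0: float, t1: float) -> float:
    """Constant, linear-in-time (start, end) ramp, or callable schedule."""
    if callable(s):
        return float(s(t))
    if isinstance(s, tuple):
        a, b = s
        if t1 <= t0:
            return float(b)
        frac = np.clip((t - t0) / (t1 - t0), 0.0, 1.0)
        return float(a + (b - a) * frac)
    return float(s)


@dataclass
class GaussianComponent:
    """One wrapped-Gaussian lobe of an EGF gradient."""

    amplitude: Schedule = 1.0     # peak concentration
    width: Schedule = 1.0         # angular s.d. (radians)
    center: float = np.pi         # angle of the peak


@dataclass
class StimulusSegment:
    t_start: float
    t_end: float
    kind: str = "none"            # none | gaussian_gradient | uniform
    amplitude: Schedule = 0.0     # used by 'uniform'
    components: Sequence[GaussianComponent] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.kind not in ("none", "gaussian_gradient", "uniform"):
            raise ValueError(f"unknown stimulus kind {self.kind!r}")
        if self.t_end < self.t_start:
            raise ValueError("segment must have t_end >= t_start")


@dataclass
class StimulusProtocol:
    """Piecewise space-time EGF field on the membrane contour."""

    segments: Sequence[StimulusSegment]

    def __post_init__(self) -> None:
        segs = sorted(self.segments, key=lambda s: s.t_start)
        for a, b in zip(segs[:-1], segs[1:]):
            if b.t_start < a.t_end - 1e-12:
                raise ValueError("stimulus segments overlap")
        self.segments = segs

    def egf(self, angles: np.ndarray, t: float) -> np.ndarray:
        """Total EGF concentration seen by each membrane bin at time ``t``."""
        out = np.zeros_like(np.asarray(angles, dtype=float))
        for seg in self.segments:
            if not (seg.t_start <= t < seg.t_end or
                    (t == seg.t_end and seg is self.segments[-1])):
                continue
            if seg.kind == "none":
                return out
            if seg.kind == "uniform":
                out += _eval_schedule(seg.amplitude, t, seg.t_start, seg.t_end)
                return out
            for comp in seg.components:
                amp = _eval_schedule(comp.amplitude, t, seg.t_start, seg.t_end)
                wid = _eval_schedule(comp.width, t, seg.t_start, seg.t_end)
                d = np.angle(np.exp(1j * (angles - comp.center)))
                out += amp * np.exp(-0.5 * (d / max(wid, 1e-9)) ** 2)
            return out
        return out

    def stimulus_end(self) -> float | None:
        """End of the last stimulating segment, or None when never stimulated."""
        active = [s.t_end for s in self.segments if s.kind != "none"]
        return max(active) if active else None

    def has_washout(self) -> bool:
        t_end = self.stimulus_end()
        if t_end is None:
            return False
        return any(s.kind == "none" and s.t_end > t_end + 1e-9
                   for s in self.segments)

    @property
    def t_end(self) -> float:
        return max(s.t_end for s in self.segments)

    def primary_direction(self) -> float:
        """Angle of the first gradient lobe (used to orient downstream analyses)."""
        for s in self.segments:
            if s.kind == "gaussian_gradient" and s.components:
                return float(s.components[0].center)
        return np.pi


# ---------------------------------------------------------------------------
# kymograph container
# ---------------------------------------------------------------------------

@dataclass
class Kymograph:
    """Space (membrane bin) x time matrix of one species or derived quantity."""

    values: np.ndarray          # (n_bins, n_times)
    times: np.ndarray
    angles: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.angles = np.asarray(self.angles, dtype=float)
        if self.values.shape != (len(self.angles), len(self.times)):
            raise ValueError("kymograph shape inconsistent with axes")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("time vector must be strictly increasing")

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    def at_time(self, t: float) -> np.ndarray:
        i = int(np.argmin(np.abs(self.times - t)))
        return self.values[:, i]

    def to_csv(self, path) -> None:
        header = ",".join(["bin_angle"] + [f"{t:.6g}" for t in self.times])
        body = np.column_stack([self.angles, self.values])
        np.savetxt(path, body, delimiter=",", header=header, comments="")

    @classmethod
    def from_csv(cls, path) -> "Kymograph":
        with open(path) as fh:
            times = np.array([float(x) for x in
                              fh.readline().strip().split(",")[1:]])
        body = np.loadtxt(path, delimiter=",", skiprows=1)
        body = np.atleast_2d(body)
        return cls(body[:, 1:], times, body[:, 0])


# ---------------------------------------------------------------------------
# reaction kinetics
# ---------------------------------------------------------------------------

def reaction_terms(Ep, EEp, RGa, N2a, params: SignalingParams, EGFt):
    """Instantaneous reaction rates (f1, f2, f3, f4) of the four species.

    Accepts scalars or per-bin arrays.  The liganded receptor is dimeric, so
    binding consumes receptor pairs (quadratic terms) and dissociation returns
    half a dimer's worth of ``Ep``.  ``f4`` carries the ``epsilon`` prefactor
    of the slow PTPN2 feedback.
    """
    Ep = np.asarray(Ep, dtype=float)
    EEp = np.asarray(EEp, dtype=float)
    RGa = np.asarray(RGa, dtype=float)
    N2a = np.asarray(N2a, dtype=float)
    EGFt = np.asarray(EGFt, dtype=float)
    if np.any(Ep < 0) or np.any(EEp < 0) or np.any(RGa < 0) or np.any(N2a < 0):
        raise ValueError("species concentrations must be non-negative")
    if np.any(EGFt < 0):
        raise ValueError("EGF concentration must be non-negative")
    p = params
    E = p.Et - Ep - EEp          # inactive, ligandless receptor
    free_egf = EGFt - EEp        # bin-local ligand depletion
    f1 = (E * (p.alpha1 * E + p.alpha2 * Ep + p.alpha3 * EEp)
          - p.gamma1 * RGa * Ep - p.gamma2 * N2a * Ep
          - p.kon * free_egf * Ep ** 2 + 0.5 * p.koff * EEp)
    f2 = p.kon * free_egf * (Ep ** 2 + E ** 2) - p.koff * EEp
    f3 = p.k1 * (p.RGt - RGa) - p.k2 * RGa - p.beta1 * RGa * (Ep + EEp)
    f4 = p.epsilon * (p.k1 * (p.N2t - N2a) - p.k2 * N2a
                      + p.beta2 * (Ep + EEp) * (p.N2t - N2a))
    return f1, f2, f3, f4


def n2a_qss(Ep, EEp, params: SignalingParams):
    """Quasi-steady-state active PTPN2 given total phosphorylated receptor."""
    Ep = np.asarray(Ep, dtype=float)
    EEp = np.asarray(EEp, dtype=float)
    if np.any(Ep < 0) or np.any(EEp < 0):
        raise ValueError("concentrations must be non-negative")
    s = Ep + EEp
    p = params
    return p.N2t * (p.k1 + p.beta2 * s) / (p.k1 + p.k2 + p.beta2 * s)


def _rga_qss(Ep, EEp, params: SignalingParams):
    # steady state of f3 given receptor phosphorylation; used for root finding
    s = np.asarray(Ep) + np.asarray(EEp)
    p = params
    return p.k1 * p.RGt / (p.k1 + p.k2 + p.beta1 * s)


def homogeneous_steady_state(params: SignalingParams, EGFt: float = 0.0,
                             branch: str = "low", tol: float = 1e-10,
                             n_bins: int = 20) -> SignalingState:
    """Uniform fixed point of the reaction network.

    With no ligand the liganded species is exactly zero and the problem reduces
    to a scalar root in ``Ep``; with ligand a 2-D root find is used.  When
    several homogeneous states coexist the one continued from the
    low-phosphorylation branch is returned unless ``branch`` says otherwise
    (``"high"`` or ``"all"`` which returns a list of states).
    """
    p = params

    if EGFt == 0.0:
        def g(ep):
            rga = _rga_qss(ep, 0.0, p)
            n2a = n2a_qss(ep, 0.0, p)
            f1, _, _, _ = reaction_terms(ep, 0.0, rga, n2a, p, 0.0)
            return float(f1)

        eps = np.linspace(0.0, p.Et * (1 - 1e-9), 2001)
        rga = _rga_qss(eps, 0.0, p)
        n2a = n2a_qss(eps, np.zeros_like(eps), p)
        vals, _, _, _ = reaction_terms(eps, np.zeros_like(eps), rga, n2a,
                                       p, np.zeros_like(eps))
        roots = []
        for i in range(len(eps) - 1):
            if vals[i] == 0.0:
                roots.append(eps[i])
            elif vals[i] * vals[i + 1] < 0:
                roots.append(brentq(g, eps[i], eps[i + 1], xtol=1e-14))
        if not roots:
            raise RuntimeError(
                f"no homogeneous steady state found at Et={p.Et}, EGFt=0; "
                f"residual range [{vals.min():.3g}, {vals.max():.3g}]")
        roots = sorted(set(np.round(roots, 13)))
        states = [SignalingState.uniform(
            n_bins, r, 0.0, _rga_qss(r, 0.0, p), n2a_qss(r, 0.0, p))
            for r in roots]
        if branch == "all":
            return states
        if branch == "middle":
            if len(states) < 3:
                raise RuntimeError(
                    f"no middle HSS branch at Et={p.Et} (found "
                    f"{len(states)} root(s))")
            st = states[1]
        else:
            st = states[-1] if branch == "high" else states[0]
    else:
        def resid(x):
            ep, eep = x
            rga = _rga_qss(ep, eep, p)
            n2a = n2a_qss(ep, eep, p)
            f1, f2, _, _ = reaction_terms(max(ep, 0), max(eep, 0),
                                          rga, n2a, p, EGFt)
            return [f1, f2]

        seed = homogeneous_steady_state(p, 0.0, branch=branch, n_bins=1)
        x0 = [float(seed.Ep[0]), min(0.5 * EGFt, 0.4 * p.Et)]
        sol, info, ier, msg = fsolve(resid, x0, full_output=True, xtol=1e-13)
        if ier != 1:
            raise RuntimeError(f"HSS root finding failed: {msg}")
        ep, eep = sol
        st = SignalingState.uniform(n_bins, ep, eep, _rga_qss(ep, eep, p),
                                    n2a_qss(ep, eep, p))

    f = reaction_terms(st.Ep[0], st.EEp[0], st.RGa[0], st.N2a[0], p, EGFt)
    res = max(abs(float(x)) for x in f)
    if res > tol:
        raise RuntimeError(f"HSS residual {res:.3g} exceeds tolerance {tol:g}")
    return st


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _periodic_laplacian(u: np.ndarray, dx: float) -> np.ndarray:
    return (np.roll(u, 1) - 2.0 * u + np.roll(u, -1)) / dx ** 2


def simulate_rd(params: SignalingParams,
                grid: MembraneGrid | None = None,
                protocol: StimulusProtocol | None = None,
                t_end: float = 100.0,
                dt: float = 0.01,
                seed: int | None = None,
                noise_on: bool = True,
                n2a_mode: str = "qss",
                record_dt: float | None = 0.5,
                initial_state: SignalingState | None = None,
                lapatinib_from: float | None = None,
                lapatinib_factor: float = 0.05) -> dict[str, Kymograph]:
    """Euler-Maruyama integration of the membrane reaction-diffusion system.

    Returns kymographs for all four species plus the applied EGF field under
    key ``"EGF"``.  Noise (additive white, amplitude ``sigma_noise``) acts on
    the ``Ep`` equation only.  ``n2a_mode`` selects the full slow PTPN2 ODE
    (``"full"``) or its quasi-steady state (``"qss"``, the default used for
    the spatial simulations).  ``lapatinib_from`` emulates pharmacological
    inhibition by scaling the autocatalytic rate ``alpha2`` by
    ``lapatinib_factor`` from that time onward.

    After each step the species are clipped into their conservation box; clip
    events are counted and reported in the kymograph metadata.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    grid = grid or MembraneGrid()
    protocol = protocol or StimulusProtocol(
        [StimulusSegment(0.0, t_end, "none")])
    dx = grid.bin_length
    maxD = max(params.D_Ep, params.D_RGa, params.D_EEp)
    if dt * maxD / dx ** 2 > 0.5:
        raise ValueError(
            f"CFL violation: dt*D/dx^2 = {dt * maxD / dx ** 2:.3g} > 0.5; "
            "reduce dt or coarsen the grid")

    p = params
    angles = grid.bin_centers
    if initial_state is None:
        state = homogeneous_steady_state(p, 0.0, n_bins=grid.n_bins)
    else:
        state = initial_state.copy()
    if n2a_mode == "qss":
        state.N2a = n2a_qss(state.Ep, state.EEp, p)
    elif n2a_mode != "full":
        raise ValueError("n2a_mode must be 'qss' or 'full'")

    rng = np.random.default_rng(seed)
    n_steps = int(round(t_end / dt))
    record_dt = record_dt if record_dt is not None else dt
    stride = max(1, int(round(record_dt / dt)))
    n_rec = n_steps // stride + 1

    recs = {name: np.empty((grid.n_bins, n_rec))
            for name in ("Ep", "EEp", "RGa", "N2a", "EGF")}
    times = np.empty(n_rec)
    clip_events = 0
    sqrt_dt = np.sqrt(dt)

    def record(idx, t, egf):
        times[idx] = t
        recs["Ep"][:, idx] = state.Ep
        recs["EEp"][:, idx] = state.EEp
        recs["RGa"][:, idx] = state.RGa
        recs["N2a"][:, idx] = state.N2a
        recs["EGF"][:, idx] = egf

    record(0, 0.0, protocol.egf(angles, 0.0))
    rec_idx = 1

    for step in range(1, n_steps + 1):
        t = (step - 1) * dt
        egf = protocol.egf(angles, t)
        pp = p
        if lapatinib_from is not None and t >= lapatinib_from:
            pp = replace(p, alpha2=p.alpha2 * lapatinib_factor)
        f1, f2, f3, f4 = reaction_terms(state.Ep, state.EEp, state.RGa,
                                        state.N2a, pp, egf)
        dEp = f1 + p.D_Ep * _periodic_laplacian(state.Ep, dx)
        dEEp = f2 + p.D_EEp * _periodic_laplacian(state.EEp, dx)
        dRGa = f3 + p.D_RGa * _periodic_laplacian(state.RGa, dx)

        state.Ep = state.Ep + dt * dEp
        if noise_on and p.sigma_noise > 0:
            state.Ep = state.Ep + p.sigma_noise * sqrt_dt * rng.standard_normal(
                grid.n_bins)
        state.EEp = state.EEp + dt * dEEp
        state.RGa = state.RGa + dt * dRGa
        if n2a_mode == "full":
            state.N2a = state.N2a + dt * f4
        else:
            state.N2a = n2a_qss(np.clip(state.Ep, 0, None),
                                np.clip(state.EEp, 0, None), p)

        # conservation box: clip and count
        lo_hits = np.count_nonzero(state.Ep < 0) + \
            np.count_nonzero(state.EEp < 0) + \
            np.count_nonzero(state.RGa < 0) + np.count_nonzero(state.N2a < 0)
        state.Ep = np.clip(state.Ep, 0.0, None)
        state.EEp = np.clip(state.EEp, 0.0, None)
        tot = state.Ep + state.EEp
        over = tot > p.Et
        if np.any(over):
            scale = p.Et / tot[over]
            state.Ep[over] *= scale
            state.EEp[over] *= scale
            lo_hits += int(np.count_nonzero(over))
        hi_hits = np.count_nonzero(state.RGa > p.RGt) + \
            np.count_nonzero(state.N2a > p.N2t)
        state.RGa = np.clip(state.RGa, 0.0, p.RGt)
        state.N2a = np.clip(state.N2a, 0.0, p.N2t)
        clip_events += int(lo_hits + hi_hits)

        if not np.all(np.isfinite(state.Ep)):
            raise FloatingPointError(f"NaN/inf encountered at step {step}")

        if step % stride == 0:
            record(rec_idx, step * dt, protocol.egf(angles, step * dt))
            rec_idx += 1

    meta = {"params_hash": p.hash(), "seed": seed, "dt": dt,
            "n2a_mode": n2a_mode, "noise_on": noise_on,
            "clip_events": clip_events,
            "clip_fraction": clip_events / (n_steps * grid.n_bins * 4),
            "Et": p.Et}
    return {name: Kymograph(recs[name][:, :rec_idx], times[:rec_idx],
                            angles, dict(meta, species=name))
            for name in recs}


# ---------------------------------------------------------------------------
# polarization metrics
# ---------------------------------------------------------------------------

def polarization_metrics(kymo: Kymograph,
                         protocol: StimulusProtocol | None = None,
                         threshold_rule: tuple[str, float] = ("range", 0.1),
                         consecutive: int = 3,
                         floor: float = 1e-6,
                         t_stim_end: float | None = None):
    """Polarization index time series and in-silico memory duration.

    The polarization index is ``p(t) = (max_bin - min_bin) / (mean_bin +
    floor)``.  Memory duration is the time from stimulus removal until the
    polarization signal first stays below threshold for ``consecutive``
    samples, where ``threshold_rule = (kind, value)`` selects the signal:
    ``"range"`` thresholds the absolute spatial range ``max_bin - min_bin``
    (robust against the noise floor of the low basal state), ``"index"``
    thresholds ``p(t)`` itself.

    Returns ``(p, memory_duration)``: the duration is ``None`` when the
    protocol has no washout, and ``inf`` when polarization persists to the
    end of the record (memory at least as long as the observation window).
    """
    v = kymo.values
    rng = v.max(axis=0) - v.min(axis=0)
    p_t = rng / (v.mean(axis=0) + floor)
    if t_stim_end is None:
        if protocol is None or not protocol.has_washout():
            return p_t, None
        t_stim_end = protocol.stimulus_end()
    kind, threshold = threshold_rule
    if kind == "range":
        below = rng < threshold
    elif kind == "index":
        below = p_t < threshold
    else:
        raise ValueError("threshold_rule kind must be 'range' or 'index'")
    start = int(np.searchsorted(kymo.times, t_stim_end - 1e-9))
    run = 0
    for i in range(start, len(p_t)):
        run = run + 1 if below[i] else 0
        if run >= consecutive:
            t_relax = kymo.times[i - consecutive + 1]
            return p_t, max(0.0, float(t_relax - t_stim_end))
    return p_t, float("inf")
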