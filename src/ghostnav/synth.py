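"""Ground-truth generators for every analysis input.

Each generator emulates one class of measurement the quantification module
consumes — stimulus protocols, ratiometric fluorescence records around a
20-bin membrane contour, binary mask series, phase-labelled migration
tracks — and ships the ground truth (polarization angle, built-in memory
durations, phase boundaries, generator parameters and seed) needed to score
any estimator.  All generators are deterministic given their seed.

Noise models: multiplicative log-normal for fluorescence intensities,
additive Gaussian white noise for track observation; both configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .motility import MotilityParams, Track, TrackEnsemble, simulate_mou
from .quantify import CellFluorescenceRecord
from .signaling import (GaussianComponent, Kymograph, StimulusProtocol,
                        StimulusSegment)

__all__ = [
    "GroundTruth",
    "make_stimulus_protocol",
    "make_parametric_kymograph",
    "make_fluorescence_record",
    "make_shape_series",
    "make_tracks",
]


@dataclass
class GroundTruth:
    """What the generator actually built, for scoring estimators."""

    polarization_angle: float | None = None
    memory_signaling: float | None = None
    memory_morphology: float | None = None
    memory_migration: float | None = None
    t_stim_start: float | None = None
    t_stim_end: float | None = None
    regime: str | None = None
    seed: int | None = None
    params: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# stimulus protocols
# ---------------------------------------------------------------------------

def make_stimulus_protocol(template: str = "single_gradient_1h",
                           amplitude: float = 0.1,
                           width: float = 0.5,
                           center: float = np.pi,
                           amplitude_ratio: float = 0.5,
                           t_total: float | None = None
                           ) -> StimulusProtocol:
    """Named stimulus protocols of the gradient experiments.

    ``single_gradient_1h``: 5 min baseline, 60 min gradient, washout.
    ``migration_5h``: 5 h gradient (continuous directed-migration assay).
    ``triple_field``: dynamic gradient, 30 min interruption, same-direction
    static gradient, 30 min interruption, opposite-direction dynamic
    gradient (direction of the third segment = first + pi).
    ``opposing_gradients``: two simultaneous wrapped Gaussians from
    opposite sides with amplitude ratio ``amplitude_ratio``.
    """
    g = lambda a=amplitude, w=width, c=center: [GaussianComponent(a, w, c)]
    if template == "single_gradient_1h":
        T = t_total or 300.0
        return StimulusProtocol([
            StimulusSegment(0, 5, "none"),
            StimulusSegment(5, 65, "gaussian_gradient", components=g()),
            StimulusSegment(65, T, "none")])
    if template == "migration_5h":
        T = t_total or 305.0
        return StimulusProtocol([
            StimulusSegment(0, 5, "none"),
            StimulusSegment(5, T, "gaussian_gradient", components=g())])
    if template == "triple_field":
        T = t_total or 425.0
        dyn = [GaussianComponent((0.0, amplitude), (1.0, width), center)]
        opp = [GaussianComponent((0.0, amplitude), (1.0, width),
                                 (center + np.pi) % (2 * np.pi))]
        return StimulusProtocol([
            StimulusSegment(0, 5, "none"),
            StimulusSegment(5, 65, "gaussian_gradient", components=dyn),
            StimulusSegment(65, 95, "none"),
            StimulusSegment(95, 155, "gaussian_gradient", components=g()),
            StimulusSegment(155, 185, "none"),
            StimulusSegment(185, 245, "gaussian_gradient", components=opp),
            StimulusSegment(245, T, "none")])
    if template == "opposing_gradients":
        T = t_total or 300.0
        comps = [GaussianComponent(amplitude, width, center),
                 GaussianComponent(amplitude * amplitude_ratio, width,
                                   (center + np.pi) % (2 * np.pi))]
        return StimulusProtocol([
            StimulusSegment(0, 5, "none"),
            StimulusSegment(5, 65, "gaussian_gradient", components=comps),
            StimulusSegment(65, T, "none")])
    raise ValueError(f"unknown protocol template {template!r}")


# ---------------------------------------------------------------------------
# parametric kymographs and fluorescence records
# ---------------------------------------------------------------------------

def make_parametric_kymograph(memory_min: float = 40.0,
                              t_stim_start: float = 5.0,
                              t_stim_end: float = 65.0,
                              t_total: float = 185.0,
                              dt: float = 1.0,
                              n_bins: int = 20,
                              angle: float = np.pi,
                              lobe_width: float = 0.7,
                              baseline: float = 0.05,
                              peak: float = 0.6,
                              noise: float = 0.0,
                              seed: int | None = None
                              ) -> tuple[Kymograph, GroundTruth]:
    """Kymograph with signal-locked polarization and a memory plateau.

    During the stimulus a wrapped-Gaussian activity lobe rises at
    ``angle``; after stimulus end the lobe persists at full amplitude for
    ``memory_min`` minutes (the plateau) and then collapses to baseline
    within ~2 samples.  Additive Gaussian noise of s.d. ``noise * peak``
    may be superposed.
    """
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, t_total + dt / 2, dt)
    angles = (np.arange(n_bins) + 0.5) * 2 * np.pi / n_bins
    d = np.angle(np.exp(1j * (angles - angle)))
    lobe = np.exp(-0.5 * (d / lobe_width) ** 2)
    amp = np.zeros_like(times)
    rise = 2.0  # min, activation delay on stimulus onset
    for i, t in enumerate(times):
        if t_stim_start <= t <= t_stim_end:
            amp[i] = min(1.0, (t - t_stim_start) / rise)
        elif t_stim_end < t <= t_stim_end + memory_min:
            amp[i] = 1.0
        elif t > t_stim_end + memory_min:
            amp[i] = np.exp(-(t - t_stim_end - memory_min) / 1.0)
    values = baseline + (peak - baseline) * lobe[:, None] * amp[None, :]
    if noise > 0:
        values = values + rng.normal(0, noise * peak, values.shape)
        values = np.clip(values, 0, None)
    ky = Kymograph(values, times, angles,
                   {"species": "EGFRp_synthetic", "seed": seed})
    gt = GroundTruth(polarization_angle=angle, memory_signaling=memory_min,
                     t_stim_start=t_stim_start, t_stim_end=t_stim_end,
                     seed=seed, params={"peak": peak, "baseline": baseline,
                                        "lobe_width": lobe_width,
                                        "noise": noise})
    return ky, gt


def make_fluorescence_record(kymo: Kymograph,
                             noise_level: float = 0.0,
                             seed: int | None = None,
                             ptb_total: float = 1000.0,
                             egfr_total: float = 800.0,
                             endo_frac: float = 0.10,
                             membrane_frac: float = 0.4,
                             egf_profile: np.ndarray | None = None
                             ) -> tuple[CellFluorescenceRecord, GroundTruth]:
    """Fluorescence channels whose ratio reproduces the input kymograph.

    Channels are constructed so that the per-bin ratio
    ``(PTB_i/(PTB_T - PTB_endo)) / (EGFR_i/EGFR_T)`` returns the input
    field exactly at zero noise; multiplicative log-normal noise of scale
    ``noise_level`` emulates shot/detection variability.  A constant
    ``endo_frac`` of the reporter sits on endosomes and is subtracted by
    the analysis; receptor distributes uniformly over the membrane bins.
    """
    rng = np.random.default_rng(seed)
    values = np.asarray(kymo.values, dtype=float)
    n_bins, n_t = values.shape
    ptb_t = np.full(n_t, ptb_total)
    ptb_endo = endo_frac * ptb_t
    egfr_t = np.full(n_t, egfr_total)
    egfr_pm = np.full((n_bins, n_t),
                      membrane_frac * egfr_total / n_bins)
    # invert the ratio definition: PTB_i = EGFRp_i * (EGFR_i/EGFR_T) * (PTB_T - PTB_endo)
    ptb_pm = values * (egfr_pm / egfr_t) * (ptb_t - ptb_endo)
    if noise_level > 0:
        ptb_pm = ptb_pm * rng.lognormal(0.0, noise_level, ptb_pm.shape)
        egfr_pm = egfr_pm * rng.lognormal(0.0, noise_level, egfr_pm.shape)
    egf_pm = None
    if egf_profile is not None:
        egf_pm = np.tile(np.asarray(egf_profile, dtype=float)[:, None],
                         (1, n_t))
        if noise_level > 0:
            egf_pm = egf_pm * rng.lognormal(0.0, noise_level, egf_pm.shape)
    rec = CellFluorescenceRecord(kymo.times, ptb_pm, egfr_pm, ptb_t,
                                 egfr_t, ptb_endo, egf_pm,
                                 meta={"seed": seed,
                                       "noise_level": noise_level})
    gt = GroundTruth(seed=seed, params={"noise_level": noise_level,
                                        "endo_frac": endo_frac})
    return rec, gt


# ---------------------------------------------------------------------------
# mask series
# ---------------------------------------------------------------------------

def make_shape_series(mode: str = "polarized_blob",
                      memory_min: float = 40.0,
                      seed: int | None = None,
                      t_stim_start: float = 5.0,
                      t_stim_end: float = 65.0,
                      t_total: float = 185.0,
                      dt: float = 1.0,
                      R: float = 2.0,
                      lobe_angle: float = np.pi,
                      lobe_amp: float = 2.0,
                      lobe_width: float = 0.15,
                      pixel_size: float = 0.1,
                      noise: float = 0.0,
                      pad_um: float = 3.0
                      ) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Binary mask series of a circle growing a directed protrusion lobe.

    ``circle`` keeps a static disc; ``polarized_blob`` adds a cosine-lobed
    protrusion toward ``lobe_angle`` whose amplitude follows the stimulus
    and persists for ``memory_min`` after washout before relaxing.
    Returns ``(masks, times, ground_truth)`` with masks shaped
    (n_times, ny, nx).
    """
    if mode not in ("circle", "polarized_blob"):
        raise ValueError("mode must be 'circle' or 'polarized_blob'")
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, t_total + dt / 2, dt)
    half = R + lobe_amp + pad_um
    n = int(round(2 * half / pixel_size)) + 1
    ax = np.linspace(-half, half, n)
    X, Y = np.meshgrid(ax, ax)
    theta = np.arctan2(Y, X)
    rad = np.hypot(X, Y)
    masks = np.empty((len(times), n, n), dtype=bool)
    tau_relax = 3.0
    for i, t in enumerate(times):
        if mode == "circle":
            amp = 0.0
        elif t < t_stim_start:
            amp = 0.0
        elif t <= t_stim_end:
            # cells elongate progressively over the whole gradient hour,
            # reaching maximal deformation around washout
            amp = (t - t_stim_start) / (t_stim_end - t_stim_start)
        elif t <= t_stim_end + memory_min:
            amp = 1.0
        else:
            amp = np.exp(-(t - t_stim_end - memory_min) / tau_relax)
        d = np.angle(np.exp(1j * (theta - lobe_angle)))
        r_b = R + lobe_amp * amp * np.exp(-0.5 * (d / lobe_width) ** 2)
        if noise > 0:
            r_b = r_b + rng.normal(0, noise, r_b.shape) * pixel_size
        masks[i] = rad <= r_b
    gt = GroundTruth(polarization_angle=lobe_angle,
                     memory_morphology=(memory_min
                                        if mode == "polarized_blob" else 0.0),
                     t_stim_start=t_stim_start, t_stim_end=t_stim_end,
                     seed=seed,
                     params={"mode": mode, "pixel_size": pixel_size,
                             "lobe_amp": lobe_amp, "R": R})
    return masks, times, gt


# ---------------------------------------------------------------------------
# tracks
# ---------------------------------------------------------------------------

def make_tracks(phases: list[tuple[float, MotilityParams]],
                n: int = 100, seed: int | None = None
                ) -> tuple[TrackEnsemble, GroundTruth]:
    """Concatenated mOU segments with continuous velocity across switches.

    ``phases`` is a list of ``(duration_min, MotilityParams)``; tracks are
    labelled per phase (``phase0``, ``phase1``, ...) and the ensemble's
    ground truth records the phase boundaries.  The velocity state carries
    over between phases, so switching the bias on/off does not reset the
    walk.
    """
    if not phases:
        raise ValueError("need at least one phase")
    rng = np.random.default_rng(seed)
    dt = phases[0][1].dt
    labels: list[np.ndarray] = []
    t_offset = 0.0
    xy = None
    v_carry = None
    boundaries = [0.0]
    for k, (dur, par) in enumerate(phases):
        if par.dt != dt:
            raise ValueError("all phases must share the sampling interval")
        par_k = MotilityParams(**{**par.__dict__, "duration": dur})
        sub_seed = int(rng.integers(0, 2 ** 31 - 1))
        ens = simulate_mou(par_k, n, seed=sub_seed, v0=v_carry)
        v_carry = ens.provenance["v_final"]     # velocity continuity
        pos = ens.positions_array()             # (n, m, 2)
        if xy is None:
            xy = pos
            n_new = pos.shape[1]
        else:
            xy = np.concatenate([xy, xy[:, -1:, :] + pos[:, 1:, :]], axis=1)
            n_new = pos.shape[1] - 1
        labels.append(np.repeat(f"phase{k}", n_new))
        t_offset += dur
        boundaries.append(t_offset)
    t = np.arange(xy.shape[1]) * dt
    phase = np.concatenate(labels)
    tracks = [Track(i, t, xy[i], phase.copy()) for i in range(n)]
    ens = TrackEnsemble(tracks, dt, {"seed": seed,
                                     "boundaries": boundaries})
    mem = None
    # migration memory ground truth: duration of the biased phase(s) after
    # the first unbiased->biased...->unbiased transition pattern, if the
    # phase list encodes gradient/memory/random phases
    biased = [k for k, (_, par) in enumerate(phases) if par.bias != 0]
    if biased:
        last_biased = biased[-1]
        mem = boundaries[last_biased + 1] - boundaries[last_biased] \
            if last_biased >= 1 else None
    gt = GroundTruth(memory_migration=mem, seed=seed,
                     params={"boundaries": boundaries,
                             "n": n, "dt": dt})
    return ens, gt
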