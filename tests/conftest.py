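import numpy as np
import pytest

from ghostnav.signaling import (GaussianComponent, MembraneGrid,
                                SignalingParams, StimulusProtocol,
                                StimulusSegment, simulate_rd)


@pytest.fixture(scope="session")
def default_params():
    return SignalingParams()


@pytest.fixture(scope="session")
def grid():
    return MembraneGrid()


def gradient_protocol(t_total=300.0, amplitude=0.1, width=0.5,
                      center=np.pi):
    """Standard 1-h gradient experiment: 5 min baseline, 60 min gradient,
    washout until t_total."""
    return StimulusProtocol([
        StimulusSegment(0, 5, "none"),
        StimulusSegment(5, 65, "gaussian_gradient",
                        components=[GaussianComponent(amplitude, width,
                                                      center)]),
        StimulusSegment(65, t_total, "none")])


@pytest.fixture(scope="session")
def regime_runs(grid):
    """Fixed-seed stochastic runs of the four receptor-abundance regimes."""
    protocol = gradient_protocol()
    runs = {}
    for Et in (1.1, 1.26, 1.35, 1.85):
        p = SignalingParams(Et=Et)
        runs[Et] = simulate_rd(p, grid, protocol, t_end=300.0, dt=0.01,
                               seed=0, record_dt=1.0)
    return protocol, runs


@pytest.fixture(scope="session")
def bif_diagram(default_params):
    from ghostnav.bifurcation import scan_bifurcation_diagram
    return scan_bifurcation_diagram(default_params, (1.0, 2.0), 1e-3,
                                    ihss_seed_Et=1.30)


@pytest.fixture(scope="session")
def criticality_cell_run(grid):
    """Coupled signaling + mechanics run at criticality under a sustained
    gradient (reduced duration)."""
    from ghostnav.mechanics import MechParams, simulate_cell
    protocol = StimulusProtocol([
        StimulusSegment(0, 5, "none"),
        StimulusSegment(5, 35, "gaussian_gradient",
                        components=[GaussianComponent(0.1, 0.5, np.pi)])])
    kys = simulate_rd(SignalingParams(), grid, protocol, t_end=35.0,
                      dt=0.01, seed=1, record_dt=0.5)
    series = simulate_cell(kys["Ep"], MechParams(), t_end=35.0,
                           extent=(30, 14), keep_masks=True)
    return kys, series
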