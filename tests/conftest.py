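import numpy as np
import pytest

import aortaflow as af
from aortaflow import hemodynamics as hd
from aortaflow import morphometry as mm
from aortaflow import ssm


@pytest.fixture(scope="session")
def small_res() -> af.Resolution:
    """Coarse sweep resolution for fast population-level tests."""
    return af.Resolution(n_samples=12, ascending_rings=40, arch_rings=60,
                         descending_rings=60, branch_rings=20)


@pytest.fixture(scope="session")
def template_geometry() -> af.AortaGeometry:
    """Default-resolution mean-anatomy geometry (~25k surface points)."""
    return af.build_geometry(af.AortaParams(), label="template")


@pytest.fixture(scope="session")
def small_population(small_res) -> list[af.AortaGeometry]:
    spec = af.PopulationSpec(n_subjects=8, seed=3)
    return af.sample_population(spec, small_res)


@pytest.fixture(scope="session")
def small_model(small_population) -> ssm.PCAModel:
    return ssm.fit_pca(small_population, n_modes=8)


@pytest.fixture(scope="session")
def healthy_waveform() -> hd.FlowWaveform:
    return hd.default_cardiac_waveform(mean_lmin=5.0)


@pytest.fixture(scope="session")
def calibrated_template(template_geometry, healthy_waveform):
    """Template network with Windkessels calibrated to the default targets."""
    tracts = mm.split_tracts(template_geometry.centerline_tree)
    net = hd.build_network(tracts)
    wk = hd.calibrate_rcr(net, healthy_waveform)
    return net, wk, tracts


@pytest.fixture(scope="session")
def ecmo_runs(calibrated_template, healthy_waveform):
    """Shock-mode template simulations at EF = 0, 4, 6 L/min."""
    _, wk, tracts = calibrated_template
    net = hd.build_network(tracts, with_ecmo_return=True)
    net.windkessels = dict(wk)
    shock = hd.scale_waveform(healthy_waveform, reduction=0.70)
    runs = {}
    for ef in (0.0, 4.0, 6.0):
        cfg = hd.SimulationConfig(ef_lmin=ef, mode="shock")
        runs[ef] = hd.simulate(net, shock, cfg)
    return net, runs
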