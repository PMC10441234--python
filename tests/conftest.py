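import pytest
from hypothesis import HealthCheck, settings

import meripchip as mc

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_design():
    """200-transcript design with 4+4 spikes; includes the validated ids."""
    return mc.default_design(n_mrna=200, n_spike_pos=4, n_spike_neg=4)


@pytest.fixture(scope="session")
def noisefree(small_design):
    cfg = mc.SimConfig(
        n_transcripts=200, n_hyper=20, n_hypo=20, n_up=20, n_down=20,
        noise_sd=0.0, seed=11,
    )
    ip, sup, truth = mc.simulate_experiment(small_design, cfg)
    return ip, sup, truth, cfg


@pytest.fixture(scope="session")
def noisy(small_design):
    cfg = mc.SimConfig(
        n_transcripts=200, n_hyper=20, n_hypo=20, n_up=20, n_down=20,
        noise_sd=0.25, seed=12,
    )
    ip, sup, truth = mc.simulate_experiment(small_design, cfg)
    return ip, sup, truth, cfg


@pytest.fixture(scope="session")
def sim_dir(tmp_path_factory):
    """A complete simulated fixture directory (design, channels, truth,
    toy GMT, qPCR table, manifest)."""
    out = tmp_path_factory.mktemp("sim")
    cfg = mc.SimConfig(
        n_transcripts=300, n_hyper=30, n_hypo=30, n_up=30, n_down=30, seed=7
    )
    manifest = mc.simulate_command(out, cfg)
    return out, cfg, manifest
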