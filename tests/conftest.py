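import numpy as np
import pandas as pd
import pytest

from dgsomi import synth


@pytest.fixture(scope="session")
def expert_session():
    """Default expert study session with ground truth (38 units, 30 laps)."""
    return synth.generate_session(synth.default_expert_config(seed=11))


@pytest.fixture(scope="session")
def nonexpert_session():
    return synth.generate_session(synth.default_nonexpert_config(seed=12))


@pytest.fixture(scope="session")
def small_session():
    """A lean session for I/O and pipeline plumbing tests: 6 units, 12 laps,
    short light protocol."""
    cfg = synth.SynthConfig(
        n_laps=12,
        units=[
            synth.UnitSpec(unit_class="WI", baseline_rate_hz=8.0,
                           reward_modulation=synth.RewardModulation(
                               "predictive", "gaussian", 3.0, -0.3, 0.5),
                           opto=synth.OptoSpec(is_chr2=True, latency_ms=2.0)),
            synth.UnitSpec(unit_class="WI", baseline_rate_hz=8.0,
                           reward_modulation=synth.RewardModulation(
                               "consumption", "gaussian", 3.0, 1.2, 0.4),
                           opto=synth.OptoSpec(is_chr2=True, latency_ms=3.0)),
            synth.UnitSpec(unit_class="PC", baseline_rate_hz=4.0,
                           opto=synth.OptoSpec(is_inhibited=True)),
            synth.UnitSpec(unit_class="PC", baseline_rate_hz=4.0),
            synth.UnitSpec(unit_class="FSI", baseline_rate_hz=15.0),
            synth.UnitSpec(unit_class="WI", baseline_rate_hz=6.0),
        ],
        synapses=[synth.SynapseSpec(pre_id=3, post_id=0, efficacy=0.3,
                                    latency_ms=2.0)],
        n_pulses_dg=40,
        n_pulses_fimbria=40,
        seed=7,
    )
    return synth.generate_session(cfg)


def poisson_train(rate_hz: float, duration_s: float, rng) -> np.ndarray:
    """Homogeneous Poisson spike train (test helper)."""
    n = rng.poisson(rate_hz * duration_s)
    return np.sort(rng.uniform(0.0, duration_s, n))
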