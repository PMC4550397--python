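import numpy as np
import pytest

from discorient.cues import compute_cues
from discorient.simulate import BehaviorModel, SimConfig, simulate_study
from discorient.workflow import process_study


@pytest.fixture(scope="session")
def mixed_study():
    """One synthetic study with all four behavior strategies.

    40 deployments per species: a sun-compass follower (offset 0), a
    southward fixed-bearing keeper (188 deg, echoing the one cardinally
    oriented species), a chamber-locked larva under forced rotation, and a
    non-directional larva.
    """
    cfg = SimConfig(seed=1234)
    behaviors = {
        "sunfollower": (40, BehaviorModel("sun_compass", param=0.0, kappa=2.0)),
        "southkeeper": (40, BehaviorModel("fixed_bearing", param=188.0, kappa=3.0)),
        "spinner": (40, BehaviorModel("chamber_locked", param=90.0, kappa=4.0)),
        "wanderer": (40, BehaviorModel("uniform_random", kappa=0.0)),
    }
    return simulate_study(replace_rotation(cfg), behaviors)


def replace_rotation(cfg: SimConfig) -> SimConfig:
    # enough chamber rotation that the artifact screen can see spinners
    from dataclasses import replace

    return replace(cfg, heading_drift=1.5)


@pytest.fixture(scope="session")
def mixed_results(mixed_study):
    """Within-run results + cue table for the mixed study."""
    table, log = process_study(mixed_study["tracks"], mixed_study["deployments"])
    cues = compute_cues(mixed_study["deployments"], mixed_study["coastline"])
    return {"results": table, "cues": cues, "log": log, "truth": mixed_study["truth"]}


@pytest.fixture()
def rng():
    return np.random.default_rng(99)
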