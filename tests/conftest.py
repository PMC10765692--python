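"""Shared fixtures: a mini two-region dataset for fast unit tests and a
session-scoped full national default run (all four scenarios) for the
behavioral checks."""
from __future__ import annotations

import pytest

from fcbs import carbon_dynamics as cd
from fcbs import forest_state as fs
from fcbs import scenario as sc
from fcbs import synthetic as syn

DEFAULT_SEED = 1


@pytest.fixture(scope="session")
def params():
    return cd.default_params()


@pytest.fixture(scope="session")
def mini_cfg():
    return syn.mini_config()


@pytest.fixture(scope="session")
def mini_curves(mini_cfg):
    return syn.generate_yield_curves(mini_cfg)


@pytest.fixture(scope="session")
def mini_inventory(mini_cfg):
    return syn.generate_inventory(mini_cfg, seed=DEFAULT_SEED)


@pytest.fixture(scope="session")
def mini_obs(mini_cfg):
    return syn.generate_observed_harvest(mini_cfg, seed=DEFAULT_SEED)


@pytest.fixture(scope="session")
def mini_spun(mini_inventory, mini_curves):
    stand, regions = mini_inventory
    state = fs.load_inventory(stand, regions)
    return fs.spinup_dom(state, mini_curves)


@pytest.fixture()
def mini_state(mini_spun):
    """Fresh copy safe to mutate."""
    return mini_spun.copy()


@pytest.fixture(scope="session")
def mini_runs(mini_spun, mini_curves, mini_obs):
    """All four scenarios on the mini dataset."""
    return {
        name: sc.run_scenario(mini_spun, mk(), mini_curves, mini_obs,
                              seed=DEFAULT_SEED)
        for name, mk in sc.SCENARIOS.items()
    }


@pytest.fixture(scope="session")
def default_dataset():
    cfg = syn.SynthConfig()
    curves = syn.generate_yield_curves(cfg)
    stand, regions = syn.generate_inventory(cfg, seed=DEFAULT_SEED)
    obs = syn.generate_observed_harvest(cfg, seed=DEFAULT_SEED)
    state = fs.spinup_dom(fs.load_inventory(stand, regions), curves)
    return {"cfg": cfg, "curves": curves, "stand": stand, "regions": regions,
            "obs": obs, "state": state}


@pytest.fixture(scope="session")
def default_runs(default_dataset):
    """All four scenarios on the seeded default national dataset."""
    d = default_dataset
    return {
        name: sc.run_scenario(d["state"], mk(), d["curves"], d["obs"],
                              seed=DEFAULT_SEED)
        for name, mk in sc.SCENARIOS.items()
    }
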