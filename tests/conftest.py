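"""Shared fixtures: desk-scale scenario ensembles computed once per session.

The scaled runs use scale 0.1 (3.6-Mb chain, 360 monomers, 12 barriers) with
200 sampled conformations each; they take tens of seconds apiece, so every
test that needs one shares these session-scoped fixtures.
"""

import numpy as np
import pytest

import loopsim as ls

SCALE = 0.1
N_SAMPLES = 200


def _run(name, seed=101, barriers_override=None):
    sc = ls.scenario(name, SCALE, seed=seed)
    barriers = sc.barriers if barriers_override is None else barriers_override
    ens = ls.run_coupled(
        sc.config, barriers, sc.forcefield, sc.schedule, seed=seed,
        n_samples=N_SAMPLES,
    )
    return sc, ens


# The heavily compared conditions (WT, ΔCTCF, barrier-free control) are run
# as three replicate seeds each and pooled: the contact-probability tail and
# insulation profiles carry slow chain-scale fluctuations that single runs
# cannot average out.
REPLICATE_SEEDS = (101, 102, 103)


def _pool(runs):
    sc = runs[0][0]
    coords = np.concatenate([ens.coordinates for _, ens in runs])
    return sc, ls.Ensemble(coordinates=coords, monomer_size=sc.config.site_size)


@pytest.fixture(scope="session")
def wt_runs():
    return [_run("wt", seed=s) for s in REPLICATE_SEEDS]


@pytest.fixture(scope="session")
def wt_scaled(wt_runs):
    return wt_runs[0]


@pytest.fixture(scope="session")
def wt_pooled(wt_runs):
    return _pool(wt_runs)


@pytest.fixture(scope="session")
def dctcf_pooled():
    return _pool([_run("dctcf", seed=s) for s in REPLICATE_SEEDS])


@pytest.fixture(scope="session")
def control_pooled():
    """WT LEF parameters with no barriers: the TAD-free baseline."""
    return _pool(
        [_run("wt", seed=s, barriers_override=[]) for s in REPLICATE_SEEDS]
    )


@pytest.fixture(scope="session")
def dcohesin_scaled():
    return _run("dcohesin", seed=101)


@pytest.fixture(scope="session")
def dwapl_scaled():
    return _run("dwapl", seed=101)


@pytest.fixture(scope="session")
def wt_map(wt_pooled):
    return ls.aggregate_contact_map(wt_pooled[1])


@pytest.fixture(scope="session")
def dctcf_map(dctcf_pooled):
    return ls.aggregate_contact_map(dctcf_pooled[1])


@pytest.fixture(scope="session")
def dwapl_map(dwapl_scaled):
    return ls.aggregate_contact_map(dwapl_scaled[1])


@pytest.fixture(scope="session")
def control_map(control_pooled):
    return ls.aggregate_contact_map(control_pooled[1])


@pytest.fixture(scope="session")
def ideal_chain_ensemble():
    """Unconfined, repulsion-free chains: exact ideal-chain statistics.

    Random-walk initial conformations are already ideal; a short integration
    keeps them so while decorrelating local detail.
    """
    ff = ls.ForceField(repulsion_strength=0.0, confinement_density=0.0)
    rng = np.random.default_rng(900)
    n, n_conf = 360, 300
    coords = np.empty((n_conf, n, 3))
    for k in range(n_conf):
        conf = ls.init_conformation(n, "random_walk", rng)
        coords[k] = ls.integrate(conf, ff, n_steps=500, rng=rng).coordinates
    return ls.Ensemble(coordinates=coords, monomer_size=10.0, seed=900,
                       forcefield=ff)


@pytest.fixture(scope="session")
def no_lef_ensembles():
    """A zero-LEF coupled run and an equivalent plain (uncoupled) run."""
    cfg = ls.build_config(10.0, 120, 1e9, 20.0, 200.0, seed=50)
    assert cfg.n_lefs == 0
    sched = ls.CouplingSchedule(steps_per_1d=250, equilibration_1d_steps=200,
                                sample_every_1d_steps=10)
    coupled = ls.run_coupled(cfg, [], schedule=sched, seed=50, n_samples=80)
    ff = ls.ForceField()
    rng = np.random.default_rng(51)
    conf = ls.init_conformation(120, "random_walk", rng)
    conf = ls.integrate(conf, ff, n_steps=200 * 250, rng=rng)
    coords = np.empty((80, 120, 3))
    for k in range(80):
        conf = ls.integrate(conf, ff, n_steps=10 * 250, rng=rng)
        coords[k] = conf.coordinates
    plain = ls.Ensemble(coordinates=coords, monomer_size=10.0, seed=51)
    return coupled, plain
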