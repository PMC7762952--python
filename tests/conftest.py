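import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import phimap as pm
from phimap.io import load_packaged_table, records_from_frame

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def constants():
    return pm.DEFAULT_CONSTANTS


@pytest.fixture(scope="session")
def table2():
    return load_packaged_table("table2")


@pytest.fixture(scope="session")
def table2_records(table2):
    return {r.complex_id: r for r in records_from_frame(table2)}


@pytest.fixture(scope="session")
def wt_cambrian(table2_records):
    return table2_records["cambrian_pWT_ML"]


@pytest.fixture(scope="session")
def toy_dimer():
    return pm.make_toy_dimer()


@pytest.fixture(scope="session")
def dimer_registry(toy_dimer):
    return pm.native_contacts(toy_dimer)


@pytest.fixture(scope="session")
def go_model(toy_dimer):
    return pm.build_go_model(toy_dimer)


@pytest.fixture(scope="session")
def two_state_truth():
    return pm.RateParameters(kon=30.4, koff=24.7)


@pytest.fixture(scope="session")
def two_state_traces(two_state_truth):
    """Noiseless preprocessed two-state concentration series."""
    spec = pm.TraceSpec(rates=two_state_truth, n_points=200,
                        ligand_series=(1.0, 2.0, 4.0, 6.0, 8.0, 10.0))
    traces, truth = pm.make_traces(spec)
    pre = pm.TraceSet([pm.preprocess(t) for t in traces])
    return pre, truth


@pytest.fixture(scope="session")
def unrestrained_control(go_model, toy_dimer):
    """Constant low-temperature (native-state) reference run."""
    sched = pm.AnnealingSchedule(
        n_cycles=40, steps_per_cycle=150, T_high=278.0, collect_fraction=0.5
    )
    traj = pm.anneal(go_model, [], sched, pm.SamplerConfig(seed=1))
    return pm.collect_ts(traj, sched)


@pytest.fixture(scope="session")
def restrained_run(go_model, toy_dimer, dimer_registry):
    """Annealing with uniform phi = 0.5 targets on two-contact residues."""
    counts = {
        r: sum(len(v) for k, v in dimer_registry.registry.items() if r in k)
        for r in toy_dimer.residues
    }
    restrained = [r for r, c in counts.items() if c == 2]
    restraints = [pm.PhiRestraint(residue=r, target=0.5) for r in restrained]
    sched = pm.AnnealingSchedule(n_cycles=200, steps_per_cycle=150,
                                 collect_fraction=0.75)
    traj = pm.anneal(go_model, restraints, sched, pm.SamplerConfig(seed=2))
    return pm.collect_ts(traj, sched), restrained


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
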