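import numpy as np
import pytest

import episeek as ek


def make_agents(n, seed, **kwargs):
    """Agents with distinct RNG streams and identical policy parameters."""
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % 2 ** 31) for s in ss.spawn(n)]
    return [ek.AgentSpec(participant_id=i + 1, seed=seeds[i], **kwargs)
            for i in range(n)]


@pytest.fixture(scope="session")
def standard_schedule():
    return ek.make_schedule(8, 100, ek.default_trajectories(), seed=1)


@pytest.fixture(scope="session")
def episodic_cohort():
    """43 heterogeneous episodic-policy agents, full 800-trial sessions."""
    agents = ek.sample_agents(43, seed=11)
    return ek.simulate_cohort(agents, "episodic", seed=12)


@pytest.fixture(scope="session")
def episodic_aggregates(episodic_cohort):
    return ek.aggregate_by_trajectory(episodic_cohort)


@pytest.fixture(scope="session")
def iid_cohort():
    """Constant-policy agents: requests independent of everything."""
    agents = make_agents(15, 21, trait_rate=0.3, episodic_weight=0.0)
    return ek.simulate_cohort(agents, "constant", seed=22)
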