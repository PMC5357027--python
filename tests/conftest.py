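"""Shared fixtures: small sealed chains built from synthetic workloads.

Chains are expensive enough to build (every transaction is signed and
verified) that the standard ones are session-scoped; tests that mutate a
chain must copy it first (`copy_chain`).
"""

from __future__ import annotations

import copy

import pytest

from trialchain.ledger import Chain
from trialchain.workload import WorkloadSpec, generate_workload, run_workload


def copy_chain(chain: Chain) -> Chain:
    return Chain(copy.deepcopy(chain.genesis_config), copy.deepcopy(chain.blocks))


@pytest.fixture(scope="session")
def seed1_workload():
    # 1 regulator deploy + CTA + trial creation + protocol deposition
    # + 10 enrolments + 50 measurements = 64 calls
    return generate_workload(
        WorkloadSpec(seed=1, n_trials=1, n_subjects_per_trial=10, n_measurements_per_subject=5)
    )


@pytest.fixture(scope="session")
def seed1_run(seed1_workload):
    return run_workload(seed1_workload)


@pytest.fixture(scope="session")
def adversarial_run():
    # >= 200 events with a fifth of the enrolment/measurement load violating
    spec = WorkloadSpec(
        seed=7,
        n_trials=1,
        n_subjects_per_trial=20,
        n_measurements_per_subject=8,
        adversarial_fraction=0.2,
    )
    return run_workload(generate_workload(spec))
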