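"""Contract-engine permissioning rules, atomicity and immutability."""

import json

import pytest

from trialchain.contracts import WorldState, apply_call, contract_address, summarize
from trialchain.identity import generate_identity, registry_entry
from trialchain.ledger import make_call, sign_transaction, state_at
from trialchain.workload import ACCEPT

REG = generate_identity("reg", "regulator", seed=b"\x51" * 32)
REG2 = generate_identity("reg2", "regulator", seed=b"\x52" * 32)
CRO = generate_identity("cro", "cro", seed=b"\x53" * 32)
CRO2 = generate_identity("cro2", "cro", seed=b"\x54" * 32)
REGISTRY = {
    i.address: registry_entry(i) for i in (REG, REG2, CRO, CRO2)
}

T0 = 1_600_000_000
DAY = 86_400
REC_START, REC_END = T0 + 4 * DAY, T0 + 8 * DAY
TRIAL_END = T0 + 20 * DAY
DOC_HASH = "ab" * 32
ENDPOINTS = [
    {"name": "time_to_alleviation_of_symptoms", "type": "primary", "definition": "hours"}
]


def call(identity, nonce, target, function, args, time=T0):
    return sign_transaction(identity, nonce, make_call(target, function, args), time)


@pytest.fixture()
def state():
    return WorldState()


def deploy(state, identity=REG, nonce=1):
    result = apply_call(state, call(identity, nonce, "DEPLOY", "deploy_regulator", {}), T0, REGISTRY)
    assert result.ok
    return result.value


def register(state, reg_addr, trial_id="T001", cro=CRO, nonce=2, **overrides):
    args = {
        "trial_id": trial_id,
        "sponsor": "Sponsor",
        "authorised_cro": cro.address,
        "window_start": T0,
        "window_end": T0 + 3 * DAY,
    }
    args.update(overrides)
    return apply_call(state, call(REG, nonce, reg_addr, "register_cta", args), T0, REGISTRY)


def create(state, reg_addr, trial_id="T001", sender=CRO, nonce=1, time=T0 + DAY):
    return apply_call(
        state,
        call(sender, nonce, reg_addr, "create_trial",
             {"trial_id": trial_id, "protocol_document_hash": DOC_HASH}),
        time,
        REGISTRY,
    )


def deposit(state, trial_addr, sender=CRO, nonce=2, **overrides):
    args = {
        "document_hash": DOC_HASH,
        "endpoints": ENDPOINTS,
        "recruitment_start": REC_START,
        "recruitment_end": REC_END,
        "trial_end": TRIAL_END,
    }
    args.update(overrides)
    return apply_call(
        state, call(sender, nonce, trial_addr, "deposit_protocol", args), T0 + 2 * DAY, REGISTRY
    )


def enrol(state, trial_addr, subject_id="S001", nonce=3, time=REC_START, consent="cd" * 32):
    args = {"subject_id": subject_id, "demographics": {"age_band": "18-"}}
    if consent is not None:
        args["consent_hash"] = consent
    return apply_call(
        state, call(CRO, nonce, trial_addr, "add_subject", args), time, REGISTRY
    )


def measure(state, trial_addr, subject_id="S001", nonce=4, time=REC_START + DAY,
            payload='{"value_hours": 97}', encrypted=False):
    return apply_call(
        state,
        call(CRO, nonce, trial_addr, "record_measurement",
             {"subject_id": subject_id, "payload": payload, "encrypted": encrypted}),
        time,
        REGISTRY,
    )


@pytest.fixture()
def trial(state):
    reg_addr = deploy(state)
    assert register(state, reg_addr).ok
    trial_addr = create(state, reg_addr).value
    assert deposit(state, trial_addr).ok
    return reg_addr, trial_addr


class TestDispatch:
    def test_unknown_contract_and_function(self, state):
        reg_addr = deploy(state)
        assert apply_call(state, call(REG, 2, "0" * 40, "register_cta", {}), T0, REGISTRY).code == "NO_CONTRACT"
        assert apply_call(state, call(REG, 2, reg_addr, "no_such_fn", {}), T0, REGISTRY).code == "NO_FUNCTION"
        assert apply_call(state, call(REG, 2, "DEPLOY", "no_such_fn", {}), T0, REGISTRY).code == "NO_FUNCTION"

    def test_failing_call_leaves_state_digest_unchanged(self, trial, state):
        reg_addr, trial_addr = trial
        before = state.digest()
        result = enrol(state, trial_addr, time=REC_END + 1)  # WINDOW_CLOSED
        assert not result.ok
        assert state.digest() == before


class TestRegulatorContract:
    def test_deploy_role_and_distinct_addresses(self, state):
        addr1 = deploy(state, REG, nonce=1)
        addr2 = deploy(state, REG, nonce=2)
        assert addr1 != addr2
        assert state.contracts[addr1]["owner"] == REG.address
        denied = apply_call(
            state, call(CRO, 1, "DEPLOY", "deploy_regulator", {}), T0, REGISTRY
        )
        assert denied.code == "ROLE_FORBIDDEN"

    def test_cta_registration_owner_only_and_duplicates(self, state):
        reg_addr = deploy(state)
        assert register(state, reg_addr).ok
        assert state.contracts[reg_addr]["ctas"]["T001"]["status"] == "approved"
        assert register(state, reg_addr, nonce=3).code == "DUPLICATE_CTA"
        other = apply_call(
            state,
            call(REG2, 1, reg_addr, "register_cta",
                 {"trial_id": "T002", "sponsor": "S", "authorised_cro": CRO.address,
                  "window_start": T0, "window_end": T0 + DAY}),
            T0,
            REGISTRY,
        )
        assert other.code == "OWNER_ONLY"


class TestTrialCreation:
    def test_authorised_cro_creates_and_is_registered(self, state):
        reg_addr = deploy(state)
        assert register(state, reg_addr).ok
        result = create(state, reg_addr)
        assert result.ok
        assert state.contracts[reg_addr]["trials"]["T001"] == result.value
        assert state.contracts[result.value]["owner"] == CRO.address
        assert result.value == contract_address(CRO.address, 1)

    def test_cta_required_wrong_cro_window_duplicate(self, state):
        reg_addr = deploy(state)
        assert create(state, reg_addr).code == "CTA_REQUIRED"
        assert register(state, reg_addr).ok
        assert create(state, reg_addr, sender=CRO2).code == "CRO_MISMATCH"
        assert create(state, reg_addr, time=T0 + 4 * DAY).code == "WINDOW_CLOSED"
        assert create(state, reg_addr).ok
        assert create(state, reg_addr, nonce=2).code == "DUPLICATE_TRIAL"


class TestProtocolDeposition:
    def test_first_deposition_accepted_then_immutable(self, state):
        reg_addr = deploy(state)
        assert register(state, reg_addr).ok
        trial_addr = create(state, reg_addr).value
        assert deposit(state, trial_addr).ok
        switched = deposit(
            state,
            trial_addr,
            nonce=3,
            endpoints=[{"name": "switched_endpoint", "type": "primary", "definition": "post hoc"}],
        )
        assert switched.code == "PROTOCOL_IMMUTABLE"
        assert state.contracts[trial_addr]["protocol"]["endpoints"] == ENDPOINTS

    def test_empty_endpoints_bad_window_and_owner(self, state):
        reg_addr = deploy(state)
        assert register(state, reg_addr).ok
        trial_addr = create(state, reg_addr).value
        assert deposit(state, trial_addr, endpoints=[]).code == "ENDPOINTS_REQUIRED"
        assert deposit(state, trial_addr, recruitment_end=TRIAL_END + 1).code == "BAD_WINDOW"
        assert deposit(state, trial_addr, sender=CRO2, nonce=1).code == "OWNER_ONLY"


class TestEnrolment:
    def test_enrolment_inside_window_increases_count(self, trial, state):
        _, trial_addr = trial
        assert enrol(state, trial_addr).ok
        assert len(state.contracts[trial_addr]["subjects"]) == 1
        assert state.contracts[trial_addr]["subjects"]["S001"]["enrolled_at"] == REC_START

    def test_enrolment_before_protocol_deposition(self, state):
        reg_addr = deploy(state)
        assert register(state, reg_addr).ok
        trial_addr = create(state, reg_addr).value
        assert enrol(state, trial_addr, nonce=2).code == "PROTOCOL_REQUIRED"

    def test_window_boundaries_are_closed_intervals(self, trial, state):
        _, trial_addr = trial
        assert enrol(state, trial_addr, subject_id="A", time=REC_START - 1).code == "WINDOW_CLOSED"
        assert enrol(state, trial_addr, subject_id="B", time=REC_END).ok
        assert enrol(state, trial_addr, subject_id="C", time=REC_END + 1, nonce=4).code == "WINDOW_CLOSED"

    def test_duplicate_subject_and_missing_consent(self, trial, state):
        _, trial_addr = trial
        assert enrol(state, trial_addr).ok
        assert enrol(state, trial_addr, nonce=4).code == "DUPLICATE_SUBJECT"
        assert enrol(state, trial_addr, subject_id="S002", nonce=4, consent=None).code == "CONSENT_REQUIRED"


class TestMeasurements:
    def test_valid_payload_appended_with_block_time(self, trial, state):
        _, trial_addr = trial
        assert enrol(state, trial_addr).ok
        payload = json.dumps({"endpoint": "time_to_symptom_alleviation", "value_h": 97})
        assert measure(state, trial_addr, payload=payload).ok
        measurements = state.contracts[trial_addr]["subjects"]["S001"]["measurements"]
        assert [m["recorded_at"] for m in measurements] == [REC_START + DAY]
        assert measurements[0]["sender"] == CRO.address

    def test_trial_end_boundary_unknown_subject_bad_payload(self, trial, state):
        _, trial_addr = trial
        assert enrol(state, trial_addr).ok
        assert measure(state, trial_addr, time=TRIAL_END).ok
        assert measure(state, trial_addr, nonce=5, time=TRIAL_END + 1).code == "TRIAL_ENDED"
        assert measure(state, trial_addr, subject_id="GHOST", nonce=5).code == "NO_SUBJECT"
        assert measure(state, trial_addr, nonce=5, payload="not-json").code == "BAD_PAYLOAD"
        # an encrypted payload is opaque: parseability is not enforced
        assert measure(state, trial_addr, nonce=5, payload="bm90LWpzb24=", encrypted=True).ok

    def test_measurements_append_only(self, trial, state):
        _, trial_addr = trial
        assert enrol(state, trial_addr).ok
        for visit in range(3):
            assert measure(state, trial_addr, nonce=4 + visit, time=REC_START + (visit + 1) * DAY).ok
        recorded = [
            m["recorded_at"] for m in state.contracts[trial_addr]["subjects"]["S001"]["measurements"]
        ]
        assert recorded == sorted(recorded) and len(recorded) == 3


class TestSummarize:
    def test_empty_state_has_zero_trials(self):
        assert summarize(WorldState()) == {"height": 0, "n_trials": 0, "trials": []}

    def test_workload_counts_match_generation(self, seed1_run):
        """1 trial x 10 subjects x 5 measurements: the summary must count
        exactly what the generator emitted."""
        report = summarize(seed1_run.state)
        assert report["n_trials"] == 1
        (trial,) = report["trials"]
        assert trial["n_subjects"] == 10
        assert all(s["n_measurements"] == 5 for s in trial["subjects"].values())
        assert trial["endpoints"][0] == "time_to_alleviation_of_symptoms"

    def test_subject_counts_non_decreasing_with_height(self, seed1_run):
        previous = 0
        for height in range(seed1_run.chain.height + 1):
            report = summarize(state_at(seed1_run.chain, height))
            count = sum(t["n_subjects"] for t in report["trials"])
            assert count >= previous
            previous = count


class TestReachableStateInvariants:
    def test_no_reachable_state_violates_protocol_rules(self, adversarial_run):
        """Replaying an adversarial workload, every reachable state keeps:
        enrolments inside the window, measurements before trial end, no
        subjects without a protocol."""
        from trialchain.ledger import iter_states

        endpoint_snapshots: dict[str, bytes] = {}
        for _, state in iter_states(adversarial_run.chain):
            for address, contract in state.contracts.items():
                if contract["type"] != "trial":
                    continue
                protocol = contract["protocol"]
                if contract["subjects"]:
                    assert protocol is not None
                for subject in contract["subjects"].values():
                    assert (
                        protocol["recruitment_start"]
                        <= subject["enrolled_at"]
                        <= protocol["recruitment_end"]
                    )
                    for m in subject["measurements"]:
                        assert m["recorded_at"] <= protocol["trial_end"]
                if protocol is not None:
                    frozen = json.dumps(protocol["endpoints"], sort_keys=True).encode()
                    previous = endpoint_snapshots.setdefault(address, frozen)
                    assert previous == frozen  # endpoint immutability across heights
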