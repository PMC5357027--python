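"""Synthetic clinical-trial workload generation and end-to-end execution.

The generator emulates an influenza (oseltamivir-style) trial programme: a
regulator deploys its contract and registers one clinical trial
authorisation per trial; each CRO creates its trial contract, deposits the
protocol (document hash, endpoints, recruitment window, end date), enrols
subjects across the recruitment window, and appends per-visit measurements
of the primary endpoint — hours to alleviation of influenza symptoms,
drawn log-normally — until the trial end date.  Logical time advances in
fixed ticks (one day per tick by default); one block is sealed per tick,
so the same seed always produces a byte-identical chain.

Each generated event carries the outcome the *generator* expects —
``ACCEPT`` or a failure code.  Those expectations come from a small rule
simulation inside this module that is written independently of the
contract engine, so replaying a workload through sealing cross-checks two
implementations of the permissioning rules against each other.  With
``adversarial_fraction > 0`` the generator deliberately injects
rule-violating events (late enrolment, measurement after the trial end,
enrolment before protocol deposition, endpoint re-definition, trial
creation by the wrong CRO), each labelled with the code it must be
rejected with.
"""

from __future__ import annotations

import hashlib
import json
import random
from dataclasses import dataclass, asdict, field

from .contracts import WorldState, contract_address
from .documents import DocumentStore
from .identity import Identity, from_seed, registry_entry
from .crypto import hash_bytes, encryption_keypair
from .ledger import Chain, SealResult, make_call, seal_block, sign_transaction

__all__ = [
    "WorkloadSpec",
    "Workload",
    "SpecError",
    "generate_workload",
    "emulate_paper_run",
    "run_workload",
    "RunResult",
]

ACCEPT = "ACCEPT"

# primary endpoint of the emulated influenza trials
PRIMARY_ENDPOINT = {
    "name": "time_to_alleviation_of_symptoms",
    "type": "primary",
    "definition": "hours from first dose to alleviation of all influenza symptoms",
}
SECONDARY_ENDPOINT = {
    "name": "incidence_of_secondary_complications",
    "type": "secondary",
    "definition": "occurrence of bronchitis, sinusitis, otitis media or pneumonia",
}

# log-normal visit values: median ~90 h to symptom alleviation
_LOGNORMAL_MU = 4.4998
_LOGNORMAL_SIGMA = 0.35

_ADVERSARIAL_KINDS = (
    "late_enrolment",
    "post_end_measurement",
    "pre_protocol_subject",
    "endpoint_redefinition",
    "wrong_cro_create",
)


class SpecError(ValueError):
    """Inconsistent workload specification."""


@dataclass(frozen=True)
class WorkloadSpec:
    """Study conditions for one generated workload.

    Defaults describe a small two-arm influenza programme; the paper-scale
    preset (:func:`emulate_paper_run`) widens them to 2 trials of 50
    subjects with 20 visits each.  ``visit_interval`` is both the visit
    spacing and the logical tick length, in seconds (one day).
    """

    seed: int
    n_trials: int = 1
    n_subjects_per_trial: int = 10
    n_measurements_per_subject: int = 5
    visit_interval: int = 86_400
    adversarial_fraction: float = 0.0
    epoch: int = 1_600_000_000  # workload t0, POSIX seconds

    # schedule (ticks relative to epoch); recruitment spans 5 ticks
    deploy_tick: int = 0
    cta_tick: int = 1
    create_tick: int = 2
    deposit_tick: int = 3
    recruitment_start_tick: int = 4
    recruitment_end_tick: int = 8

    def __post_init__(self):
        if min(self.n_trials, self.n_subjects_per_trial, self.n_measurements_per_subject) < 1:
            raise SpecError("all counts must be positive")
        if not 0.0 <= self.adversarial_fraction <= 1.0:
            raise SpecError("adversarial_fraction must lie in [0, 1]")
        if self.visit_interval < 1:
            raise SpecError("visit_interval must be positive")
        if not (
            self.deploy_tick
            <= self.cta_tick
            <= self.create_tick
            <= self.deposit_tick
            < self.recruitment_start_tick
            < self.recruitment_end_tick
        ):
            raise SpecError("schedule ticks out of order")

    def time_at(self, tick: int) -> int:
        return self.epoch + tick * self.visit_interval

    @property
    def trial_end_tick(self) -> int:
        # last visit of the last-enrolled subject, plus one margin tick
        return self.recruitment_end_tick + self.n_measurements_per_subject + 1

    @property
    def recruitment_window(self) -> tuple[int, int]:
        return self.time_at(self.recruitment_start_tick), self.time_at(self.recruitment_end_tick)

    @property
    def trial_end(self) -> int:
        return self.time_at(self.trial_end_tick)

    @property
    def cta_window(self) -> tuple[int, int]:
        return self.time_at(self.cta_tick), self.time_at(self.deposit_tick)

    def expected_clean_events(self) -> int:
        t, s, m = self.n_trials, self.n_subjects_per_trial, self.n_measurements_per_subject
        return 1 + 3 * t + t * s + t * s * m

    def expected_adversarial_events(self) -> int:
        t, s, m = self.n_trials, self.n_subjects_per_trial, self.n_measurements_per_subject
        return round(self.adversarial_fraction * (t * s + t * s * m))


@dataclass
class Workload:
    header: dict
    identities: list[dict]  # {label, role, seed_hex}
    events: list[dict]
    protocol_documents: dict[str, str]  # trial_id -> document text
    encryption_keys: dict[str, str]  # trial_id -> regulator private key (off-chain)

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "Workload":
        data = json.loads(text)
        return cls(**data)


def _trial_id(index: int) -> str:
    return f"OSLT-{index + 1:03d}"


def _identity_seed(workload_seed: int, label: str) -> bytes:
    return hashlib.sha256(f"identity:{workload_seed}:{label}".encode()).digest()


def _protocol_document(spec: WorkloadSpec, trial_id: str) -> str:
    rs, re_ = spec.recruitment_window
    return (
        f"SYNTHETIC TRIAL PROTOCOL {trial_id}\n"
        f"A randomised synthetic influenza treatment trial (workload seed {spec.seed}).\n"
        f"Primary endpoint: {PRIMARY_ENDPOINT['name']} — {PRIMARY_ENDPOINT['definition']}.\n"
        f"Secondary endpoint: {SECONDARY_ENDPOINT['name']}.\n"
        f"Recruitment window: {rs}..{re_} (POSIX seconds, inclusive).\n"
        f"Trial end: {spec.trial_end}.\n"
        f"Planned enrolment: {spec.n_subjects_per_trial} subjects, "
        f"{spec.n_measurements_per_subject} visits each.\n"
    )


def generate_workload(spec: WorkloadSpec) -> Workload:
    """Deterministically expand a spec into a labelled event stream."""
    rng = random.Random(spec.seed)
    trial_ids = [_trial_id(i) for i in range(spec.n_trials)]

    labels = [("regulator-1", "regulator")]
    labels += [(f"cro-{i + 1}", "cro") for i in range(spec.n_trials)]
    labels.append(("cro-rogue", "cro"))
    identities = [
        {"label": label, "role": role, "seed_hex": _identity_seed(spec.seed, label).hex()}
        for label, role in labels
    ]
    cro_of = {tid: f"cro-{i + 1}" for i, tid in enumerate(trial_ids)}

    documents = {tid: _protocol_document(spec, tid) for tid in trial_ids}
    doc_hashes = {tid: hash_bytes(documents[tid].encode()) for tid in trial_ids}
    encryption_keys: dict[str, str] = {}
    encryption_pubs: dict[str, str] = {}
    for tid in trial_ids:
        seed = hashlib.sha256(f"enckey:{spec.seed}:{tid}".encode()).digest()
        priv, pub = encryption_keypair(seed)
        encryption_keys[tid] = priv
        encryption_pubs[tid] = pub

    events: list[dict] = []

    def emit(tick, sender, target_ref, function, args, adversarial=False, note=""):
        events.append(
            {
                "tick": tick,
                "time": spec.time_at(tick),
                "sender": sender,
                "target_ref": target_ref,
                "function": function,
                "args": args,
                "adversarial": adversarial,
                "note": note,
            }
        )

    emit(spec.deploy_tick, "regulator-1", "DEPLOY", "deploy_regulator", {})
    rs, re_ = spec.recruitment_window
    cw_start, cw_end = spec.cta_window
    for tid in trial_ids:
        emit(
            spec.cta_tick,
            "regulator-1",
            "regulator",
            "register_cta",
            {
                "trial_id": tid,
                "sponsor": "Synthetica Pharma Ltd",
                "authorised_cro": cro_of[tid],  # label; resolved to address at run time
                "window_start": cw_start,
                "window_end": cw_end,
                "encryption_pubkey": encryption_pubs[tid],
            },
        )
    for tid in trial_ids:
        emit(
            spec.create_tick,
            cro_of[tid],
            "regulator",
            "create_trial",
            {"trial_id": tid, "protocol_document_hash": doc_hashes[tid]},
        )
    for tid in trial_ids:
        emit(
            spec.deposit_tick,
            cro_of[tid],
            f"trial:{tid}",
            "deposit_protocol",
            {
                "document_hash": doc_hashes[tid],
                "endpoints": [PRIMARY_ENDPOINT, SECONDARY_ENDPOINT],
                "recruitment_start": rs,
                "recruitment_end": re_,
                "trial_end": spec.trial_end,
            },
        )

    # enrolment spread across the recruitment window, then per-visit data
    rec_span = spec.recruitment_end_tick - spec.recruitment_start_tick + 1
    enrol_tick: dict[tuple[str, str], int] = {}
    for tid in trial_ids:
        for j in range(spec.n_subjects_per_trial):
            subject_id = f"{tid}-S{j + 1:03d}"
            tick = spec.recruitment_start_tick + (j * rec_span) // spec.n_subjects_per_trial
            enrol_tick[(tid, subject_id)] = tick
            emit(
                tick,
                cro_of[tid],
                f"trial:{tid}",
                "add_subject",
                {
                    "subject_id": subject_id,
                    "demographics": {
                        "age_band": f"{18 + 10 * rng.randrange(0, 6)}-",
                        "sex": rng.choice(["F", "M"]),
                        "arm": rng.choice(["treatment", "placebo"]),
                    },
                    "consent_hash": hash_bytes(
                        f"consent:{spec.seed}:{tid}:{subject_id}".encode()
                    ),
                },
            )
    for tid in trial_ids:
        for j in range(spec.n_subjects_per_trial):
            subject_id = f"{tid}-S{j + 1:03d}"
            base = enrol_tick[(tid, subject_id)]
            for visit in range(1, spec.n_measurements_per_subject + 1):
                value = round(rng.lognormvariate(_LOGNORMAL_MU, _LOGNORMAL_SIGMA), 1)
                payload = json.dumps(
                    {
                        "subject_id": subject_id,
                        "visit": visit,
                        "endpoint": PRIMARY_ENDPOINT["name"],
                        "value_hours": value,
                    },
                    sort_keys=True,
                )
                emit(
                    base + visit,
                    cro_of[tid],
                    f"trial:{tid}",
                    "record_measurement",
                    {"subject_id": subject_id, "payload": payload, "encrypted": False},
                )

    _inject_adversarial(spec, events, trial_ids, cro_of, doc_hashes, emit)

    events.sort(key=lambda e: e["tick"])  # stable: intra-tick order preserved
    _attach_expectations(events, cro_of)

    header = {
        "seed": spec.seed,
        "spec": {
            "n_trials": spec.n_trials,
            "n_subjects_per_trial": spec.n_subjects_per_trial,
            "n_measurements_per_subject": spec.n_measurements_per_subject,
            "visit_interval": spec.visit_interval,
            "adversarial_fraction": spec.adversarial_fraction,
            "epoch": spec.epoch,
            "recruitment_window": list(spec.recruitment_window),
            "trial_end": spec.trial_end,
        },
        "measurement_distribution": {
            "family": "lognormal",
            "mu": _LOGNORMAL_MU,
            "sigma": _LOGNORMAL_SIGMA,
            "unit": "hours",
        },
        "trial_ids": trial_ids,
        "n_events": len(events),
    }
    return Workload(
        header=header,
        identities=identities,
        events=events,
        protocol_documents=documents,
        encryption_keys=encryption_keys,
    )


def _inject_adversarial(spec, events, trial_ids, cro_of, doc_hashes, emit):
    n_adv = spec.expected_adversarial_events()
    for i in range(n_adv):
        kind = _ADVERSARIAL_KINDS[i % len(_ADVERSARIAL_KINDS)]
        tid = trial_ids[i % len(trial_ids)]
        cro = cro_of[tid]
        if kind == "late_enrolment":
            emit(
                spec.recruitment_end_tick + 1,
                cro,
                f"trial:{tid}",
                "add_subject",
                {
                    "subject_id": f"{tid}-LATE-{i:03d}",
                    "demographics": {"age_band": "38-", "sex": "F", "arm": "treatment"},
                    "consent_hash": hash_bytes(f"consent:late:{spec.seed}:{i}".encode()),
                },
                adversarial=True,
                note=kind,
            )
        elif kind == "post_end_measurement":
            emit(
                spec.trial_end_tick + 1,
                cro,
                f"trial:{tid}",
                "record_measurement",
                {
                    "subject_id": f"{tid}-S001",
                    "payload": json.dumps({"visit": 99, "value_hours": 1.0}),
                    "encrypted": False,
                },
                adversarial=True,
                note=kind,
            )
        elif kind == "pre_protocol_subject":
            emit(
                spec.create_tick,
                cro,
                f"trial:{tid}",
                "add_subject",
                {
                    "subject_id": f"{tid}-EARLY-{i:03d}",
                    "demographics": {"age_band": "28-", "sex": "M", "arm": "placebo"},
                    "consent_hash": hash_bytes(f"consent:early:{spec.seed}:{i}".encode()),
                },
                adversarial=True,
                note=kind,
            )
        elif kind == "endpoint_redefinition":
            rs, re_ = spec.recruitment_window
            emit(
                spec.recruitment_start_tick,
                cro,
                f"trial:{tid}",
                "deposit_protocol",
                {
                    "document_hash": doc_hashes[tid],
                    "endpoints": [
                        {
                            "name": "switched_surrogate_endpoint",
                            "type": "primary",
                            "definition": "post-hoc surrogate outcome",
                        }
                    ],
                    "recruitment_start": rs,
                    "recruitment_end": re_,
                    "trial_end": spec.trial_end,
                },
                adversarial=True,
                note=kind,
            )
        elif kind == "wrong_cro_create":
            emit(
                spec.deposit_tick,
                "cro-rogue",
                "regulator",
                "create_trial",
                {"trial_id": tid, "protocol_document_hash": doc_hashes[tid]},
                adversarial=True,
                note=kind,
            )


def _attach_expectations(events: list[dict], cro_of: dict[str, str]) -> None:
    """Independent rule simulation labelling each event ACCEPT or a code.

    Deliberately re-implements the permissioning rules on a minimal state
    model (no addresses, no hashing, no signatures) so it can serve as a
    cross-implementation oracle against the contract engine.  Check order
    matches the engine's documented order.
    """
    regulator_deployed = False
    ctas: dict[str, dict] = {}
    trials: set[str] = set()
    protocol: dict[str, dict | None] = {}
    subjects: dict[str, set] = {}

    for event in events:
        func, args, time, sender = event["function"], event["args"], event["time"], event["sender"]
        code = None
        if func == "deploy_regulator":
            if not sender.startswith("regulator"):
                code = "ROLE_FORBIDDEN"
            else:
                regulator_deployed = True
        elif func == "register_cta":
            if not regulator_deployed:
                code = "NO_CONTRACT"
            elif not sender.startswith("regulator"):
                code = "OWNER_ONLY"
            elif args["trial_id"] in ctas:
                code = "DUPLICATE_CTA"
            else:
                ctas[args["trial_id"]] = args
        elif func == "create_trial":
            tid = args["trial_id"]
            cta = ctas.get(tid)
            if not regulator_deployed:
                code = "NO_CONTRACT"
            elif cta is None:
                code = "CTA_REQUIRED"
            elif sender != cta["authorised_cro"]:
                code = "CRO_MISMATCH"
            elif not (cta["window_start"] <= time <= cta["window_end"]):
                code = "WINDOW_CLOSED"
            elif tid in trials:
                code = "DUPLICATE_TRIAL"
            else:
                trials.add(tid)
                protocol[tid] = None
                subjects[tid] = set()
        else:
            tid = event["target_ref"].split(":", 1)[1]
            if tid not in trials:
                code = "NO_CONTRACT"
            elif sender != cro_of.get(tid):
                code = "OWNER_ONLY"
            elif func == "deposit_protocol":
                if protocol[tid] is not None:
                    code = "PROTOCOL_IMMUTABLE"
                elif not args["endpoints"]:
                    code = "ENDPOINTS_REQUIRED"
                elif not (
                    args["recruitment_start"] < args["recruitment_end"] <= args["trial_end"]
                ):
                    code = "BAD_WINDOW"
                else:
                    protocol[tid] = args
            elif func == "add_subject":
                proto = protocol[tid]
                if proto is None:
                    code = "PROTOCOL_REQUIRED"
                elif not (proto["recruitment_start"] <= time <= proto["recruitment_end"]):
                    code = "WINDOW_CLOSED"
                elif args["subject_id"] in subjects[tid]:
                    code = "DUPLICATE_SUBJECT"
                elif not args.get("consent_hash"):
                    code = "CONSENT_REQUIRED"
                else:
                    subjects[tid].add(args["subject_id"])
            elif func == "record_measurement":
                proto = protocol[tid]
                if proto is None:
                    code = "PROTOCOL_REQUIRED"
                elif args["subject_id"] not in subjects[tid]:
                    code = "NO_SUBJECT"
                elif time > proto["trial_end"]:
                    code = "TRIAL_ENDED"
                else:
                    try:
                        json.loads(args["payload"])
                    except ValueError:
                        code = "BAD_PAYLOAD"
        event["expect"] = ACCEPT if code is None else code


def emulate_paper_run(seed: int) -> Workload:
    """Paper-scale preset: 2 trials x 50 subjects x 20 visits (2,107 events)."""
    return generate_workload(
        WorkloadSpec(
            seed=seed,
            n_trials=2,
            n_subjects_per_trial=50,
            n_measurements_per_subject=20,
        )
    )


# --- execution --------------------------------------------------------------

@dataclass
class RunResult:
    chain: Chain
    state: WorldState
    identities: dict[str, Identity]
    trial_addresses: dict[str, str]
    regulator_address: str | None
    outcomes: list[tuple[dict, str]]  # (event, actual outcome)
    mismatches: list[tuple[dict, str]]  # events whose actual outcome differed
    seal_results: list[SealResult] = field(default_factory=list)


def run_workload(
    workload: Workload,
    store: DocumentStore | None = None,
    network_id: str = "trialchain-synthetic",
) -> RunResult:
    """Sign, seal and audit-track a generated workload end to end.

    One block is sealed per logical tick; the regulator seals.  Protocol
    documents are deposited into *store* when given, so existence proofs
    can be taken against the resulting chain.
    """
    identities = {
        rec["label"]: from_seed(rec["label"], rec["role"], bytes.fromhex(rec["seed_hex"]))
        for rec in workload.identities
    }
    regulator = next(i for i in identities.values() if i.role == "regulator")
    chain = Chain.create(
        network_id=network_id,
        sealers=[regulator.address],
        identities={i.address: registry_entry(i) for i in identities.values()},
        timestamp=workload.events[0]["time"] if workload.events else workload.header["spec"]["epoch"],
    )
    if store is not None:
        for text in workload.protocol_documents.values():
            store.put(text.encode())

    state = WorldState()
    nonces: dict[str, int] = {}
    contract_refs: dict[str, str] = {}  # "regulator" / "trial:TID" -> address
    outcomes: list[tuple[dict, str]] = []
    mismatches: list[tuple[dict, str]] = []
    seal_results: list[SealResult] = []
    trial_addresses: dict[str, str] = {}

    by_tick: dict[int, list[dict]] = {}
    for event in workload.events:
        by_tick.setdefault(event["tick"], []).append(event)

    for tick in sorted(by_tick):
        tick_events = by_tick[tick]
        pending = []
        tx_to_event = {}
        for event in tick_events:
            sender = identities[event["sender"]]
            target = (
                "DEPLOY"
                if event["target_ref"] == "DEPLOY"
                else contract_refs.get(event["target_ref"], "0" * 40)
            )
            args = dict(event["args"])
            if event["function"] == "register_cta":
                # the generator names the CRO by label; the chain needs its address
                args["authorised_cro"] = identities[args["authorised_cro"]].address
            nonce = nonces.get(sender.address, 0) + 1
            tx = sign_transaction(
                sender, nonce, make_call(target, event["function"], args), event["time"]
            )
            pending.append(tx)
            tx_to_event[tx["tx_hash"]] = event
            if event["expect"] == ACCEPT:
                nonces[sender.address] = nonce
                # contract addresses are a pure function of (sender, nonce),
                # so references can be resolved before the block is sealed
                if event["function"] == "deploy_regulator":
                    contract_refs["regulator"] = contract_address(sender.address, nonce)
                elif event["function"] == "create_trial":
                    addr = contract_address(sender.address, nonce)
                    contract_refs[f"trial:{event['args']['trial_id']}"] = addr
                    trial_addresses[event["args"]["trial_id"]] = addr

        result = seal_block(chain, pending, tick_events[0]["time"], regulator, state=state)
        seal_results.append(result)
        state = result.state
        nonces = dict(state.nonces)
        rejected_codes = {tx["tx_hash"]: code for tx, code in result.rejected}
        for tx in pending:
            event = tx_to_event[tx["tx_hash"]]
            actual = rejected_codes.get(tx["tx_hash"], ACCEPT)
            outcomes.append((event, actual))
            if actual != event["expect"]:
                mismatches.append((event, actual))

    return RunResult(
        chain=chain,
        state=state,
        identities=identities,
        trial_addresses=trial_addresses,
        regulator_address=contract_refs.get("regulator"),
        outcomes=outcomes,
        mismatches=mismatches,
        seal_results=seal_results,
    )
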