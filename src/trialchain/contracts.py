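"""Regulator and trial contract state machines.

Two contract types mirror the regulatory hierarchy of a clinical trial:

* the **regulator contract** holds clinical trial authorisations (CTAs)
  and a container of the trial contracts deployed under them; only the
  regulator that deployed it may register CTAs;
* a **trial contract**, owned by the CRO named in its CTA, holds the trial
  protocol (document hash, endpoints, recruitment window, end date), the
  enrolled subjects and their successive clinical measurements.

Every mutation arrives as a contract call inside a signed transaction and
is judged against the protocol rules at the *block* timestamp of inclusion:
no subject outside the recruitment window, no measurement after the trial
end, no subject before the protocol is deposited, and no second protocol
deposition ever (endpoint switching is structurally impossible — there is
no call that edits or removes anything).

Checks run strictly before any mutation, so a failing call leaves the
world state byte-identical (atomicity).  The check order within each call
is part of the engine's contract and is mirrored by the workload
generator's independent oracle:

* ``create_trial``: CTA_REQUIRED, CRO_MISMATCH, WINDOW_CLOSED, DUPLICATE_TRIAL
* ``add_subject``: OWNER_ONLY, PROTOCOL_REQUIRED, WINDOW_CLOSED,
  DUPLICATE_SUBJECT, CONSENT_REQUIRED
* ``record_measurement``: OWNER_ONLY, NO_SUBJECT, TRIAL_ENDED, BAD_PAYLOAD

All window comparisons are closed intervals: a call at exactly the window
end is accepted, one tick later is rejected.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from typing import Any

from .crypto import hash_value

__all__ = [
    "WorldState",
    "CallResult",
    "apply_call",
    "summarize",
    "DEPLOY_TARGET",
    "contract_address",
]

DEPLOY_TARGET = "DEPLOY"

# failure codes surfaced by apply_call
NO_CONTRACT = "NO_CONTRACT"
NO_FUNCTION = "NO_FUNCTION"
ROLE_FORBIDDEN = "ROLE_FORBIDDEN"
OWNER_ONLY = "OWNER_ONLY"
DUPLICATE_CTA = "DUPLICATE_CTA"
CTA_REQUIRED = "CTA_REQUIRED"
CRO_MISMATCH = "CRO_MISMATCH"
WINDOW_CLOSED = "WINDOW_CLOSED"
DUPLICATE_TRIAL = "DUPLICATE_TRIAL"
PROTOCOL_IMMUTABLE = "PROTOCOL_IMMUTABLE"
ENDPOINTS_REQUIRED = "ENDPOINTS_REQUIRED"
BAD_WINDOW = "BAD_WINDOW"
PROTOCOL_REQUIRED = "PROTOCOL_REQUIRED"
DUPLICATE_SUBJECT = "DUPLICATE_SUBJECT"
CONSENT_REQUIRED = "CONSENT_REQUIRED"
NO_SUBJECT = "NO_SUBJECT"
TRIAL_ENDED = "TRIAL_ENDED"
BAD_PAYLOAD = "BAD_PAYLOAD"
BAD_ARGS = "BAD_ARGS"


@dataclass
class WorldState:
    """Contract states and per-sender nonces at a given block height.

    The state at height h is a pure function of blocks 0..h; replaying the
    same chain always reproduces it byte-for-byte.
    """

    height: int = 0
    contracts: dict[str, dict] = field(default_factory=dict)
    nonces: dict[str, int] = field(default_factory=dict)

    def digest(self) -> str:
        return hash_value(
            {"height": self.height, "contracts": self.contracts, "nonces": self.nonces}
        )

    def copy(self) -> "WorldState":
        return WorldState(
            height=self.height,
            contracts=copy.deepcopy(self.contracts),
            nonces=dict(self.nonces),
        )


@dataclass(frozen=True)
class CallResult:
    ok: bool
    code: str | None = None
    value: Any = None


def contract_address(sender: str, nonce: int) -> str:
    """Deterministic contract address from the deploying (sender, nonce)."""
    return hash_value(["contract", sender, nonce])[-40:]


def _fail(code: str) -> CallResult:
    return CallResult(ok=False, code=code)


def _str_arg(args: dict, key: str) -> str | None:
    value = args.get(key)
    return value if isinstance(value, str) and value else None


def _int_arg(args: dict, key: str) -> int | None:
    value = args.get(key)
    return value if isinstance(value, int) and not isinstance(value, bool) else None


def apply_call(state: WorldState, tx: dict, block_time: int, registry: dict) -> CallResult:
    """Dispatch a (signature/nonce-verified) transaction's contract call.

    On success the state is mutated in place and ``value`` carries any
    return (a deployed contract address).  On failure the state is
    untouched and ``code`` names the violated rule.
    """
    call = tx["call"]
    target = call["target"]
    function = call["function"]
    args = call.get("args", {})
    sender = tx["sender"]

    if target == DEPLOY_TARGET:
        if function == "deploy_regulator":
            return _deploy_regulator(state, sender, tx["nonce"], registry)
        return _fail(NO_FUNCTION)

    contract = state.contracts.get(target)
    if contract is None:
        return _fail(NO_CONTRACT)

    if contract["type"] == "regulator":
        if function == "register_cta":
            return _register_cta(contract, sender, args)
        if function == "create_trial":
            return _create_trial(state, contract, sender, tx["nonce"], args, block_time)
        return _fail(NO_FUNCTION)

    if contract["type"] == "trial":
        if function == "deposit_protocol":
            return _deposit_protocol(contract, sender, args)
        if function == "add_subject":
            return _add_subject(contract, sender, args, block_time)
        if function == "record_measurement":
            return _record_measurement(contract, sender, args, block_time)
        return _fail(NO_FUNCTION)

    return _fail(NO_FUNCTION)


def _deploy_regulator(state: WorldState, sender: str, nonce: int, registry: dict) -> CallResult:
    entry = registry.get(sender)
    if entry is None or entry.get("role") != "regulator":
        return _fail(ROLE_FORBIDDEN)
    address = contract_address(sender, nonce)
    state.contracts[address] = {
        "type": "regulator",
        "owner": sender,
        "ctas": {},
        "trials": {},
    }
    return CallResult(ok=True, value=address)


def _register_cta(contract: dict, sender: str, args: dict) -> CallResult:
    if sender != contract["owner"]:
        return _fail(OWNER_ONLY)
    trial_id = _str_arg(args, "trial_id")
    sponsor = _str_arg(args, "sponsor")
    authorised_cro = _str_arg(args, "authorised_cro")
    window_start = _int_arg(args, "window_start")
    window_end = _int_arg(args, "window_end")
    if not (trial_id and sponsor and authorised_cro) or window_start is None or window_end is None:
        return _fail(BAD_ARGS)
    if trial_id in contract["ctas"]:
        return _fail(DUPLICATE_CTA)
    if window_start > window_end:
        return _fail(BAD_WINDOW)
    contract["ctas"][trial_id] = {
        "trial_id": trial_id,
        "sponsor": sponsor,
        "authorised_cro": authorised_cro,
        # off-chain licensing agreement assumed concluded before registration
        "status": "approved",
        "window_start": window_start,
        "window_end": window_end,
        "encryption_pubkey": _str_arg(args, "encryption_pubkey"),
    }
    return CallResult(ok=True, value=trial_id)


def _create_trial(
    state: WorldState,
    regulator: dict,
    sender: str,
    nonce: int,
    args: dict,
    block_time: int,
) -> CallResult:
    trial_id = _str_arg(args, "trial_id")
    document_hash = _str_arg(args, "protocol_document_hash")
    if not trial_id or not document_hash:
        return _fail(BAD_ARGS)
    cta = regulator["ctas"].get(trial_id)
    if cta is None or cta["status"] != "approved":
        return _fail(CTA_REQUIRED)
    if sender != cta["authorised_cro"]:
        return _fail(CRO_MISMATCH)
    if not (cta["window_start"] <= block_time <= cta["window_end"]):
        return _fail(WINDOW_CLOSED)
    if trial_id in regulator["trials"]:
        return _fail(DUPLICATE_TRIAL)
    address = contract_address(sender, nonce)
    state.contracts[address] = {
        "type": "trial",
        "owner": sender,
        "trial_id": trial_id,
        "protocol_document_hash": document_hash,  # pending full deposition
        "protocol": None,
        "subjects": {},
        "subject_order": [],
        "regulator_pubkey": cta["encryption_pubkey"],
    }
    regulator["trials"][trial_id] = address
    return CallResult(ok=True, value=address)


def _deposit_protocol(contract: dict, sender: str, args: dict) -> CallResult:
    if sender != contract["owner"]:
        return _fail(OWNER_ONLY)
    if contract["protocol"] is not None:
        return _fail(PROTOCOL_IMMUTABLE)
    endpoints = args.get("endpoints")
    document_hash = _str_arg(args, "document_hash")
    rec_start = _int_arg(args, "recruitment_start")
    rec_end = _int_arg(args, "recruitment_end")
    trial_end = _int_arg(args, "trial_end")
    if (
        not isinstance(endpoints, list)
        or not document_hash
        or rec_start is None
        or rec_end is None
        or trial_end is None
    ):
        return _fail(BAD_ARGS)
    if not endpoints:
        return _fail(ENDPOINTS_REQUIRED)
    for endpoint in endpoints:
        if not isinstance(endpoint, dict) or not _str_arg(endpoint, "name"):
            return _fail(BAD_ARGS)
    if not (rec_start < rec_end <= trial_end):
        return _fail(BAD_WINDOW)
    contract["protocol"] = {
        "document_hash": document_hash,
        "endpoints": endpoints,
        "recruitment_start": rec_start,
        "recruitment_end": rec_end,
        "trial_end": trial_end,
    }
    return CallResult(ok=True)


def _add_subject(contract: dict, sender: str, args: dict, block_time: int) -> CallResult:
    if sender != contract["owner"]:
        return _fail(OWNER_ONLY)
    protocol = contract["protocol"]
    if protocol is None:
        return _fail(PROTOCOL_REQUIRED)
    subject_id = _str_arg(args, "subject_id")
    if not subject_id:
        return _fail(BAD_ARGS)
    if not (protocol["recruitment_start"] <= block_time <= protocol["recruitment_end"]):
        return _fail(WINDOW_CLOSED)
    if subject_id in contract["subjects"]:
        return _fail(DUPLICATE_SUBJECT)
    consent_hash = _str_arg(args, "consent_hash")
    if not consent_hash:
        return _fail(CONSENT_REQUIRED)
    demographics = args.get("demographics")
    if not isinstance(demographics, dict):
        return _fail(BAD_ARGS)
    contract["subjects"][subject_id] = {
        "subject_id": subject_id,
        "demographics": demographics,
        "consent_hash": consent_hash,
        "enrolled_at": block_time,
        "measurements": [],
    }
    contract["subject_order"].append(subject_id)
    return CallResult(ok=True)


def _record_measurement(contract: dict, sender: str, args: dict, block_time: int) -> CallResult:
    if sender != contract["owner"]:
        return _fail(OWNER_ONLY)
    protocol = contract["protocol"]
    if protocol is None:
        return _fail(PROTOCOL_REQUIRED)
    subject_id = _str_arg(args, "subject_id")
    payload = args.get("payload")
    encrypted = args.get("encrypted", False)
    if not subject_id or not isinstance(payload, str) or not isinstance(encrypted, bool):
        return _fail(BAD_ARGS)
    subject = contract["subjects"].get(subject_id)
    if subject is None:
        return _fail(NO_SUBJECT)
    if block_time > protocol["trial_end"]:
        return _fail(TRIAL_ENDED)
    if not encrypted:
        try:
            json.loads(payload)
        except ValueError:
            return _fail(BAD_PAYLOAD)
    subject["measurements"].append(
        {
            "recorded_at": block_time,
            "payload": payload,
            "encrypted": encrypted,
            "sender": sender,
        }
    )
    return CallResult(ok=True)


def summarize(state: WorldState) -> dict:
    """Read-everything report: every trial, subject and data point.

    Mirrors the registry view a regulator would query: trial count, per
    trial the owning CRO address, protocol hash and endpoint names, the
    subject roster with enrolment timestamps, and per-subject measurement
    counts with first/last record timestamps.
    """
    trials = []
    for address in sorted(state.contracts):
        contract = state.contracts[address]
        if contract["type"] != "trial":
            continue
        protocol = contract["protocol"]
        subjects = {}
        for subject_id in contract["subject_order"]:
            subject = contract["subjects"][subject_id]
            measurements = subject["measurements"]
            subjects[subject_id] = {
                "enrolled_at": subject["enrolled_at"],
                "consent_hash": subject["consent_hash"],
                "n_measurements": len(measurements),
                "first_recorded_at": measurements[0]["recorded_at"] if measurements else None,
                "last_recorded_at": measurements[-1]["recorded_at"] if measurements else None,
                "senders": sorted({m["sender"] for m in measurements}),
            }
        trials.append(
            {
                "trial_id": contract["trial_id"],
                "address": address,
                "owner": contract["owner"],
                "protocol_document_hash": contract["protocol_document_hash"],
                "endpoints": [e["name"] for e in protocol["endpoints"]] if protocol else [],
                "n_subjects": len(subjects),
                "subjects": subjects,
            }
        )
    trials.sort(key=lambda t: t["trial_id"])
    return {"height": state.height, "n_trials": len(trials), "trials": trials}
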