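"""Append-only hash-chained ledger: transactions, blocks, sealing, audit.

The chain is sealed by a single authority named in the genesis
configuration (proof-of-authority): the network the artifact models is
private and permissioned, so there is no mining and no fork — finality is
inclusion in a sealed block.  Timestamps are injected parameters (a
logical clock); contract rules judge recruitment windows and trial end
dates against the *block* timestamp of inclusion, never a sender-claimed
time.  A sender-side timestamp is nonetheless carried on each transaction
for provenance, signed along with the call.

Tamper evidence is layered: the signature binds (sender, nonce,
sender_time, call); tx_hash commits to the whole signed transaction
including its signature bytes; the Merkle root commits to the ordered
tx_hashes; the block hash commits to the header including the Merkle root;
and each block's prev_hash commits to its predecessor.  Flipping any
single byte of any serialized transaction or header therefore breaks at
least one recomputation, which `verify_chain` reports with block/tx
coordinates.  `verify_chain` additionally replays every contract call, so
a block containing a rule-violating call (however well signed) is flagged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterator

from . import ed25519
from .contracts import WorldState, apply_call
from .crypto import hash_bytes, merkle_root
from .identity import Identity
from .serialization import canonical_serialize

__all__ = [
    "Transaction",
    "sign_transaction",
    "verify_transaction",
    "Chain",
    "SealResult",
    "SealError",
    "seal_block",
    "AuditReport",
    "verify_chain",
    "state_at",
    "iter_states",
]

GENESIS_PREV_HASH = "0" * 64

# verification failure codes
UNKNOWN_SENDER = "UNKNOWN_SENDER"
BAD_SIGNATURE = "BAD_SIGNATURE"
BAD_NONCE = "BAD_NONCE"
TX_HASH_MISMATCH = "TX_HASH_MISMATCH"
SEALER_FORBIDDEN = "SEALER_FORBIDDEN"
TIMESTAMP_REGRESSION = "TIMESTAMP_REGRESSION"
PREV_HASH_MISMATCH = "PREV_HASH_MISMATCH"
BLOCK_HASH_MISMATCH = "BLOCK_HASH_MISMATCH"
MERKLE_MISMATCH = "MERKLE_MISMATCH"
BAD_HEIGHT = "BAD_HEIGHT"
BAD_GENESIS = "BAD_GENESIS"
RULE_VIOLATION = "RULE_VIOLATION"
MALFORMED_BLOCK = "MALFORMED_BLOCK"


# --- transactions -----------------------------------------------------------

def make_call(target: str, function: str, args: dict) -> dict:
    return {"target": target, "function": function, "args": args}


def signing_bytes(sender: str, nonce: int, sender_time: int, call: dict) -> bytes:
    return canonical_serialize(
        {"sender": sender, "nonce": nonce, "sender_time": sender_time, "call": call}
    )


def transaction_hash(tx: dict) -> str:
    """Digest of the full signed transaction (signature included)."""
    body = {k: v for k, v in tx.items() if k != "tx_hash"}
    return hash_bytes(canonical_serialize(body))


def sign_transaction(identity: Identity, nonce: int, call: dict, sender_time: int) -> dict:
    """Build and sign a transaction; the result verifies immediately."""
    signature = identity.sign(signing_bytes(identity.address, nonce, sender_time, call))
    tx = {
        "sender": identity.address,
        "nonce": nonce,
        "sender_time": sender_time,
        "call": call,
        "signature": signature.hex(),
    }
    tx["tx_hash"] = transaction_hash(tx)
    return tx


@lru_cache(maxsize=200_000)
def _verify_signature_cached(public_key: str, message: bytes, signature: str) -> bool:
    # signature verification is a pure function; the cache makes repeated
    # full-chain audits (e.g. tamper sweeps) cheap for untouched blocks
    try:
        return ed25519.verify(bytes.fromhex(public_key), message, bytes.fromhex(signature))
    except ValueError:
        return False


def verify_transaction(tx: dict, registry: dict, expected_nonce: int) -> str | None:
    """Return None if the transaction is valid, else a failure code."""
    entry = registry.get(tx.get("sender"))
    if entry is None:
        return UNKNOWN_SENDER
    if tx.get("tx_hash") != transaction_hash(tx):
        return TX_HASH_MISMATCH
    message = signing_bytes(tx["sender"], tx["nonce"], tx["sender_time"], tx["call"])
    if not _verify_signature_cached(entry["public_key"], message, tx["signature"]):
        return BAD_SIGNATURE
    if tx["nonce"] != expected_nonce:
        return BAD_NONCE
    return None


# --- blocks and the chain ---------------------------------------------------

def block_header_bytes(block: dict) -> bytes:
    return canonical_serialize(
        {
            "height": block["height"],
            "prev_hash": block["prev_hash"],
            "timestamp": block["timestamp"],
            "merkle_root": block["merkle_root"],
            "sealer": block["sealer"],
        }
    )


def block_hash(block: dict) -> str:
    return hash_bytes(block_header_bytes(block))


def _build_block(height, prev_hash, timestamp, sealer, transactions) -> dict:
    block = {
        "height": height,
        "prev_hash": prev_hash,
        "timestamp": timestamp,
        "merkle_root": merkle_root([tx["tx_hash"] for tx in transactions]),
        "sealer": sealer,
        "transactions": transactions,
    }
    block["block_hash"] = block_hash(block)
    return block


@dataclass
class Chain:
    """Genesis configuration plus the ordered list of sealed blocks."""

    genesis_config: dict
    blocks: list[dict] = field(default_factory=list)

    @classmethod
    def create(
        cls,
        network_id: str,
        sealers: list[str],
        identities: dict[str, dict],
        timestamp: int,
    ) -> "Chain":
        config = {
            "network_id": network_id,
            "hash": "sha256",
            "signature_scheme": "ed25519",
            "sealers": list(sealers),
            "identities": identities,
        }
        genesis = _build_block(0, GENESIS_PREV_HASH, timestamp, sealers[0], [])
        return cls(genesis_config=config, blocks=[genesis])

    @property
    def tip(self) -> dict:
        return self.blocks[-1]

    @property
    def height(self) -> int:
        return self.tip["height"]

    @property
    def registry(self) -> dict:
        return self.genesis_config["identities"]

    @property
    def sealers(self) -> list[str]:
        return self.genesis_config["sealers"]

    def truncated(self, confirmations: int) -> "Chain":
        """Read-side view up to tip − confirmations (finality margin)."""
        if confirmations < 0 or confirmations > self.height:
            raise ValueError("confirmations out of range")
        if confirmations == 0:
            return self
        return Chain(self.genesis_config, self.blocks[: len(self.blocks) - confirmations])

    # --- persistence: genesis.json + chain.jsonl, one block per line ---

    def save(self, directory: Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "genesis.json").write_text(
            json.dumps(self.genesis_config, sort_keys=True, indent=2) + "\n"
        )
        with open(directory / "chain.jsonl", "w") as fh:
            for block in self.blocks:
                fh.write(json.dumps(block, sort_keys=True, separators=(",", ":")) + "\n")

    @classmethod
    def load(cls, directory: Path) -> "Chain":
        directory = Path(directory)
        config = json.loads((directory / "genesis.json").read_text())
        blocks = []
        with open(directory / "chain.jsonl") as fh:
            for line in fh:
                line = line.strip()
                if line:
                    blocks.append(json.loads(line))
        return cls(genesis_config=config, blocks=blocks)


# --- sealing ----------------------------------------------------------------

class SealError(Exception):
    def __init__(self, code: str, message: str = ""):
        super().__init__(message or code)
        self.code = code


@dataclass
class SealResult:
    block: dict
    accepted: list[dict]
    rejected: list[tuple[dict, str]]  # (transaction, failure code) — reported, not dropped
    state: WorldState


def seal_block(
    chain: Chain,
    pending: list[dict],
    timestamp: int,
    sealer: Identity | str,
    state: WorldState | None = None,
) -> SealResult:
    """Seal the pending transactions into a new block and append it.

    Each transaction is signature/nonce-verified and its contract call
    applied against the working state; transactions failing either stage
    are excluded from the block and reported with their failure code.
    *state* may carry the incrementally maintained tip state to avoid a
    full replay; it defaults to ``state_at(chain, tip)``.
    """
    sealer_address = sealer.address if isinstance(sealer, Identity) else sealer
    if sealer_address not in chain.sealers:
        raise SealError(SEALER_FORBIDDEN, f"sealer {sealer_address} not authorised")
    if timestamp < chain.tip["timestamp"]:
        raise SealError(TIMESTAMP_REGRESSION, "block timestamp precedes tip")

    if state is None:
        state = state_at(chain, chain.height)
    accepted: list[dict] = []
    rejected: list[tuple[dict, str]] = []
    for tx in pending:
        expected_nonce = state.nonces.get(tx.get("sender"), 0) + 1
        code = verify_transaction(tx, chain.registry, expected_nonce)
        if code is None:
            result = apply_call(state, tx, timestamp, chain.registry)
            if not result.ok:
                code = result.code
        if code is None:
            state.nonces[tx["sender"]] = tx["nonce"]
            accepted.append(tx)
        else:
            rejected.append((tx, code))

    block = _build_block(
        chain.height + 1, chain.tip["block_hash"], timestamp, sealer_address, accepted
    )
    chain.blocks.append(block)
    state.height = block["height"]
    return SealResult(block=block, accepted=accepted, rejected=rejected, state=state)


# --- audit and historic state ----------------------------------------------

@dataclass
class AuditReport:
    valid: bool
    failures: list[tuple[int, int | None, str, str]]  # (height, tx index, code, message)

    def render(self) -> str:
        if self.valid:
            return "VALID"
        lines = ["INVALID"]
        for height, tx_index, code, message in self.failures:
            where = f"block {height}" + ("" if tx_index is None else f" tx {tx_index}")
            lines.append(f"  {where}: {code} {message}")
        return "\n".join(lines)


def verify_chain(chain: Chain) -> AuditReport:
    """Full-chain audit: structure, hashes, signatures and rule replay.

    Failures are report entries, never exceptions: a corrupted or even
    structurally mangled ledger still yields a complete list of
    (block, transaction) coordinates.
    """
    failures: list[tuple[int, int | None, str, str]] = []
    registry = chain.registry
    sealers = set(chain.sealers)

    if not chain.blocks:
        return AuditReport(valid=False, failures=[(0, None, BAD_GENESIS, "empty chain")])
    try:
        genesis = chain.blocks[0]
        if genesis["height"] != 0 or genesis["prev_hash"] != GENESIS_PREV_HASH:
            failures.append((0, None, BAD_GENESIS, "malformed genesis block"))
        if genesis["transactions"]:
            failures.append((0, None, BAD_GENESIS, "genesis block must be empty"))
    except (KeyError, TypeError) as exc:
        failures.append((0, None, MALFORMED_BLOCK, f"unauditable genesis: {exc!r}"))

    state = WorldState()
    prev = None
    for block_index, block in enumerate(chain.blocks):
        # a structurally mangled block (missing or retyped fields) is itself
        # a tamper finding, not an excuse to abort the audit
        try:
            _verify_block(block_index, block, prev, state, registry, sealers, failures)
        except (KeyError, TypeError, AttributeError, ValueError) as exc:
            failures.append(
                (block_index, None, MALFORMED_BLOCK, f"unauditable block: {exc!r}")
            )
        prev = block

    return AuditReport(valid=not failures, failures=failures)


def _verify_block(height, block, prev, state, registry, sealers, failures) -> None:
    if prev is not None:
        if block["height"] != prev["height"] + 1:
            failures.append((height, None, BAD_HEIGHT, "non-consecutive height"))
        if block["prev_hash"] != prev["block_hash"]:
            failures.append((height, None, PREV_HASH_MISMATCH, "broken chain link"))
        if block["timestamp"] < prev["timestamp"]:
            failures.append((height, None, TIMESTAMP_REGRESSION, "timestamp decreased"))
    if block["sealer"] not in sealers:
        failures.append((height, None, SEALER_FORBIDDEN, "unauthorised sealer"))
    if block["block_hash"] != block_hash(block):
        failures.append((height, None, BLOCK_HASH_MISMATCH, "header hash mismatch"))

    recomputed_hashes = []
    for index, tx in enumerate(block["transactions"]):
        try:
            recomputed = transaction_hash(tx)
            recomputed_hashes.append(recomputed)
            if tx.get("tx_hash") != recomputed:
                failures.append((height, index, TX_HASH_MISMATCH, "tx hash mismatch"))
                continue
            expected_nonce = state.nonces.get(tx.get("sender"), 0) + 1
            code = verify_transaction(tx, registry, expected_nonce)
            if code is not None:
                failures.append((height, index, code, "transaction verification failed"))
                continue
            result = apply_call(state, tx, block["timestamp"], registry)
            if not result.ok:
                failures.append(
                    (height, index, RULE_VIOLATION, f"contract rule violated: {result.code}")
                )
                continue
            state.nonces[tx["sender"]] = tx["nonce"]
        except (KeyError, TypeError, AttributeError, ValueError) as exc:
            failures.append((height, index, MALFORMED_BLOCK, f"unauditable tx: {exc!r}"))
    if block["merkle_root"] != merkle_root(recomputed_hashes):
        failures.append((height, None, MERKLE_MISMATCH, "merkle root mismatch"))
    state.height = block["height"]


def state_at(chain: Chain, height: int) -> WorldState:
    """World state after replaying blocks 0..height, computed from scratch.

    Pure and deterministic: repeated calls return identical states, and a
    chain extension never changes the state at an existing height.
    """
    if height < 0 or height > chain.height:
        raise ValueError(f"height {height} out of range 0..{chain.height}")
    state = WorldState()
    for block in chain.blocks[: height + 1]:
        _apply_block(state, block, chain.registry)
    return state


def iter_states(chain: Chain) -> Iterator[tuple[int, WorldState]]:
    """Yield (height, state) for every height in one incremental replay.

    Equivalent to ``state_at`` at each height but O(n) overall.  The yielded
    state is a live view that advances with iteration; snapshot with
    ``state.copy()`` if it must outlive the step.
    """
    state = WorldState()
    for block in chain.blocks:
        _apply_block(state, block, chain.registry)
        yield block["height"], state


def _apply_block(state: WorldState, block: dict, registry: dict) -> None:
    for tx in block["transactions"]:
        result = apply_call(state, tx, block["timestamp"], registry)
        if not result.ok:
            raise ValueError(
                f"invalid chain: tx {tx['tx_hash']} in block {block['height']} "
                f"fails replay with {result.code}"
            )
        state.nonces[tx["sender"]] = tx["nonce"]
    state.height = block["height"]
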