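"""Content-addressed document storage and blockchain-anchored existence proofs.

Large artefacts — protocol PDFs, consent scans — never live on the chain;
only their SHA-256 content addresses do.  The bytes themselves sit in a
local directory store keyed by digest (a stand-in for a distributed
content-addressed network: same addressing scheme, no peers), so deleting
the off-chain bytes can never invalidate the ledger, it only makes
retrieval fail.

`prove_existence` realises proof-of-existence: the earliest block whose
transactions embed a document's hash demonstrates the document existed,
unmodified, at that block's timestamp.  Because the chain is append-only
the proof can only gain confirmations, never change.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .crypto import hash_bytes
from .ledger import Chain

__all__ = [
    "DocumentStore",
    "ExistenceProof",
    "prove_existence",
    "NotFoundError",
    "IntegrityError",
]


class NotFoundError(KeyError):
    """No document stored under the given content hash."""


class IntegrityError(ValueError):
    """Stored bytes no longer match their content address."""


class DocumentStore:
    """Flat-file store under ``store/<first-2-hex>/<digest>``."""

    def __init__(self, root: Path):
        self.root = Path(root)

    def _path(self, content_hash: str) -> Path:
        return self.root / content_hash[:2] / content_hash

    def put(self, data: bytes) -> str:
        """Store bytes, returning their content address; idempotent."""
        content_hash = hash_bytes(data)
        path = self._path(content_hash)
        if not path.exists():
            path.parent.mkdir(parents=True, exist_ok=True)
            path.write_bytes(data)
        return content_hash

    def get(self, content_hash: str) -> bytes:
        """Retrieve bytes by content address, re-verifying on read."""
        path = self._path(content_hash)
        if not path.exists():
            raise NotFoundError(content_hash)
        data = path.read_bytes()
        if hash_bytes(data) != content_hash:
            raise IntegrityError(f"stored bytes for {content_hash} are corrupt")
        return data

    def has(self, content_hash: str) -> bool:
        return self._path(content_hash).exists()


@dataclass(frozen=True)
class ExistenceProof:
    document_hash: str
    block_height: int
    block_timestamp: int
    tx_hash: str


def _args_contain(value, needle: str) -> bool:
    if isinstance(value, str):
        return value == needle
    if isinstance(value, dict):
        return any(_args_contain(v, needle) for v in value.values())
    if isinstance(value, list):
        return any(_args_contain(v, needle) for v in value)
    return False


def prove_existence(chain: Chain, document_hash: str) -> ExistenceProof | None:
    """Earliest on-chain anchoring of *document_hash*, or None.

    Scans blocks in height order for the first transaction whose call
    arguments embed the hash; the proof cites that block's height and
    timestamp and is stable under any chain extension.
    """
    for block in chain.blocks:
        for tx in block["transactions"]:
            if _args_contain(tx["call"].get("args", {}), document_hash):
                return ExistenceProof(
                    document_hash=document_hash,
                    block_height=block["height"],
                    block_timestamp=block["timestamp"],
                    tx_hash=tx["tx_hash"],
                )
    return None
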