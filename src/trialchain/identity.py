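"""Network identities: regulators, CROs and pharma sponsors.

An identity is a signing keypair plus a role.  The 20-byte address is a
pure function of the public key, so a transaction's sender address is
always resolvable to the organisation that holds the key (for a trial
contract, the CRO).  Private keys live off-ledger in key files; the genesis
configuration registers only roles and public keys.
"""

from __future__ import annotations

import json
import secrets
from dataclasses import dataclass
from pathlib import Path

from . import ed25519
from .crypto import derive_address

__all__ = ["Identity", "ROLES", "generate_identity", "registry_entry"]

ROLES = ("regulator", "cro", "pharma")


@dataclass(frozen=True)
class Identity:
    label: str
    role: str
    seed_hex: str  # 32-byte signing seed, hex; never serialized on-chain
    public_key: str
    address: str

    def sign(self, message: bytes) -> bytes:
        return ed25519.sign(bytes.fromhex(self.seed_hex), message)

    # --- key-file persistence (CLI `keygen` output) ---

    def write_files(self, directory: Path) -> tuple[Path, Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        key_path = directory / f"{self.label}.key"
        key_path.write_text(self.seed_hex + "\n")
        sidecar = directory / f"{self.label}.identity.json"
        sidecar.write_text(
            json.dumps(
                {
                    "label": self.label,
                    "role": self.role,
                    "public_key": self.public_key,
                    "address": self.address,
                },
                indent=2,
                sort_keys=True,
            )
            + "\n"
        )
        return key_path, sidecar

    @classmethod
    def read_files(cls, key_path: Path) -> "Identity":
        key_path = Path(key_path)
        seed_hex = key_path.read_text().strip()
        sidecar = key_path.with_suffix("").with_suffix(".identity.json")
        meta = json.loads(sidecar.read_text())
        identity = from_seed(meta["label"], meta["role"], bytes.fromhex(seed_hex))
        if identity.address != meta["address"]:
            raise ValueError(f"key file {key_path} does not match its identity record")
        return identity


def from_seed(label: str, role: str, seed: bytes) -> Identity:
    if role not in ROLES:
        raise ValueError(f"unknown role {role!r}; expected one of {ROLES}")
    public = ed25519.secret_to_public(seed).hex()
    return Identity(
        label=label,
        role=role,
        seed_hex=seed.hex(),
        public_key=public,
        address=derive_address(public),
    )


def generate_identity(label: str, role: str, seed: bytes | None = None) -> Identity:
    """Create an identity; *seed* omitted draws 32 random bytes."""
    if seed is None:
        seed = secrets.token_bytes(32)
    return from_seed(label, role, seed)


def registry_entry(identity: Identity) -> dict:
    """The public half registered in genesis_config."""
    return {"role": identity.role, "public_key": identity.public_key}
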