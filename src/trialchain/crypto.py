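"""Hashing, addresses, Merkle roots and sealed-box payload encryption.

SHA-256 is the single digest function across the whole artifact: ledger
hashes, content addresses in the document store, and Merkle roots all share
it, so a protocol document's content address is directly searchable in
serialized transaction arguments (proof-of-existence).

Sender addresses are the last 20 bytes of the SHA-256 of the encoded
public key, rendered as 40 lowercase hex characters — the Ethereum-style
truncation with the hash function unified to SHA-256.

The sealed box encrypts measurement payloads to a per-trial regulator key:
an ephemeral curve keypair is generated per message, a shared point is
derived by Diffie-Hellman against the recipient key, and HMAC-SHA256
provides both the keystream and the authentication tag.  Decryption with
any other trial's key fails the tag check.
"""

from __future__ import annotations

import base64
import hashlib
import hmac
import secrets
from typing import Callable

from . import ed25519
from .serialization import canonical_serialize

__all__ = [
    "hash_bytes",
    "derive_address",
    "merkle_root",
    "EMPTY_MERKLE_ROOT",
    "encryption_keypair",
    "seal_payload",
    "open_payload",
    "DecryptError",
    "KeyError_",
]

DIGEST_HEX_LEN = 64
ADDRESS_HEX_LEN = 40


class KeyError_(ValueError):
    """Malformed cryptographic key material."""


class DecryptError(ValueError):
    """Sealed box failed to open (wrong key or tampered ciphertext)."""


def hash_bytes(data: bytes) -> str:
    """SHA-256 digest of *data*, lowercase hex."""
    return hashlib.sha256(data).hexdigest()


def hash_value(value) -> str:
    """Digest of the canonical serialization of a structured value."""
    return hash_bytes(canonical_serialize(value))


def derive_address(public_key_hex: str) -> str:
    """Last 20 bytes of SHA-256 of the encoded public key, as hex."""
    try:
        raw = bytes.fromhex(public_key_hex)
    except ValueError as exc:
        raise KeyError_("public key is not valid hex") from exc
    if len(raw) != 32:
        raise KeyError_("public key must encode 32 bytes")
    return hashlib.sha256(raw).digest()[-20:].hex()


EMPTY_MERKLE_ROOT = hashlib.sha256(b"").hexdigest()


def merkle_root(tx_hashes: list[str]) -> str:
    """Binary Merkle root over ordered transaction digests.

    Sibling digests are concatenated (raw bytes) and hashed pairwise; an odd
    node at any level is paired with itself.  The empty list maps to the
    digest of the empty byte string — the documented sentinel for empty
    blocks.
    """
    if not tx_hashes:
        return EMPTY_MERKLE_ROOT
    level = [bytes.fromhex(h) for h in tx_hashes]
    while len(level) > 1:
        if len(level) % 2:
            level.append(level[-1])
        level = [
            hashlib.sha256(level[i] + level[i + 1]).digest()
            for i in range(0, len(level), 2)
        ]
    if len(tx_hashes) == 1:
        # a single leaf is still committed through one hashing round
        return hashlib.sha256(level[0] + level[0]).hexdigest()
    return level[0].hex()


# --- sealed-box payload encryption -----------------------------------------

def encryption_keypair(seed: bytes) -> tuple[str, str]:
    """Derive a (private, public) encryption keypair from a 32-byte seed.

    The private half is the hex seed itself; the regulator files one such
    seed per trial contract.
    """
    if len(seed) != 32:
        raise KeyError_("encryption seed must be 32 bytes")
    scalar = ed25519.dh_secret_scalar(seed)
    return seed.hex(), ed25519.dh_public(scalar).hex()


def _derive_keys(shared: bytes, eph_pub: bytes, recipient_pub: bytes) -> tuple[bytes, bytes]:
    material = hashlib.sha256(shared + eph_pub + recipient_pub).digest()
    enc_key = hashlib.sha256(material + b"enc").digest()
    mac_key = hashlib.sha256(material + b"mac").digest()
    return enc_key, mac_key


def _keystream_xor(key: bytes, data: bytes) -> bytes:
    out = bytearray()
    for block_index in range(0, len(data), 32):
        block = hmac.new(key, (block_index // 32).to_bytes(8, "big"), hashlib.sha256).digest()
        chunk = data[block_index : block_index + 32]
        out += bytes(a ^ b for a, b in zip(chunk, block))
    return bytes(out)


def seal_payload(
    recipient_public_hex: str,
    plaintext: str,
    rng: Callable[[int], bytes] = secrets.token_bytes,
) -> str:
    """Encrypt *plaintext* to the recipient's public key.

    Returns base64 text (stored verbatim in the measurement payload field
    with ``encrypted=True``).  A fresh ephemeral keypair is drawn from *rng*
    per call, so identical plaintexts seal to distinct ciphertexts.
    """
    recipient_pub = bytes.fromhex(recipient_public_hex)
    eph_seed = rng(32)
    eph_scalar = ed25519.dh_secret_scalar(eph_seed)
    eph_pub = ed25519.dh_public(eph_scalar)
    shared = ed25519.dh_shared_secret(eph_scalar, recipient_pub, reuse_peer=True)
    enc_key, mac_key = _derive_keys(shared, eph_pub, recipient_pub)
    ciphertext = _keystream_xor(enc_key, plaintext.encode("utf-8"))
    tag = hmac.new(mac_key, eph_pub + ciphertext, hashlib.sha256).digest()
    return base64.b64encode(eph_pub + ciphertext + tag).decode("ascii")


def open_payload(recipient_private_hex: str, box: str) -> str:
    """Open a sealed payload with the trial's private key.

    Raises :class:`DecryptError` if the key does not match or the box was
    altered — failure code DECRYPT_FAIL.
    """
    try:
        raw = base64.b64decode(box.encode("ascii"), validate=True)
    except (ValueError, UnicodeEncodeError) as exc:
        raise DecryptError("DECRYPT_FAIL") from exc
    if len(raw) < 64:
        raise DecryptError("DECRYPT_FAIL")
    eph_pub, ciphertext, tag = raw[:32], raw[32:-32], raw[-32:]
    seed = bytes.fromhex(recipient_private_hex)
    scalar = ed25519.dh_secret_scalar(seed)
    recipient_pub = ed25519.dh_public(scalar)
    try:
        shared = ed25519.dh_shared_secret(scalar, eph_pub)
    except ed25519.SignatureError as exc:
        raise DecryptError("DECRYPT_FAIL") from exc
    enc_key, mac_key = _derive_keys(shared, eph_pub, recipient_pub)
    expected = hmac.new(mac_key, eph_pub + ciphertext, hashlib.sha256).digest()
    if not hmac.compare_digest(tag, expected):
        raise DecryptError("DECRYPT_FAIL")
    return _keystream_xor(enc_key, ciphertext).decode("utf-8")
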