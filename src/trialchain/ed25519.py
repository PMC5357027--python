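"""Ed25519 signatures and curve Diffie-Hellman, implemented from RFC 8032.

Pure Python over the twisted Edwards curve -x^2 + y^2 = 1 + d x^2 y^2
(edwards25519).  Signatures are *deterministic* — the nonce is derived from
the secret prefix and the message — which is what makes block hashes in
this ledger reproducible across runs: the same workload seed always yields
a byte-identical chain.

Points are held in extended homogeneous coordinates (X, Y, Z, T) with
x = X/Z, y = Y/Z, x*y = T/Z.  Fixed-base scalar multiplication uses a
radix-16 precomputed table (built lazily on first use), which makes key
generation and signing cheap; verification additionally needs one
variable-base multiplication, for which small per-point tables are cached
because a ledger verifies many signatures from few identities.

Test vectors from RFC 8032 section 7.1 pin this implementation in the test
suite.
"""

from __future__ import annotations

import hashlib
from functools import lru_cache

__all__ = [
    "secret_to_public",
    "sign",
    "verify",
    "dh_secret_scalar",
    "dh_public",
    "dh_shared_secret",
    "SignatureError",
]

P = 2**255 - 19
L = 2**252 + 27742317777372353535851937790883648493
D = (-121665 * pow(121666, P - 2, P)) % P

_IDENT = (0, 1, 1, 0)


class SignatureError(ValueError):
    """Malformed key, point or signature."""


def _point_add(p, q):
    x1, y1, z1, t1 = p
    x2, y2, z2, t2 = q
    a = (y1 - x1) * (y2 - x2) % P
    b = (y1 + x1) * (y2 + x2) % P
    c = 2 * t1 * t2 * D % P
    dd = 2 * z1 * z2 % P
    e = b - a
    f = dd - c
    g = dd + c
    h = b + a
    return (e * f % P, g * h % P, f * g % P, e * h % P)


def _point_double(p):
    x1, y1, z1, _ = p
    a = x1 * x1 % P
    b = y1 * y1 % P
    c = 2 * z1 * z1 % P
    h = a + b
    e = h - (x1 + y1) * (x1 + y1)
    g = a - b
    f = c + g
    return (e * f % P, g * h % P, f * g % P, e * h % P)


def _point_equal(p, q):
    x1, y1, z1, _ = p
    x2, y2, z2, _ = q
    return (x1 * z2 - x2 * z1) % P == 0 and (y1 * z2 - y2 * z1) % P == 0


def _recover_x(y: int, sign_bit: int) -> int:
    if y >= P:
        raise SignatureError("y coordinate out of range")
    x2 = (y * y - 1) * pow(D * y * y + 1, P - 2, P) % P
    x = pow(x2, (P + 3) // 8, P)
    if (x * x - x2) % P != 0:
        x = x * pow(2, (P - 1) // 4, P) % P
    if (x * x - x2) % P != 0:
        raise SignatureError("point not on curve")
    if x == 0 and sign_bit:
        raise SignatureError("invalid sign bit")
    if x & 1 != sign_bit:
        x = P - x
    return x


def _compress(p) -> bytes:
    x, y, z, _ = p
    zinv = pow(z, P - 2, P)
    x = x * zinv % P
    y = y * zinv % P
    return (y | ((x & 1) << 255)).to_bytes(32, "little")


def _decompress(data: bytes):
    if len(data) != 32:
        raise SignatureError("point encoding must be 32 bytes")
    raw = int.from_bytes(data, "little")
    sign_bit = raw >> 255
    y = raw & ((1 << 255) - 1)
    x = _recover_x(y, sign_bit)
    return (x, y, 1, x * y % P)


_BY = 4 * pow(5, P - 2, P) % P
_BX = _recover_x(_BY, 0)
_BASE = (_BX, _BY, 1, _BX * _BY % P)

_base_table: list[list[tuple[int, int, int, int]]] | None = None


def _get_base_table():
    global _base_table
    if _base_table is None:
        table = []
        radix_point = _BASE
        for _ in range(64):
            row = [_IDENT]
            acc = _IDENT
            for _ in range(15):
                acc = _point_add(acc, radix_point)
                row.append(acc)
            table.append(row)
            for _ in range(4):
                radix_point = _point_double(radix_point)
        _base_table = table
    return _base_table


def _base_mult(k: int):
    table = _get_base_table()
    acc = _IDENT
    for i in range(64):
        digit = (k >> (4 * i)) & 0xF
        if digit:
            acc = _point_add(acc, table[i][digit])
    return acc


@lru_cache(maxsize=64)
def _point_table(compressed: bytes):
    """Radix-16 table for a variable point, cached per point.

    A chain has few identities but many signatures, so amortising the table
    build across verifications of the same public key pays for itself after
    the second signature.
    """
    base = _decompress(compressed)
    table = []
    radix_point = base
    for _ in range(64):
        row = [_IDENT]
        acc = _IDENT
        for _ in range(15):
            acc = _point_add(acc, radix_point)
            row.append(acc)
        table.append(row)
        for _ in range(4):
            radix_point = _point_double(radix_point)
    return table


def _cached_mult(k: int, compressed: bytes):
    table = _point_table(compressed)
    acc = _IDENT
    for i in range(64):
        digit = (k >> (4 * i)) & 0xF
        if digit:
            acc = _point_add(acc, table[i][digit])
    return acc


def _scalar_mult(k: int, point):
    """Plain double-and-add; preferable to table building for one-shot points."""
    acc = _IDENT
    addend = point
    while k:
        if k & 1:
            acc = _point_add(acc, addend)
        addend = _point_double(addend)
        k >>= 1
    return acc


def _clamp(data: bytes) -> int:
    a = bytearray(data)
    a[0] &= 248
    a[31] &= 127
    a[31] |= 64
    return int.from_bytes(a, "little")


def _expand_secret(seed: bytes) -> tuple[int, bytes]:
    if len(seed) != 32:
        raise SignatureError("secret seed must be 32 bytes")
    h = hashlib.sha512(seed).digest()
    return _clamp(h[:32]), h[32:]


def secret_to_public(seed: bytes) -> bytes:
    """Derive the 32-byte public key from a 32-byte secret seed."""
    a, _ = _expand_secret(seed)
    return _compress(_base_mult(a))


def sign(seed: bytes, message: bytes) -> bytes:
    """RFC 8032 Ed25519 signature (64 bytes), deterministic in the inputs."""
    a, prefix = _expand_secret(seed)
    public = _compress(_base_mult(a))
    r = int.from_bytes(hashlib.sha512(prefix + message).digest(), "little") % L
    r_enc = _compress(_base_mult(r))
    k = int.from_bytes(hashlib.sha512(r_enc + public + message).digest(), "little") % L
    s = (r + k * a) % L
    return r_enc + s.to_bytes(32, "little")


def verify(public: bytes, message: bytes, signature: bytes) -> bool:
    """Check a signature; returns False on any malformation or mismatch."""
    if len(signature) != 64:
        return False
    try:
        r_point = _decompress(signature[:32])
        _decompress(public)  # validates the key encoding
    except SignatureError:
        return False
    s = int.from_bytes(signature[32:], "little")
    if s >= L:
        return False
    k = int.from_bytes(
        hashlib.sha512(signature[:32] + public + message).digest(), "little"
    ) % L
    lhs = _base_mult(s)
    rhs = _point_add(r_point, _cached_mult(k, public))
    return _point_equal(lhs, rhs)


# --- Diffie-Hellman on the same curve, used by the sealed-box encryption ---

def dh_secret_scalar(seed: bytes) -> int:
    """Clamped DH scalar from a 32-byte seed (low bits cleared, so the
    cofactor subgroup is annihilated in every shared-secret computation)."""
    if len(seed) != 32:
        raise SignatureError("DH seed must be 32 bytes")
    return _clamp(hashlib.sha512(seed).digest()[:32])


def dh_public(scalar: int) -> bytes:
    return _compress(_base_mult(scalar))


def dh_shared_secret(scalar: int, peer_public: bytes, reuse_peer: bool = False) -> bytes:
    """Shared point scalar*PeerPub, compressed; symmetric in the two parties.

    Set *reuse_peer* when the same peer key recurs across many calls (a
    trial's long-lived regulator key): the multiplication table is then
    cached per point.  Leave it off for one-shot peers such as ephemeral
    sealed-box keys.
    """
    if reuse_peer:
        return _compress(_cached_mult(scalar, peer_public))
    return _compress(_scalar_mult(scalar, _decompress(peer_public)))
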