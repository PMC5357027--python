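"""Canonical, deterministic serialization of ledger content.

Everything that is hashed on the chain — transaction bodies, block headers,
contract states — goes through this encoding, so two nodes (or two runs)
that hold equal values produce identical bytes and therefore identical
digests.  The encoding is type-tagged and length-prefixed:

    Z                     null
    T / F                 booleans
    I <uleb len> <ascii>  integer, minimal decimal representation
    S <uleb len> <utf-8>  text string
    B <uleb len> <raw>    byte string
    L <uleb count> items  list, in order
    M <uleb count> k,v..  map; string keys sorted by their UTF-8 bytes

Lengths and counts are minimal unsigned LEB128.  The decoder is strict: it
rejects non-minimal varints, unsorted or duplicate map keys, non-canonical
integer spellings and trailing garbage, so the encoding is injective in
both directions — a byte string either *is* the canonical encoding of
exactly one value or it does not decode at all.  Floats are rejected
outright; clinical measurement payloads carry their numbers inside an
opaque JSON string, which is hashed as text, avoiding any float-formatting
drift between platforms.
"""

from __future__ import annotations

from typing import Any

__all__ = ["canonical_serialize", "canonical_deserialize", "SerializationError"]


class SerializationError(ValueError):
    """Raised for unserializable input or a non-canonical byte stream."""


def _encode_uleb128(n: int) -> bytes:
    if n < 0:
        raise SerializationError("negative length")
    out = bytearray()
    while True:
        byte = n & 0x7F
        n >>= 7
        if n:
            out.append(byte | 0x80)
        else:
            out.append(byte)
            return bytes(out)


def _decode_uleb128(data: bytes, pos: int) -> tuple[int, int]:
    result = 0
    shift = 0
    start = pos
    while True:
        if pos >= len(data):
            raise SerializationError("truncated varint")
        byte = data[pos]
        pos += 1
        result |= (byte & 0x7F) << shift
        if not byte & 0x80:
            # minimality: the final group must be non-zero unless the whole
            # value is a single 0x00 byte
            if byte == 0 and pos - start > 1:
                raise SerializationError("non-minimal varint")
            return result, pos
        shift += 7
        if shift > 63:
            raise SerializationError("varint too long")


def _encode(value: Any, out: bytearray) -> None:
    if value is None:
        out.append(0x5A)  # 'Z'
    elif value is True:
        out.append(0x54)  # 'T'
    elif value is False:
        out.append(0x46)  # 'F'
    elif isinstance(value, int):
        body = str(value).encode("ascii")
        out.append(0x49)  # 'I'
        out += _encode_uleb128(len(body))
        out += body
    elif isinstance(value, str):
        body = value.encode("utf-8")
        out.append(0x53)  # 'S'
        out += _encode_uleb128(len(body))
        out += body
    elif isinstance(value, (bytes, bytearray)):
        out.append(0x42)  # 'B'
        out += _encode_uleb128(len(value))
        out += bytes(value)
    elif isinstance(value, (list, tuple)):
        out.append(0x4C)  # 'L'
        out += _encode_uleb128(len(value))
        for item in value:
            _encode(item, out)
    elif isinstance(value, dict):
        keys = list(value.keys())
        for k in keys:
            if not isinstance(k, str):
                raise SerializationError(f"map keys must be strings, got {type(k).__name__}")
        encoded_keys = sorted((k.encode("utf-8"), k) for k in keys)
        if len({ek for ek, _ in encoded_keys}) != len(encoded_keys):
            raise SerializationError("duplicate map keys")
        out.append(0x4D)  # 'M'
        out += _encode_uleb128(len(keys))
        for _, k in encoded_keys:
            _encode(k, out)
            _encode(value[k], out)
    elif isinstance(value, float):
        raise SerializationError("floats are not permitted in hashed content")
    else:
        raise SerializationError(f"unserializable type {type(value).__name__}")


def canonical_serialize(value: Any) -> bytes:
    """Encode *value* deterministically; equal values give identical bytes."""
    out = bytearray()
    _encode(value, out)
    return bytes(out)


_INT_CANON_OK = frozenset(b"0123456789")


def _decode(data: bytes, pos: int) -> tuple[Any, int]:
    if pos >= len(data):
        raise SerializationError("truncated stream")
    tag = data[pos]
    pos += 1
    if tag == 0x5A:
        return None, pos
    if tag == 0x54:
        return True, pos
    if tag == 0x46:
        return False, pos
    if tag == 0x49:
        length, pos = _decode_uleb128(data, pos)
        body = data[pos : pos + length]
        if len(body) != length:
            raise SerializationError("truncated integer")
        pos += length
        text = body.decode("ascii", errors="strict") if all(
            c in _INT_CANON_OK or c == 0x2D for c in body
        ) else None
        if not text:
            raise SerializationError("bad integer body")
        try:
            n = int(text)
        except ValueError as exc:
            raise SerializationError("bad integer body") from exc
        if str(n).encode("ascii") != body:
            raise SerializationError("non-canonical integer")
        return n, pos
    if tag == 0x53:
        length, pos = _decode_uleb128(data, pos)
        body = data[pos : pos + length]
        if len(body) != length:
            raise SerializationError("truncated string")
        pos += length
        try:
            return body.decode("utf-8", errors="strict"), pos
        except UnicodeDecodeError as exc:
            raise SerializationError("invalid utf-8") from exc
    if tag == 0x42:
        length, pos = _decode_uleb128(data, pos)
        body = data[pos : pos + length]
        if len(body) != length:
            raise SerializationError("truncated bytes")
        return bytes(body), pos + length
    if tag == 0x4C:
        count, pos = _decode_uleb128(data, pos)
        items = []
        for _ in range(count):
            item, pos = _decode(data, pos)
            items.append(item)
        return items, pos
    if tag == 0x4D:
        count, pos = _decode_uleb128(data, pos)
        result: dict[str, Any] = {}
        prev_key: bytes | None = None
        for _ in range(count):
            key, pos = _decode(data, pos)
            if not isinstance(key, str):
                raise SerializationError("map key is not a string")
            key_bytes = key.encode("utf-8")
            if prev_key is not None and key_bytes <= prev_key:
                raise SerializationError("map keys not strictly sorted")
            prev_key = key_bytes
            value, pos = _decode(data, pos)
            result[key] = value
        return result, pos
    raise SerializationError(f"unknown tag 0x{tag:02x}")


def canonical_deserialize(data: bytes) -> Any:
    """Strictly decode bytes produced by :func:`canonical_serialize`.

    Raises :class:`SerializationError` on any deviation from canonical form,
    so ``canonical_serialize(canonical_deserialize(b)) == b`` whenever the
    call succeeds.
    """
    value, pos = _decode(data, 0)
    if pos != len(data):
        raise SerializationError("trailing bytes after value")
    return value
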