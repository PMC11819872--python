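"""Authenticated, compressed telemetry envelopes with a bit-exact frame.

Alert messages are DEFLATE-compressed, then sealed with AES-128-GCM under
a 16-byte pre-shared squad key; the sender id and a per-sender monotone
sequence number are bound as associated data, so neither can be swapped
without breaking the tag.  Replay protection is a transport concern (the
base station checks sequence monotonicity); decryption itself accepts any
authentic envelope.

Wire format (big-endian)::

    magic 0x5356 | version 0x01 | len(sender) 1B | sender UTF-8
    | seq 8B | nonce 12B | len(ciphertext) 4B | ciphertext | tag 16B
"""

from __future__ import annotations

import os
import struct
import zlib
from dataclasses import dataclass

from ._aes import AuthenticationError, gcm_decrypt, gcm_encrypt

__all__ = [
    "KeyConfig",
    "SecureEnvelope",
    "KeyLengthError",
    "TamperError",
    "FrameError",
    "encrypt_message",
    "decrypt_message",
    "frame",
    "unframe",
]

MAGIC = b"\x53\x56"
VERSION = 1
NONCE_LEN = 12
TAG_LEN = 16


class KeyLengthError(ValueError):
    """The pre-shared key is not exactly 16 bytes."""


class TamperError(Exception):
    """Authentication failed: ciphertext, tag, AAD or key do not match."""


class FrameError(ValueError):
    """Malformed wire frame (bad magic, version, or truncated layout)."""


@dataclass(frozen=True)
class KeyConfig:
    """A 16-byte pre-shared squad key with an identifier."""

    key: bytes
    key_id: str = "squad-key"

    def __post_init__(self) -> None:
        if len(self.key) != 16:
            raise KeyLengthError(f"key must be exactly 16 bytes, got {len(self.key)}")

    @classmethod
    def from_hex(cls, key_hex: str, key_id: str = "squad-key") -> "KeyConfig":
        try:
            raw = bytes.fromhex(key_hex)
        except ValueError as exc:
            raise KeyLengthError(f"key_hex is not valid hex: {exc}") from exc
        return cls(key=raw, key_id=key_id)


@dataclass(frozen=True)
class SecureEnvelope:
    """One sealed message unit: fresh nonce, ciphertext and GCM tag."""

    sender_id: str
    seq: int
    nonce: bytes
    ciphertext: bytes
    tag: bytes


def _aad(sender_id: str, seq: int) -> bytes:
    return sender_id.encode() + b"|" + struct.pack(">Q", seq)


def encrypt_message(
    plaintext: bytes,
    key: KeyConfig,
    sender_id: str,
    seq: int,
    nonce_source=None,
) -> SecureEnvelope:
    """Compress and seal ``plaintext`` into a :class:`SecureEnvelope`.

    A fresh random 12-byte nonce is drawn per message (``nonce_source``
    may supply a deterministic byte source for reproducible simulations;
    it must never repeat a nonce under one key).
    """
    if not plaintext:
        raise ValueError("plaintext must be non-empty")
    nonce = (nonce_source or os.urandom)(NONCE_LEN)
    if len(nonce) != NONCE_LEN:
        raise ValueError(f"nonce source must yield {NONCE_LEN} bytes")
    compressed = zlib.compress(plaintext)
    ciphertext, tag = gcm_encrypt(key.key, nonce, compressed, _aad(sender_id, seq))
    return SecureEnvelope(sender_id=sender_id, seq=seq, nonce=nonce, ciphertext=ciphertext, tag=tag)


def decrypt_message(envelope: SecureEnvelope, key: KeyConfig) -> bytes:
    """Authenticate, decrypt and decompress an envelope.

    Any modification of nonce, ciphertext, tag, sender id or sequence
    number raises :class:`TamperError`; nothing is returned on failure.
    """
    try:
        compressed = gcm_decrypt(
            key.key, envelope.nonce, envelope.ciphertext, envelope.tag,
            _aad(envelope.sender_id, envelope.seq),
        )
    except AuthenticationError as exc:
        raise TamperError("envelope failed authentication") from exc
    try:
        return zlib.decompress(compressed)
    except zlib.error as exc:  # authenticated but undecodable: corrupt at rest
        raise FrameError(f"authenticated payload failed to decompress: {exc}") from exc


def frame(envelope: SecureEnvelope) -> bytes:
    """Serialize an envelope to the length-prefixed wire layout."""
    sender = envelope.sender_id.encode()
    if len(sender) > 255:
        raise FrameError("sender_id exceeds 255 UTF-8 bytes")
    return b"".join(
        [
            MAGIC,
            bytes([VERSION, len(sender)]),
            sender,
            struct.pack(">Q", envelope.seq),
            envelope.nonce,
            struct.pack(">I", len(envelope.ciphertext)),
            envelope.ciphertext,
            envelope.tag,
        ]
    )


def unframe(data: bytes) -> SecureEnvelope:
    """Parse a wire frame back into an envelope; strict about layout."""
    if len(data) < 4 or data[:2] != MAGIC:
        raise FrameError("bad magic")
    if data[2] != VERSION:
        raise FrameError(f"unsupported frame version {data[2]}")
    sender_len = data[3]
    pos = 4
    if len(data) < pos + sender_len + 8 + NONCE_LEN + 4:
        raise FrameError("truncated frame header")
    sender = data[pos : pos + sender_len].decode()
    pos += sender_len
    (seq,) = struct.unpack_from(">Q", data, pos)
    pos += 8
    nonce = data[pos : pos + NONCE_LEN]
    pos += NONCE_LEN
    (ct_len,) = struct.unpack_from(">I", data, pos)
    pos += 4
    if len(data) != pos + ct_len + TAG_LEN:
        raise FrameError("frame length does not match declared ciphertext length")
    ciphertext = data[pos : pos + ct_len]
    tag = data[pos + ct_len :]
    return SecureEnvelope(sender_id=sender, seq=seq, nonce=nonce, ciphertext=ciphertext, tag=tag)
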