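"""AES-128 and GCM primitives in pure Python.

Self-contained implementation of the AES-128 block cipher (encryption
direction only — GCM needs nothing else) and the GCM authenticated mode
with a 12-byte nonce and 16-byte tag.  The S-box and the round T-tables
are derived algebraically at import time from the GF(2^8) arithmetic that
defines them, and GHASH uses per-key 8-bit lookup tables, so throughput
is adequate for telemetry-sized messages.

Correctness is pinned by the standard known-answer vectors in the test
suite.  This module is not hardened against side channels; it protects
confidentiality and integrity of simulated field telemetry, not secrets
on shared hardware.
"""

from __future__ import annotations

import hmac

__all__ = ["aes128_encrypt_block", "expand_key", "gcm_encrypt", "gcm_decrypt", "AuthenticationError"]


class AuthenticationError(Exception):
    """GCM tag verification failed: the message was tampered with or the key is wrong."""


# --- GF(2^8) tables -----------------------------------------------------------

def _build_sbox() -> list[int]:
    # exp/log tables over GF(2^8) with generator 0x03
    exp = [0] * 510
    log = [0] * 256
    x = 1
    for i in range(255):
        exp[i] = x
        log[x] = i
        # multiply by 0x03 = x * 2 ^ x
        x ^= (x << 1) ^ (0x11B if x & 0x80 else 0)
        x &= 0xFF
    for i in range(255, 510):
        exp[i] = exp[i - 255]
    sbox = [0] * 256
    for b in range(256):
        inv = 0 if b == 0 else exp[255 - log[b]]
        s = inv
        for _ in range(4):
            inv = ((inv << 1) | (inv >> 7)) & 0xFF
            s ^= inv
        sbox[b] = s ^ 0x63
    return sbox


_SBOX = _build_sbox()


def _xtime(a: int) -> int:
    a <<= 1
    return (a ^ 0x11B) & 0xFF if a & 0x100 else a


def _build_ttables() -> tuple[list[int], list[int], list[int], list[int]]:
    t0, t1, t2, t3 = [], [], [], []
    for b in range(256):
        s = _SBOX[b]
        s2 = _xtime(s)
        s3 = s2 ^ s
        w = (s2 << 24) | (s << 16) | (s << 8) | s3
        t0.append(w)
        t1.append(((w >> 8) | (w << 24)) & 0xFFFFFFFF)
        t2.append(((w >> 16) | (w << 16)) & 0xFFFFFFFF)
        t3.append(((w >> 24) | (w << 8)) & 0xFFFFFFFF)
    return t0, t1, t2, t3


_T0, _T1, _T2, _T3 = _build_ttables()
_RCON = [0x01, 0x02, 0x04, 0x08, 0x10, 0x20, 0x40, 0x80, 0x1B, 0x36]


def expand_key(key: bytes) -> list[int]:
    """AES-128 key schedule: 16-byte key -> 44 32-bit round-key words."""
    if len(key) != 16:
        raise ValueError(f"AES-128 key must be 16 bytes, got {len(key)}")
    w = [int.from_bytes(key[i : i + 4], "big") for i in range(0, 16, 4)]
    for i in range(4, 44):
        temp = w[i - 1]
        if i % 4 == 0:
            temp = ((temp << 8) | (temp >> 24)) & 0xFFFFFFFF  # RotWord
            temp = (
                (_SBOX[(temp >> 24) & 0xFF] << 24)
                | (_SBOX[(temp >> 16) & 0xFF] << 16)
                | (_SBOX[(temp >> 8) & 0xFF] << 8)
                | _SBOX[temp & 0xFF]
            )
            temp ^= _RCON[i // 4 - 1] << 24
        w.append(w[i - 4] ^ temp)
    return w


def aes128_encrypt_block(block: bytes, round_keys: list[int]) -> bytes:
    """Encrypt one 16-byte block with pre-expanded round keys."""
    rk = round_keys
    s0 = int.from_bytes(block[0:4], "big") ^ rk[0]
    s1 = int.from_bytes(block[4:8], "big") ^ rk[1]
    s2 = int.from_bytes(block[8:12], "big") ^ rk[2]
    s3 = int.from_bytes(block[12:16], "big") ^ rk[3]
    for rnd in range(1, 10):
        k = 4 * rnd
        t0 = _T0[s0 >> 24] ^ _T1[(s1 >> 16) & 0xFF] ^ _T2[(s2 >> 8) & 0xFF] ^ _T3[s3 & 0xFF] ^ rk[k]
        t1 = _T0[s1 >> 24] ^ _T1[(s2 >> 16) & 0xFF] ^ _T2[(s3 >> 8) & 0xFF] ^ _T3[s0 & 0xFF] ^ rk[k + 1]
        t2 = _T0[s2 >> 24] ^ _T1[(s3 >> 16) & 0xFF] ^ _T2[(s0 >> 8) & 0xFF] ^ _T3[s1 & 0xFF] ^ rk[k + 2]
        t3 = _T0[s3 >> 24] ^ _T1[(s0 >> 16) & 0xFF] ^ _T2[(s1 >> 8) & 0xFF] ^ _T3[s2 & 0xFF] ^ rk[k + 3]
        s0, s1, s2, s3 = t0, t1, t2, t3
    out = bytearray(16)
    for i, (a, b, c, d) in enumerate(((s0, s1, s2, s3), (s1, s2, s3, s0), (s2, s3, s0, s1), (s3, s0, s1, s2))):
        w = (
            (_SBOX[a >> 24] << 24)
            | (_SBOX[(b >> 16) & 0xFF] << 16)
            | (_SBOX[(c >> 8) & 0xFF] << 8)
            | _SBOX[d & 0xFF]
        ) ^ rk[40 + i]
        out[4 * i : 4 * i + 4] = w.to_bytes(4, "big")
    return bytes(out)


# --- GHASH --------------------------------------------------------------------

_R = 0xE1000000000000000000000000000000


def _gf_mult(x: int, y: int) -> int:
    """Carry-less multiplication in GF(2^128) with the GCM bit order."""
    z = 0
    v = x
    for i in range(127, -1, -1):
        if (y >> i) & 1:
            z ^= v
        v = (v >> 1) ^ _R if v & 1 else v >> 1
    return z


def _ghash_tables(h: int) -> list[list[int]]:
    """Per-byte-position lookup tables for multiplication by H."""
    tables = []
    t = [_gf_mult(b << 120, h) for b in range(256)]
    tables.append(t)
    for _pos in range(1, 16):
        prev = tables[-1]
        t = []
        for v in prev:
            for _ in range(8):  # multiply by x^8: shift right with reduction
                v = (v >> 1) ^ _R if v & 1 else v >> 1
            t.append(v)
        tables.append(t)
    return tables


class _Gcm:
    """AES-128-GCM context for one key (tables cached)."""

    def __init__(self, key: bytes):
        self.rk = expand_key(key)
        h = int.from_bytes(aes128_encrypt_block(b"\x00" * 16, self.rk), "big")
        self.htab = _ghash_tables(h)

    def _ghash(self, data: bytes) -> int:
        if len(data) % 16:
            raise ValueError("GHASH input must be block-aligned")
        y = 0
        htab = self.htab
        for off in range(0, len(data), 16):
            y ^= int.from_bytes(data[off : off + 16], "big")
            z = 0
            for pos in range(16):
                z ^= htab[pos][(y >> (120 - 8 * pos)) & 0xFF]
            y = z
        return y

    def _ctr(self, nonce: bytes, data: bytes) -> bytes:
        out = bytearray()
        ctr = int.from_bytes(nonce + b"\x00\x00\x00\x01", "big")
        for off in range(0, len(data), 16):
            ctr = (ctr & ~0xFFFFFFFF) | ((ctr + 1) & 0xFFFFFFFF)
            ks = aes128_encrypt_block(ctr.to_bytes(16, "big"), self.rk)
            chunk = data[off : off + 16]
            out.extend(bytes(a ^ b for a, b in zip(chunk, ks)))
        return bytes(out)

    def _tag(self, nonce: bytes, aad: bytes, ciphertext: bytes) -> bytes:
        def pad(b: bytes) -> bytes:
            return b + b"\x00" * (-len(b) % 16)

        lengths = (len(aad) * 8).to_bytes(8, "big") + (len(ciphertext) * 8).to_bytes(8, "big")
        s = self._ghash(pad(aad) + pad(ciphertext) + lengths)
        j0 = nonce + b"\x00\x00\x00\x01"
        ek = aes128_encrypt_block(j0, self.rk)
        return bytes(a ^ b for a, b in zip(s.to_bytes(16, "big"), ek))


# Building a _Gcm context (key schedule + GHASH tables) costs tens of
# milliseconds in pure Python; telemetry reuses one squad key for many
# messages, so contexts are cached per key.
_CTX_CACHE: dict[bytes, _Gcm] = {}


def _context(key: bytes) -> _Gcm:
    ctx = _CTX_CACHE.get(key)
    if ctx is None:
        if len(_CTX_CACHE) >= 32:
            _CTX_CACHE.pop(next(iter(_CTX_CACHE)))
        ctx = _CTX_CACHE[key] = _Gcm(key)
    return ctx


def gcm_encrypt(key: bytes, nonce: bytes, plaintext: bytes, aad: bytes = b"") -> tuple[bytes, bytes]:
    """AES-128-GCM: returns (ciphertext, 16-byte tag)."""
    if len(nonce) != 12:
        raise ValueError(f"GCM nonce must be 12 bytes, got {len(nonce)}")
    ctx = _context(key)
    ct = ctx._ctr(nonce, plaintext)
    return ct, ctx._tag(nonce, aad, ct)


def gcm_decrypt(key: bytes, nonce: bytes, ciphertext: bytes, tag: bytes, aad: bytes = b"") -> bytes:
    """Authenticate then decrypt; raises :class:`AuthenticationError` on any tamper."""
    if len(nonce) != 12:
        raise ValueError(f"GCM nonce must be 12 bytes, got {len(nonce)}")
    ctx = _context(key)
    expected = ctx._tag(nonce, aad, ciphertext)
    if not hmac.compare_digest(expected, tag):
        raise AuthenticationError("GCM authentication failed")
    return ctx._ctr(nonce, ciphertext)
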