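"""Secure channel: cipher known answers, envelope contracts, wire frame."""

import json
import os

import pytest

from vitalfield._aes import aes128_encrypt_block, expand_key, gcm_decrypt, gcm_encrypt
from vitalfield.secure import (
    FrameError,
    KeyConfig,
    KeyLengthError,
    SecureEnvelope,
    TamperError,
    decrypt_message,
    encrypt_message,
    frame,
    unframe,
)


class TestCipherKnownAnswers:
    """Frozen standard test vectors for the block cipher and GCM mode."""

    def test_aes128_block_vector(self):
        rk = expand_key(bytes.fromhex("000102030405060708090a0b0c0d0e0f"))
        ct = aes128_encrypt_block(bytes.fromhex("00112233445566778899aabbccddeeff"), rk)
        assert ct.hex() == "69c4e0d86a7b0430d8cdb78070b4c55a"

    def test_aes128_zero_vector(self):
        rk = expand_key(bytes(16))
        assert aes128_encrypt_block(bytes(16), rk).hex() == "66e94bd4ef8a2c3b884cfa59ca342b2e"

    def test_gcm_empty_plaintext_vector(self):
        ct, tag = gcm_encrypt(bytes(16), bytes(12), b"")
        assert ct == b""
        assert tag.hex() == "58e2fccefa7e3061367f1d57a4e7455a"

    def test_gcm_single_block_vector(self):
        ct, tag = gcm_encrypt(bytes(16), bytes(12), bytes(16))
        assert ct.hex() == "0388dace60b6a392f328c2b971b2fe78"
        assert tag.hex() == "ab6e47d42cec13bdf53a67b21257bddf"

    def test_gcm_rejects_bad_tag(self):
        ct, tag = gcm_encrypt(bytes(16), bytes(12), b"payload payload!")
        from vitalfield._aes import AuthenticationError

        with pytest.raises(AuthenticationError):
            gcm_decrypt(bytes(16), bytes(12), ct, bytes(16))


class TestKeyConfig:
    @pytest.mark.parametrize("n", [15, 17, 32, 0])
    def test_non_16_byte_keys_rejected(self, n):
        with pytest.raises(KeyLengthError):
            KeyConfig(key=bytes(n))

    def test_hex_loading(self):
        key = KeyConfig.from_hex("00112233445566778899aabbccddeeff")
        assert len(key.key) == 16
        with pytest.raises(KeyLengthError):
            KeyConfig.from_hex("0011223344")


class TestEnvelope:
    def test_round_trip_on_random_payloads(self, squad_key):
        rng = os.urandom
        for i in range(100):
            payload = rng(1 + (i * 37) % 512)
            env = encrypt_message(payload, squad_key, "N01", seq=i + 1)
            assert decrypt_message(env, squad_key) == payload

    def test_round_trip_64_kib(self, squad_key):
        payload = os.urandom(65536)
        env = encrypt_message(payload, squad_key, "N01", seq=1)
        assert decrypt_message(env, squad_key) == payload

    def test_empty_plaintext_rejected(self, squad_key):
        with pytest.raises(ValueError, match="non-empty"):
            encrypt_message(b"", squad_key, "N01", seq=1)

    def test_compression_before_encryption_shrinks_repetitive_payloads(self, squad_key):
        payload = b"HR=80;SPO2=98;RESP=16;" * 500  # ~10 KiB, highly repetitive
        env = encrypt_message(payload, squad_key, "N01", seq=1)
        assert len(env.ciphertext) < len(payload)

    def test_wrong_key_of_correct_length_is_tamper_not_garbage(self, squad_key):
        env = encrypt_message(b"alert", squad_key, "N01", seq=1)
        other = KeyConfig(key=bytes(16))
        with pytest.raises(TamperError):
            decrypt_message(env, other)

    def test_associated_data_binds_sender_and_seq(self, squad_key):
        env = encrypt_message(b"alert", squad_key, "N01", seq=5)
        forged_sender = SecureEnvelope("N02", env.seq, env.nonce, env.ciphertext, env.tag)
        forged_seq = SecureEnvelope(env.sender_id, 6, env.nonce, env.ciphertext, env.tag)
        for forged in (forged_sender, forged_seq):
            with pytest.raises(TamperError):
                decrypt_message(forged, squad_key)

    def test_exhaustive_single_bit_tamper_detection(self, squad_key):
        env = encrypt_message(os.urandom(32), squad_key, "N01", seq=1)
        for field in ("ciphertext", "tag"):
            raw = bytearray(getattr(env, field))
            for byte in range(len(raw)):
                for bit in range(8):
                    raw[byte] ^= 1 << bit
                    broken = SecureEnvelope(
                        env.sender_id, env.seq, env.nonce,
                        bytes(raw) if field == "ciphertext" else env.ciphertext,
                        bytes(raw) if field == "tag" else env.tag,
                    )
                    with pytest.raises(TamperError):
                        decrypt_message(broken, squad_key)
                    raw[byte] ^= 1 << bit

    def test_no_plaintext_substring_leaks_into_ciphertext(self, squad_key):
        snapshot = json.dumps(
            {"node_id": "N03", "hr": 128.4, "spo2": 88.1, "resp": 27.9, "pulse": 126.0,
             "x": 41.2, "y": 77.8}
        ).encode()
        probes = [snapshot, b'"hr":', b'"node_id"', b"N03"]
        for seq in range(1, 1001):
            env = encrypt_message(snapshot, squad_key, "N03", seq=seq)
            blob = env.ciphertext + env.tag
            assert all(p not in blob for p in probes)

    def test_nonce_uniqueness_policy(self, squad_key):
        # the envelope layer draws 12 random bytes per message; at 10^5
        # draws a collision would indicate a broken source
        seen = {os.urandom(12) for _ in range(100_000)}
        assert len(seen) == 100_000
        envs = [encrypt_message(b"x", squad_key, "N01", seq=i) for i in range(1, 501)]
        nonces = {e.nonce for e in envs}
        assert len(nonces) == len(envs)

    def test_replay_is_accepted_by_decrypt(self, squad_key):
        """Replay rejection is the transport's job; decrypt only authenticates."""
        env = encrypt_message(b"alert", squad_key, "N01", seq=9)
        assert decrypt_message(env, squad_key) == b"alert"
        assert decrypt_message(env, squad_key) == b"alert"


class TestFrame:
    def make_envelope(self, n=33):
        return SecureEnvelope("NodeA", 77, os.urandom(12), os.urandom(n), os.urandom(16))

    def test_round_trip_identity(self):
        for n in (1, 16, 33, 1024):
            env = self.make_envelope(n)
            assert unframe(frame(env)) == env

    def test_total_length_closed_form(self):
        env = self.make_envelope(33)
        expected = 2 + 1 + (1 + len(env.sender_id)) + 8 + 12 + 4 + 33 + 16
        assert len(frame(env)) == expected

    def test_truncation_by_one_byte_is_rejected(self):
        data = frame(self.make_envelope())
        with pytest.raises(FrameError):
            unframe(data[:-1])

    def test_bad_magic_and_version_rejected(self):
        data = bytearray(frame(self.make_envelope()))
        bad_magic = b"XX" + bytes(data[2:])
        with pytest.raises(FrameError, match="magic"):
            unframe(bad_magic)
        data[2] = 99
        with pytest.raises(FrameError, match="version"):
            unframe(bytes(data))

    def test_frame_starts_with_magic_0x5356(self):
        assert frame(self.make_envelope())[:2] == b"\x53\x56"
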