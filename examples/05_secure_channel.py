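"""Seal, frame, tamper with, and reject a telemetry alert.

Alerts are DEFLATE-compressed and AES-128-GCM-encrypted under a 16-byte
pre-shared squad key; the sender id and sequence number ride as
authenticated associated data, and the frame is a fixed binary layout.
"""

import json

from vitalfield import KeyConfig, encrypt_message, decrypt_message
from vitalfield.secure import SecureEnvelope, TamperError, frame, unframe

key = KeyConfig.from_hex("00112233445566778899aabbccddeeff")
alert = json.dumps(
    {"node_id": "N04", "hr": 131.2, "spo2": 87.4, "resp": 27.9, "pulse": 129.8,
     "state": "abnormal", "x": 41.2, "y": 77.8}
).encode()

env = encrypt_message(alert, key, sender_id="N04", seq=17)
wire = frame(env)
print(f"plaintext {len(alert)} B -> ciphertext {len(env.ciphertext)} B "
      f"(compressed before encryption), frame {len(wire)} B")
print(f"frame magic/version: {wire[:3].hex()}  nonce: {env.nonce.hex()}")

received = unframe(wire)
print("round trip ok:", decrypt_message(received, key) == alert)

flipped = bytearray(env.ciphertext)
flipped[0] ^= 0x01
broken = SecureEnvelope(env.sender_id, env.seq, env.nonce, bytes(flipped), env.tag)
try:
    decrypt_message(broken, key)
except TamperError as exc:
    print(f"single flipped bit -> rejected: {exc}")

impostor = SecureEnvelope("N99", env.seq, env.nonce, env.ciphertext, env.tag)
try:
    decrypt_message(impostor, key)
except TamperError:
    print("swapped sender id -> rejected: identity is authenticated, not just the payload")
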