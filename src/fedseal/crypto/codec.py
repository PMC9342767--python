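"""Encrypt-then-MAC authenticated encryption for weight exchange.

The on-wire object is ``iv || body || tag`` where ``body`` is the
AES-256-CBC encryption of the payload under the encryption key and
``tag`` is HMAC-SHA512 over ``iv || body`` under an *independent*
authentication key.  Covering the IV with the MAC is essential: the
classic CBC malleability attack XORs a chosen mask into the IV to flip
bits of the first plaintext block, and an IV left outside the tag would
leave exactly that surface open.  Verification is constant-time and
happens strictly before any decryption, so no plaintext-dependent
signal ever escapes from a forged ciphertext.

:func:`raw_cbc_encrypt` / :func:`raw_cbc_decrypt` expose the
*unauthenticated* CBC baseline, and :func:`cbc_iv_flip_attack` mounts
the malleability attack against it, for demonstration and testing.
"""

from __future__ import annotations

import hmac
import hashlib
import secrets
from dataclasses import dataclass

from . import aes

__all__ = [
    "ENC_KEY_BYTES",
    "MAC_KEY_BYTES",
    "TAG_BYTES",
    "IV_BYTES",
    "SymmetricKeyPair",
    "AuthCiphertext",
    "IntegrityError",
    "kgen",
    "aead_encrypt",
    "aead_decrypt",
    "raw_cbc_encrypt",
    "raw_cbc_decrypt",
    "cbc_iv_flip_attack",
]

ENC_KEY_BYTES = 32  # AES-256
MAC_KEY_BYTES = 64  # HMAC-SHA512 block-sized key
TAG_BYTES = 64      # full SHA-512 output, untruncated
IV_BYTES = 16


class IntegrityError(Exception):
    """Authentication-tag mismatch: the ciphertext was not produced by a key holder.

    In the protocol this is the signal that the parameter server (or the
    channel) modified the stored ciphertext.  The exception deliberately
    carries no plaintext material.
    """


@dataclass(frozen=True)
class SymmetricKeyPair:
    """Independent encryption and authentication keys, K = (Ke, Ka)."""

    enc_key: bytes
    mac_key: bytes

    def __post_init__(self) -> None:
        if len(self.enc_key) != ENC_KEY_BYTES:
            raise ValueError(f"enc_key must be {ENC_KEY_BYTES} bytes")
        if len(self.mac_key) != MAC_KEY_BYTES:
            raise ValueError(f"mac_key must be {MAC_KEY_BYTES} bytes")


@dataclass(frozen=True)
class AuthCiphertext:
    """IV + CBC body + HMAC tag; the object E stored on the parameter server."""

    iv: bytes
    body: bytes
    tag: bytes

    def __post_init__(self) -> None:
        if len(self.iv) != IV_BYTES:
            raise ValueError("iv must be 16 bytes")
        if not self.body or len(self.body) % 16:
            raise ValueError("body must be a non-empty multiple of 16 bytes")
        if len(self.tag) != TAG_BYTES:
            raise ValueError(f"tag must be {TAG_BYTES} bytes")

    @property
    def nbytes(self) -> int:
        return IV_BYTES + len(self.body) + TAG_BYTES


def kgen(security_parameter: int = 256) -> SymmetricKeyPair:
    """Generate a fresh key pair from the OS randomness source.

    Both keys are drawn independently and uniformly; only the 256-bit
    security level is supported.
    """
    if security_parameter != 256:
        raise ValueError("only security_parameter=256 is supported")
    return SymmetricKeyPair(
        enc_key=secrets.token_bytes(ENC_KEY_BYTES),
        mac_key=secrets.token_bytes(MAC_KEY_BYTES),
    )


def _mac(mac_key: bytes, iv: bytes, body: bytes) -> bytes:
    return hmac.new(mac_key, iv + body, hashlib.sha512).digest()


def aead_encrypt(key: SymmetricKeyPair, plaintext: bytes) -> AuthCiphertext:
    """Encrypt-then-MAC: CBC-encrypt under a fresh random IV, then tag iv||body."""
    if not plaintext:
        raise ValueError("plaintext must be non-empty")
    iv = aes.random_iv()
    body = aes.cbc_encrypt(key.enc_key, iv, plaintext)
    return AuthCiphertext(iv=iv, body=body, tag=_mac(key.mac_key, iv, body))


def aead_decrypt(key: SymmetricKeyPair, ct: AuthCiphertext) -> bytes:
    """Verify the tag (constant time) and only then decrypt.

    Raises
    ------
    IntegrityError
        If the tag does not verify.  Padding errors after a valid tag
        cannot occur for honestly produced ciphertexts and are treated
        as fatal (RuntimeError) rather than folded into IntegrityError.
    """
    expected = _mac(key.mac_key, ct.iv, ct.body)
    if not hmac.compare_digest(expected, ct.tag):
        raise IntegrityError("authentication tag mismatch")
    try:
        return aes.cbc_decrypt(key.enc_key, ct.iv, ct.body)
    except aes.PaddingError as exc:  # pragma: no cover - unreachable by construction
        raise RuntimeError("padding failure after a valid tag") from exc


def raw_cbc_encrypt(enc_key: bytes, plaintext: bytes, iv: bytes | None = None) -> tuple[bytes, bytes]:
    """Unauthenticated AES-256-CBC (the malleable baseline). Returns (iv, body)."""
    iv = aes.random_iv() if iv is None else iv
    return iv, aes.cbc_encrypt(enc_key, iv, plaintext)


def raw_cbc_decrypt(enc_key: bytes, iv: bytes, body: bytes) -> bytes:
    """Decrypt unauthenticated CBC; malformed padding raises PaddingError."""
    return aes.cbc_decrypt(enc_key, iv, body)


def cbc_iv_flip_attack(iv: bytes, body: bytes, r: bytes) -> tuple[bytes, bytes]:
    """The CBC malleability attack: replace IV with IV xor r.

    Decrypting ``(iv ^ r, body)`` yields the original first plaintext
    block XORed with ``r`` while every later block is untouched — a
    server holding no key can steer the first 16 plaintext bytes at
    will.  Against the authenticated codec the same modification is
    rejected, because the tag covers the IV.
    """
    if len(r) != IV_BYTES:
        raise ValueError("mask r must be one 16-byte block")
    return bytes(a ^ b for a, b in zip(iv, r)), body
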