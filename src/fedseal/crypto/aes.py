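"""AES-256 block cipher and CBC mode, implemented in pure Python.

The implementation follows the standard Rijndael construction (byte
substitution, row shifts, column mixing over GF(2^8), and the 14-round
key schedule for 256-bit keys) and is exercised against the published
NIST reference vectors in the test suite.  It is intended for the
desk-scale weight bundles this package moves around, not for bulk
throughput; security-wise the usual caveat about table-lookup timing
side channels in pure software applies.
"""

from __future__ import annotations

import secrets

__all__ = [
    "aes256_encrypt_block",
    "aes256_decrypt_block",
    "cbc_encrypt",
    "cbc_decrypt",
    "pkcs7_pad",
    "pkcs7_unpad",
    "random_iv",
    "PaddingError",
]

BLOCK = 16


class PaddingError(ValueError):
    """Raised when PKCS#7 padding is malformed on decryption."""


def _build_sbox() -> tuple[bytes, bytes]:
    # multiplicative inverse in GF(2^8) via log/antilog tables (generator 3)
    exp = [0] * 510
    log = [0] * 256
    x = 1
    for i in range(255):
        exp[i] = x
        log[x] = i
        x ^= (x << 1) ^ (0x11B if x & 0x80 else 0)
        x &= 0xFF
    for i in range(255, 510):
        exp[i] = exp[i - 255]

    def inv(b: int) -> int:
        return 0 if b == 0 else exp[255 - log[b]]

    sbox = bytearray(256)
    for b in range(256):
        v = inv(b)
        r = 0x63
        for _ in range(5):
            r ^= v
            v = ((v << 1) | (v >> 7)) & 0xFF
        sbox[b] = r
    inv_sbox = bytearray(256)
    for b in range(256):
        inv_sbox[sbox[b]] = b
    return bytes(sbox), bytes(inv_sbox)


SBOX, INV_SBOX = _build_sbox()


def _xtime(b: int) -> int:
    return ((b << 1) ^ 0x1B) & 0xFF if b & 0x80 else b << 1


def _gmul(a: int, b: int) -> int:
    p = 0
    while b:
        if b & 1:
            p ^= a
        a = _xtime(a)
        b >>= 1
    return p


# precomputed multiplication tables for MixColumns / InvMixColumns
_MUL = {c: bytes(_gmul(c, x) for x in range(256)) for c in (2, 3, 9, 11, 13, 14)}

RCON = [0x01, 0x02, 0x04, 0x08, 0x10, 0x20, 0x40, 0x80, 0x1B, 0x36, 0x6C]


def _expand_key_256(key: bytes) -> list[list[int]]:
    """Return the 15 round keys as flat 16-byte lists (column-major words)."""
    if len(key) != 32:
        raise ValueError("AES-256 key must be 32 bytes")
    words = [list(key[4 * i : 4 * i + 4]) for i in range(8)]
    for i in range(8, 60):
        w = list(words[i - 1])
        if i % 8 == 0:
            w = w[1:] + w[:1]
            w = [SBOX[b] for b in w]
            w[0] ^= RCON[i // 8 - 1]
        elif i % 8 == 4:
            w = [SBOX[b] for b in w]
        words.append([a ^ b for a, b in zip(words[i - 8], w)])
    return [sum(words[4 * r : 4 * r + 4], []) for r in range(15)]


def _encrypt_block(state: bytearray, rks: list[list[int]]) -> bytes:
    sbox, m2, m3 = SBOX, _MUL[2], _MUL[3]
    for i in range(16):
        state[i] ^= rks[0][i]
    for rnd in range(1, 14):
        # SubBytes + ShiftRows fused
        s = [sbox[b] for b in state]
        s = [
            s[0], s[5], s[10], s[15],
            s[4], s[9], s[14], s[3],
            s[8], s[13], s[2], s[7],
            s[12], s[1], s[6], s[11],
        ]
        rk = rks[rnd]
        for c in range(4):
            a0, a1, a2, a3 = s[4 * c : 4 * c + 4]
            state[4 * c] = m2[a0] ^ m3[a1] ^ a2 ^ a3 ^ rk[4 * c]
            state[4 * c + 1] = a0 ^ m2[a1] ^ m3[a2] ^ a3 ^ rk[4 * c + 1]
            state[4 * c + 2] = a0 ^ a1 ^ m2[a2] ^ m3[a3] ^ rk[4 * c + 2]
            state[4 * c + 3] = m3[a0] ^ a1 ^ a2 ^ m2[a3] ^ rk[4 * c + 3]
    s = [sbox[b] for b in state]
    s = [
        s[0], s[5], s[10], s[15],
        s[4], s[9], s[14], s[3],
        s[8], s[13], s[2], s[7],
        s[12], s[1], s[6], s[11],
    ]
    rk = rks[14]
    return bytes(b ^ k for b, k in zip(s, rk))


def _decrypt_block(block: bytes, rks: list[list[int]]) -> bytes:
    inv, m9, m11, m13, m14 = INV_SBOX, _MUL[9], _MUL[11], _MUL[13], _MUL[14]
    s = [b ^ k for b, k in zip(block, rks[14])]
    for rnd in range(13, 0, -1):
        # InvShiftRows + InvSubBytes fused
        s = [
            s[0], s[13], s[10], s[7],
            s[4], s[1], s[14], s[11],
            s[8], s[5], s[2], s[15],
            s[12], s[9], s[6], s[3],
        ]
        s = [inv[b] for b in s]
        rk = rks[rnd]
        s = [b ^ k for b, k in zip(s, rk)]
        out = [0] * 16
        for c in range(4):
            a0, a1, a2, a3 = s[4 * c : 4 * c + 4]
            out[4 * c] = m14[a0] ^ m11[a1] ^ m13[a2] ^ m9[a3]
            out[4 * c + 1] = m9[a0] ^ m14[a1] ^ m11[a2] ^ m13[a3]
            out[4 * c + 2] = m13[a0] ^ m9[a1] ^ m14[a2] ^ m11[a3]
            out[4 * c + 3] = m11[a0] ^ m13[a1] ^ m9[a2] ^ m14[a3]
        s = out
    s = [
        s[0], s[13], s[10], s[7],
        s[4], s[1], s[14], s[11],
        s[8], s[5], s[2], s[15],
        s[12], s[9], s[6], s[3],
    ]
    s = [inv[b] for b in s]
    return bytes(b ^ k for b, k in zip(s, rks[0]))


def aes256_encrypt_block(key: bytes, block: bytes) -> bytes:
    if len(block) != BLOCK:
        raise ValueError("block must be 16 bytes")
    return _encrypt_block(bytearray(block), _expand_key_256(key))


def aes256_decrypt_block(key: bytes, block: bytes) -> bytes:
    if len(block) != BLOCK:
        raise ValueError("block must be 16 bytes")
    return _decrypt_block(block, _expand_key_256(key))


def pkcs7_pad(data: bytes) -> bytes:
    n = BLOCK - len(data) % BLOCK
    return data + bytes([n]) * n


def pkcs7_unpad(data: bytes) -> bytes:
    if not data or len(data) % BLOCK:
        raise PaddingError("ciphertext length not a multiple of the block size")
    n = data[-1]
    if not 1 <= n <= BLOCK or data[-n:] != bytes([n]) * n:
        raise PaddingError("bad PKCS#7 padding")
    return data[:-n]


def random_iv() -> bytes:
    return secrets.token_bytes(BLOCK)


def cbc_encrypt(key: bytes, iv: bytes, plaintext: bytes) -> bytes:
    """AES-256-CBC with PKCS#7 padding; returns the ciphertext body."""
    if len(iv) != BLOCK:
        raise ValueError("IV must be 16 bytes")
    rks = _expand_key_256(key)
    data = pkcs7_pad(plaintext)
    out = bytearray()
    prev = iv
    for i in range(0, len(data), BLOCK):
        blk = bytearray(b ^ p for b, p in zip(data[i : i + BLOCK], prev))
        prev = _encrypt_block(blk, rks)
        out += prev
    return bytes(out)


def cbc_decrypt(key: bytes, iv: bytes, body: bytes) -> bytes:
    """Inverse of :func:`cbc_encrypt`; raises :class:`PaddingError` on bad padding."""
    if len(iv) != BLOCK:
        raise ValueError("IV must be 16 bytes")
    if not body or len(body) % BLOCK:
        raise PaddingError("ciphertext body length not a multiple of 16")
    rks = _expand_key_256(key)
    out = bytearray()
    prev = iv
    for i in range(0, len(body), BLOCK):
        blk = body[i : i + BLOCK]
        out += bytes(b ^ p for b, p in zip(_decrypt_block(blk, rks), prev))
        prev = blk
    return pkcs7_unpad(bytes(out))
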