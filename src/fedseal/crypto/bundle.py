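"""Canonical binary serialization of named weight arrays.

A :class:`WeightBundle` is the plaintext that moves between trainers:
an ordered collection of named float32 arrays, each name prefixed with
``base/`` (the shared backbone W) or ``head/`` (a trainer's task head
V).  Entries are kept sorted by name so that serialization is
deterministic — the same weights always produce the same bytes, which
is what makes bit-exact protocol-equivalence checks meaningful.

File format (little-endian):

``FSWB`` magic, u16 version=1, u32 entry count, then per entry:
u16 name length, UTF-8 name, u8 rank, rank x u64 dims, raw IEEE-754
binary32 payload.

Ciphertext files use ``FSCT`` magic, u16 version=1, 16-byte IV,
u64 body length, body, 64-byte tag.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np

from .codec import AuthCiphertext, IV_BYTES, TAG_BYTES

__all__ = [
    "WeightBundle",
    "FormatError",
    "serialize_weights",
    "deserialize_weights",
    "serialized_nbytes",
    "write_ciphertext",
    "read_ciphertext",
]

_MAGIC = b"FSWB"
_CT_MAGIC = b"FSCT"
_VERSION = 1
_NAMESPACES = ("base/", "head/")


class FormatError(ValueError):
    """Malformed serialized data: bad magic, version, or truncation.

    Deliberately distinct from IntegrityError — a format error on
    verified plaintext indicates a software bug, not server tampering.
    """


@dataclass
class WeightBundle:
    """Ordered, named float32 weight arrays with base/ and head/ namespaces."""

    entries: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        canon: dict[str, np.ndarray] = {}
        for name in sorted(self.entries):
            arr = np.ascontiguousarray(self.entries[name], dtype=np.float32)
            if not name.startswith(_NAMESPACES):
                raise ValueError(f"entry {name!r} must be namespaced base/ or head/")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"entry {name!r} contains non-finite values")
            canon[name] = arr
        self.entries = canon

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[tuple[str, np.ndarray]]:
        return iter(self.entries.items())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WeightBundle):
            return NotImplemented
        if list(self.entries) != list(other.entries):
            return False
        return all(
            a.shape == b.shape and np.array_equal(a, b, equal_nan=True)
            for (_, a), (_, b) in zip(self, other)
        )

    @property
    def n_parameters(self) -> int:
        return int(sum(a.size for a in self.entries.values()))

    def select(self, prefix: str) -> "WeightBundle":
        """Sub-bundle of entries whose names start with *prefix*."""
        return WeightBundle({n: a for n, a in self.entries.items() if n.startswith(prefix)})

    def merge(self, other: "WeightBundle") -> "WeightBundle":
        overlap = set(self.entries) & set(other.entries)
        if overlap:
            raise ValueError(f"duplicate entries on merge: {sorted(overlap)[:3]}")
        return WeightBundle({**self.entries, **other.entries})

    @classmethod
    def from_arrays(cls, arrays: Mapping[str, np.ndarray]) -> "WeightBundle":
        return cls(dict(arrays))


def serialize_weights(bundle: WeightBundle) -> bytes:
    """Deterministic binary encoding; identical bundles give identical bytes."""
    out = bytearray()
    out += _MAGIC
    out += struct.pack("<HI", _VERSION, len(bundle))
    for name, arr in bundle:
        raw_name = name.encode("utf-8")
        out += struct.pack("<H", len(raw_name))
        out += raw_name
        out += struct.pack("<B", arr.ndim)
        out += struct.pack(f"<{arr.ndim}Q", *arr.shape)
        out += arr.tobytes(order="C")
    return bytes(out)


def serialized_nbytes(shapes: Iterable[tuple[str, tuple[int, ...]]]) -> int:
    """Exact serialized size for an entry table, without materializing arrays."""
    total = 4 + 6  # magic + version/count
    for name, shape in shapes:
        n = 1
        for d in shape:
            n *= d
        total += 2 + len(name.encode("utf-8")) + 1 + 8 * len(shape) + 4 * n
    return total


class _Reader:
    def __init__(self, data: bytes):
        self.data = data
        self.pos = 0

    def take(self, n: int) -> bytes:
        if self.pos + n > len(self.data):
            raise FormatError("truncated data")
        chunk = self.data[self.pos : self.pos + n]
        self.pos += n
        return chunk

    def unpack(self, fmt: str) -> tuple:
        return struct.unpack(fmt, self.take(struct.calcsize(fmt)))


def deserialize_weights(data: bytes) -> WeightBundle:
    """Reconstruct a bundle; fails closed (never returns a partial bundle)."""
    rd = _Reader(data)
    if rd.take(4) != _MAGIC:
        raise FormatError("bad magic: not a weight-bundle stream")
    version, count = rd.unpack("<HI")
    if version != _VERSION:
        raise FormatError(f"unsupported version {version}")
    entries: dict[str, np.ndarray] = {}
    for _ in range(count):
        (name_len,) = rd.unpack("<H")
        name = rd.take(name_len).decode("utf-8")
        (rank,) = rd.unpack("<B")
        shape = rd.unpack(f"<{rank}Q") if rank else ()
        n = 1
        for d in shape:
            n *= d
        arr = np.frombuffer(rd.take(4 * n), dtype="<f4").reshape(shape).copy()
        if name in entries:
            raise FormatError(f"duplicate entry {name!r}")
        entries[name] = arr
    if rd.pos != len(data):
        raise FormatError("trailing bytes after last entry")
    return WeightBundle(entries)


def write_ciphertext(ct: AuthCiphertext) -> bytes:
    return b"".join(
        [_CT_MAGIC, struct.pack("<H", _VERSION), ct.iv, struct.pack("<Q", len(ct.body)), ct.body, ct.tag]
    )


def read_ciphertext(data: bytes) -> AuthCiphertext:
    rd = _Reader(data)
    if rd.take(4) != _CT_MAGIC:
        raise FormatError("bad magic: not a ciphertext stream")
    (version,) = rd.unpack("<H")
    if version != _VERSION:
        raise FormatError(f"unsupported version {version}")
    iv = rd.take(IV_BYTES)
    (body_len,) = rd.unpack("<Q")
    body = rd.take(body_len)
    tag = rd.take(TAG_BYTES)
    if rd.pos != len(data):
        raise FormatError("trailing bytes after tag")
    return AuthCiphertext(iv=iv, body=body, tag=tag)
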