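"""Compact binary reference format (.qref).

Loading a large phased reference panel from VCF dominates start-up time, so
the panel can be converted once into this packed binary form and read back
without any VCF parsing.

Layout: an 8-byte magic (``PBQREF\\x00\\x01``) and a little-endian uint32
format version in the clear, followed by a zlib-compressed body:

* uint64 n_haps, uint64 n_sites, uint64 n_samples
* sample identifiers (newline-joined, utf-8, length-prefixed)
* variant table (tab/newline text block: chrom, pos, id, ref, alt)
* panel allele frequencies as float32[n_sites]
* the allele matrix as one padded bit-row per variant across all haplotypes

Round-trips are bit-exact (allele frequencies to float32 precision).
"""

from __future__ import annotations

import struct
import zlib
from pathlib import Path

import numpy as np

from .panel import HaplotypePanel, VariantRecord

__all__ = ["write_binary_reference", "read_binary_reference", "QrefFormatError", "MAGIC"]

MAGIC = b"PBQREF\x00\x01"
VERSION = 1


class QrefFormatError(ValueError):
    """Raised when a file is not a readable binary reference."""


def _pack_block(data: bytes) -> bytes:
    return struct.pack("<Q", len(data)) + data


class _Reader:
    def __init__(self, buf: bytes):
        self.buf = buf
        self.off = 0

    def take(self, n: int) -> bytes:
        if self.off + n > len(self.buf):
            raise QrefFormatError("truncated binary reference body")
        out = self.buf[self.off : self.off + n]
        self.off += n
        return out

    def block(self) -> bytes:
        (n,) = struct.unpack("<Q", self.take(8))
        return self.take(n)


def write_binary_reference(
    panel: HaplotypePanel,
    variants: list[VariantRecord],
    path,
    sample_ids: list[str] | None = None,
) -> None:
    """Serialise a panel + variant table to ``path``."""
    if len(variants) != panel.n_sites:
        raise ValueError("variant table length != panel sites")
    if sample_ids is None:
        sample_ids = [f"REF{i}" for i in range(panel.n_haps // 2)]
    body = bytearray()
    body += struct.pack("<QQQ", panel.n_haps, panel.n_sites, len(sample_ids))
    body += _pack_block("\n".join(sample_ids).encode())
    vtab = "\n".join(
        f"{v.chrom}\t{v.pos}\t{v.vid}\t{v.ref_allele}\t{v.alt_allele}" for v in variants
    )
    body += _pack_block(vtab.encode())
    afs = np.array([v.panel_af for v in variants], dtype="<f4")
    body += _pack_block(afs.tobytes())
    body += _pack_block(np.ascontiguousarray(panel.packed).tobytes())
    with open(path, "wb") as fh:
        fh.write(MAGIC)
        fh.write(struct.pack("<I", VERSION))
        fh.write(zlib.compress(bytes(body), level=6))


def read_binary_reference(path) -> tuple[HaplotypePanel, list[VariantRecord], list[str]]:
    """Read a binary reference; inverse of :func:`write_binary_reference`."""
    raw = Path(path).read_bytes()
    if len(raw) < len(MAGIC) + 4:
        raise QrefFormatError(f"{path}: file too short for a binary reference")
    if raw[: len(MAGIC)] != MAGIC:
        raise QrefFormatError(f"{path}: bad magic bytes (not a .qref file)")
    (version,) = struct.unpack("<I", raw[len(MAGIC) : len(MAGIC) + 4])
    if version != VERSION:
        raise QrefFormatError(f"{path}: unsupported version {version}")
    try:
        body = zlib.decompress(raw[len(MAGIC) + 4 :])
    except zlib.error as exc:
        raise QrefFormatError(f"{path}: corrupt or truncated body ({exc})") from exc
    rd = _Reader(body)
    n_haps, n_sites, _n_samples = struct.unpack("<QQQ", rd.take(24))
    sample_blob = rd.block().decode()
    sample_ids = sample_blob.split("\n") if sample_blob else []
    vtab = rd.block().decode()
    afs = np.frombuffer(rd.block(), dtype="<f4")
    if len(afs) != n_sites:
        raise QrefFormatError("allele-frequency table length mismatch")
    variants = []
    if vtab:
        for line, af in zip(vtab.split("\n"), afs):
            chrom, pos, vid, ref, alt = line.split("\t")
            variants.append(VariantRecord(chrom, int(pos), vid, ref, alt, float(af)))
    if len(variants) != n_sites:
        raise QrefFormatError("variant table length mismatch")
    row_bytes = (n_haps + 7) // 8
    packed = np.frombuffer(rd.block(), dtype=np.uint8)
    if packed.size != n_sites * row_bytes:
        raise QrefFormatError("allele matrix size mismatch")
    panel = HaplotypePanel.from_packed(
        packed.reshape(n_sites, row_bytes).copy(), int(n_haps)
    )
    return panel, variants, sample_ids


def is_binary_reference(path) -> bool:
    """Cheap magic-byte sniff used to dispatch reference loading."""
    try:
        with open(path, "rb") as fh:
            return fh.read(len(MAGIC)) == MAGIC
    except OSError:
        return False
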