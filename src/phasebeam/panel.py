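"""Bit-packed haplotype panels and variant metadata.

A :class:`HaplotypePanel` stores a biallelic haplotype matrix (haplotypes x
sites) packed one bit per allele, one padded bit-row per *site* across all
haplotypes.  This mirrors the register-oriented representation used by fast
PBWT implementations: a site column can be handed to popcount-style rank
queries without unpacking the whole matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["VariantRecord", "HaplotypePanel"]

MISSING = -1  # sentinel for a missing allele/genotype throughout the package


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic SNV with reference-panel metadata.

    ``pos`` follows the 1-based VCF convention; all internal site indices are
    0-based and only refer to positions through these records.
    """

    chrom: str
    pos: int
    vid: str
    ref_allele: str
    alt_allele: str
    panel_af: float = float("nan")

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ValueError(
                f"ref and alt allele identical at {self.chrom}:{self.pos}"
            )
        if not np.isnan(self.panel_af) and not 0.0 <= self.panel_af <= 1.0:
            raise ValueError(f"panel_af outside [0,1] at {self.chrom}:{self.pos}")


class HaplotypePanel:
    """Biallelic haplotype matrix of N haplotypes over M sites.

    Alleles are 0/1 only.  Storage is one packed bit-row per site
    (``np.packbits`` over haplotypes, MSB first), so ``packed`` has shape
    ``(n_sites, ceil(n_haps / 8))``.

    Parameters
    ----------
    alleles:
        array-like of shape (n_haps, n_sites) with entries in {0, 1}.
    site_ids:
        optional per-site link to an external variant table (defaults to
        0..M-1).
    """

    def __init__(self, alleles, site_ids=None):
        a = np.asarray(alleles, dtype=np.uint8)
        if a.ndim != 2:
            raise ValueError("allele matrix must be 2-D (haplotypes x sites)")
        if a.size and a.max() > 1:
            raise ValueError("panel is not biallelic: alleles outside {0,1}")
        if a.shape[0] < 1:
            raise ValueError("panel needs at least one haplotype")
        self.n_haps: int = a.shape[0]
        self.n_sites: int = a.shape[1]
        # pack per site: row m holds the alleles of all haplotypes at site m
        self.packed: np.ndarray = np.packbits(a.T, axis=1) if a.size else np.zeros(
            (self.n_sites, (self.n_haps + 7) // 8), dtype=np.uint8
        )
        if site_ids is None:
            site_ids = np.arange(self.n_sites)
        self.site_ids: np.ndarray = np.asarray(site_ids)
        if self.site_ids.shape != (self.n_sites,):
            raise ValueError("site_ids must have one entry per site")

    @classmethod
    def from_packed(cls, packed: np.ndarray, n_haps: int, site_ids=None) -> "HaplotypePanel":
        """Rebuild a panel from packed per-site bit-rows (qref ingestion)."""
        packed = np.asarray(packed, dtype=np.uint8)
        obj = cls.__new__(cls)
        obj.n_haps = int(n_haps)
        obj.n_sites = packed.shape[0]
        if packed.ndim != 2 or packed.shape[1] != (n_haps + 7) // 8:
            raise ValueError("packed row width inconsistent with n_haps")
        obj.packed = packed
        obj.site_ids = (
            np.arange(obj.n_sites) if site_ids is None else np.asarray(site_ids)
        )
        return obj

    # ------------------------------------------------------------------
    def column(self, m: int) -> np.ndarray:
        """Alleles of every haplotype at site ``m`` as a (n_haps,) uint8 array."""
        return np.unpackbits(self.packed[m], count=self.n_haps)

    @property
    def matrix(self) -> np.ndarray:
        """Dense (n_haps, n_sites) uint8 allele matrix (lossless unpack)."""
        if self.n_sites == 0:
            return np.zeros((self.n_haps, 0), dtype=np.uint8)
        return np.unpackbits(self.packed, axis=1, count=self.n_haps).T.copy()

    def restrict(self, hap_idx=None, site_idx=None, flip=None) -> "HaplotypePanel":
        """Sub-panel over ``hap_idx`` rows and ``site_idx`` columns.

        ``flip`` optionally marks sites (boolean, aligned with ``site_idx``)
        whose 0/1 meaning must be complemented — used when the target cohort
        encodes a variant with ref and alt swapped relative to the panel.
        """
        mat = self.matrix
        if hap_idx is not None:
            mat = mat[np.asarray(hap_idx)]
        ids = self.site_ids
        if site_idx is not None:
            site_idx = np.asarray(site_idx)
            mat = mat[:, site_idx]
            ids = ids[site_idx]
        if flip is not None:
            flip = np.asarray(flip, dtype=bool)
            mat = mat ^ flip[np.newaxis, :]
        return HaplotypePanel(mat, site_ids=ids)

    def allele_frequencies(self) -> np.ndarray:
        """Per-site alternate (allele-1) frequency across all haplotypes."""
        if self.n_sites == 0:
            return np.zeros(0)
        ones = np.unpackbits(self.packed, axis=1, count=self.n_haps).sum(axis=1)
        return ones / self.n_haps

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"HaplotypePanel(n_haps={self.n_haps}, n_sites={self.n_sites})"
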