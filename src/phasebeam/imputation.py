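"""Imputation of reference-only sites from set-maximal matches.

Each phased target haplotype is matched against the reference PBWT over
the *shared* (typed) sites.  A reference-only site falls in a gap between
two consecutive shared sites; the haplotypes whose set-maximal match spans
that gap vote for the site's allele, weighted by match length, and their
weighted mean is the allele dosage.  Shared sites with a missing target
genotype are imputed the same way; typed, non-missing sites keep their
phased allele as a hard 0/1 dosage.  When no match spans a site the panel
allele frequency is used as the dosage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .panel import HaplotypePanel
from .pbwt import PbwtIndex, set_maximal_matches

__all__ = [
    "DosageRecord",
    "SiteStats",
    "BlockPlan",
    "impute_haplotype",
    "combine_diplotype",
    "hard_call",
    "site_r2",
    "plan_blocks",
    "apply_r2_filter",
]

log = logging.getLogger(__name__)


@dataclass
class DosageRecord:
    """Per-variant imputation output for one (diploid) sample."""

    sample_id: str
    variant_id: str
    ads: tuple[float, float]
    ds: float
    gp: tuple[float, float, float]
    hard_gt: tuple[int, int]


@dataclass
class SiteStats:
    """Per-variant cohort summary written to INFO."""

    af: float
    maf: float
    ac: int
    an: int
    panel_af: float
    r2: float
    typed: bool = False


def impute_haplotype(
    ref_index: PbwtIndex,
    ref_panel: HaplotypePanel,
    site_map: np.ndarray,
    target_hap,
    panel_af: np.ndarray | None = None,
    weighting: str = "length",
    shared_panel: HaplotypePanel | None = None,
) -> np.ndarray:
    """Allele dosage at every reference site for one phased haplotype.

    Parameters
    ----------
    ref_index:
        PBWT of the full reference panel restricted to the shared sites.
    ref_panel:
        the full reference panel over *all* sites (allele source).
    site_map:
        global reference site index of each shared site, strictly
        increasing.
    target_hap:
        phased alleles over the shared sites; -1 marks deferred (missing)
        genotypes, which are imputed like reference-only sites.
    panel_af:
        fallback dosage where no match spans a site (defaults to the
        panel's own frequencies).
    weighting:
        "length" weights each spanning match by its shared-site length,
        "uniform" weights all spanning matches equally.
    shared_panel:
        the shared-site slice of the panel if the caller already has it
        (avoids re-slicing); must agree with ``ref_index``.
    """
    if weighting not in ("length", "uniform"):
        raise ValueError(f"unknown weighting {weighting!r}")
    site_map = np.asarray(site_map)
    s_count = site_map.shape[0]
    if s_count == 0:
        raise ValueError("no shared sites; nothing to anchor imputation on")
    hap = np.asarray(target_hap, dtype=np.int16).ravel()
    if hap.shape[0] != s_count:
        raise ValueError("target haplotype length != number of shared sites")
    if panel_af is None:
        panel_af = ref_panel.allele_frequencies()

    if shared_panel is None:
        shared_panel = ref_panel.restrict(site_idx=site_map)
    matches = set_maximal_matches(ref_index, shared_panel, hap)

    n_ref_sites = ref_panel.n_sites
    dosage = np.empty(n_ref_sites, dtype=np.float64)

    all_sites = np.arange(n_ref_sites)
    is_shared = np.zeros(n_ref_sites, dtype=bool)
    is_shared[site_map] = True
    # typed, non-missing shared sites carry their phased allele verbatim
    typed_mask = hap >= 0
    dosage[site_map[typed_mask]] = hap[typed_mask]

    # group the sites still to impute by the shared-site gap they fall in:
    # gap k lies between shared sites k-1 and k (0 and S are the edges)
    ref_only = all_sites[~is_shared]
    gap_of = np.searchsorted(site_map, ref_only)
    need: dict[int, np.ndarray] = {
        int(k): ref_only[gap_of == k] for k in np.unique(gap_of)
    }
    deferred = site_map[~typed_mask]  # shared-missing, keyed by condensed index

    full_mat = ref_panel.matrix

    def weighted(sites: np.ndarray, haps: list[int], ws: list[float]) -> None:
        if not haps:
            dosage[sites] = panel_af[sites]
            return
        w = np.asarray(ws, dtype=np.float64)
        a = full_mat[np.asarray(haps)][:, sites].astype(np.float64)
        dosage[sites] = (w @ a) / w.sum()

    # spanning matches per gap: an interior gap k needs s < k < e; the edge
    # gaps only require the match to touch the terminal shared site
    for k, sites in need.items():
        haps, ws = [], []
        for mt in matches:
            covers = (
                (mt.start < k < mt.end)
                or (k == 0 and mt.start == 0)
                or (k == s_count and mt.end == s_count)
            )
            if covers:
                haps.append(mt.hap)
                ws.append(float(mt.length) if weighting == "length" else 1.0)
        weighted(sites, haps, ws)

    # deferred shared sites: matches covering the site itself
    for cond_k in np.flatnonzero(~typed_mask):
        g_site = site_map[cond_k]
        haps, ws = [], []
        for mt in matches:
            if mt.start <= cond_k < mt.end:
                haps.append(mt.hap)
                ws.append(float(mt.length) if weighting == "length" else 1.0)
        weighted(np.array([g_site]), haps, ws)

    return dosage


def combine_diplotype(d_a, d_b) -> tuple[np.ndarray, np.ndarray]:
    """Genotype dosage and genotype probabilities from two allele dosages.

    The two haplotype copies are treated as independent, so
    gp = ((1-dA)(1-dB), dA(1-dB)+dB(1-dA), dA*dB) and ds = dA + dB.
    """
    d_a = np.asarray(d_a, dtype=np.float64)
    d_b = np.asarray(d_b, dtype=np.float64)
    for d in (d_a, d_b):
        if d.size and (d.min() < 0.0 or d.max() > 1.0):
            raise ValueError("allele dosage outside [0, 1]")
    ds = d_a + d_b
    gp = np.stack(
        (
            (1 - d_a) * (1 - d_b),
            d_a * (1 - d_b) + d_b * (1 - d_a),
            d_a * d_b,
        ),
        axis=-1,
    )
    return ds, gp


def hard_call(ads) -> np.ndarray:
    """Hard genotype from allele dosages: allele 1 iff dosage > 0.5.

    An exact 0.5 ties to the reference allele (0).
    """
    d = np.asarray(ads, dtype=np.float64)
    return (d > 0.5).astype(np.int8)


def site_r2(dosages) -> float:
    """Imputation accuracy estimate at one site from haploid dosages.

    r2 = Var(d) / (p(1-p)) with the population variance and p the mean
    dosage; a monomorphic site (p(1-p) = 0) returns 0 by convention and the
    result is clamped to [0, 1].
    """
    d = np.asarray(dosages, dtype=np.float64).ravel()
    if d.size == 0:
        raise ValueError("site_r2 needs at least one dosage")
    if np.all(d == d[0]):  # constant dosages: zero variance exactly
        return 0.0
    p = d.mean()
    denom = p * (1.0 - p)
    if denom <= 0.0:
        return 0.0
    var = np.mean((d - p) ** 2)
    return float(min(1.0, max(0.0, var / denom)))


@dataclass
class BlockPlan:
    """Deterministic partition of the imputed-site list for multi-worker IO.

    Sites are split contiguously into ``n_blocks`` near-equal blocks, each
    block into chunks; workers may process chunks in any schedule (the
    canonical order is round-robin across blocks), but every chunk owns a
    fixed output slot and blocks are concatenated in order, so the output
    is byte-identical for any worker count.
    """

    blocks: list[list[range]]

    @property
    def processing_order(self) -> list[tuple[int, int]]:
        order = []
        max_chunks = max((len(b) for b in self.blocks), default=0)
        for c in range(max_chunks):
            for b, chunks in enumerate(self.blocks):
                if c < len(chunks):
                    order.append((b, c))
        return order

    def emitted_sites(self) -> np.ndarray:
        out = []
        for b in self.blocks:
            for r in b:
                out.extend(r)
        return np.asarray(out, dtype=np.int64)


def plan_blocks(n_imputed_sites: int, n_blocks: int, chunk_size: int) -> BlockPlan:
    if n_blocks < 1 or chunk_size < 1:
        raise ValueError("n_blocks and chunk_size must be >= 1")
    if n_imputed_sites == 0:
        return BlockPlan([])
    base, extra = divmod(n_imputed_sites, n_blocks)
    blocks: list[list[range]] = []
    start = 0
    for b in range(n_blocks):
        size = base + (1 if b < extra else 0)
        chunks = [
            range(s, min(s + chunk_size, start + size))
            for s in range(start, start + size, chunk_size)
        ]
        if chunks:
            blocks.append(chunks)
        start += size
    return BlockPlan(blocks)


def apply_r2_filter(records, stats, threshold) -> list:
    """Drop imputed-only entries whose r2 falls below ``threshold``.

    Typed (genotyped, non-missing) variants are never dropped.  ``records``
    and ``stats`` run in parallel; survivors keep their order.
    """
    if threshold is None:
        return list(records)
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("r2 filter threshold must lie in [0, 1]")
    out = []
    n_dropped = 0
    for rec, st in zip(records, stats):
        if not st.typed and st.r2 < threshold:
            n_dropped += 1
            continue
        out.append(rec)
    if n_dropped:
        log.info("r2 filter removed %d imputed variants", n_dropped)
    return out
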