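"""End-to-end pipeline: reconcile -> phase -> impute -> write.

The reference is read once and serves both stages.  Output rendering is
partitioned by a :class:`~phasebeam.imputation.BlockPlan`; chunks are pure
functions of their site range and land in fixed output slots, so the
emitted VCF is byte-identical for any worker count or block count.
"""

from __future__ import annotations

import logging
import os
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .imputation import (
    SiteStats,
    apply_r2_filter,
    hard_call,
    impute_haplotype,
    plan_blocks,
    site_r2,
)
from .panel import MISSING
from .pbwt import build_pbwt
from .phasing import (
    USAGE_LABELS,
    PhasedSample,
    PhasingParams,
    phase_sample,
    reverse_phase,
    select_k_best,
)
from .qref import is_binary_reference, read_binary_reference
from .reconcile import reconcile_variants
from .vcfio import (
    read_reference_vcf,
    read_target_vcf,
    write_confidence_file,
    write_phased_vcf,
)

__all__ = ["RunConfig", "Chunk", "chunk_plan", "run_pipeline", "PipelineResult"]

log = logging.getLogger(__name__)

MIN_CHUNK_OVERLAP = 50


@dataclass
class RunConfig:
    """Configuration of one phase-impute run."""

    ref_path: str
    target_path: str
    out_prefix: str
    phasing: PhasingParams = field(default_factory=PhasingParams)
    allow_refalt_swap: bool = False
    allow_strand_flip: bool = False
    skip_phasing: bool = False
    skip_imputation: bool = False
    r2_filter: float | None = None
    output_info: tuple[str, ...] = ("DS", "GP")
    n_blocks: int = 1
    chunk_size: int = 1024  # sites per output chunk inside a block
    max_chunk_sites: int | None = None  # phasing chunk limit; None = no chunking
    workers: int = 1
    status_file: str | None = None
    imputation_weighting: str = "length"

    def __post_init__(self) -> None:
        if self.skip_phasing and self.skip_imputation:
            raise ValueError("--skipPhasing and --skipImputation are mutually exclusive")
        for p in (self.ref_path, self.target_path):
            if not Path(p).exists():
                raise FileNotFoundError(p)


@dataclass(frozen=True)
class Chunk:
    """A phasing chunk: full working range plus the owned output range."""

    start: int
    end: int
    own_start: int
    own_end: int


def chunk_plan(n_sites: int, chunk_limit: int, overlap: int | None = None) -> list[Chunk]:
    """Split a site range into overlapping chunks with unique ownership.

    Chunks are contiguous, at most ``chunk_limit`` sites long, and extend
    ``overlap`` sites (default 5% of the limit, minimum 50) past each
    internal boundary.  Each site is *owned* by the chunk whose centre is
    nearest, so owned ranges partition [0, n_sites) exactly once.
    """
    if overlap is None:
        overlap = max(MIN_CHUNK_OVERLAP, chunk_limit // 20)
    if chunk_limit < 2 * overlap:
        raise ValueError(
            f"chunk limit {chunk_limit} below twice the overlap ({overlap})"
        )
    if n_sites <= chunk_limit:
        return [Chunk(0, n_sites, 0, n_sites)]
    core = chunk_limit - 2 * overlap
    n_chunks = -(-n_sites // core)
    base, extra = divmod(n_sites, n_chunks)
    cores = []
    start = 0
    for c in range(n_chunks):
        size = base + (1 if c < extra else 0)
        cores.append((start, start + size))
        start += size
    chunks = []
    centres = [(s + e) / 2 for s, e in cores]
    # ownership boundaries at midpoints between consecutive chunk centres
    bounds = [0] + [int(round((a + b) / 2)) for a, b in zip(centres, centres[1:])] + [n_sites]
    for c, (s, e) in enumerate(cores):
        chunks.append(
            Chunk(
                start=max(0, s - overlap),
                end=min(n_sites, e + overlap),
                own_start=bounds[c],
                own_end=bounds[c + 1],
            )
        )
    return chunks


@dataclass
class PipelineResult:
    """Paths and in-memory summaries returned by :func:`run_pipeline`."""

    output_vcf: Path | None
    confidence_file: Path | None
    sample_ids: list[str]
    n_shared_sites: int
    n_output_sites: int
    stats: list[SiteStats] = field(default_factory=list)
    ads: np.ndarray | None = None  # (n_ref_sites, n_samples, ploidy)
    site_index: np.ndarray | None = None  # ref site index per output row


class _Status:
    def __init__(self, path):
        self.path = Path(path) if path else None

    def update(self, percent: int, stage: str) -> None:
        if self.path is None:
            return
        tmp = self.path.with_suffix(self.path.suffix + ".tmp")
        tmp.write_text(f"{percent}% {stage}\n")
        os.replace(tmp, self.path)


def _load_reference(path):
    if is_binary_reference(path):
        return read_binary_reference(path)
    return read_reference_vcf(path)


def _phase_cohort(shared_panel, geno_shared, sample_ids, alignment, ref_panel, cfg):
    """Phase every sample over the shared sites, chunking when configured."""
    n_shared = shared_panel.n_sites
    params = cfg.phasing
    chunks = (
        chunk_plan(n_shared, cfg.max_chunk_sites)
        if cfg.max_chunk_sites and n_shared > cfg.max_chunk_sites
        else [Chunk(0, n_shared, 0, n_shared)]
    )
    results: list[PhasedSample] = []
    shared_idx_all = np.arange(n_shared)
    for s, sid in enumerate(sample_ids):
        g = geno_shared[:, s]
        selected = select_k_best(shared_panel, g, params.k)
        hap_a = np.full(n_shared, -1, dtype=np.int8)
        hap_b = np.full(n_shared, -1, dtype=np.int8)
        conf = np.full(n_shared, np.nan)
        usage = np.zeros(n_shared, dtype=np.int8)
        prev_res = None
        prev_rng = None
        for ch in chunks:
            sl = slice(ch.start, ch.end)
            sub = shared_panel.restrict(hap_idx=selected, site_idx=shared_idx_all[sl])
            from .phasing import CondensedReference  # local to avoid cycle noise

            cond = CondensedReference(
                sample_id=sid,
                selected=selected,
                panel=sub,
                site_map=shared_idx_all[sl],
                index=build_pbwt(sub),
            )
            res = phase_sample(cond, g[sl], params)
            res = reverse_phase(cond, g[sl], res, params)
            ha, hb = res.hap_a, res.hap_b
            if prev_res is not None:
                # align pair order with the previous chunk over the overlap
                lo = ch.start
                hi = min(prev_rng[1], ch.end)
                if hi > lo:
                    pa = hap_a[lo:hi]
                    ca = ha[lo - ch.start : hi - ch.start]
                    het = (pa >= 0) & (ca >= 0) & (pa != hap_b[lo:hi])
                    if het.any() and 2 * (pa[het] == ca[het]).sum() < het.sum():
                        ha, hb = hb, ha
            own = slice(ch.own_start, ch.own_end)
            rel = slice(ch.own_start - ch.start, ch.own_end - ch.start)
            hap_a[own] = ha[rel]
            hap_b[own] = hb[rel]
            conf[own] = res.confidence[rel]
            usage[own] = res.usage[rel]
            prev_res = res
            prev_rng = (ch.start, ch.end)
        results.append(PhasedSample(sid, hap_a, hap_b, conf, usage))
    return results


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Execute the configured run and write its outputs.

    Returns a :class:`PipelineResult` carrying output paths plus the
    imputed dosages and per-site statistics for programmatic use.
    """
    status = _Status(cfg.status_file)
    status.update(0, "reading reference")
    ref_panel, ref_variants, _ref_samples = _load_reference(cfg.ref_path)
    status.update(10, "reading target")
    target = read_target_vcf(cfg.target_path)
    if target.n_sites and ref_variants:
        t_chroms = {v.chrom for v in target.variants}
        r_chroms = {v.chrom for v in ref_variants}
        if not t_chroms & r_chroms:
            raise ValueError(
                f"target chromosomes {sorted(t_chroms)} do not overlap "
                f"reference chromosomes {sorted(r_chroms)}"
            )

    status.update(20, "reconciling variants")
    alignment = reconcile_variants(
        target.variants,
        ref_variants,
        allow_refalt_swap=cfg.allow_refalt_swap,
        allow_strand_flip=cfg.allow_strand_flip,
    )
    shared_t = alignment.shared_target_idx
    shared_ref = alignment.shared_ref_idx
    flips = alignment.shared_flip
    if shared_t.size == 0:
        raise ValueError(
            "no shared variants between target and reference; "
            "check chromosome naming and allele orientation flags"
        )
    log.info("variant reconciliation: %s", alignment.n_by_class())

    geno_shared = target.genotypes[shared_t]
    # shared-site panel in the target's allele orientation, for phasing
    shared_panel_t = ref_panel.restrict(site_idx=shared_ref, flip=flips)

    out_prefix = Path(cfg.out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    conf_path = None

    ploidy = target.ploidy
    status.update(30, "phasing")
    if ploidy == 1:
        # haploid targets (non-PAR X, Y) have no phase freedom: the single
        # haplotype is the genotype itself, missing sites deferred
        phased = []
        for s, sid in enumerate(target.sample_ids):
            ha = geno_shared[:, s].astype(np.int8)
            conf = np.full(shared_t.size, np.nan)
            usage = np.where(ha >= 0, 1, 2).astype(np.int8)
            phased.append(PhasedSample(sid, ha, ha.copy(), conf, usage))
    elif cfg.skip_phasing:
        if target.haplotypes is None:
            raise ValueError("--skipPhasing requires a fully phased target VCF")
        phased = []
        for s, sid in enumerate(target.sample_ids):
            ha = target.haplotypes[2 * s][shared_t].astype(np.int8)
            hb = target.haplotypes[2 * s + 1][shared_t].astype(np.int8)
            conf = np.full(shared_t.size, np.nan)
            usage = np.where(ha != hb, 0, 1).astype(np.int8)
            usage[(ha < 0) | (hb < 0)] = 2
            phased.append(PhasedSample(sid, ha, hb, conf, usage))
    else:
        phased = _phase_cohort(
            shared_panel_t, geno_shared, target.sample_ids, alignment, ref_panel, cfg
        )
        conf_path = out_prefix.with_suffix(".phasing.tsv")
        rows = []
        for res in phased:
            for k, ref_site in enumerate(shared_ref):
                v = ref_variants[ref_site]
                rows.append(
                    (
                        res.sample_id,
                        v.chrom,
                        v.pos,
                        res.confidence[k],
                        USAGE_LABELS[int(res.usage[k])],
                    )
                )
        write_confidence_file(conf_path, rows)

    flip_i = flips.astype(np.int8)
    if cfg.skip_imputation:
        status.update(90, "writing phased output")
        out_vcf = Path(str(out_prefix) + ".phased.vcf")
        shared_variants = [ref_variants[i] for i in shared_ref]
        if ploidy == 1:
            from .vcfio import write_haploid_vcf

            hap1 = np.vstack(
                [np.where(r.hap_a >= 0, r.hap_a ^ flip_i, -1) for r in phased]
            )
            write_haploid_vcf(out_vcf, shared_variants, target.sample_ids, hap1)
            status.update(100, "done")
            return PipelineResult(
                out_vcf, conf_path, target.sample_ids,
                int(shared_t.size), int(shared_t.size),
            )
        haps = np.empty((2 * len(phased), shared_t.size), dtype=np.int8)  # diploid
        for s, res in enumerate(phased):
            # back to reference orientation for output
            haps[2 * s] = np.where(res.hap_a >= 0, res.hap_a ^ flip_i, -1)
            haps[2 * s + 1] = np.where(res.hap_b >= 0, res.hap_b ^ flip_i, -1)
        write_phased_vcf(out_vcf, shared_variants, target.sample_ids, haps)
        status.update(100, "done")
        return PipelineResult(
            out_vcf, conf_path, target.sample_ids, int(shared_t.size), int(shared_t.size)
        )

    status.update(50, "imputing")
    shared_panel_ref = ref_panel.restrict(site_idx=shared_ref)
    shared_index = build_pbwt(shared_panel_ref)
    panel_af = ref_panel.allele_frequencies()
    n_samples = len(phased)
    n_ref_sites = ref_panel.n_sites
    ads = np.empty((n_ref_sites, n_samples, ploidy), dtype=np.float64)
    for s, res in enumerate(phased):
        for j, hap in enumerate((res.hap_a, res.hap_b)[:ploidy]):
            hap_ref = np.where(hap >= 0, hap ^ flip_i, MISSING).astype(np.int16)
            ads[:, s, j] = impute_haplotype(
                shared_index,
                ref_panel,
                shared_ref,
                hap_ref,
                panel_af=panel_af,
                weighting=cfg.imputation_weighting,
                shared_panel=shared_panel_ref,
            )

    status.update(80, "computing site statistics")
    calls = hard_call(ads)  # (sites, samples, 2)
    typed = np.zeros(n_ref_sites, dtype=bool)
    typed[shared_ref] = True
    stats: list[SiteStats] = []
    for m in range(n_ref_sites):
        d = ads[m].ravel()
        af = float(d.mean())
        ac = int(calls[m].sum())
        an = ploidy * n_samples
        stats.append(
            SiteStats(
                af=af,
                maf=min(af, 1.0 - af),
                ac=ac,
                an=an,
                panel_af=float(panel_af[m]),
                r2=site_r2(d),
                typed=bool(typed[m]),
            )
        )

    site_index = np.asarray(
        apply_r2_filter(list(range(n_ref_sites)), stats, cfg.r2_filter), dtype=np.int64
    )

    status.update(90, "writing output")
    out_vcf = Path(str(out_prefix) + ".imputed.vcf")
    plan = plan_blocks(len(site_index), cfg.n_blocks, cfg.chunk_size)
    _write_blocks(
        out_vcf, plan, site_index, ref_variants, target, calls, ads, stats, cfg, ploidy
    )
    status.update(100, "done")
    return PipelineResult(
        out_vcf,
        conf_path,
        target.sample_ids,
        int(shared_t.size),
        int(site_index.size),
        stats=[stats[i] for i in site_index],
        ads=ads,
        site_index=site_index,
    )


def _write_blocks(
    out_vcf, plan, site_index, ref_variants, target, calls, ads, stats, cfg, ploidy=2
):
    """Render VCF chunks (possibly concurrently) into fixed output slots."""
    from .vcfio import _open_out, _uniq_chroms, imputed_header, render_imputed_records

    def render(chunk_range) -> bytes:
        rows = site_index[list(chunk_range)]
        return render_imputed_records(
            [ref_variants[i] for i in rows],
            calls[rows],
            ads[rows],
            [stats[i] for i in rows],
            output_info=cfg.output_info,
            ploidy=ploidy,
        )

    slots: dict[tuple[int, int], bytes] = {}
    order = plan.processing_order
    if cfg.workers > 1 and order:
        with ThreadPoolExecutor(max_workers=cfg.workers) as ex:
            rendered = list(
                ex.map(lambda bc: render(plan.blocks[bc[0]][bc[1]]), order)
            )
        for bc, data in zip(order, rendered):
            slots[bc] = data
    else:
        for b, c in order:
            slots[(b, c)] = render(plan.blocks[b][c])

    with _open_out(out_vcf) as fh:
        fh.write(
            imputed_header(
                target.sample_ids, cfg.output_info, contigs=_uniq_chroms(ref_variants)
            ).encode()
        )
        for b, chunks in enumerate(plan.blocks):
            for c in range(len(chunks)):
                fh.write(slots[(b, c)])
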