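"""VCF input/output.

Reading goes through cyvcf2 (VCF and VCF.gz).  Output VCFs are rendered by
this module's own serialiser so the FORMAT/INFO layout (GT, ADS, DS, GP;
AF/MAF/AC/AN/RefPanelAF/R2, TYPED/IMPUTED) and float formatting are fixed
and byte-stable across runs — a requirement for the determinism contract.

Coordinates are 1-based VCF POS at this boundary and 0-based site indices
everywhere else in the package.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass

import numpy as np
from cyvcf2 import VCF

from .panel import HaplotypePanel, VariantRecord

__all__ = [
    "read_reference_vcf",
    "read_target_vcf",
    "TargetData",
    "write_phased_vcf",
    "write_genotype_vcf",
    "write_imputed_vcf",
    "write_confidence_file",
]

log = logging.getLogger(__name__)

_SNV = {"A", "C", "G", "T"}


def _is_biallelic_snv(ref: str, alts: tuple[str, ...]) -> bool:
    return len(alts) == 1 and ref in _SNV and alts[0] in _SNV


def read_reference_vcf(
    path, multiallelic: str = "drop"
) -> tuple[HaplotypePanel, list[VariantRecord], list[str]]:
    """Load a fully phased diploid reference panel from VCF.

    One haplotype per phased allele (two per sample).  Non-SNV and
    multiallelic records are dropped with a log entry by default; policy
    ``decompose`` keeps each single-base alternate of a multiallelic record
    as its own 0/1 site.  Unphased or missing genotypes are an error — a
    reference panel must be fully resolved.
    """
    if multiallelic not in ("drop", "decompose"):
        raise ValueError(f"unknown multiallelic policy {multiallelic!r}")
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows: list[np.ndarray] = []
    variants: list[VariantRecord] = []
    n_dropped = 0
    for v in vcf:
        gts = v.genotype.array()
        if gts.shape[1] != 3:  # ploidy+1 columns; require diploid reference
            raise ValueError(f"reference record {v.CHROM}:{v.POS} is not diploid")
        alleles = gts[:, :2].astype(np.int64)
        phased = gts[:, 2]
        if (alleles < 0).any():
            raise ValueError(
                f"missing genotype in reference at {v.CHROM}:{v.POS}"
            )
        if not phased.all():
            raise ValueError(
                f"unphased genotype in reference at {v.CHROM}:{v.POS}"
            )
        alts = tuple(v.ALT)
        if _is_biallelic_snv(v.REF, alts):
            rows.append((alleles == 1).astype(np.uint8).reshape(-1))
            variants.append(
                VariantRecord(v.CHROM, v.POS, v.ID or ".", v.REF, alts[0])
            )
        elif multiallelic == "decompose":
            kept_any = False
            for ai, alt in enumerate(alts, start=1):
                if len(alt) == 1 and alt in _SNV and len(v.REF) == 1:
                    rows.append((alleles == ai).astype(np.uint8).reshape(-1))
                    variants.append(
                        VariantRecord(v.CHROM, v.POS, v.ID or ".", v.REF, alt)
                    )
                    kept_any = True
            if not kept_any:
                n_dropped += 1
        else:
            n_dropped += 1
            log.info(
                "dropping non-biallelic-SNV reference record %s:%d", v.CHROM, v.POS
            )
    if n_dropped:
        log.warning("dropped %d non-biallelic-SNV reference records", n_dropped)
    mat = (
        np.vstack(rows).T if rows else np.zeros((2 * len(samples), 0), dtype=np.uint8)
    )
    panel = HaplotypePanel(mat)
    afs = panel.allele_frequencies()
    variants = [
        VariantRecord(r.chrom, r.pos, r.vid, r.ref_allele, r.alt_allele, float(af))
        for r, af in zip(variants, afs)
    ]
    return panel, variants, samples


@dataclass
class TargetData:
    """Target cohort genotypes over its typed sites.

    ``genotypes`` holds the allele dose (0/1/2, -1 missing) per site and
    sample; ``haplotypes`` is the (2*n_samples, n_sites) phased matrix when
    every genotype in the file was phased (used by --skipPhasing), else None.
    """

    variants: list[VariantRecord]
    genotypes: np.ndarray  # (n_sites, n_samples) int8
    sample_ids: list[str]
    ploidy: int
    haplotypes: np.ndarray | None = None

    @property
    def n_sites(self) -> int:
        return len(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


def read_target_vcf(path) -> TargetData:
    """Load target genotypes (possibly unphased, missing allowed)."""
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    variants: list[VariantRecord] = []
    doses: list[np.ndarray] = []
    hap_rows: list[np.ndarray] = []
    all_phased = True
    ploidy: int | None = None
    for v in vcf:
        gts = v.genotype.array()
        p = gts.shape[1] - 1
        if ploidy is None:
            ploidy = p
        elif ploidy != p:
            raise ValueError(
                f"mixed ploidy in target at {v.CHROM}:{v.POS}; split by region first"
            )
        alleles = gts[:, :p].astype(np.int64)
        alts = tuple(v.ALT)
        if len(alts) != 1:
            raise ValueError(
                f"target record {v.CHROM}:{v.POS} is not biallelic; normalise first"
            )
        alt = alts[0] if alts[0] else "."
        variants.append(VariantRecord(v.CHROM, v.POS, v.ID or ".", v.REF, alt))
        miss = (alleles < 0).any(axis=1)
        dose = np.where(miss, -1, (alleles == 1).sum(axis=1)).astype(np.int8)
        doses.append(dose)
        if p == 2 and not np.logical_or(gts[:, 2], miss).all():
            all_phased = False
        hrow = np.where(alleles < 0, -1, (alleles == 1)).astype(np.int8)
        hap_rows.append(hrow.reshape(-1))
    geno = (
        np.vstack(doses)
        if doses
        else np.zeros((0, len(samples)), dtype=np.int8)
    )
    haps = None
    if all_phased and hap_rows:
        haps = np.vstack(hap_rows).T.copy()  # (ploidy*n_samples, n_sites)
    return TargetData(variants, geno, samples, ploidy or 2, haps)


# ----------------------------------------------------------------------
# writers


def _open_out(path):
    path = str(path)
    if path.endswith(".gz"):
        # fixed mtime/name so identical content gzips byte-identically
        return gzip.GzipFile(filename="", mode="wb", fileobj=open(path, "wb"), mtime=0)
    return open(path, "wb")


def _header(sample_ids, extra_lines=(), contigs=()) -> str:
    lines = ["##fileformat=VCFv4.2", "##source=phasebeam"]
    lines += [f"##contig=<ID={c}>" for c in contigs]
    lines += list(extra_lines)
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(sample_ids)
    )
    return "\n".join(lines) + "\n"


def write_phased_vcf(path, variants, sample_ids, haplotypes) -> None:
    """Write a fully phased diploid VCF (haplotypes: 2*n_samples x n_sites)."""
    haps = np.asarray(haplotypes)
    with _open_out(path) as fh:
        fh.write(
            _header(
                sample_ids,
                ['##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">'],
                contigs=_uniq_chroms(variants),
            ).encode()
        )
        for m, v in enumerate(variants):
            col = haps[:, m]
            cells = "\t".join(
                f"{col[2 * s]}|{col[2 * s + 1]}" for s in range(len(sample_ids))
            )
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.vid}\t{v.ref_allele}\t{v.alt_allele}"
                f"\t.\tPASS\t.\tGT\t{cells}\n".encode()
            )


def write_haploid_vcf(path, variants, sample_ids, haplotypes) -> None:
    """Write haploid calls (one allele per sample; -1 missing)."""
    haps = np.asarray(haplotypes)
    with _open_out(path) as fh:
        fh.write(
            _header(
                sample_ids,
                ['##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">'],
                contigs=_uniq_chroms(variants),
            ).encode()
        )
        for m, v in enumerate(variants):
            cells = "\t".join(
                "." if haps[s, m] < 0 else str(int(haps[s, m]))
                for s in range(len(sample_ids))
            )
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.vid}\t{v.ref_allele}\t{v.alt_allele}"
                f"\t.\tPASS\t.\tGT\t{cells}\n".encode()
            )


def write_genotype_vcf(path, variants, sample_ids, genotypes) -> None:
    """Write unphased diploid genotypes (doses 0/1/2, -1 missing)."""
    geno = np.asarray(genotypes)
    cell = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    with _open_out(path) as fh:
        fh.write(
            _header(
                sample_ids,
                ['##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">'],
                contigs=_uniq_chroms(variants),
            ).encode()
        )
        for m, v in enumerate(variants):
            cells = "\t".join(cell[int(g)] for g in geno[m])
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.vid}\t{v.ref_allele}\t{v.alt_allele}"
                f"\t.\tPASS\t.\tGT\t{cells}\n".encode()
            )


_INFO_HEADERS = [
    '##INFO=<ID=AF,Number=A,Type=Float,Description="Imputed alternate allele frequency">',
    '##INFO=<ID=MAF,Number=1,Type=Float,Description="Imputed minor allele frequency">',
    '##INFO=<ID=AC,Number=A,Type=Integer,Description="Alternate allele count (hard calls)">',
    '##INFO=<ID=AN,Number=1,Type=Integer,Description="Called allele number">',
    '##INFO=<ID=RefPanelAF,Number=1,Type=Float,Description="Reference panel alternate allele frequency">',
    '##INFO=<ID=R2,Number=1,Type=Float,Description="Estimated imputation accuracy">',
    '##INFO=<ID=TYPED,Number=0,Type=Flag,Description="Variant genotyped in the target">',
    '##INFO=<ID=IMPUTED,Number=0,Type=Flag,Description="Variant imputed from the reference">',
]

_FORMAT_HEADERS = {
    "GT": '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    "ADS": '##FORMAT=<ID=ADS,Number=.,Type=Float,Description="Per-haplotype alternate allele dosage">',
    "DS": '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Genotype dosage">',
    "GP": '##FORMAT=<ID=GP,Number=G,Type=Float,Description="Genotype probabilities">',
}


def _uniq_chroms(variants):
    return list(dict.fromkeys(v.chrom for v in variants))


def format_fields(output_info) -> list[str]:
    sel = {s.upper() for s in output_info}
    return ["GT"] + [f for f in ("ADS", "DS", "GP") if f in sel]


def imputed_header(sample_ids, output_info=(), contigs=()) -> str:
    fields = format_fields(output_info)
    return _header(
        sample_ids,
        _INFO_HEADERS + [_FORMAT_HEADERS[f] for f in fields],
        contigs=contigs,
    )


def render_imputed_records(
    variants,
    hard_calls,  # (n_sites, n_samples, ploidy) int8
    ads,  # (n_sites, n_samples, ploidy) float
    stats,  # SiteStats-like with af/maf/ac/an/panel_af/r2/typed
    output_info=(),
    ploidy: int = 2,
    phased: bool = True,
) -> bytes:
    """Render imputed VCF data lines (no header) for a run of sites.

    A pure function of its inputs so output chunks can be produced by any
    worker in any order and concatenated deterministically.
    """
    fmt_fields = format_fields(output_info)
    sep = "|" if phased else "/"
    n_samples = hard_calls.shape[1] if len(variants) else 0
    lines = []
    for m, (v, st) in enumerate(zip(variants, stats)):
        info = (
            f"AF={st.af:.5f};MAF={st.maf:.5f};AC={st.ac};AN={st.an};"
            f"RefPanelAF={st.panel_af:.5f};R2={st.r2:.5f};"
            + ("TYPED" if st.typed else "IMPUTED")
        )
        cells = []
        for s in range(n_samples):
            gt = sep.join(str(int(x)) for x in hard_calls[m, s, :ploidy])
            parts = [gt]
            d = ads[m, s, :ploidy]
            if "ADS" in fmt_fields:
                parts.append(",".join(f"{x:.3f}" for x in d))
            if "DS" in fmt_fields:
                parts.append(f"{d.sum():.3f}")
            if "GP" in fmt_fields:
                if ploidy == 2:
                    da, db = float(d[0]), float(d[1])
                    gp = (
                        (1 - da) * (1 - db),
                        da * (1 - db) + db * (1 - da),
                        da * db,
                    )
                else:
                    gp = (1 - float(d[0]), float(d[0]))
                parts.append(",".join(f"{x:.3f}" for x in gp))
            cells.append(":".join(parts))
        lines.append(
            f"{v.chrom}\t{v.pos}\t{v.vid}\t{v.ref_allele}\t{v.alt_allele}"
            f"\t.\tPASS\t{info}\t{':'.join(fmt_fields)}\t" + "\t".join(cells)
        )
    return ("\n".join(lines) + "\n").encode() if lines else b""


def write_imputed_vcf(
    path,
    variants,
    sample_ids,
    hard_calls,
    ads,
    stats,
    output_info=(),
    ploidy: int = 2,
    phased: bool = True,
) -> None:
    """Write the imputation output VCF (header + rendered records).

    FORMAT always carries GT; ADS/DS/GP are appended as selected via
    ``output_info``.  Variant IDs are whatever the reference carries,
    verbatim.
    """
    with _open_out(path) as fh:
        fh.write(
            imputed_header(
                sample_ids, output_info, contigs=_uniq_chroms(variants)
            ).encode()
        )
        fh.write(
            render_imputed_records(
                variants, hard_calls, ads, stats, output_info, ploidy, phased
            )
        )


def write_confidence_file(path, rows) -> None:
    """Phasing confidences/usage: sample, chrom, pos, confidence, usage."""
    with open(path, "w") as fh:
        fh.write("sample\tchrom\tpos\tconfidence\tusage\n")
        for sample, chrom, pos, conf, usage in rows:
            c = "." if conf is None or np.isnan(conf) else f"{conf:.4f}"
            fh.write(f"{sample}\t{chrom}\t{pos}\t{c}\t{usage}\n")
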