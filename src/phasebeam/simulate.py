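"""Synthetic reference panels and target cohorts with known truth.

Two generators cover complementary needs.  The *frequency panel* draws every
allele independently while holding a per-site allele-frequency spectrum —
matching how very large panels are emulated for scale tests — but it has no
linkage, so it carries no phasing signal.  *Mosaic targets* therefore build
each target haplotype as a copy-path over panel haplotypes with a per-site
switch probability, which gives the panel-target relationship real phasing
and imputation tools exploit; allele errors and array-style site masking
complete an end-to-end testbed with exact held-out truth.

All randomness flows from a single seed through four named substreams
(panel, mosaics, errors, masking) so every artefact is reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .panel import HaplotypePanel, VariantRecord
from .qref import write_binary_reference
from .vcfio import write_genotype_vcf, write_phased_vcf

__all__ = [
    "SimConfig",
    "SimulationTruth",
    "simulate_frequency_panel",
    "simulate_mosaic_targets",
    "mask_to_array",
    "write_simulation",
]

_STREAMS = ("panel", "mosaics", "errors", "masking")


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset.

    ``af_spectrum`` is either an explicit per-site frequency list or a
    ``("beta", a, b)`` tuple; the default Beta(0.8, 0.8) gives a realistic
    U-shaped spectrum with both rare and common variants.
    """

    n_ref_samples: int = 200
    n_sites: int = 1000
    af_spectrum: object = ("beta", 0.8, 0.8)
    n_targets: int = 20
    mosaic_switch_rate: float = 0.005
    allele_error_rate: float = 0.002
    array_fraction: float = 0.5
    seed: int | None = None
    chrom: str = "1"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory for reproducible simulation")
        for name in ("mosaic_switch_rate", "allele_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0.0 < self.array_fraction <= 1.0:
            raise ValueError("array_fraction must lie in (0, 1]")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(_STREAMS.index(stream),))
        )


@dataclass
class SimulationTruth:
    """Ground truth for the simulated targets (pre-error haplotypes)."""

    haplotypes: np.ndarray  # (2*n_targets, n_sites) 0/1, before error injection
    breakpoints: list[np.ndarray]  # per target haplotype: sites where copy source switched
    error_positions: list[np.ndarray]  # per target haplotype: sites with flipped alleles
    sample_ids: list[str]


_BASES = np.array(["A", "C", "G", "T"])


def _site_frequencies(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    spec = config.af_spectrum
    if isinstance(spec, tuple) and len(spec) == 3 and spec[0] == "beta":
        return rng.beta(spec[1], spec[2], size=config.n_sites)
    af = np.asarray(spec, dtype=float)
    if af.shape != (config.n_sites,):
        raise ValueError("explicit af_spectrum must have one entry per site")
    if af.min() < 0.0 or af.max() > 1.0:
        raise ValueError("allele frequency outside [0, 1]")
    return af


def simulate_frequency_panel(
    config: SimConfig,
) -> tuple[HaplotypePanel, list[VariantRecord]]:
    """Reference panel with site-independent draws at given frequencies.

    Every haplotype's allele at a site is an independent Bernoulli draw at
    the site's target frequency, so realised frequencies converge to the
    spectrum while the panel carries no linkage.  Deterministic per seed.
    """
    rng = config.rng("panel")
    af = _site_frequencies(config, rng)
    n_haps = 2 * config.n_ref_samples
    alleles = (rng.random((n_haps, config.n_sites)) < af).astype(np.uint8)
    panel = HaplotypePanel(alleles)
    realised = panel.allele_frequencies()
    ref_idx = rng.integers(0, 4, size=config.n_sites)
    alt_idx = (ref_idx + rng.integers(1, 4, size=config.n_sites)) % 4
    variants = [
        VariantRecord(
            config.chrom,
            100 * (m + 1),  # spaced, strictly increasing physical positions
            f"sim{m}",
            str(_BASES[ref_idx[m]]),
            str(_BASES[alt_idx[m]]),
            float(realised[m]),
        )
        for m in range(config.n_sites)
    ]
    return panel, variants


def simulate_mosaic_targets(
    panel: HaplotypePanel, config: SimConfig
) -> tuple[np.ndarray, SimulationTruth]:
    """Targets as mosaics of panel haplotypes, with truth recorded pre-error.

    Each of the 2*n_targets haplotypes starts from a uniformly chosen panel
    haplotype and re-draws its copy source with probability
    ``mosaic_switch_rate`` at every site.  Allele errors are then injected
    at ``allele_error_rate`` into the *emitted* haplotypes; genotypes are
    the unphased sum of the two emitted haplotypes.
    """
    if panel.n_haps == 0 or panel.n_sites == 0:
        raise ValueError("panel must be non-empty")
    rng = config.rng("mosaics")
    err_rng = config.rng("errors")
    mat = panel.matrix
    n_hap_t = 2 * config.n_targets
    m_sites = panel.n_sites
    truth = np.empty((n_hap_t, m_sites), dtype=np.int8)
    emitted = np.empty_like(truth)
    breakpoints: list[np.ndarray] = []
    error_positions: list[np.ndarray] = []
    for h in range(n_hap_t):
        switch = rng.random(m_sites) < config.mosaic_switch_rate
        switch[0] = False
        sources = rng.integers(0, panel.n_haps, size=int(switch.sum()) + 1)
        seg = np.cumsum(switch)  # segment id per site
        src = sources[seg]
        truth[h] = mat[src, np.arange(m_sites)]
        flips = err_rng.random(m_sites) < config.allele_error_rate
        emitted[h] = truth[h] ^ flips
        breakpoints.append(np.flatnonzero(switch))
        error_positions.append(np.flatnonzero(flips))
    genotypes = (emitted[0::2] + emitted[1::2]).T.astype(np.int8)
    ids = [f"T{i}" for i in range(config.n_targets)]
    return genotypes, SimulationTruth(truth, breakpoints, error_positions, ids)


def mask_to_array(
    targets: np.ndarray, truth: SimulationTruth, config: SimConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split sites into typed ("array") and masked (held-out) subsets.

    Retains an exact-count, seeded uniform subset of
    ``round(array_fraction * n_sites)`` sites as the target's typed sites.
    Returns (typed site indices, masked site indices, genotypes at typed
    sites); truth at masked sites lives in ``truth.haplotypes``.
    """
    m_sites = targets.shape[0]
    n_keep = int(round(config.array_fraction * m_sites))
    if n_keep == 0:
        raise ValueError("array_fraction leaves zero typed sites")
    rng = config.rng("masking")
    typed = np.sort(rng.choice(m_sites, size=n_keep, replace=False))
    masked = np.setdiff1d(np.arange(m_sites), typed)
    return typed, masked, targets[typed]


def write_simulation(config: SimConfig, out_dir) -> dict[str, Path]:
    """Generate a full dataset and write it under ``out_dir``.

    Emits the phased reference (VCF + binary reference), the masked
    unphased target VCF, tab-delimited truth tables and the serialised
    configuration; everything regenerates from the config alone.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    panel, variants = simulate_frequency_panel(config)
    genotypes, truth = simulate_mosaic_targets(panel, config)
    typed, masked, array_geno = mask_to_array(genotypes, truth, config)

    ref_samples = [f"R{i}" for i in range(config.n_ref_samples)]
    paths = {
        "reference_vcf": out / "reference.vcf",
        "reference_qref": out / "reference.qref",
        "target_vcf": out / "target.vcf",
        "truth_haps": out / "truth_haplotypes.tsv",
        "typed_sites": out / "typed_sites.tsv",
        "config": out / "sim_config.json",
    }
    write_phased_vcf(paths["reference_vcf"], variants, ref_samples, panel.matrix)
    write_binary_reference(panel, variants, paths["reference_qref"], ref_samples)
    write_genotype_vcf(
        paths["target_vcf"],
        [variants[i] for i in typed],
        truth.sample_ids,
        array_geno,
    )
    with open(paths["truth_haps"], "w") as fh:
        cols = "\t".join(
            f"{s}_A\t{s}_B" for s in truth.sample_ids
        )
        fh.write(f"chrom\tpos\t{cols}\n")
        for m, v in enumerate(variants):
            row = "\t".join(str(int(a)) for a in truth.haplotypes[:, m])
            fh.write(f"{v.chrom}\t{v.pos}\t{row}\n")
    with open(paths["typed_sites"], "w") as fh:
        fh.write("chrom\tpos\ttyped\n")
        typed_set = set(typed.tolist())
        for m, v in enumerate(variants):
            fh.write(f"{v.chrom}\t{v.pos}\t{int(m in typed_set)}\n")
    cfg = dataclasses.asdict(config)
    if isinstance(cfg["af_spectrum"], np.ndarray):
        cfg["af_spectrum"] = cfg["af_spectrum"].tolist()
    paths["config"].write_text(json.dumps(cfg, indent=2) + "\n")
    return paths
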