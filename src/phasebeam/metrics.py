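"""Phasing and imputation accuracy metrics.

Switch errors compare the *relative* phase orientation of consecutive
heterozygous call sites against a known-truth haplotype pair, so a global
swap of the two haplotypes in either argument changes nothing.  Genotype
errors are "soft": each variant contributes one minus the probability the
imputation assigned to the true genotype, which rewards calibrated
uncertainty rather than lucky hard calls.  Both rates are normalised by
the number of target variants, not by the number of evaluated sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TruthSet",
    "SwitchErrorResult",
    "switch_error_rate",
    "soft_genotype_error_rate",
    "maf_stratified_r2",
]


@dataclass
class TruthSet:
    """True haplotype pairs over evaluation sites (one row pair per sample)."""

    haplotypes: np.ndarray  # (2*n_samples, n_sites) 0/1
    sample_ids: list[str]

    def pair(self, s: int) -> tuple[np.ndarray, np.ndarray]:
        return self.haplotypes[2 * s], self.haplotypes[2 * s + 1]

    def genotypes(self) -> np.ndarray:
        """(n_sites, n_samples) allele doses derived from the truth pairs."""
        h = self.haplotypes
        return (h[0::2] + h[1::2]).T


@dataclass
class SwitchErrorResult:
    rate: float  # switch errors / n_target_variants
    n_switch_errors: int
    n_het_evaluated: int
    n_excluded: int  # het sites with a target/truth genotype mismatch
    rate_per_het: float  # alternative normalisation, for interpretability


def switch_error_rate(
    phased_pair: tuple[np.ndarray, np.ndarray],
    truth_pair: tuple[np.ndarray, np.ndarray],
    n_target_variants: int,
) -> SwitchErrorResult:
    """Switch errors of a phased pair against the truth pair.

    A switch error occurs at a heterozygous call site (after the first)
    whenever the phased pair changes orientation relative to the previous
    het site and the truth does not, or vice versa.  Het sites where the
    target and truth genotypes disagree are skipped and tallied.  Samples
    with fewer than two comparable het sites have rate 0 by convention.
    """
    pa, pb = (np.asarray(x) for x in phased_pair)
    ta, tb = (np.asarray(x) for x in truth_pair)
    if not (pa.shape == pb.shape == ta.shape == tb.shape):
        raise ValueError("phased and truth pairs must cover the same sites")
    truth_het = ta != tb
    target_het = (pa != pb) & (pa >= 0) & (pb >= 0)
    both = truth_het & target_het
    excluded = int((truth_het ^ target_het).sum())
    sites = np.flatnonzero(both)
    if sites.size < 2:
        return SwitchErrorResult(0.0, 0, int(sites.size), excluded, 0.0)
    # orientation: does phased hap_a carry the same allele as truth hap_a?
    orient = pa[sites] == ta[sites]
    errors = int((orient[1:] != orient[:-1]).sum())
    return SwitchErrorResult(
        rate=errors / n_target_variants,
        n_switch_errors=errors,
        n_het_evaluated=int(sites.size),
        n_excluded=excluded,
        rate_per_het=errors / (sites.size - 1),
    )


def soft_genotype_error_rate(
    gp: np.ndarray, truth_genotypes: np.ndarray, n_variants: int
) -> float:
    """Mean soft genotype error: sum over variants of (1 - gp[true]) / n.

    ``gp`` has one probability triple per evaluated variant and
    ``truth_genotypes`` the true allele dose (0, 1, 2) at each.
    """
    gp = np.asarray(gp, dtype=np.float64)
    x = np.asarray(truth_genotypes, dtype=np.int64).ravel()
    if gp.ndim != 2 or gp.shape[1] != 3 or gp.shape[0] != x.shape[0]:
        raise ValueError("need one genotype-probability triple per variant")
    if np.isnan(gp).any():
        raise ValueError("missing genotype probabilities in evaluation set")
    err = (1.0 - gp[np.arange(x.size), x]).sum()
    return float(err / n_variants)


def maf_stratified_r2(site_stats: pd.DataFrame, maf_thresholds) -> pd.DataFrame:
    """Cumulative mean r2 over variants with MAF above each threshold.

    ``site_stats`` needs columns ``maf`` and ``r2``.  Strata are cumulative
    (every variant with maf > t), not binned.  Empty strata report
    n_variants 0 and a null mean instead of propagating NaN.
    """
    thresholds = list(maf_thresholds)
    if any(b < a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("maf thresholds must be ascending")
    maf = site_stats["maf"].to_numpy(dtype=float)
    r2 = site_stats["r2"].to_numpy(dtype=float)
    rows = []
    for t in thresholds:
        mask = maf > t
        n = int(mask.sum())
        rows.append(
            {
                "threshold": t,
                "n_variants": n,
                "mean_r2": float(r2[mask].mean()) if n else np.nan,
            }
        )
    return pd.DataFrame(rows)
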