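"""Score an imputed VCF against simulator truth tables.

Produces per-sample switch error and soft genotype error rates (the
latter over held-out, imputed-only sites) and a cumulative MAF-stratified
r2 summary from the VCF's INFO fields.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .metrics import maf_stratified_r2, soft_genotype_error_rate, switch_error_rate

__all__ = ["evaluate_run"]


def _read_truth(truth_tsv: str) -> tuple[pd.DataFrame, list[str], np.ndarray]:
    df = pd.read_csv(truth_tsv, sep="\t")
    hap_cols = [c for c in df.columns if c.endswith(("_A", "_B"))]
    samples = list(dict.fromkeys(c[:-2] for c in hap_cols))
    haps = np.column_stack(
        [df[f"{s}_{ab}"].to_numpy() for s in samples for ab in ("A", "B")]
    ).T  # (2*n_samples, n_sites)
    return df[["chrom", "pos"]], samples, haps.astype(np.int8)


def evaluate_run(
    imputed_vcf: str,
    truth_tsv: str,
    typed_tsv: str,
    maf_thresholds=(0.0, 0.001, 0.01, 0.05, 0.1),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Return (per-sample metrics, MAF-stratified r2 table).

    Switch errors are evaluated at the typed sites (normalised by the
    number of typed variants); soft genotype errors at the held-out
    (masked) sites, using the GP field (normalised by the number of masked
    variants).
    """
    key, samples, truth_haps = _read_truth(truth_tsv)
    typed_df = pd.read_csv(typed_tsv, sep="\t")
    pos_row = {
        (c, p): i for i, (c, p) in enumerate(zip(key["chrom"].astype(str), key["pos"]))
    }
    typed_pos = {
        (str(r.chrom), int(r.pos)) for r in typed_df.itertuples() if r.typed
    }

    vcf = VCF(str(imputed_vcf))
    vcf_samples = list(vcf.samples)
    rows = []
    gts = []
    gps = []
    infos = []
    for v in vcf:
        loc = (str(v.CHROM), int(v.POS))
        if loc not in pos_row:
            continue
        g = v.genotype.array()
        gts.append(g[:, :2])
        gp = v.format("GP")
        gps.append(gp)
        infos.append(
            {
                "row": pos_row[loc],
                "typed": loc in typed_pos,
                "maf": v.INFO.get("MAF"),
                "r2": v.INFO.get("R2"),
            }
        )
    info = pd.DataFrame(infos)
    gt = np.stack(gts)  # (n_out_sites, n_samples, 2)
    truth_rows = info["row"].to_numpy()
    typed_mask = info["typed"].to_numpy()
    masked_mask = ~typed_mask
    n_typed = int(typed_mask.sum())
    n_masked = int(masked_mask.sum())

    per_sample = []
    for s, sid in enumerate(vcf_samples):
        si = samples.index(sid)
        ta = truth_haps[2 * si][truth_rows]
        tb = truth_haps[2 * si + 1][truth_rows]
        sw = switch_error_rate(
            (gt[typed_mask, s, 0], gt[typed_mask, s, 1]),
            (ta[typed_mask], tb[typed_mask]),
            n_typed,
        )
        entry = {
            "sample": sid,
            "switch_error_rate": sw.rate,
            "switch_errors": sw.n_switch_errors,
            "switch_error_rate_per_het": sw.rate_per_het,
            "n_het_evaluated": sw.n_het_evaluated,
            "n_het_excluded": sw.n_excluded,
        }
        if gps[0] is not None and n_masked:
            gp_s = np.stack([gps[i][s] for i in np.flatnonzero(masked_mask)])
            truth_geno = (ta + tb)[masked_mask]
            entry["soft_genotype_error_rate"] = soft_genotype_error_rate(
                gp_s, truth_geno, n_masked
            )
        per_sample.append(entry)

    stats = info.loc[masked_mask, ["maf", "r2"]].astype(float)
    strata = maf_stratified_r2(stats, maf_thresholds)
    return pd.DataFrame(per_sample), strata
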