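# Methods

This note records the model, the parameter choices, the numerical
conventions and the limits of what the test suite demonstrates.

## Phasing model

Phasing is a beam search over diplotype hypotheses under a conditional
haplotype-copying (Li–Stephens-flavoured) score. A hypothesis carries one
PBWT interval per haplotype-under-construction; the interval is the set of
condensed-reference haplotypes that match the haplotype's allele pattern
since its last copy restart. The score is a product of per-site factors:

* extension supported by the panel (non-empty interval): factor 1;
* extension that empties the interval: the haplotype restarts from all
  panel carriers of the required allele, with factor ρ·ε — ρ for switching
  the local copy source (recombination), ε for the implied local mismatch
  against every haplotype that was being copied;
* monomorphic panel columns are forced with no penalty, so columns carrying
  no information never accumulate spurious restart mass;
* missing genotypes branch both haplotypes over both alleles, weighted by
  the panel frequency of the extended pattern (normalised interval size),
  and the site is marked `missing_deferred` — its genotype is left to the
  imputation stage, which treats it exactly like an untyped reference site.

This is deliberately a *scoring* model, not a calibrated population-genetic
likelihood: ρ and ε shape the ranking of diplotypes, and only ratios
matter. Defaults ρ = 0.008 and ε = 0.003 (both CLI-exposed) are in the
range conventional for dense array data, where a copy switch should cost
roughly as much as two to three isolated mismatches; the beam's behaviour
is insensitive to factors of a few because decisions are dominated by
match-length differences. ρ > 0 also guarantees the beam can never lose
all states.

Beam parameters default to width P = 128 and merge-history length Δ = 24;
states identical in interval pair and last-Δ phase decisions merge by
summing mass (the surviving traceback chain is the dominant branch's,
ties broken by processing order; pruning ties break by lexicographic
history, so beam content is deterministic). One phasing iteration is run;
without adding target haplotypes to the panel (a non-goal) further
iterations would be no-ops.

### Probability representation

Path probabilities are significand × 2^exponent with a *shared* exponent
across the beam. When the best significand falls below 2⁻⁶⁴ all states are
rescaled so it returns to (0.5, 1]; summation of same-scale doubles is then
exact to machine precision, with no log-space approximation. States whose
significand underflows to zero relative to the beam leader (ratio below
roughly 2⁻¹⁰⁷⁴) are dropped — they could never influence output. A test
drives a path whose probability is hundreds of orders of magnitude below
double range and checks agreement with extended-precision log-space
enumeration to 1e−10 relative.

### Confidences, traceback, reverse pass

Output haplotypes follow the highest-probability terminal state. Per-het
confidence is the terminal probability mass agreeing with the chosen
orientation at that site divided by total terminal mass, clamped to
[0.5, 1]; for decisions older than Δ the attribution follows each state's
surviving traceback chain and is therefore approximate.

The reverse pass re-phases against the site-reversed condensed reference.
Combining the passes is a genuinely open design point; per-site
"higher-confidence-wins" turned out to be counterproductive because
confidences saturate at 0.5 or 1.0 exactly where the passes disagree, so
the rule degenerates to a coin flip that can break consistent orientation
runs. Instead, each transition (relative orientation between consecutive
het sites) where the reverse pass disagrees is adopted, greedily left to
right, only if it increases the model's own path probability of the full
diplotype. The combined result therefore never scores worse than the
forward pass under the phasing model, and in simulation its switch error
is never worse on average. Where a reverse transition is adopted the
reverse pass's confidence replaces the forward one.

Pre-phasing (off by default) runs a quarter-width coarse beam first; where
the coarse pass agrees with the main pass, the larger of the two
confidences is kept. It never changes haplotypes.

### K-best selection

The condensed reference keeps the K haplotypes minimising the count of
conflicts with the sample's homozygous genotypes (het and missing sites
constrain nothing), ties broken by haplotype index. K defaults to 10 000
and saturates at the panel size; selection affects phasing only —
imputation always uses the full panel.

## Imputation

Set-maximal matches of each phased haplotype against the typed-site slice
of the full reference panel are computed by a vectorised agreement-run
sweep (any algorithm with the same output contract is conformant; the
output is checked against an O(N·M²) definition-based oracle). Missing
(deferred) target sites match either allele, so no-calls never truncate
matches.

An untyped reference site between typed sites k−1 and k is voted on by
matches that span both flanks (start < k and end > k in typed-site
coordinates); sites before the first / after the last typed site use
matches touching the respective terminal typed site. Votes are weighted by
match length in typed sites — longer set-maximal matches indicate closer
local ancestry — with a `uniform` weighting available as a configuration
alternative. With no spanning match the dosage falls back to the panel
allele frequency. Typed, non-missing sites emit the phased allele as a
hard 0/1 dosage.

The per-site accuracy estimate r² = Var(d)/(p̄(1−p̄)) uses the population
variance of the cohort's imputed haploid dosages; monomorphic dosage
vectors return 0 by convention (detected exactly, not via a tolerance) and
values are clamped to [0, 1]. This estimates the squared correlation
between imputed dosage and true allele without needing truth. The optional
r² filter removes imputed-only sites below threshold; genotyped sites are
never removed.

### Output determinism

Imputed sites are split contiguously into blocks (sizes differing by at
most one), blocks into fixed-size chunks, processed round-robin across
blocks. Each chunk renders its VCF lines as a pure function of its site
range into a fixed output slot; concatenation order is block order. Output
bytes are therefore identical for any worker count and any block count —
verified byte-for-byte in the tests. Float formatting is fixed (dosages
and GP at 3 decimals, INFO statistics at 5), and gzip output uses a zeroed
mtime so compressed files are reproducible too.

## Chunked phasing

When a typed-site range exceeds `--maxChunkSites`, phasing runs on
overlapping chunks (overlap 5% of the limit, minimum 50 sites). Each site
is owned by the chunk whose centre is nearest, so owned ranges partition
the sites; consecutive chunks are pair-order aligned by majority haplotype
agreement over the overlap. Chunk boundaries can in principle cost a
switch error where a phase run crosses the boundary with low local
evidence; the single-chunk path is bit-identical to the unchunked run.

## The simulator

Two generators with distinct purposes:

* the **frequency panel** draws each allele independently, holding a
  per-site frequency spectrum (default Beta(0.8, 0.8), a U-shaped spectrum
  with both rare and common variants). It reproduces panel-scale allele
  frequencies but carries *no linkage* — it cannot exhibit phasing signal
  and is used for scale, frequency and format tests;
* **mosaic targets** copy-path through the panel's haplotypes with a
  per-site switch probability (default 0.005) and per-site allele error
  rate (default 0.002), giving the target–panel relationship that phasing
  and imputation actually exploit. Truth haplotypes are recorded before
  error injection; genotypes are the unphased sum of the error-injected
  haplotypes. Array masking retains an exact-count random half
  (`array_fraction` 0.5) of sites as typed.

Default cohort sizes used by the acceptance script — 200 reference
samples, 600 sites, 20 targets (and 100/300/10 for the noise-free
recovery check) — are chosen so every quantity is a stable statistic of at
least 20 samples and several hundred sites while a full run stays in the
seconds range.

All randomness flows from one mandatory seed through four named substreams
(panel, mosaics, errors, masking), so artefacts regenerate bit-identically
from the serialised configuration.

**What passing these tests does not show.** Mosaic targets descend
perfectly from the panel apart from injected noise; real cohorts contain
ancestry not represented in any reference, structural variation,
genotyping artefacts correlated along the array, and recombination
clustered in hotspots rather than uniform per site. Absolute error rates
here are therefore optimistic; the tests demonstrate correctness of the
machinery and relative behaviour (monotonicity in K, degradation with
noise), not field accuracy.

## Numerical and edge conventions

* Coordinates: 1-based VCF POS only at the I/O boundary; 0-based half-open
  internally.
* Hard calls: allele 1 iff dosage > 0.5; exactly 0.5 calls the reference
  allele.
* Switch error: samples with fewer than two comparable het sites score 0;
  het sites where target and truth genotypes disagree are excluded and
  tallied. The primary rate divides by the number of target variants; a
  per-het-site rate is reported alongside for interpretability.
* Strand-ambiguous SNVs (A/T, C/G) never auto-flip, even with the flip
  flag: a flip is indistinguishable from a swap for them, and silent
  mis-orientation is worse than exclusion. Duplicate reference positions
  with conflicting alleles exclude the target variant with a warning.
* Multiallelic and non-SNV reference records: dropped with a log entry by
  default; a `decompose` policy retains single-base alternates as separate
  biallelic sites.
* Binary reference (.qref analogue): 8-byte magic and uint32 version in
  the clear, zlib-compressed body (sample table, variant table, float32
  allele frequencies, bit-packed per-variant rows). Round-trips bit-exactly;
  the layout is this package's own and not byte-compatible with any other
  tool's format.
* PAR tables for GRCh37/GRCh38 are packaged and overridable; X records are
  partitioned into PAR (diploid) and non-PAR (haploid for males) slices
  whose concatenation preserves input order.
* Occurrence counts are checkpointed every 64 haplotypes with popcount
  completion between checkpoints, keeping the rank index small while rank
  queries stay O(1).

## Known limitations

* The identical-by-descent pre-check some phasing tools perform is omitted
  by design, with no flag to re-enable it.
* Phasing without a reference, multi-iteration re-phasing with target
  augmentation, BCF/tabix support, liftover and meta-imputation are out of
  scope.
* The per-site dosage estimator (match-length weighting, both-flank
  spanning rule) is a documented choice among reasonable alternatives; the
  `uniform` weighting is provided for sensitivity checks.
* Beam confidences are approximate beyond the merge-history window Δ and
  are clamped to [0.5, 1].
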