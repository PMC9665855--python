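"""Beam-search phasing: selection, condensed reference, exactness, reverse."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phasebeam.panel import HaplotypePanel
from phasebeam.pbwt import build_pbwt
from phasebeam.phasing import (
    USAGE_HOM_FORCED,
    USAGE_MISSING_DEFERRED,
    CondensedReference,
    PhasingParams,
    _Beam,
    build_condensed_reference,
    phase_sample,
    reverse_phase,
    select_k_best,
)
from phasebeam.metrics import switch_error_rate
from phasebeam.simulate import (
    SimConfig,
    simulate_frequency_panel,
    simulate_mosaic_targets,
)

from conftest import identity_alignment
from oracles import enumerate_diplotypes


def make_condensed(X, selected=None):
    panel = HaplotypePanel(X)
    sel = np.arange(panel.n_haps) if selected is None else np.asarray(selected)
    sub = panel.restrict(hap_idx=sel)
    return CondensedReference("s", sel, sub, np.arange(sub.n_sites), build_pbwt(sub))


class TestSelectKBest:
    def test_selection_saturates_to_all_indices(self, rng):
        panel = HaplotypePanel(rng.integers(0, 2, (6, 9)))
        g = rng.integers(0, 3, 9)
        assert select_k_best(panel, g, 100).tolist() == list(range(6))
        assert select_k_best(panel, g, "max").tolist() == list(range(6))

    def test_all_missing_ties_break_by_index(self, rng):
        panel = HaplotypePanel(rng.integers(0, 2, (8, 5)))
        g = np.full(5, -1)
        assert select_k_best(panel, g, 3).tolist() == [0, 1, 2]

    def test_source_haplotypes_have_distance_zero(self, rng):
        X = rng.integers(0, 2, (40, 30))
        panel = HaplotypePanel(X)
        h1, h2 = 11, 29
        g = X[h1] + X[h2]
        sel = select_k_best(panel, g, 40)
        # direct-count oracle for the compatibility distance
        def dist(h):
            d = 0
            for m in range(30):
                if g[m] == 0 and X[h, m] == 1:
                    d += 1
                if g[m] == 2 and X[h, m] == 0:
                    d += 1
            return d

        assert dist(h1) == 0 and dist(h2) == 0
        dists = np.array([dist(h) for h in range(40)])
        k5 = select_k_best(panel, g, 5)
        worst_selected = dists[k5].max()
        assert worst_selected <= np.sort(dists)[4]

    def test_no_sites_is_an_error(self):
        panel = HaplotypePanel(np.zeros((2, 0), dtype=np.uint8))
        with pytest.raises(ValueError, match="shared sites"):
            select_k_best(panel, np.zeros(0), 1)


class TestCondensedReference:
    def test_whole_panel_all_shared_equals_recoded_panel(self, rng):
        X = rng.integers(0, 2, (10, 8))
        panel = HaplotypePanel(X)
        aln = identity_alignment(8)
        aln.flip[:] = [True, False] * 4
        cond = build_condensed_reference(panel, aln, np.arange(10), "s")
        expect = X ^ np.array([1, 0] * 4, dtype=np.uint8)
        np.testing.assert_array_equal(cond.panel.matrix, expect)

    def test_single_shared_site(self, rng):
        X = rng.integers(0, 2, (10, 8))
        panel = HaplotypePanel(X)
        aln = identity_alignment(8)
        keep = 3
        aln.classes = [
            c if i == keep else type(c).TARGET_ONLY for i, c in enumerate(aln.classes)
        ]
        aln.ref_index = np.where(np.arange(8) == keep, keep, -1)
        cond = build_condensed_reference(panel, aln, np.arange(10), "s")
        assert cond.panel.n_sites == 1
        assert cond.index.c0(0) == int((X[:, keep] == 0).sum())

    def test_matches_slice_then_build_oracle(self, rng):
        X = rng.integers(0, 2, (20, 15))
        panel = HaplotypePanel(X)
        aln = identity_alignment(15)
        sel = np.array([1, 4, 7, 9, 13])
        cond = build_condensed_reference(panel, aln, sel, "s")
        oracle = build_pbwt(HaplotypePanel(X[sel]))
        for m in range(16):
            assert list(cond.index.prefix[m]) == list(oracle.prefix[m])

    def test_empty_selection_rejected(self, rng):
        panel = HaplotypePanel(rng.integers(0, 2, (4, 4)))
        with pytest.raises(ValueError, match="empty"):
            build_condensed_reference(panel, identity_alignment(4), [], "s")


class TestPhaseSample:
    def test_all_homozygous_is_forced_and_width_independent(self, rng):
        X = rng.integers(0, 2, (12, 20))
        cond = make_condensed(X)
        g = (2 * X[0]).astype(np.int8)
        outs = [
            phase_sample(cond, g, PhasingParams(beam_width=p, delta=d))
            for p, d in ((1, 1), (128, 24))
        ]
        for out in outs:
            np.testing.assert_array_equal(out.hap_a, X[0])
            np.testing.assert_array_equal(out.hap_b, X[0])
            assert np.all(out.usage == USAGE_HOM_FORCED)

    def test_recovers_constructed_truth_pair(self, rng):
        X = rng.integers(0, 2, (25, 40))
        cond = make_condensed(X)
        g = (X[2] + X[18]).astype(np.int8)
        res = phase_sample(
            cond, g, PhasingParams(recomb_penalty=1e-4, mismatch_penalty=1e-4)
        )
        truth = (X[2], X[18])
        sw = switch_error_rate((res.hap_a, res.hap_b), truth, 40)
        assert sw.rate == 0.0

    def test_single_het_site_confidence_half(self, rng):
        X = rng.integers(0, 2, (10, 12))
        X[:, 6] = [0, 1] * 5  # guarantee both alleles present at the het site
        cond = make_condensed(X)
        g = np.zeros(12, dtype=np.int8)
        g[6] = 1
        res = phase_sample(cond, g)
        assert res.confidence[6] == pytest.approx(0.5, abs=1e-12)

    def test_invalid_genotype_rejected(self, rng):
        cond = make_condensed(rng.integers(0, 2, (4, 3)))
        with pytest.raises(ValueError, match="invalid genotype"):
            phase_sample(cond, np.array([0, 3, 1]))

    def test_missing_sites_deferred_not_imputed(self, rng):
        X = rng.integers(0, 2, (15, 25))
        cond = make_condensed(X)
        g = (X[1] + X[8]).astype(np.int8)
        g[[3, 12]] = -1
        res = phase_sample(cond, g)
        assert np.all(res.hap_a[[3, 12]] == -1)
        assert np.all(res.usage[[3, 12]] == USAGE_MISSING_DEFERRED)
        ok = g >= 0
        np.testing.assert_array_equal((res.hap_a + res.hap_b)[ok], g[ok])

    @pytest.mark.parametrize("seed", range(4))
    def test_saturated_beam_equals_exhaustive_enumeration(self, seed):
        """With beam width 2^hets and delta >= hets the beam reproduces the
        exhaustive diplotype enumeration: identical total probability mass
        (1e-10 relative) and a best diplotype attaining the oracle optimum."""
        rng = np.random.default_rng(300 + seed)
        n, m_sites = 8, 12
        X = rng.integers(0, 2, (n, m_sites))
        g = rng.integers(0, 3, m_sites).astype(np.int8)
        n_het = int((g == 1).sum())
        params = PhasingParams(beam_width=2 ** max(n_het, 1), delta=24)
        cond = make_condensed(X)
        oracle, het = enumerate_diplotypes(X, g, params)

        states, scale_exp, het_sites = _Beam(cond.index, params).run(g)
        assert het_sites == het
        beam_log_total = math.log(sum(s[2] for s in states)) + scale_exp * math.log(2)
        mx = max(oracle.values())
        oracle_log_total = mx + math.log(
            math.fsum(math.exp(v - mx) for v in oracle.values())
        )
        assert beam_log_total == pytest.approx(oracle_log_total, rel=1e-10)

        res = phase_sample(cond, g, params)
        got_bits = tuple(int(res.hap_a[m]) for m in het)
        best = max(oracle.values())
        assert oracle[got_bits] == pytest.approx(best, rel=1e-12)

    def test_scaled_representation_matches_logspace_on_long_low_probability_paths(self):
        """Mantissa/exponent bookkeeping must agree with extended-precision
        log-space accumulation even when the path probability underflows
        double range (many forced restarts)."""
        n, m_sites = 4, 400
        X = np.zeros((n, m_sites), dtype=np.uint8)
        X[:2] = 1  # both alleles present everywhere; het columns
        g = np.zeros(m_sites, dtype=np.int8)
        g[::2] = 2  # forces allele-1 then allele-0 alternately -> restarts
        params = PhasingParams()
        cond = make_condensed(X)
        states, scale_exp, _ = _Beam(cond.index, params).run(g)
        beam_log = math.log(sum(s[2] for s in states)) + scale_exp * math.log(2)
        oracle, _ = enumerate_diplotypes(X, g, params)
        assert len(oracle) == 1
        assert beam_log == pytest.approx(oracle[()], rel=1e-10)
        assert beam_log < math.log(5e-324)  # genuinely below double range


class TestReversePhase:
    def test_disabled_flag_is_identity(self, rng):
        X = rng.integers(0, 2, (10, 15))
        cond = make_condensed(X)
        g = (X[0] + X[5]).astype(np.int8)
        fwd = phase_sample(cond, g)
        assert reverse_phase(cond, g, fwd, PhasingParams(reverse_phasing=False)) is fwd

    def test_agreement_everywhere_returns_forward_result(self, rng):
        X = rng.integers(0, 2, (20, 30))
        cond = make_condensed(X)
        g = (X[3] + X[11]).astype(np.int8)
        params = PhasingParams(recomb_penalty=1e-4, mismatch_penalty=1e-4)
        fwd = phase_sample(cond, g, params)
        comb = reverse_phase(cond, g, fwd, params)
        np.testing.assert_array_equal(comb.hap_a, fwd.hap_a)
        np.testing.assert_array_equal(comb.hap_b, fwd.hap_b)

    def test_reverse_pass_never_degrades_mean_switch_error(self):
        """Paired comparison over simulated mosaic targets: adding the
        reverse pass must not increase the mean switch error rate."""
        cfg = SimConfig(
            n_ref_samples=60,
            n_sites=200,
            n_targets=20,
            mosaic_switch_rate=0.01,
            allele_error_rate=0.003,
            seed=77,
        )
        panel, _ = simulate_frequency_panel(cfg)
        geno, truth = simulate_mosaic_targets(panel, cfg)
        fwd_rates, rev_rates = [], []
        p_fwd = PhasingParams(k="max", reverse_phasing=False)
        p_rev = PhasingParams(k="max", reverse_phasing=True)
        for s in range(cfg.n_targets):
            g = geno[:, s]
            cond = make_condensed(panel.matrix)
            fwd = phase_sample(cond, g, p_fwd)
            rev = reverse_phase(cond, g, fwd, p_rev)
            np.testing.assert_array_equal(rev.hap_a + rev.hap_b, g)
            tpair = (truth.haplotypes[2 * s], truth.haplotypes[2 * s + 1])
            fwd_rates.append(
                switch_error_rate((fwd.hap_a, fwd.hap_b), tpair, cfg.n_sites).rate
            )
            rev_rates.append(
                switch_error_rate((rev.hap_a, rev.hap_b), tpair, cfg.n_sites).rate
            )
        assert np.mean(rev_rates) <= np.mean(fwd_rates) + 1e-12


@settings(max_examples=25, deadline=None, derandomize=True)
@given(data=st.data(), n=st.integers(2, 10), m=st.integers(1, 12))
def test_diplotype_consistency_property(data, n, m):
    """hap_a + hap_b equals the input genotype at every non-missing site,
    for arbitrary panels, genotypes and beam configurations."""
    X = np.array(
        data.draw(st.lists(st.integers(0, 1), min_size=n * m, max_size=n * m)),
        dtype=np.uint8,
    ).reshape(n, m)
    g = np.array(
        data.draw(st.lists(st.sampled_from([0, 1, 2, -1]), min_size=m, max_size=m)),
        dtype=np.int8,
    )
    width = data.draw(st.sampled_from([1, 2, 8, 64]))
    delta = data.draw(st.sampled_from([1, 4, 24]))
    cond = make_condensed(X)
    res = phase_sample(cond, g, PhasingParams(beam_width=width, delta=delta))
    ok = g >= 0
    np.testing.assert_array_equal((res.hap_a + res.hap_b)[ok], g[ok])
    het = g == 1
    assert np.all(res.confidence[het] >= 0.5) and np.all(res.confidence[het] <= 1.0)
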