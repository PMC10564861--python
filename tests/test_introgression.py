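"""HMM decoding against exhaustive path enumeration; tract calling; calibration."""

import itertools
import math

import numpy as np
import pytest

from archpain.introgression import (
    HMMParams,
    IntrogressionTract,
    apply_length_cutoff,
    calibrate_length_cutoff,
    call_tracts,
    decode_haplotype,
    decode_panel,
    emission_logprob,
    path_loglik,
    sequence_loglik,
    summarize_introgression,
    tract_frequency_profile,
)
from tests.conftest import make_sites


def enumerate_oracle(alleles, sites, params):
    """Independent brute force: joint log-lik of all 2^n paths.

    Builds emissions and transitions from first principles (no shared code
    with the decoder beyond parameter values) and returns the argmax path
    plus exact per-site archaic posteriors via path summation.
    """
    n = len(sites)
    pi = [1.0 - params.p_arch_prior, params.p_arch_prior]

    def emit(site, allele, state):
        if state == 1:
            p = min(max(site.archaic_gt / 2.0, params.emit_error), 1 - params.emit_error)
        else:
            p = min(max(site.modern_derived_freq, params.freq_floor), 1 - params.freq_floor)
        return math.log(p if allele == 1 else 1 - p)

    def trans(d, i, j):
        s = 1.0 - math.exp(-params.switch_rate * d)
        return math.log(s * pi[j]) if i != j else math.log(1.0 - s * pi[1 - i])

    best, best_ll = None, -math.inf
    total = -math.inf
    post = np.full(n, -math.inf)
    for path in itertools.product((0, 1), repeat=n):
        ll = math.log(pi[path[0]]) + emit(sites[0], alleles[0], path[0])
        for t in range(1, n):
            ll += trans(sites[t].pos - sites[t - 1].pos, path[t - 1], path[t])
            ll += emit(sites[t], alleles[t], path[t])
        if ll > best_ll:
            best, best_ll = path, ll
        total = np.logaddexp(total, ll)
        for t in range(n):
            if path[t] == 1:
                post[t] = np.logaddexp(post[t], ll)
    return np.array(best), best_ll, np.exp(post - total), total


def random_instance(rng, n_sites):
    pos = np.sort(rng.choice(np.arange(1000, 2_000_000, 137), size=n_sites, replace=False))
    gts = rng.integers(0, 3, size=n_sites)
    freqs = rng.uniform(0.01, 0.99, size=n_sites)
    sites = make_sites(pos, gts, freqs)
    alleles = rng.integers(0, 2, size=n_sites)
    params = HMMParams(
        p_arch_prior=float(rng.uniform(0.05, 0.4)),
        switch_rate=float(rng.uniform(1e-6, 1e-4)),
        emit_error=float(rng.uniform(0.005, 0.1)),
        freq_floor=float(rng.uniform(0.005, 0.1)),
    )
    return alleles, sites, params


class TestEmissions:
    def test_archaic_homozygous_derived(self):
        site = make_sites([100], [2], [0.3])[0]
        params = HMMParams(emit_error=0.01)
        assert emission_logprob(site, 1, "archaic", params) == pytest.approx(math.log(0.99))

    def test_modern_half_frequency_symmetric(self):
        site = make_sites([100], [0], [0.5])[0]
        params = HMMParams()
        assert emission_logprob(site, 1, "modern", params) == pytest.approx(math.log(0.5))
        assert emission_logprob(site, 0, "modern", params) == pytest.approx(math.log(0.5))

    def test_archaic_heterozygous_exactly_half(self):
        site = make_sites([100], [1], [0.2])[0]
        assert emission_logprob(site, 1, "archaic", HMMParams()) == pytest.approx(math.log(0.5))


class TestDecoding:
    def test_all_modern_when_archaic_has_no_support(self):
        # archaic proxy ancestral everywhere; alleles drawn at modern freqs
        rng = np.random.default_rng(0)
        freqs = rng.uniform(0.3, 0.7, 50)
        sites = make_sites(np.arange(1, 51) * 1000, np.zeros(50, int), freqs)
        alleles = (rng.random(50) < freqs).astype(int)
        # force several derived observations to make modern clearly favoured
        path, post = decode_haplotype(alleles, sites, HMMParams())
        assert path.sum() == 0

    def test_identical_emissions_resolved_by_prior(self):
        # archaic_gt/2 == modern freq == 0.5 at every site: states equivalent
        sites = make_sites(np.arange(1, 21) * 500, np.ones(20, int), np.full(20, 0.5))
        alleles = np.tile([0, 1], 10)
        params = HMMParams(p_arch_prior=0.02)
        path, post = decode_haplotype(alleles, sites, params)
        assert path.sum() == 0
        assert np.allclose(post, params.p_arch_prior, atol=1e-9)

    @pytest.mark.parametrize("trial", range(10))
    def test_viterbi_and_posteriors_match_exhaustive_enumeration(self, trial):
        rng = np.random.default_rng(100 + trial)
        alleles, sites, params = random_instance(rng, 10)
        path, post = decode_haplotype(alleles, sites, params)
        oracle_path, oracle_ll, oracle_post, _ = enumerate_oracle(alleles, sites, params)
        assert path_loglik(path, alleles, sites, params) == pytest.approx(oracle_ll, abs=1e-10)
        assert np.allclose(post, oracle_post, atol=1e-10)

    def test_forward_backward_totals_agree(self):
        rng = np.random.default_rng(7)
        alleles, sites, params = random_instance(rng, 200)
        f, b = sequence_loglik(alleles, sites, params)
        assert f == pytest.approx(b, abs=1e-8)

    def test_total_likelihood_matches_enumeration(self):
        rng = np.random.default_rng(17)
        alleles, sites, params = random_instance(rng, 10)
        f, _ = sequence_loglik(alleles, sites, params)
        _, _, _, total = enumerate_oracle(alleles, sites, params)
        assert f == pytest.approx(total, abs=1e-10)

    def test_viterbi_dominates_random_paths(self):
        rng = np.random.default_rng(23)
        alleles, sites, params = random_instance(rng, 60)
        path, _ = decode_haplotype(alleles, sites, params)
        best = path_loglik(path, alleles, sites, params)
        for _ in range(1000):
            alt = rng.integers(0, 2, size=60)
            assert path_loglik(alt, alleles, sites, params) <= best + 1e-12

    def test_no_underflow_on_long_sequences(self):
        rng = np.random.default_rng(31)
        n = 100_000
        pos = np.cumsum(rng.integers(100, 900, size=n)) + 1
        sites = make_sites(pos, rng.integers(0, 3, n), rng.uniform(0.01, 0.99, n))
        alleles = rng.integers(0, 2, n)
        path, post = decode_haplotype(alleles, sites, HMMParams())
        assert np.isfinite(post).all()
        assert np.all((post >= 0) & (post <= 1))

    def test_zero_sites_error(self):
        with pytest.raises(ValueError):
            decode_panel(np.empty((1, 0), dtype=int), [], HMMParams())


class TestCallTracts:
    def _run(self, path, post, positions=None):
        n = len(path)
        positions = positions if positions is not None else np.arange(1, n + 1) * 1000
        sites = make_sites(positions, np.full(n, 2), np.full(n, 0.1))
        return np.asarray(path), np.asarray(post), sites

    def test_all_modern_path_empty(self):
        path, post, sites = self._run([0] * 5, [0.001] * 5)
        assert call_tracts(path, post, sites, HMMParams()) == []

    def test_confident_run_retained_with_mean_posterior(self):
        path, post, sites = self._run([0, 1, 1, 1, 0], [0.01, 0.999, 0.999, 0.999, 0.01])
        for mode in ("per_site", "tract_mean"):
            (tract,) = call_tracts(path, post, sites, HMMParams(), retention=mode)
            assert tract.mean_posterior == pytest.approx(0.999)
            assert (tract.start_pos, tract.end_pos, tract.n_sites) == (2000, 4000, 3)

    def test_tract_mean_mode_drops_run_dragged_below_threshold(self):
        # mean of (0.999 x 9, 0.5) = 0.9491 < 0.99 -> dropped under tract_mean
        post = [0.999] * 9 + [0.5]
        path, post, sites = self._run([1] * 10, post)
        assert call_tracts(path, post, sites, HMMParams(), retention="tract_mean") == []
        # excising the 0.5 site restores retention
        path2, post2, sites2 = self._run([1] * 9, [0.999] * 9)
        (t,) = call_tracts(path2, post2, sites2, HMMParams(), retention="tract_mean")
        assert t.mean_posterior == pytest.approx(0.999)
        # the per-site rule performs that excision itself
        (t,) = call_tracts(path, post, sites, HMMParams(), retention="per_site")
        assert t.n_sites == 9 and t.mean_posterior == pytest.approx(0.999)

    def test_min_tract_len_applied(self):
        path, post, sites = self._run([1] * 3, [0.999] * 3)
        assert call_tracts(path, post, sites, HMMParams(min_tract_len=5000)) == []


class TestCalibration:
    def _tract(self, hap, start, length):
        return IntrogressionTract(hap_id=hap, start_pos=start, end_pos=start + length - 1,
                                  n_sites=3, mean_posterior=0.999)

    def test_clean_africans_give_smallest_grid_value(self):
        tracts = [self._tract("nam1", 10_000, 100_000)]
        res = calibrate_length_cutoff(tracts, {"afr1"}, (1, 4_180_000))
        assert res.cutoff_bp == 500.0 and res.achieved

    def test_hand_enumerated_grid_example(self):
        # African tracts of 5/10/23/40 kb on one 4.18 Mb chromosome with
        # tolerance 1e-4 (residual budget 418 bp): every grid value up to
        # 40.0 kb keeps the 40 kb tract (40,000 bp > 418); 40.5 kb is the
        # smallest L discarding enough bp.
        tracts = [self._tract("afr1", s, L) for s, L in
                  [(10_000, 5_000), (200_000, 10_000), (500_000, 23_000), (900_000, 40_000)]]
        tracts.append(self._tract("nam1", 50_000, 123_000))
        res = calibrate_length_cutoff(tracts, {"afr1"}, (1, 4_180_000), tolerance=1e-4)
        assert res.cutoff_bp == 40_500.0
        assert res.achieved and not res.discards_all_non_african

    def test_degenerate_flag_when_cutoff_exceeds_all_non_african(self):
        tracts = [self._tract("afr1", 10_000, 200_000), self._tract("nam1", 50_000, 30_000)]
        res = calibrate_length_cutoff(tracts, {"afr1"}, (1, 4_180_000), tolerance=1e-4)
        assert res.discards_all_non_african

    def test_no_african_haplotypes_error(self):
        with pytest.raises(ValueError, match="African"):
            calibrate_length_cutoff([], set(), (1, 100))


class TestSummaries:
    def test_single_tract_percentage_arithmetic(self):
        t = IntrogressionTract("h1", 1, 41_800, n_sites=10, mean_posterior=0.999)
        df = summarize_introgression([t], {"g": {"h1"}}, (1, 4_180_000))
        assert df.loc[0, "mean_pct_archaic"] == pytest.approx(1.0)
        assert df.loc[0, "n_tracts"] == 1

    def test_duplicated_haplotypes_double_counts_not_frequency(self):
        t1 = IntrogressionTract("h1", 1000, 2000, 3, 0.999)
        t2 = IntrogressionTract("h2", 1000, 2000, 3, 0.999)
        q = np.array([1500])
        single = tract_frequency_profile([t1], 1, q)
        double = tract_frequency_profile([t1, t2], 2, q)
        assert single[0] == double[0] == 1.0

    def test_profile_matches_interval_stabbing_oracle(self):
        rng = np.random.default_rng(3)
        tracts = []
        for k in range(300):
            s = int(rng.integers(1, 4_000_000))
            tracts.append(IntrogressionTract(f"h{k % 50}", s, s + int(rng.integers(1, 200_000)), 2, 0.999))
        probes = rng.integers(1, 4_200_000, size=1000)
        prof = tract_frequency_profile(tracts, 50, probes)
        for q, v in zip(probes, prof):
            brute = sum(1 for t in tracts if t.start_pos <= q <= t.end_pos) / 50
            assert v == pytest.approx(brute)

    def test_raising_length_cutoff_is_monotone(self):
        rng = np.random.default_rng(5)
        tracts = []
        for k in range(200):
            s = int(rng.integers(1, 4_000_000))
            tracts.append(IntrogressionTract(f"h{k % 40}", s, s + int(rng.integers(1000, 150_000)), 2, 0.999))
        groups = {"all": {f"h{i}" for i in range(40)}}
        probes = np.linspace(1, 4_180_000, 50)
        prev_n, prev_pct, prev_prof = math.inf, math.inf, np.full(50, math.inf)
        for cutoff in (0, 10_000, 50_000, 100_000, 200_000):
            kept = apply_length_cutoff(tracts, cutoff)
            df = summarize_introgression(kept, groups, (1, 4_180_000))
            prof = tract_frequency_profile(kept, 40, probes)
            assert len(kept) <= prev_n
            assert df.loc[0, "mean_pct_archaic"] <= prev_pct + 1e-12
            assert np.all(prof <= prev_prof + 1e-12)
            prev_n, prev_pct, prev_prof = len(kept), df.loc[0, "mean_pct_archaic"], prof
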