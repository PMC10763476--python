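import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from imphazard import imputation_engine as ie, synthetic_data as sd
from imphazard.core import MISSING, CohortStudy, HaplotypePanel, SiteInfo


def brute_force_posteriors(target, ref, pos_bp, rho_per_kb, eps):
    """Exhaustive copying-path enumeration oracle (independent of the HMM)."""
    K, L = ref.shape
    d_kb = np.diff(np.asarray(pos_bp, dtype=float)) / 1000.0
    stay = np.exp(-rho_per_kb * d_kb / K)

    def emit(l, k):
        if target[l] == MISSING:
            return 1.0
        return 1.0 - eps if ref[k, l] == target[l] else eps

    post = np.zeros((L, K))
    total = 0.0
    for path in itertools.product(range(K), repeat=L):
        p = (1.0 / K) * emit(0, path[0])
        for l in range(1, L):
            t = 1.0 - stay[l - 1]
            p *= (stay[l - 1] if path[l] == path[l - 1] else 0.0) + t / K
            p *= emit(l, path[l])
        total += p
        for l in range(L):
            post[l, path[l]] += p
    return post / total


def panel_from(ref, pos):
    sites = [
        SiteInfo(id=f"s{i}", chrom="1", pos_bp=int(p), ref_allele="A", alt_allele="G")
        for i, p in enumerate(pos)
    ]
    return HaplotypePanel(ref, sites)


class TestCopyingPosteriors:
    def test_single_state_posterior_one(self):
        ref = np.array([[0, 1, 0]], dtype=np.int8)
        panel = panel_from(ref, [100, 200, 300])
        cfg = ie.ImputationConfig(reference=panel, epsilon=0.01)
        post = ie.copying_posteriors(np.array([0, 1, 0], dtype=np.int8), cfg)
        np.testing.assert_allclose(post, 1.0)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            K = int(rng.integers(2, 5))
            L = int(rng.integers(2, 6))
            ref = rng.integers(0, 2, (K, L)).astype(np.int8)
            pos = np.sort(rng.choice(40000, L, replace=False)) + 1
            target = rng.integers(0, 2, L).astype(np.int8)
            target[rng.random(L) < 0.3] = MISSING
            cfg = ie.ImputationConfig(reference=panel_from(ref, pos), rho_per_kb=0.4,
                                      epsilon=0.01)
            got = ie.copying_posteriors(target, cfg)
            want = brute_force_posteriors(target, ref, pos, 0.4, 0.01)
            np.testing.assert_allclose(got, want, atol=1e-9)

    def test_exact_match_limit(self):
        rng = np.random.default_rng(1)
        ref = rng.integers(0, 2, (4, 6)).astype(np.int8)
        panel = panel_from(ref, np.arange(6) * 1000 + 1)
        cfg = ie.ImputationConfig(reference=panel, rho_per_kb=0.0, epsilon=1e-9)
        post = ie.copying_posteriors(ref[2].copy(), cfg)
        # rho=0, eps->0: posterior concentrates on haplotypes identical to the target
        matches = (ref == ref[2]).all(axis=1)
        np.testing.assert_allclose(post[:, matches].sum(axis=1), 1.0, atol=1e-6)

    def test_duplicate_collapse_is_exact(self):
        # duplicated reference rows must not change per-haplotype marginals
        rng = np.random.default_rng(3)
        base = rng.integers(0, 2, (3, 4)).astype(np.int8)
        ref = np.vstack([base, base[1], base[1]])  # hap 1 tripled
        pos = [100, 5100, 9100, 15100]
        target = np.array([1, MISSING, 0, 1], dtype=np.int8)
        cfg = ie.ImputationConfig(reference=panel_from(ref, pos), epsilon=0.02)
        got = ie.copying_posteriors(target, cfg)
        want = brute_force_posteriors(target, ref, pos, 0.4, 0.02)
        np.testing.assert_allclose(got, want, atol=1e-9)


class TestImputeMasked:
    def _study_and_ref(self, seed=0, noise=0.0):
        founders = sd.build_founders(5, 12, 3, "monophyletic", seed=seed)
        freqs = np.array([0.4, 0.2, 0.1, 0.2, 0.1])
        cfg = sd.SimulationConfig(
            founder_haplotypes=founders,
            founder_freqs_reference=freqs,
            founder_freqs_cases=freqs,
            founder_freqs_controls=freqs,
            n_reference_haps=200,
            n_cases=25,
            n_controls=25,
            mutation_rate=noise,
            recombination_rate=noise,
            seed=seed,
        )
        return sd.sample_cohort(cfg), sd.sample_reference_panel(cfg)

    def test_forced_alt_when_reference_fixed(self):
        ref_alleles = np.ones((6, 3), dtype=np.int8)
        ref_alleles[:, 0] = [0, 1, 0, 1, 0, 1]
        panel = panel_from(ref_alleles, [100, 200, 300])
        sites = panel.sites
        study = CohortStudy(
            cases=np.array([[1, 2, 2]], dtype=np.int8),
            controls=np.array([[0, 2, 2]], dtype=np.int8),
            sites=sites,
            truth_case_haps=HaplotypePanel(np.array([[1, 1, 1], [0, 1, 1]]), sites),
            truth_control_haps=HaplotypePanel(np.array([[0, 1, 1], [0, 1, 1]]), sites),
        )
        cfg = ie.ImputationConfig(reference=panel, epsilon=1e-12)
        post = ie.impute_masked(study, [sites[1].id], cfg)
        np.testing.assert_allclose(post.cases[:, 0], [[0, 0, 1]], atol=1e-9)
        np.testing.assert_allclose(post.controls[:, 0], [[0, 0, 1]], atol=1e-9)

    def test_self_reference_identity(self):
        study, _ = self._study_and_ref(seed=2, noise=0.0)
        own = HaplotypePanel(
            np.vstack([study.truth_case_haps.alleles, study.truth_control_haps.alleles]),
            study.sites,
        )
        masked = [s.id for s in study.sites if s.is_associated]
        cfg = ie.ImputationConfig(reference=own)
        post = ie.impute_masked(study, masked, cfg)
        calls_cases = ie.call_genotypes(post.cases, 0.9)
        calls_controls = ie.call_genotypes(post.controls, 0.9)
        idx = [study.site_index()[m] for m in masked]
        np.testing.assert_array_equal(calls_cases, study.cases[:, idx])
        np.testing.assert_array_equal(calls_controls, study.controls[:, idx])

    def test_uncorrelated_masked_site_pulled_to_reference_frequency(self):
        # masked site independent of scaffold in the reference: imputed dosage
        # approaches 2f regardless of the study's true frequency
        rng = np.random.default_rng(7)
        L = 8
        n_ref = 400
        scaffold = rng.integers(0, 2, (n_ref, L)).astype(np.int8)
        f = 0.3
        masked_col = (rng.random(n_ref) < f).astype(np.int8)
        ref = np.column_stack([scaffold[:, :4], masked_col, scaffold[:, 4:]])
        pos = np.arange(L + 1) * 900 + 1
        panel = panel_from(ref, pos)
        sites = panel.sites
        # 100 study individuals whose truth carries NO alt at the masked site
        n = 100
        haps = np.zeros((2 * n, L + 1), dtype=np.int8)
        haps[:, np.r_[0:4, 5:L + 1]] = rng.integers(0, 2, (2 * n, L))
        genos = haps[0::2] + haps[1::2]
        study = CohortStudy(
            cases=genos, controls=genos.copy(), sites=sites,
            truth_case_haps=HaplotypePanel(haps, sites),
            truth_control_haps=HaplotypePanel(haps.copy(), sites),
        )
        cfg = ie.ImputationConfig(reference=panel, epsilon=0.01)
        post = ie.impute_masked(study, [sites[4].id], cfg)
        dosage = (post.cases[:, 0, 1] + 2 * post.cases[:, 0, 2]).mean()
        assert dosage == pytest.approx(2 * f, abs=0.15)

    def test_masked_site_absent_from_reference_reported(self):
        study, ref = self._study_and_ref(seed=3)
        keep = [i for i, s in enumerate(ref.sites) if s.id != study.sites[2].id]
        ref_sub = ref.subset_sites(keep)
        cfg = ie.ImputationConfig(reference=ref_sub)
        post = ie.impute_masked(study, [study.sites[2].id], cfg)
        assert post.not_imputable == [study.sites[2].id]
        assert post.site_ids == []

    def test_scaffold_site_absent_raises(self):
        study, ref = self._study_and_ref(seed=3)
        masked = [s.id for s in study.sites if s.is_associated]
        dropped = next(i for i, s in enumerate(study.sites) if not s.is_associated)
        keep = [i for i in range(ref.n_sites) if i != dropped]
        cfg = ie.ImputationConfig(reference=ref.subset_sites(keep))
        with pytest.raises(ie.NotImputableError, match=study.sites[dropped].id):
            ie.impute_masked(study, masked, cfg)


class TestCallGenotypes:
    def test_clear_argmax_called(self):
        assert ie.call_genotypes(np.array([[0.95, 0.03, 0.02]]), 0.9)[0] == 0

    def test_below_threshold_missing(self):
        assert ie.call_genotypes(np.array([[0.50, 0.40, 0.10]]), 0.9)[0] == MISSING

    def test_zero_threshold_always_calls(self):
        rng = np.random.default_rng(0)
        p = rng.dirichlet(np.ones(3), size=50)
        calls = ie.call_genotypes(p, 1e-12)
        assert (calls != MISSING).all()
        np.testing.assert_array_equal(calls, p.argmax(axis=1))

    def test_tie_at_threshold_missing(self):
        assert ie.call_genotypes(np.array([[0.5, 0.5, 0.0]]), 0.5)[0] == MISSING

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_missingness_monotone_in_threshold(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.dirichlet(np.ones(3), size=20)
        t1, t2 = sorted(rng.uniform(0.4, 1.0, 2))
        m1 = (ie.call_genotypes(p, t1) == MISSING).sum()
        m2 = (ie.call_genotypes(p, t2) == MISSING).sum()
        assert m1 <= m2


class TestInfoScore:
    def test_degenerate_triples_give_one(self):
        p = np.array([[1.0, 0, 0], [0, 0, 1.0], [0, 1.0, 0]])
        assert ie.info_score(p) == pytest.approx(1.0)

    def test_hand_computed_half(self):
        p = np.array([[0.25, 0.5, 0.25]] * 2)
        # e = 1, f = 1.5, theta = 0.5 -> 1 - 1.0/1.0 = 0
        assert ie.info_score(p) == pytest.approx(0.0, abs=1e-12)

    def test_boundary_theta_zero(self):
        p = np.array([[1.0, 0, 0]] * 5)
        assert ie.info_score(p) == pytest.approx(1.0)

    def test_never_exceeds_one(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.dirichlet(np.ones(3), size=10)
            assert ie.info_score(p) <= 1.0 + 1e-12


def test_genotype_triples_normalized():
    founders = sd.build_founders(4, 10, 2, "monophyletic", seed=0)
    freqs = np.array([0.4, 0.3, 0.2, 0.1])
    cfg = sd.SimulationConfig(
        founder_haplotypes=founders,
        founder_freqs_reference=freqs,
        founder_freqs_cases=freqs,
        founder_freqs_controls=freqs,
        n_reference_haps=100,
        n_cases=10,
        n_controls=10,
        mutation_rate=0.01,
        seed=1,
    )
    study = sd.sample_cohort(cfg)
    ref = sd.sample_reference_panel(cfg)
    masked = [s.id for s in study.sites if s.is_associated]
    post = ie.impute_masked(study, masked, ie.ImputationConfig(reference=ref))
    np.testing.assert_allclose(post.cases.sum(axis=-1), 1.0, atol=1e-9)
    np.testing.assert_allclose(post.controls.sum(axis=-1), 1.0, atol=1e-9)
    assert (post.cases >= 0).all()


def test_default_epsilon_formula():
    K = 1000
    theta = 1.0 / np.sum(1.0 / np.arange(1, K))
    assert ie.default_epsilon(K) == pytest.approx(theta / (2 * (K + theta)))
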