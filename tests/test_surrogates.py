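"""Connectome harmonics, GFT and sign-randomised surrogate contracts."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from boldcomplexity import (
    RoiTimeSeries,
    StructuralConnectome,
    SyntheticSpec,
    ValidationError,
    basis_from_connectome,
    gen_fgn,
    gen_subject,
    gft,
    graph_basis,
    graph_psd,
    harmonic_complexity,
    igft,
    knee_point,
    make_surrogate,
    normalized_laplacian,
    surrogate_ensemble,
)
from boldcomplexity.pipeline import surrogate_null
from boldcomplexity.surrogates import rademacher_signs


def ring(n: int) -> StructuralConnectome:
    w = np.zeros((n, n))
    for i in range(n):
        w[i, (i + 1) % n] = w[(i + 1) % n, i] = 1.0
    return StructuralConnectome(weights=w)


class TestLaplacian:
    def test_two_node_eigenvalues(self):
        con = StructuralConnectome(weights=np.array([[0.0, 1.0], [1.0, 0.0]]))
        evals = np.linalg.eigvalsh(normalized_laplacian(con))
        np.testing.assert_allclose(evals, [0.0, 2.0], atol=1e-12)

    def test_ring_of_four_eigenvalues(self):
        evals = np.linalg.eigvalsh(normalized_laplacian(ring(4)))
        np.testing.assert_allclose(evals, [0.0, 1.0, 1.0, 2.0], atol=1e-12)

    def test_adjacency_normalisation_reproduces_degrees(self, connectome30):
        # rows of D^{−1/2} A D^{−1/2}, rescaled by sqrt-degree products,
        # recover the original degree vector
        lap = normalized_laplacian(connectome30)
        a_norm = np.eye(30) - lap
        d = connectome30.degrees()
        rebuilt = a_norm * np.sqrt(d)[:, None] * np.sqrt(d)[None, :]
        np.testing.assert_allclose(rebuilt.sum(axis=1), d, rtol=1e-10)

    def test_isolated_node_rejected(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        with pytest.raises(ValidationError, match="isolated"):
            normalized_laplacian(StructuralConnectome(weights=w))

    def test_combinatorial_variant(self, connectome30):
        lap = normalized_laplacian(connectome30, variant="combinatorial")
        np.testing.assert_allclose(lap.sum(axis=1), 0.0, atol=1e-10)


class TestGraphBasis:
    def test_orthonormal_and_ascending(self, basis30):
        n = basis30.n_roi
        gram = basis30.eigenvectors.T @ basis30.eigenvectors
        np.testing.assert_allclose(gram, np.eye(n), atol=1e-8)
        assert np.all(np.diff(basis30.eigenvalues) >= -1e-10)
        assert basis30.eigenvalues[0] == pytest.approx(0.0, abs=1e-10)
        assert basis30.eigenvalues[-1] <= 2.0 + 1e-10

    def test_regular_graph_first_harmonic_constant(self):
        basis = graph_basis(normalized_laplacian(ring(6)))
        first = basis.eigenvectors[:, 0]
        np.testing.assert_allclose(first, first[0], atol=1e-10)

    def test_deterministic_on_rerun(self, connectome30):
        a = basis_from_connectome(connectome30)
        b = basis_from_connectome(connectome30)
        assert np.array_equal(a.eigenvectors, b.eigenvectors)
        assert np.array_equal(a.eigenvalues, b.eigenvalues)

    def test_sign_convention(self, basis30):
        for j in range(basis30.n_roi):
            v = basis30.eigenvectors[:, j]
            assert v[np.argmax(np.abs(v))] > 0

    def test_asymmetric_rejected(self):
        lap = np.array([[1.0, 0.3], [-0.2, 1.0]])
        with pytest.raises(ValidationError):
            graph_basis(lap)


class TestGft:
    def test_round_trip_and_parseval(self, basis30, rng):
        data = RoiTimeSeries(rng.standard_normal((64, 30)), tr=0.72)
        coeff = gft(basis30, data)
        np.testing.assert_allclose(igft(basis30, coeff), data.values,
                                   atol=1e-10)
        np.testing.assert_allclose((coeff**2).sum(axis=1),
                                   (data.values**2).sum(axis=1), atol=1e-10)

    def test_constant_frame_on_regular_graph(self):
        basis = graph_basis(normalized_laplacian(ring(8)))
        frame = np.ones((1, 8))
        coeff = gft(basis, frame)
        energy = coeff[0] ** 2
        assert energy[0] == pytest.approx(energy.sum(), rel=1e-10)

    def test_graph_psd_single_harmonic(self, basis30):
        coeff = np.zeros((16, 30))
        coeff[:, 4] = 2.0
        signal = igft(basis30, coeff)
        power = graph_psd(gft(basis30, signal))
        assert power[4] == pytest.approx(4.0, rel=1e-10)
        assert np.abs(np.delete(power, 4)).max() < 1e-16

    def test_graph_psd_normalized_and_parseval(self, basis30, rng):
        data = rng.standard_normal((64, 30))
        power = graph_psd(data @ basis30.eigenvectors)
        assert power.sum() == pytest.approx(
            (data**2).sum(axis=1).mean(), rel=1e-10)
        assert graph_psd(data @ basis30.eigenvectors,
                         normalize=True).max() == 1.0


@pytest.fixture(scope="module")
def coupled_subject(connectome30):
    spec = SyntheticSpec(n_roi=30, n_time=399, coupling_strength=1.0,
                         subject_sd=0.0)
    return gen_subject(spec, connectome30, seed=11)


class TestSurrogates:
    def test_all_plus_one_is_identity(self, coupled_subject, basis30):
        surr = make_surrogate(coupled_subject, basis30, np.ones(30))
        np.testing.assert_allclose(surr.values, coupled_subject.values,
                                   atol=1e-12)

    def test_temporal_gram_preserved(self, coupled_subject, basis30):
        signs = rademacher_signs(30, 5, master_seed=0)
        gram = coupled_subject.values @ coupled_subject.values.T
        for s in signs:
            surr = make_surrogate(coupled_subject, basis30, s)
            np.testing.assert_allclose(surr.values @ surr.values.T, gram,
                                       atol=1e-8)

    def test_harmonic_magnitudes_preserved(self, coupled_subject, basis30):
        s = rademacher_signs(30, 1, master_seed=3)[0]
        surr = make_surrogate(coupled_subject, basis30, s)
        np.testing.assert_allclose(gft(basis30, surr) ** 2,
                                   gft(basis30, coupled_subject) ** 2,
                                   atol=1e-10)

    def test_involutory(self, coupled_subject, basis30):
        s = rademacher_signs(30, 1, master_seed=4)[0]
        twice = make_surrogate(make_surrogate(coupled_subject, basis30, s),
                               basis30, s)
        np.testing.assert_allclose(twice.values, coupled_subject.values,
                                   atol=1e-10)

    def test_invalid_sign_vector_rejected(self, coupled_subject, basis30):
        with pytest.raises(ValidationError):
            make_surrogate(coupled_subject, basis30, np.full(30, 0.5))

    def test_ensemble_regenerable_and_distinct(self, coupled_subject, basis30):
        ens = surrogate_ensemble(coupled_subject, basis30, n_surr=100,
                                 master_seed=21)
        assert len(ens) == 100
        # any surrogate regenerable in isolation from (master_seed, index)
        rng = np.random.default_rng((21, 57))
        signs = rng.choice([-1.0, 1.0], size=30)
        signs[0] = 1.0
        assert np.array_equal(ens.sign_vectors[57], signs)
        assert len({tuple(v) for v in ens.sign_vectors}) == 100

    def test_hurst_varies_but_graph_psd_fixed(self, coupled_subject, basis30):
        """Spatial reallocation: per-ROI scaling exponents vary across the
        ensemble while the pooled graph spectral power is untouched."""
        from boldcomplexity.complexity import dfa_hurst_batch

        ens = surrogate_ensemble(coupled_subject, basis30, n_surr=20,
                                 master_seed=2)
        base_psd = graph_psd(gft(basis30, coupled_subject))
        hursts = []
        for surr in ens:
            np.testing.assert_allclose(graph_psd(gft(basis30, surr)),
                                       base_psd, atol=1e-10)
            hursts.append(dfa_hurst_batch(surr.values))
        assert np.array(hursts).std(axis=0).min() > 0

    def test_fc_randomised_sign_test(self, coupled_subject, basis30):
        """Off-diagonal FC entries shift between original and surrogates
        (two-sided sign test at 0.01, far above the 1% null rate)."""
        from scipy.stats import binomtest

        iu = np.triu_indices(30, 1)
        fc_orig = np.corrcoef(coupled_subject.values.T)[iu]
        ens = surrogate_ensemble(coupled_subject, basis30, n_surr=100,
                                 master_seed=77)
        fc_surr = np.array([np.corrcoef(s.values.T)[iu] for s in ens])
        rejections = 0
        for e in range(fc_orig.size):
            k = int((fc_surr[:, e] > fc_orig[e]).sum())
            if binomtest(k, 100, 0.5).pvalue < 0.01:
                rejections += 1
        assert rejections / fc_orig.size > 0.2


class TestHarmonicComplexity:
    def test_recovers_harmonic_complexity_ordering(self, basis30):
        # coefficients built with H decreasing across harmonics: the
        # complexity index must decrease along the harmonic axis
        hs = np.linspace(0.9, 0.5, 30)
        coeff = np.column_stack([gen_fgn(h, 1024, seed=(5, i))
                                 for i, h in enumerate(hs)])
        data = RoiTimeSeries(igft(basis30, coeff), tr=0.72)
        _, ci = harmonic_complexity(gft(basis30, data), scales=range(1, 6))
        rho = spearmanr(ci, np.arange(30)).statistic
        assert rho < -0.4

    def test_constant_harmonic_zero_entropy(self, basis30):
        coeff = np.zeros((256, 30))
        coeff[:, 3] = 5.0
        curves, ci = harmonic_complexity(coeff, scales=range(1, 4))
        np.testing.assert_array_equal(curves[3].entropy, 0.0)

    def test_white_noise_lower_ci_than_coupled(self, basis30, coupled_subject,
                                               rng):
        white = RoiTimeSeries(rng.standard_normal((399, 30)), tr=0.72)
        _, ci_white = harmonic_complexity(gft(basis30, white),
                                          scales=range(1, 6))
        _, ci_coupled = harmonic_complexity(gft(basis30, coupled_subject),
                                            scales=range(1, 6))
        assert np.nanmean(ci_coupled) > np.nanmean(ci_white)


class TestKneePoint:
    def test_piecewise_linear_breakpoint(self):
        y = np.concatenate([np.linspace(10, 2, 9), np.linspace(2, 1.8, 12)[1:]])
        assert knee_point(y) == 8

    def test_straight_line_has_no_knee(self):
        assert knee_point(np.linspace(3.0, 1.0, 15)) is None

    def test_reversed_profile_symmetric(self):
        y = np.concatenate([np.linspace(10, 2, 9), np.linspace(2, 1.8, 12)[1:]])
        assert knee_point(y[::-1]) == len(y) - 1 - knee_point(y)


class TestSurrogateNullHelper:
    def test_hurst_null_matches_per_surrogate_estimates(self, coupled_subject,
                                                        basis30):
        from boldcomplexity.complexity import dfa_hurst_batch

        null = surrogate_null(coupled_subject, basis30, n_surr=5,
                              master_seed=3, statistic="hurst")
        ens = surrogate_ensemble(coupled_subject, basis30, n_surr=5,
                                 master_seed=3)
        direct = np.vstack([dfa_hurst_batch(s.values) for s in ens])
        np.testing.assert_allclose(null, direct, rtol=1e-12)
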