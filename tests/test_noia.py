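import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from breedarch.markers import GenotypeMatrix
from breedarch.noia import (
    build_kernels,
    epistatic_kernels,
    gaussian_kernel,
    noia_coding,
    optimize_bandwidth,
    relationship_matrices,
)

from .conftest import random_genotypes


class TestNoiaCoding:
    def test_hand_fixture(self, toy_genotypes):
        """Codes [2,1,1,0] (freqs 1/4,1/2,1/4): Wa=[1,0,0,-1], Wd=+-0.5."""
        d = noia_coding(toy_genotypes)
        assert np.allclose(d.Wa[:, 0], [1, 0, 0, -1])
        assert np.allclose(d.Wd[:, 0], [-0.5, 0.5, 0.5, -0.5])
        assert abs(np.sum(d.Wa[:, 0] * d.Wd[:, 0])) < 1e-12

    def test_hwe_half_frequency_contrast(self):
        """At HWE with p=0.5 the dominance coding is the classical contrast."""
        # genotype counts 1:2:1 over 4k individuals = exact HWE at p=0.5
        codes = np.repeat([2, 1, 1, 0], 1000).astype(np.int8)[:, None]
        g = GenotypeMatrix(codes, ["c1"], [1], [f"i{i}" for i in range(4000)])
        d = noia_coding(g)
        by_code = {c: d.Wd[codes[:, 0] == c, 0][0] for c in (0, 1, 2)}
        assert by_code[2] == pytest.approx(-0.5)
        assert by_code[1] == pytest.approx(0.5)
        assert by_code[0] == pytest.approx(-0.5)

    def test_all_heterozygous_locus_degenerate(self):
        codes = np.ones((6, 1), dtype=np.int8)
        g = GenotypeMatrix(codes, ["c1"], [1], [f"i{i}" for i in range(6)])
        d = noia_coding(g)
        assert d.degenerate[0]
        assert np.all(d.Wd[:, 0] == 0.0)

    def test_orthogonality_random_populations(self):
        """Zero-sum and zero-cross-product identities hold without HWE."""
        rng = np.random.default_rng(99)
        for _ in range(20):
            g = random_genotypes(rng, rng.integers(20, 200), 30)
            d = noia_coding(g)
            ok = ~d.degenerate
            assert np.abs(d.Wa[:, ok].sum(axis=0)).max() < 1e-9
            assert np.abs(d.Wd[:, ok].sum(axis=0)).max() < 1e-9
            assert np.abs((d.Wa[:, ok] * d.Wd[:, ok]).sum(axis=0)).max() < 1e-9

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_orthogonality_property(self, seed):
        rng = np.random.default_rng(seed)
        g = random_genotypes(rng, int(rng.integers(10, 120)), 12, missing_rate=0.05)
        d = noia_coding(g)
        ok = ~d.degenerate
        assert np.abs(d.Wa[:, ok].sum(axis=0)).max() < 1e-9
        assert np.abs((d.Wa[:, ok] * d.Wd[:, ok]).sum(axis=0)).max() < 1e-9


class TestRelationshipMatrices:
    def test_trace_normalized(self, breeding_design):
        A, D = relationship_matrices(breeding_design)
        n = breeding_design.n_individuals
        assert np.trace(A) == pytest.approx(n, abs=1e-6)
        assert np.trace(D) == pytest.approx(n, abs=1e-6)
        assert np.allclose(A, A.T)

    def test_single_locus_hand_product(self, toy_genotypes):
        d = noia_coding(toy_genotypes)
        A, _ = relationship_matrices(d)
        # Wa = [1,0,0,-1]: tr(Wa Wa') = 2, scale = 2/4 -> A11 = 1/0.5 = 2
        assert A[0, 0] == pytest.approx(2.0)
        assert A[0, 3] == pytest.approx(-2.0)

    def test_duplicated_individuals_share_rows(self):
        rng = np.random.default_rng(5)
        g = random_genotypes(rng, 10, 20)
        codes = np.vstack([g.codes, g.codes[:1]])
        g2 = GenotypeMatrix(
            codes, g.chrom, g.pos, [f"i{i}" for i in range(11)]
        )
        A, D = relationship_matrices(noia_coding(g2))
        assert np.allclose(A[0], A[10])
        assert np.allclose(D[0], D[10])

    def test_fully_inbred_panel_has_no_dominance_matrix(self):
        """A panel without heterozygotes has an all-zero dominance coding."""
        rng = np.random.default_rng(13)
        codes = (2 * rng.integers(0, 2, (12, 6))).astype(np.int8)
        g = GenotypeMatrix(codes, ["c1"] * 6, np.arange(1, 7),
                           [f"i{i}" for i in range(12)])
        with pytest.raises(ValueError, match="dominance"):
            relationship_matrices(noia_coding(g))

    def test_hwe_matches_centered_grm(self):
        """In the NOIA coding Wa is the frequency-centered score, so A equals
        the standard centered genomic relationship matrix after matching
        normalizations."""
        rng = np.random.default_rng(6)
        L = 50
        p = rng.uniform(0.2, 0.8, L)
        codes = ((rng.random((40, L)) < p).astype(int)
                 + (rng.random((40, L)) < p).astype(int)).astype(np.int8)
        g = GenotypeMatrix(codes, ["c1"] * L, np.arange(1, L + 1),
                           [f"i{i}" for i in range(40)])
        A, _ = relationship_matrices(noia_coding(g))
        x = codes.astype(float)
        x -= x.mean(axis=0)
        grm = x @ x.T
        grm *= len(x) / np.trace(grm)
        assert np.allclose(A, grm, atol=1e-8)


class TestEpistaticKernels:
    def test_traces(self, breeding_design):
        A, D = relationship_matrices(breeding_design)
        Vaa, Vad, Vdd = epistatic_kernels(A, D)
        n = A.shape[0]
        for m in (Vaa, Vad, Vdd):
            assert np.trace(m) == pytest.approx(n, abs=1e-6)

    def test_identity_is_fixed_point(self):
        eye = np.eye(7)
        Vaa, Vad, Vdd = epistatic_kernels(eye, eye)
        assert np.allclose(Vaa, eye)

    def test_single_locus_hand_computation(self, toy_genotypes):
        d = noia_coding(toy_genotypes)
        A, D = relationship_matrices(d)
        Vaa, _, _ = epistatic_kernels(A, D)
        raw = A * A  # tr = 8 for the fixture
        assert np.trace(raw) == pytest.approx(8.0)
        assert np.allclose(Vaa, raw / 2.0)

    def test_psd(self, breeding_kernels):
        for name in ("A", "D", "Vaa", "Vad", "Vdd", "K"):
            m = getattr(breeding_kernels, name)
            w = np.linalg.eigvalsh(m)
            assert w.min() > -1e-8 * max(1.0, w.max())

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            epistatic_kernels(np.eye(3), np.eye(4))


class TestGaussianKernel:
    def test_identical_rows(self):
        x = np.ones((3, 5))
        S, K = gaussian_kernel(x, 0.5)
        assert np.all(S == 0)
        assert np.all(K == 1.0)

    def test_direct_value(self):
        x = np.array([[0.0, 0.0], [1.0, 1.0]])
        S, K = gaussian_kernel(x, 0.5)
        assert S[0, 1] == pytest.approx(2.0)
        assert K[0, 1] == pytest.approx(np.exp(-1.0))

    def test_diagonal_exactly_one(self, breeding_pop):
        geno, _ = breeding_pop
        _, K = gaussian_kernel(geno, 0.01)
        assert np.all(np.diag(K) == 1.0)

    def test_invalid_bandwidth(self):
        with pytest.raises(ValueError, match="bandwidth"):
            gaussian_kernel(np.ones((2, 2)), 0.0)


class TestBandwidthSelection:
    @pytest.fixture(scope="class")
    def distances(self):
        rng = np.random.default_rng(3)
        x = rng.integers(0, 3, (200, 150)).astype(float)
        S, _ = gaussian_kernel(x, 1.0)
        return S

    def test_recovery_majority_at_high_signal(self, distances):
        """y drawn from K(h0) at a grid point: h0 is selected most often."""
        S = distances
        rng = np.random.default_rng(17)
        med = np.median(S[S > 0])
        h0 = 1.0 / med
        K0 = np.exp(-h0 * S)
        np.fill_diagonal(K0, 1.0)
        w, U = np.linalg.eigh(K0)
        w = np.clip(w, 0, None)
        hits = 0
        n_rep = 11
        for _ in range(n_rep):
            u = U @ (rng.standard_normal(len(S)) * np.sqrt(w))
            y = u + rng.normal(0, 0.05 * u.std(), len(S))
            hits += abs(optimize_bandwidth(S, y) - h0) < 1e-12
        assert hits > n_rep / 2

    def test_constant_response_returns_smallest(self, distances):
        h = optimize_bandwidth(distances, np.ones(len(distances)))
        med = np.median(distances[distances > 0])
        assert h == pytest.approx(0.01 / med)

    def test_scale_invariance(self, distances):
        """h enters only through h*S: doubling S halves the selected h."""
        rng = np.random.default_rng(23)
        y = rng.standard_normal(len(distances))
        h1 = optimize_bandwidth(distances, y)
        h2 = optimize_bandwidth(2.0 * distances, y)
        assert h2 == pytest.approx(h1 / 2.0)

    def test_minimum_size(self, distances):
        with pytest.raises(ValueError, match="at least 10"):
            optimize_bandwidth(distances[:5, :5], np.zeros(5))


def test_build_kernels_all_traces(breeding_kernels):
    n = len(breeding_kernels.ids)
    for name in ("A", "D", "Vaa", "Vad", "Vdd"):
        assert np.trace(getattr(breeding_kernels, name)) == pytest.approx(n, abs=1e-6)
    assert np.all(np.diag(breeding_kernels.K) == 1.0)
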