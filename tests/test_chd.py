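"""Connectome harmonics: template construction, Laplacian spectra,
projection identities and windowed spectra."""

import numpy as np
import pytest

from semstory import ValidationError, make_toy_connectome
from semstory.chd import (HarmonicWeights, StructuralConnectome,
                          build_template_adjacency, compute_harmonics,
                          harmonic_windows, project_signal, reconstruct_signal,
                          window_length)


@pytest.fixture(scope="module")
def ring_basis():
    return compute_harmonics(make_toy_connectome("ring", 64))


class TestTemplateAdjacency:
    def _coords(self, n, spread=1000.0):
        # coordinates far apart so the local rule never fires unless asked
        return np.column_stack([np.arange(n) * spread, np.zeros(n), np.zeros(n)])

    def test_interregion_links_from_mean_threshold(self):
        # [[0, 3], [3, 0]]: mean of entries = 1.5, so 3 > 1.5 connects regions
        labels = np.array([0, 0, 1, 1])
        conn = build_template_adjacency(np.array([[0.0, 3.0], [3.0, 0.0]]),
                                        labels, self._coords(4),
                                        local_radius_mm=1.0)
        cross = conn.adjacency[np.ix_(labels == 0, labels == 1)]
        assert np.all(cross == 1)

    def test_local_rule_links_close_vertices_in_unconnected_regions(self):
        labels = np.array([0, 1, 1, 0])
        coords = self._coords(4, spread=5.0)  # chain, 5 mm between neighbours
        region = np.array([[0.0, 0.0], [0.0, 0.0]])
        conn = build_template_adjacency(region, labels, coords,
                                        local_radius_mm=10.0)
        assert conn.adjacency[0, 1] == 1  # 5 mm < 10 mm despite no tract

    def test_asymmetric_input_symmetrized_before_threshold(self):
        # (M + M^T)/2 of [[0, 2], [0, 0]] is [[0, 1], [1, 0]]; mean 0.5; 1 > 0.5
        labels = np.array([0, 0, 1, 1])
        coords = self._coords(4, spread=5.0)  # local rule keeps graph connected
        conn = build_template_adjacency(np.array([[0.0, 2.0], [0.0, 0.0]]),
                                        labels, coords, local_radius_mm=6.0)
        cross = conn.adjacency[np.ix_(labels == 0, labels == 1)]
        assert np.all(cross[cross.shape[0] - 1:, :1] == 1)
        assert np.array_equal(conn.adjacency, conn.adjacency.T)

    def test_donor_stack_averaged_first(self):
        labels = np.array([0, 0, 1, 1])
        stack = np.stack([np.array([[0.0, 4.0], [4.0, 0.0]]),
                          np.array([[0.0, 0.0], [0.0, 0.0]])])
        # mean matrix [[0, 2], [2, 0]]; threshold 1 -> regions connected
        conn = build_template_adjacency(stack, labels, self._coords(4),
                                        local_radius_mm=1.0)
        assert conn.adjacency[0, 2] == 1

    def test_disconnected_result_errors_naming_components(self):
        labels = np.array([0, 0, 1, 1])
        region = np.array([[0.0, 0.0], [0.0, 0.0]])
        with pytest.raises(ValidationError, match="disconnected"):
            build_template_adjacency(region, labels, self._coords(4),
                                     local_radius_mm=1.5)

    def test_empty_or_negative_region_matrix_rejected(self):
        with pytest.raises(ValidationError):
            build_template_adjacency(np.empty((0, 0)), np.array([]),
                                     np.empty((0, 3)))
        with pytest.raises(ValidationError):
            build_template_adjacency(np.array([[0.0, -1.0], [-1.0, 0.0]]),
                                     np.array([0, 1]), self._coords(2))


class TestSpectra:
    def test_ring_spectrum_matches_closed_form(self, ring_basis):
        # normalized Laplacian of the n-cycle: 1 - cos(2 pi k / n)
        n = 64
        expected = np.sort(1 - np.cos(2 * np.pi * np.arange(n) / n))
        assert np.allclose(np.sort(ring_basis.eigenvalues), expected, atol=1e-8)

    def test_complete_graph_spectrum(self):
        n = 5
        A = (np.ones((n, n)) - np.eye(n)).astype(np.uint8)
        conn = StructuralConnectome(adjacency=A, coords=np.zeros((n, 3)))
        basis = compute_harmonics(conn)
        expected = np.array([0.0] + [n / (n - 1)] * (n - 1))
        assert np.allclose(basis.eigenvalues, expected, atol=1e-10)

    def test_normalized_laplacian_bounds_and_zero_mode(self, ring_basis):
        lam = ring_basis.eigenvalues
        assert lam[0] == pytest.approx(0.0, abs=1e-10)
        assert lam[-1] <= 2.0 + 1e-10
        assert np.all(np.diff(lam) >= -1e-12)
        # zero-mode eigenvector proportional to D^{1/2} 1
        v0 = ring_basis.eigenvectors[:, 0]
        ref = np.sqrt(ring_basis.degrees)
        ref = ref / np.linalg.norm(ref)
        assert np.allclose(np.abs(v0), ref, atol=1e-8)

    def test_eigenpairs_satisfy_laplacian_equation(self):
        conn = make_toy_connectome("lattice", 20, spacing_mm=5.0, radius_mm=8.0)
        basis = compute_harmonics(conn)
        deg = conn.degrees
        A = conn.adjacency.astype(float)
        lap = np.eye(conn.n) - A / np.sqrt(np.outer(deg, deg))
        resid = lap @ basis.eigenvectors - basis.eigenvectors * basis.eigenvalues
        assert np.max(np.abs(resid)) < 1e-8
        gram = basis.eigenvectors.T @ basis.eigenvectors
        assert np.allclose(gram, np.eye(conn.n), atol=1e-8)

    def test_spectrum_invariant_under_vertex_permutation(self, rng):
        conn = make_toy_connectome("lattice", 16, spacing_mm=5.0, radius_mm=8.0)
        perm = rng.permutation(conn.n)
        permuted = StructuralConnectome(
            adjacency=conn.adjacency[np.ix_(perm, perm)],
            coords=conn.coords[perm])
        a = compute_harmonics(conn).eigenvalues
        b = compute_harmonics(permuted).eigenvalues
        assert np.allclose(a, b, atol=1e-10)

    def test_isolated_vertex_guarded(self):
        A = np.zeros((4, 4), dtype=np.uint8)
        A[0, 1] = A[1, 0] = 1
        A[2, 3] = A[3, 2] = 1
        with pytest.raises(ValidationError):
            StructuralConnectome(adjacency=A, coords=np.zeros((4, 3)))


class TestProjection:
    def test_basis_vector_projects_to_unit_weight(self, ring_basis):
        F = ring_basis.eigenvectors[:, 3][None, :]
        w = project_signal(F, ring_basis).weights[0]
        expected = np.zeros(64)
        expected[3] = 1.0
        assert np.allclose(w, expected, atol=1e-10)

    def test_linear_combination_recovered(self, ring_basis):
        F = (2.0 * ring_basis.eigenvectors[:, 1]
             + 3.0 * ring_basis.eigenvectors[:, 5])[None, :]
        w = project_signal(F, ring_basis).weights[0]
        assert w[1] == pytest.approx(2.0, abs=1e-10)
        assert w[5] == pytest.approx(3.0, abs=1e-10)
        mask = np.ones(64, bool)
        mask[[1, 5]] = False
        assert np.max(np.abs(w[mask])) < 1e-10

    def test_reconstruction_and_parseval_on_random_signals(self, ring_basis, rng):
        F = rng.standard_normal((7, 64))
        weights = project_signal(F, ring_basis)
        recon = reconstruct_signal(weights, ring_basis)
        assert np.max(np.abs(recon - F)) < 1e-6
        assert np.allclose((weights.weights ** 2).sum(axis=1),
                           (F ** 2).sum(axis=1), atol=1e-6)

    def test_width_mismatch_rejected(self, ring_basis, rng):
        with pytest.raises(ValidationError):
            project_signal(rng.standard_normal((3, 10)), ring_basis)


class TestWindows:
    def test_window_length_205_for_fsaverage_size(self):
        assert window_length(5124, 0.04) == 205

    def test_window_count_matches_enumeration(self, rng):
        # n=100, window 10, step 5 -> starts 0,5,...,90 -> 19 windows
        w = HarmonicWeights(weights=rng.standard_normal((4, 100)),
                            eigenvalues=np.linspace(0, 2, 100))
        spec = harmonic_windows(w, window_frac=0.10, step_frac=0.05)
        starts = list(range(0, 91, 5))
        assert spec.n_windows == 19
        assert spec.window_bounds == [(s, s + 10) for s in starts]

    def test_zero_weights_give_zero_energy(self):
        w = HarmonicWeights(weights=np.zeros((3, 50)),
                            eigenvalues=np.linspace(0, 2, 50))
        spec = harmonic_windows(w, window_frac=0.2, step_frac=0.1)
        assert np.all(spec.energies == 0)

    def test_energies_non_negative_all_modes(self, rng):
        w = HarmonicWeights(weights=rng.standard_normal((5, 40)),
                            eigenvalues=np.linspace(0, 2, 40))
        for mode in ("mean_abs", "mean_square", "lambda_weighted"):
            spec = harmonic_windows(w, 0.25, 0.125, energy_mode=mode)
            assert np.all(spec.energies >= 0)

    def test_window_longer_than_basis_rejected(self, rng):
        w = HarmonicWeights(weights=rng.standard_normal((2, 10)),
                            eigenvalues=np.linspace(0, 2, 10))
        with pytest.raises(ValidationError):
            harmonic_windows(w, window_frac=1.0, step_frac=2.0)

    def test_degenerate_ring_pair_energies_stable(self):
        """Windowed energies are insensitive to rotations within the ring's
        paired (degenerate) eigenspaces when the window covers the pair."""
        conn = make_toy_connectome("ring", 16)
        basis = compute_harmonics(conn)
        rng = np.random.default_rng(0)
        F = rng.standard_normal((3, 16))
        w = project_signal(F, basis)
        spec = harmonic_windows(w, window_frac=0.125, step_frac=0.125,
                                energy_mode="mean_square")
        # rotate within the first degenerate pair (modes 1, 2)
        theta = 0.7
        rot = np.eye(16)
        rot[1:3, 1:3] = [[np.cos(theta), -np.sin(theta)],
                         [np.sin(theta), np.cos(theta)]]
        w2 = HarmonicWeights(weights=w.weights @ rot, eigenvalues=basis.eigenvalues)
        spec2 = harmonic_windows(w2, window_frac=0.125, step_frac=0.125,
                                 energy_mode="mean_square")
        # window 0 covers modes 0-1, window 1 covers 2-3: squared energy is
        # only approximately invariant when a pair straddles windows
        assert np.allclose(spec.energies.sum(axis=1),
                           spec2.energies.sum(axis=1), atol=1e-9)


def test_frequency_localised_effects_decode_in_matching_windows():
    """A condition effect built from low-frequency harmonics is decoded in
    the lowest windows only; a top-frequency effect in the highest."""
    from semstory import ExperimentDesign, PlantedEffects, make_bold_experiment
    from semstory.mvpa import ClassifierConfig, group_searchlight_classify

    conn = make_toy_connectome("ring", 24)
    basis = compute_harmonics(conn)
    design = ExperimentDesign(n_subjects=3, n_conditions=2,
                              trials_per_condition=3, ideation_volumes=10,
                              n_rois=24, seed=2)
    rng = np.random.default_rng(5)

    def build_dataset(mode_idx):
        ds = make_bold_experiment(design, PlantedEffects(), ideation_only=True)
        vals = ds.values.copy()
        pattern = basis.eigenvectors[:, mode_idx] * 6.0
        vals[:, 1] += pattern  # condition 1 carries the spatial pattern
        return ds.with_values(vals)

    def window_performance(ds):
        # project each sample onto the basis, then window energies as units
        flat = ds.values.reshape(-1, 24)
        weights = project_signal(flat, basis)
        spec = harmonic_windows(weights, window_frac=0.25, step_frac=0.25,
                                energy_mode="mean_abs")
        # build a dataset whose "ROIs" are the windows
        from semstory.dataset import RoiTimeSeriesDataset
        energies = spec.energies.reshape(ds.values.shape[:4] + (spec.n_windows,))
        win = RoiTimeSeriesDataset(values=energies, design=design,
                                   roi_labels=[f"win{i}" for i in range(spec.n_windows)])
        perf = group_searchlight_classify(
            win, 0, 1, config=ClassifierConfig(n_label_permutations=0, seed=0))
        return perf.table["score"].to_numpy()

    low = window_performance(build_dataset(1))
    high = window_performance(build_dataset(23))
    assert np.argmax(low) == 0
    assert np.argmax(high) == len(high) - 1
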