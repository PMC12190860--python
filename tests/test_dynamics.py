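import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from allonet import (
    ConformationalEnsemble,
    build_toy_structure,
    compute_contact_occupancy,
    compute_dccm,
    compute_generalized_correlation,
    compute_rmsd_series,
    compute_rmsf,
    generalized_correlation_from_covariance,
    sample_enm_ensemble,
    subsample,
    superpose_frames,
)
from allonet.synthetic import ENMSpec

from conftest import make_iid_ensemble
from oracles import quaternion_superpose_rmsd


def _rigid_copies(structure, n, seed):
    """Frames that are exact rigid motions of the reference."""
    ref = structure.reference_coordinates()
    rng = np.random.default_rng(seed)
    frames = []
    for _ in range(n):
        rot = Rotation.random(random_state=rng).as_matrix()
        shift = rng.uniform(-20, 20, 3)
        frames.append(ref @ rot.T + shift)
    return ConformationalEnsemble(reference=structure,
                                  frames=np.stack(frames))


class TestSuperpose:
    def test_rigid_motion_removed(self):
        structure = build_toy_structure(10, "helix", seed=0)
        ens = _rigid_copies(structure, 5, seed=1)
        fitted = superpose_frames(ens)
        rmsd = compute_rmsd_series(fitted)
        assert np.all(rmsd < 1e-8)

    def test_reference_maps_to_itself(self):
        structure = build_toy_structure(8, "helix")
        ref = structure.reference_coordinates()
        ens = ConformationalEnsemble(reference=structure,
                                     frames=np.stack([ref, ref]))
        fitted = superpose_frames(ens)
        assert np.abs(fitted.frames - ref[None]).max() < 1e-8

    def test_matches_quaternion_oracle(self):
        rng = np.random.default_rng(42)
        structure = build_toy_structure(10, "helix", seed=3)
        ca = structure.reference_coordinates()[structure.ca_index]
        perturbed = ca + 0.7 * rng.standard_normal(ca.shape)
        rot = Rotation.random(random_state=rng).as_matrix()
        moved = perturbed @ rot.T + [5.0, -3.0, 2.0]
        # implementation route: build a CA-only ensemble and superpose
        from allonet.ensemble_io import AtomRecord, ReferenceStructure

        atoms = [
            AtomRecord("A", str(i + 1), "GLY", "CA", "C", ca[i])
            for i in range(len(ca))
        ]
        ref = ReferenceStructure(atoms=atoms)
        ens = ConformationalEnsemble(reference=ref, frames=moved[None])
        rmsd = compute_rmsd_series(superpose_frames(ens))[0]
        assert rmsd == pytest.approx(
            quaternion_superpose_rmsd(moved, ca), abs=1e-8)

    def test_too_few_residues_rejected(self):
        structure = build_toy_structure(8, "helix")
        ref = structure.reference_coordinates()
        ens = ConformationalEnsemble(reference=structure,
                                     frames=ref[None])
        with pytest.raises(ValueError):
            superpose_frames(ens, selection=[0, 1])


class TestRmsd:
    def test_replicated_reference_is_zero(self):
        structure = build_toy_structure(6, "extended")
        ref = structure.reference_coordinates()
        ens = ConformationalEnsemble(
            reference=structure, frames=np.stack([ref] * 4))
        assert np.all(compute_rmsd_series(ens) == 0.0)

    def test_unit_shift_gives_unit_rmsd(self):
        structure = build_toy_structure(6, "extended")
        ref = structure.reference_coordinates()
        shifted = ref + [1.0, 0.0, 0.0]
        ens = ConformationalEnsemble(reference=structure,
                                     frames=shifted[None])
        assert compute_rmsd_series(ens)[0] == pytest.approx(1.0)

    def test_matches_direct_formula(self, helix_ensemble):
        ens, _ = helix_ensemble
        small = subsample(ens, 20)
        rmsd = compute_rmsd_series(small)
        ca = small.ca_coordinates()
        ref = small.reference.reference_coordinates()[
            small.reference.ca_index]
        brute = np.array([
            np.sqrt(np.mean(np.sum((ca[f] - ref) ** 2, axis=1)))
            for f in range(small.n_frames)
        ])
        assert np.allclose(rmsd, brute, atol=1e-12)


class TestRmsf:
    def test_static_ensemble_is_zero(self):
        structure = build_toy_structure(6, "extended")
        ref = structure.reference_coordinates()
        ens = ConformationalEnsemble(
            reference=structure, frames=np.stack([ref] * 3))
        assert np.all(compute_rmsf(ens).values < 1e-12)

    def test_isotropic_jitter_closed_form(self):
        sigma = 0.5
        ens = make_iid_ensemble(20, 4000, sigma, seed=5)
        rmsf = compute_rmsf(ens).values
        assert rmsf.mean() == pytest.approx(sigma * np.sqrt(3), rel=0.03)

    def test_matches_analytic_covariance(self, helix_ensemble):
        ens, truth = helix_ensemble
        rmsf = compute_rmsf(ens).values
        n = ens.n_residues
        blocks = truth.covariance.reshape(n, 3, n, 3)
        expected = np.sqrt(np.einsum("idid->i", blocks))
        assert np.abs(rmsf - expected).max() < 0.15 * expected.max()

    def test_single_frame_rejected(self):
        structure = build_toy_structure(6, "extended")
        ens = ConformationalEnsemble(
            reference=structure,
            frames=structure.reference_coordinates()[None])
        with pytest.raises(ValueError):
            compute_rmsf(ens)


class TestDccm:
    def test_diagonal_is_one(self, helix_ensemble):
        ens, _ = helix_ensemble
        c = compute_dccm(ens).values
        assert np.all(np.diag(c) == 1.0)

    def test_duplicated_and_negated_displacements(self):
        structure = build_toy_structure(4, "extended")
        ref = structure.reference_coordinates()
        rng = np.random.default_rng(0)
        frames = ref[None] + np.zeros((50, ref.shape[0], 3))
        noise = rng.standard_normal((50, 3))
        ca = structure.ca_index
        frames[:, ca[0], :] += noise
        frames[:, ca[1], :] += noise          # identical motion
        frames[:, ca[2], :] -= noise          # opposite motion
        frames[:, ca[3], :] += rng.standard_normal((50, 3))
        ens = ConformationalEnsemble(reference=structure, frames=frames)
        c = compute_dccm(ens).values
        assert c[0, 1] == pytest.approx(1.0)
        assert c[0, 2] == pytest.approx(-1.0)

    def test_estimate_matches_analytic(self, helix_ensemble):
        ens, truth = helix_ensemble
        c = compute_dccm(ens).values
        assert np.abs(c - truth.analytic_dccm).max() < 0.08

    def test_zero_fluctuation_residue_warns_and_zeroes(self):
        structure = build_toy_structure(4, "extended")
        ref = structure.reference_coordinates()
        rng = np.random.default_rng(1)
        frames = ref[None] + 0.3 * rng.standard_normal((30, ref.shape[0], 3))
        frames[:, structure.ca_index[0], :] = ref[structure.ca_index[0]]
        ens = ConformationalEnsemble(reference=structure, frames=frames)
        with pytest.warns(UserWarning, match="zero fluctuation"):
            c = compute_dccm(ens).values
        assert c[0, 0] == 1.0
        assert np.all(c[0, 1:] == 0.0)


class TestGeneralizedCorrelation:
    def test_closed_form_on_known_covariance(self):
        # two residues, known 6x6 covariance with cross-coupling rho
        rho = 0.6
        cov = np.eye(6)
        cov[0, 3] = cov[3, 0] = rho
        c = generalized_correlation_from_covariance(cov).values
        mi = -0.5 * np.log(1 - rho ** 2)
        expected = np.sqrt(1 - np.exp(-2 * mi / 3))
        assert c[0, 1] == pytest.approx(expected, abs=1e-10)

    def test_independent_residues_near_zero(self):
        cov = np.eye(6)
        c = generalized_correlation_from_covariance(cov).values
        assert c[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_perfect_coupling_gives_one(self):
        # block-duplicated covariance: residue 2 is residue 1
        base = np.array([[2.0, 0.3, 0.1],
                         [0.3, 1.5, 0.2],
                         [0.1, 0.2, 1.0]])
        cov = np.block([[base, base], [base, base]])
        c = generalized_correlation_from_covariance(cov).values
        assert c[0, 1] == pytest.approx(1.0)

    def test_dominates_signed_correlation(self, helix_ensemble):
        ens, _ = helix_ensemble
        signed = np.abs(compute_dccm(ens).values)
        gen = compute_generalized_correlation(ens).values
        assert np.all(signed <= gen + 0.1)


class TestContactOccupancy:
    @staticmethod
    def _pair_ensemble(distances):
        """Two GLY residues (CA only) at given per-frame separations."""
        structure = build_toy_structure(4, "extended",
                                        sequence="GGGG")
        ref = structure.reference_coordinates().copy()
        frames = np.stack([ref] * len(distances))
        for f, d in enumerate(distances):
            frames[f, structure.ca_index[1]] = \
                frames[f, structure.ca_index[0]] + [d, 0, 0]
        return ConformationalEnsemble(reference=structure, frames=frames)

    def test_always_within_cutoff(self):
        ens = self._pair_ensemble([4.0] * 6)
        occ = compute_contact_occupancy(ens, cutoff=5.0)
        assert occ.values[0, 1] == 1.0

    def test_never_within_cutoff(self):
        ens = self._pair_ensemble([10.0] * 6)
        occ = compute_contact_occupancy(ens, cutoff=5.0)
        assert occ.values[0, 1] == 0.0

    def test_half_the_frames(self):
        ens = self._pair_ensemble([4.0, 10.0] * 3)
        occ = compute_contact_occupancy(ens, cutoff=5.0)
        assert occ.values[0, 1] == 0.5

    def test_monotone_in_cutoff(self, toy_complex):
        ens, _ = toy_complex
        small = subsample(ens, 10)
        occ4 = compute_contact_occupancy(small, cutoff=4.0).values
        occ6 = compute_contact_occupancy(small, cutoff=6.0).values
        assert np.all(occ6 >= occ4)


class TestSubsample:
    def test_identity_when_n_equals_f(self, toy_complex):
        ens, _ = toy_complex
        out = subsample(ens, ens.n_frames)
        assert np.array_equal(out.frames, ens.frames)

    def test_stride_convention(self, toy_complex):
        ens, _ = toy_complex
        four = subsample(ens, 4)
        picked = subsample(four, 2)
        assert picked.frame_labels == [four.frame_labels[1],
                                       four.frame_labels[3]]

    def test_stride_includes_last_frame(self, toy_complex):
        ens, _ = toy_complex
        out = subsample(ens, 7)
        assert out.frame_labels[-1] == ens.frame_labels[-1]

    def test_random_is_seed_deterministic(self, toy_complex):
        ens, _ = toy_complex
        a = subsample(ens, 13, scheme="random", seed=5)
        b = subsample(ens, 13, scheme="random", seed=5)
        assert a.frame_labels == b.frame_labels

    def test_random_requires_seed(self, toy_complex):
        ens, _ = toy_complex
        with pytest.raises(ValueError):
            subsample(ens, 5, scheme="random")

    def test_oversampling_rejected(self, toy_complex):
        ens, _ = toy_complex
        with pytest.raises(ValueError):
            subsample(ens, ens.n_frames + 1)


class TestInvariants:
    def test_matrices_symmetric_and_bounded_many_seeds(self):
        for seed in range(100):
            ens = make_iid_ensemble(5, 12, 0.4, seed=seed)
            c = compute_dccm(ens).values
            g = compute_generalized_correlation(ens).values
            assert np.allclose(c, c.T, atol=1e-10)
            assert np.allclose(g, g.T, atol=1e-10)
            assert c.min() >= -1.0 and c.max() <= 1.0
            assert g.min() >= 0.0 and g.max() <= 1.0
            assert np.all(np.diag(c) == 1.0)
            assert np.all(np.diag(g) == 1.0)

    def test_rigid_motion_invariance_after_superposition(self):
        structure = build_toy_structure(10, "helix", seed=2)
        ens, _ = sample_enm_ensemble(structure,
                                     ENMSpec(n_frames=200, seed=8))
        fitted = superpose_frames(ens)
        rmsf0 = compute_rmsf(fitted).values
        dccm0 = compute_dccm(fitted).values

        rot = Rotation.from_euler("xyz", [30, -40, 75],
                                  degrees=True).as_matrix()
        moved = ConformationalEnsemble(
            reference=structure,
            frames=ens.frames @ rot.T + np.array([10.0, -4.0, 7.0]),
        )
        fitted_moved = superpose_frames(moved)
        assert np.abs(compute_rmsf(fitted_moved).values -
                      rmsf0).max() < 1e-8
        assert np.abs(compute_dccm(fitted_moved).values -
                      dccm0).max() < 1e-8
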