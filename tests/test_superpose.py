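"""Kabsch superposition, lRMSD, centralization, and splitting."""

import numpy as np
import pytest
from Bio.SVDSuperimposer import SVDSuperimposer
from scipy.spatial.transform import Rotation

import decoyfeat as df
from decoyfeat.errors import InvalidSpecError, ShapeError


def random_conformation(rng, n=12):
    return df.Conformation(rng.normal(scale=5.0, size=(n, 3)))


class TestKabsch:
    def test_identity_for_equal_inputs(self, rng):
        a = random_conformation(rng)
        transform, rmsd = df.kabsch_superpose(a, a)
        assert rmsd < 1e-10
        assert np.abs(transform.rotation - np.eye(3)).max() < 1e-8

    def test_exact_recovery_of_rigid_motion(self, rng):
        a = random_conformation(rng)
        R = Rotation.from_euler("z", 37, degrees=True).as_matrix()
        b = df.Conformation(a.coords @ R.T + np.array([1.0, 2.0, 3.0]))
        _, rmsd = df.kabsch_superpose(a, b)
        assert rmsd < 1e-8

    def test_returns_proper_rotation(self, rng):
        a, b = random_conformation(rng), random_conformation(rng)
        transform, _ = df.kabsch_superpose(a, b)
        R = transform.rotation
        assert np.abs(R.T @ R - np.eye(3)).max() < 1e-10
        assert abs(np.linalg.det(R) - 1.0) < 1e-10

    def test_beats_random_rotation_sampling(self, rng):
        # brute-force oracle: no random rotation + optimal translation does
        # better than the closed-form optimum
        samples = Rotation.random(2000, rng=np.random.default_rng(1)).as_matrix()
        for _ in range(10):
            P = rng.normal(scale=4.0, size=(5, 3))
            Q = rng.normal(scale=4.0, size=(5, 3))
            _, best = df.kabsch_superpose(P, Q)
            Pc, Qc = P - P.mean(0), Q - Q.mean(0)
            rotated = np.einsum("kij,nj->kni", samples, Pc)
            rmsds = np.sqrt(((rotated - Qc) ** 2).sum(axis=(1, 2)) / 5)
            assert best <= rmsds.min() + 1e-9

    def test_agrees_with_biopython_superimposer(self, rng):
        for _ in range(20):
            P = rng.normal(scale=4.0, size=(8, 3))
            Q = rng.normal(scale=4.0, size=(8, 3))
            _, ours = df.kabsch_superpose(P, Q)
            sup = SVDSuperimposer()
            sup.set(Q, P)  # Biopython superposes the second onto the first
            sup.run()
            assert ours == pytest.approx(sup.get_rms(), abs=1e-8)

    def test_shape_errors(self):
        with pytest.raises(ShapeError):
            df.kabsch_superpose(np.zeros((3, 3)), np.zeros((4, 3)))
        with pytest.raises(ShapeError):
            df.kabsch_superpose(np.zeros((0, 3)), np.zeros((0, 3)))


class TestLrmsd:
    def test_symmetric_and_rigid_invariant(self, rng):
        a, b = random_conformation(rng), random_conformation(rng)
        assert df.lrmsd(a, b) == pytest.approx(df.lrmsd(b, a), abs=1e-9)
        R = Rotation.random(rng=np.random.default_rng(3)).as_matrix()
        moved = df.Conformation(b.coords @ R.T + 10.0)
        assert df.lrmsd(a, moved) == pytest.approx(df.lrmsd(a, b), abs=1e-9)

    def test_translation_only_gives_zero(self, rng):
        a = random_conformation(rng)
        b = df.Conformation(a.coords + np.array([10.0, 0.0, 0.0]))
        assert df.lrmsd(a, b) < 1e-9

    def test_matches_direct_recomputation_after_superposition(self, rng):
        a = random_conformation(rng, n=30)
        b_coords = a.coords.copy()
        b_coords[4] += np.array([1.0, 0.0, 0.0])
        b = df.Conformation(b_coords)
        transform, value = df.kabsch_superpose(b, a)
        resid = transform.apply(b.coords) - a.coords
        direct = np.sqrt((resid**2).sum() / 30)
        assert value == pytest.approx(direct, abs=1e-12)

    def test_triangle_inequality_on_superposed_metric(self, rng):
        for _ in range(20):
            a, b, c = (random_conformation(rng, n=10) for _ in range(3))
            assert df.lrmsd(a, c) <= df.lrmsd(a, b) + df.lrmsd(b, c) + 1e-6


class TestCentralize:
    def test_reference_row_exactly_zero(self, clean_ensemble):
        ensemble, _ = clean_ensemble
        dataset = df.centralize(ensemble, reference_index=0)
        assert np.all(dataset.deviations[0] == 0.0)

    def test_reconstruct_inverts_centralization(self, clean_ensemble):
        ensemble, _ = clean_ensemble
        dataset = df.centralize(ensemble)
        i = 7
        rebuilt = df.reconstruct(dataset.deviations[i], dataset.reference)
        transform, _ = df.kabsch_superpose(ensemble[i], dataset.reference)
        assert np.abs(
            rebuilt.coords - transform.apply(ensemble[i].coords)
        ).max() < 1e-12

    def test_native_anchored_rows_give_planted_labels(self, clean_ensemble):
        ensemble, _ = clean_ensemble
        dataset = df.centralize(ensemble, reference=ensemble.native)
        norms = np.linalg.norm(dataset.deviations, axis=1)
        recomputed = norms / np.sqrt(ensemble.n_residues)
        assert np.abs(recomputed - dataset.labels).max() < 1e-6

    def test_idempotent_under_resuperposition(self, clean_ensemble):
        ensemble, _ = clean_ensemble
        first = df.centralize(ensemble)
        aligned = df.DecoyEnsemble(
            conformations=[
                df.reconstruct(row, first.reference) for row in first.deviations
            ],
            target_id=ensemble.target_id,
        )
        second = df.centralize(aligned)
        assert np.abs(second.deviations - first.deviations).max() < 1e-9

    def test_invalid_reference_index(self, clean_ensemble):
        ensemble, _ = clean_ensemble
        with pytest.raises(IndexError):
            df.centralize(ensemble, reference_index=len(ensemble))


class TestReconstruct:
    def test_zero_deviation_returns_reference(self, clean_ensemble):
        ensemble, _ = clean_ensemble
        ref = ensemble[0]
        out = df.reconstruct(np.zeros(3 * ref.n_atoms), ref)
        assert np.array_equal(out.coords, ref.coords)

    def test_error_identity_between_deviation_and_coordinate_space(self, rng):
        # ||dS^ - dS||^2 == ||S^ - S||^2 exactly, since the reference cancels
        ref = df.Conformation(rng.normal(size=(10, 3)))
        for _ in range(100):
            ds = rng.normal(size=30)
            ds_hat = rng.normal(size=30)
            dev_err = ((ds_hat - ds) ** 2).sum()
            coord_err = (
                (df.reconstruct(ds_hat, ref).coords - df.reconstruct(ds, ref).coords)
                ** 2
            ).sum()
            assert dev_err == pytest.approx(coord_err, abs=1e-12 * max(1, dev_err))

    def test_length_mismatch(self, rng):
        ref = df.Conformation(rng.normal(size=(10, 3)))
        with pytest.raises(ShapeError):
            df.reconstruct(np.zeros(29), ref)


class TestSplitDataset:
    def test_default_split_sizes(self, noisy_dataset):
        dataset, _, _ = noisy_dataset
        m = dataset.n_structures
        assert len(dataset.split["train"]) == m - int(0.1 * m) - int(0.4 * m)
        assert len(dataset.split["validation"]) == int(0.1 * m)
        assert len(dataset.split["test"]) == int(0.4 * m)

    @pytest.mark.parametrize(
        "m,expected", [(1000, (500, 100, 400)), (10, (5, 1, 4))]
    )
    def test_floor_arithmetic_with_remainder_to_train(self, m, expected):
        ref = df.Conformation(np.zeros((4, 3)))
        dataset = df.DeviationDataset(reference=ref, deviations=np.zeros((m, 12)))
        df.split_dataset(dataset, (0.5, 0.1, 0.4), seed=1)
        sizes = tuple(
            len(dataset.split[p]) for p in ("train", "validation", "test")
        )
        assert sizes == expected

    def test_disjoint_and_covering(self, noisy_dataset):
        dataset, _, _ = noisy_dataset
        allidx = np.concatenate([dataset.split[p] for p in dataset.split])
        assert np.array_equal(np.sort(allidx), np.arange(dataset.n_structures))

    def test_reproducible_under_seed(self, clean_ensemble):
        ensemble, _ = clean_ensemble
        d1 = df.split_dataset(df.centralize(ensemble), seed=3)
        s1 = {k: v.copy() for k, v in d1.split.items()}
        d2 = df.split_dataset(df.centralize(ensemble), seed=3)
        assert all(np.array_equal(s1[k], d2.split[k]) for k in s1)

    def test_bad_fractions_rejected(self, clean_ensemble):
        ensemble, _ = clean_ensemble
        dataset = df.centralize(ensemble)
        with pytest.raises(InvalidSpecError):
            df.split_dataset(dataset, (0.5, 0.2, 0.4))

    def test_split_serializes_round_trip(self, noisy_dataset, tmp_path):
        dataset, _, _ = noisy_dataset
        path = tmp_path / "split.json"
        dataset.save_split(path)
        other = df.DeviationDataset(
            reference=dataset.reference, deviations=dataset.deviations
        )
        other.load_split(path)
        assert all(
            np.array_equal(dataset.split[k], other.split[k]) for k in dataset.split
        )
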