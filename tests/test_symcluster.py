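"""Symmetry-agnostic clustering: scoring, symmetry-aware RMSD, graph clustering."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from symflux.docking import EnergyComponents
from symflux.geometry import kabsch_superpose, paired_rmsd, rotate_about_axis
from symflux.symcluster import (
    Axis,
    SymClusterParams,
    UNCLUSTERED,
    cluster_summary,
    estimate_symmetry_axis,
    graph_clusters,
    ligand_axis_distance,
    min_cluster_size,
    modified_score,
    rmsd_matrix,
    select_reference,
    symaware_ligand_rmsd,
    symmetry_angles,
)
from symflux.synthetic import canonical_axis, gen_docking_ensemble


class TestModifiedScore:
    def test_default_weights_drop_restraint_term(self):
        e = EnergyComponents(e_vdw=-50.0, e_elec=-100.0, e_desolv=-10.0, e_air=200.0)
        assert modified_score(e) == pytest.approx(-80.0)

    def test_all_zero_components(self):
        e = EnergyComponents(e_vdw=0.0, e_elec=0.0, e_desolv=0.0, e_air=0.0)
        assert modified_score(e) == 0.0

    def test_air_weight_is_linear(self):
        e = EnergyComponents(e_vdw=-50.0, e_elec=-100.0, e_desolv=-10.0, e_air=200.0)
        with_air = modified_score(e, (1.0, 0.2, 1.0, 0.1))
        without = modified_score(e, (1.0, 0.2, 1.0, 0.0))
        assert with_air - without == pytest.approx(20.0)

    def test_missing_required_component_named(self):
        with pytest.raises(ValueError, match="e_elec"):
            modified_score(EnergyComponents(e_vdw=-1.0, e_desolv=-1.0))


class TestSelectReference:
    def _model(self, model_id, score_vdw):
        class Stub:
            pass

        m = Stub()
        m.model_id = model_id
        m.energies = EnergyComponents(e_vdw=score_vdw, e_elec=0.0, e_desolv=0.0)
        return m

    def test_minimum_score_wins(self):
        models = [self._model(i, s) for i, s in enumerate([-80.0, -95.0, -60.0])]
        assert select_reference(models) == 1

    def test_tie_breaks_to_lowest_id(self):
        models = [self._model(3, -95.0), self._model(1, -95.0), self._model(2, -10.0)]
        assert select_reference(models) == 1

    def test_single_model(self):
        assert select_reference([self._model(5, -1.0)]) == 5

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_reference([])


class TestSymmetryAngles:
    @pytest.mark.parametrize(
        "n,expected",
        [
            (5, [0.0, 72.0, 144.0, 216.0, 288.0]),
            (1, [0.0]),
            (4, [0.0, 90.0, 180.0, 270.0]),
        ],
    )
    def test_angles(self, n, expected):
        assert symmetry_angles(n) == expected

    def test_invalid_fold_rejected(self):
        with pytest.raises(ValueError):
            symmetry_angles(0)


def _scramble(model, k_sym, flip, n_fold=5):
    """Return a copy of `model` with its ligand moved to another symmetry
    point (and optionally chain-swapped) — the degeneracy the clustering
    must see through."""
    from symflux.docking import DockingModel
    from symflux.structure import Structure
    from dataclasses import replace

    lig_set = set(model.ligand_chains)
    lig_idx = [i for i, a in enumerate(model.structure.atoms) if a.chain_id in lig_set]
    coords = model.structure.coords()
    lig = coords[lig_idx]
    lig = rotate_about_axis(lig, np.array([0.0, 0.0, 1.0]), k_sym * 360.0 / n_fold)
    if flip:
        half = len(lig) // 2
        lig = np.vstack([lig[half:], lig[:half]])
    coords = coords.copy()
    coords[lig_idx] = lig
    atoms = [replace(a, position=c) for a, c in zip(model.structure.atoms, coords)]
    return DockingModel(Structure(atoms), model.energies, model.model_id + 1000,
                        model.receptor_chains, model.ligand_chains)


class TestSymawareRmsd:
    def test_symmetry_equivalent_pose_is_zero_but_naive_is_not(self, clean_ensemble):
        models, _ = clean_ensemble
        ref = models[0]
        rotated = _scramble(ref, k_sym=1, flip=False)
        params = SymClusterParams()
        naive = SymClusterParams(n_fold=1, allow_ligand_flip=False)
        assert symaware_ligand_rmsd(rotated, ref, params, canonical_axis()) == pytest.approx(
            0.0, abs=1e-6
        )
        assert symaware_ligand_rmsd(rotated, ref, naive, canonical_axis()) > 1.0

    def test_flip_equivalent_pose_needs_flip_enabled(self, clean_ensemble):
        models, _ = clean_ensemble
        ref = models[0]
        flipped = _scramble(ref, k_sym=2, flip=True)
        with_flip = SymClusterParams(allow_ligand_flip=True)
        without = SymClusterParams(allow_ligand_flip=False)
        assert symaware_ligand_rmsd(flipped, ref, with_flip, canonical_axis()) == pytest.approx(
            0.0, abs=1e-6
        )
        assert symaware_ligand_rmsd(flipped, ref, without, canonical_axis()) > 1.0

    def test_matches_exhaustive_enumeration_oracle(self, small_ensemble, small_params):
        # independent oracle: explicit loop over all n_fold x 2 combinations
        # using only the geometry primitives
        models, _ = small_ensemble
        model, ref = models[3], models[15]
        axis = estimate_symmetry_axis(ref)
        transform, _ = kabsch_superpose(model.receptor_coords("CA"), ref.receptor_coords("CA"))
        lig_ref = ref.ligand_coords("CA")
        combos = []
        for flipped in (False, True):
            lig = transform.apply(model.ligand_coords("CA", flipped=flipped))
            for k in range(5):
                rot = rotate_about_axis(lig, axis.direction, k * 72.0, center=axis.point)
                combos.append(paired_rmsd(rot, lig_ref))
        oracle = min(combos)
        assert len(combos) == 10
        assert symaware_ligand_rmsd(model, ref, small_params, axis) == pytest.approx(
            oracle, abs=1e-9
        )

    def test_self_rmsd_zero_and_bounded_by_naive(self, small_ensemble, small_params):
        models, _ = small_ensemble
        naive_params = SymClusterParams(n_fold=1, allow_ligand_flip=False,
                                        min_cluster_floor=3)
        for m in models[::5]:
            assert symaware_ligand_rmsd(m, m, small_params) == pytest.approx(0.0, abs=1e-9)
        for a, b in zip(models[:6], models[6:12]):
            sym = symaware_ligand_rmsd(a, b, small_params)
            naive = symaware_ligand_rmsd(a, b, naive_params)
            assert sym <= naive + 1e-9

    def test_symmetric_in_model_and_reference_for_rigid_structures(self, clean_ensemble):
        models, _ = clean_ensemble
        params = SymClusterParams()
        for a, b in [(models[0], models[5]), (models[2], models[9])]:
            r1 = symaware_ligand_rmsd(a, b, params)
            r2 = symaware_ligand_rmsd(b, a, params)
            assert r1 == pytest.approx(r2, abs=1e-6)


class TestRmsdMatrix:
    def test_two_models(self, small_ensemble, small_params):
        models, _ = small_ensemble
        matrix, count = rmsd_matrix(models[:2], small_params)
        assert count == 2
        assert matrix[0, 0] == matrix[1, 1] == 0.0
        assert matrix[0, 1] == matrix[1, 0] > 0

    def test_ten_models_symmetric_with_count_90(self, small_ensemble, small_params):
        models, _ = small_ensemble
        matrix, count = rmsd_matrix(models[:10], small_params)
        assert count == 90
        assert np.allclose(matrix, matrix.T)
        # direct per-pair recomputation confirms the vectorized kernel
        # (matrix entry (i, j) for i < j uses model j as the reference)
        for i in range(0, 9, 3):
            for j in range(i + 1, 10, 4):
                expected = symaware_ligand_rmsd(models[i], models[j], small_params)
                assert matrix[i, j] == pytest.approx(expected, abs=1e-9)


class TestGraphClusters:
    def test_minimum_size_rule(self):
        assert min_cluster_size(200, 0.05, 10) == 10
        assert min_cluster_size(201, 0.05, 10) == 11  # ceil, never under-counting
        assert min_cluster_size(40, 0.05, 10) == 10

    def test_all_similar_models_form_one_cluster(self):
        n = 20
        result = graph_clusters(np.zeros((n, n)), SymClusterParams())
        assert result.cluster_sizes == [20]
        assert set(result.labels) == {0}

    def test_planted_two_cluster_recovery_is_exact(self, small_ensemble, small_params):
        models, truth = small_ensemble
        matrix, _ = rmsd_matrix(models, small_params)
        result = graph_clusters(matrix, small_params)
        assert adjusted_rand_score(truth.planted["labels"], result.labels) == 1.0
        assert result.cluster_sizes == [12, 8]
        assert int(np.sum(result.labels == UNCLUSTERED)) == 4

    def test_asymmetric_matrix_rejected(self):
        m = np.zeros((3, 3))
        m[0, 1] = 1.0
        with pytest.raises(ValueError, match="symmetric"):
            graph_clusters(m, SymClusterParams())

    def test_labels_invariant_under_symmetry_scramble(self, clean_ensemble):
        models, truth = clean_ensemble
        params = SymClusterParams(min_cluster_floor=2, min_cluster_frac=0.05)
        rng = np.random.default_rng(42)
        scrambled = [
            _scramble(m, k_sym=int(rng.integers(5)), flip=bool(rng.integers(2)))
            for m in models
        ]
        base = graph_clusters(rmsd_matrix(models, params)[0], params)
        scr = graph_clusters(rmsd_matrix(scrambled, params)[0], params)
        assert np.array_equal(base.labels, scr.labels)


class TestClusterSummary:
    def _models_with(self, values):
        class Stub:
            pass

        out = []
        for i, v in enumerate(values):
            m = Stub()
            m.model_id = i
            m.energies = EnergyComponents(hs=v)
            out.append(m)
        return out

    def test_small_sample_quartiles_linear_interpolation(self):
        models = self._models_with([1.0, 2.0, 3.0, 4.0, 5.0])
        stats = cluster_summary(models, np.zeros(5, dtype=int))[0]["hs"]
        assert (stats["q25"], stats["median"], stats["q75"]) == (2.0, 3.0, 4.0)

    def test_constant_values_collapse_whiskers(self):
        models = self._models_with([7.0] * 6)
        stats = cluster_summary(models, np.zeros(6, dtype=int))[0]["hs"]
        assert stats["q75"] - stats["q25"] == 0.0
        assert stats["whisker_low"] == stats["whisker_high"] == 7.0

    def test_quartiles_match_sorting_oracle(self, rng):
        values = rng.normal(10.0, 3.0, size=100)
        models = self._models_with(values)
        stats = cluster_summary(models, np.zeros(100, dtype=int))[0]["hs"]
        # sort-based linear-interpolation oracle
        v = np.sort(values)

        def q(p):
            h = p * (len(v) - 1)
            lo = int(np.floor(h))
            return v[lo] + (h - lo) * (v[min(lo + 1, len(v) - 1)] - v[lo])

        assert stats["q25"] == pytest.approx(q(0.25), abs=1e-12)
        assert stats["median"] == pytest.approx(q(0.50), abs=1e-12)
        assert stats["q75"] == pytest.approx(q(0.75), abs=1e-12)


class TestLigandAxisDistance:
    def _model_with_ligand_at(self, positions):
        from symflux.docking import DockingModel
        from symflux.structure import AtomRecord, RecordClass, Structure

        atoms = [
            AtomRecord("A", i + 1, "GLY", "CA", "C", np.array([30.0, float(i), 0.0]),
                       RecordClass.PROTEIN)
            for i in range(3)
        ]
        for i, p in enumerate(positions):
            atoms.append(
                AtomRecord("X", i + 1, "ALA", "CA", "C", np.array(p, dtype=float),
                           RecordClass.PROTEIN)
            )
        return DockingModel(Structure(atoms), EnergyComponents(), 0, ("A",), ("X",))

    def test_three_four_five(self):
        m = self._model_with_ligand_at([(3.0, 4.0, 0.0)])
        axis = Axis(np.zeros(3), np.array([0.0, 0.0, 1.0]))
        assert ligand_axis_distance(m, axis) == pytest.approx(5.0)

    def test_atom_on_axis(self):
        m = self._model_with_ligand_at([(0.0, 0.0, 12.0)])
        axis = Axis(np.zeros(3), np.array([0.0, 0.0, 1.0]))
        assert ligand_axis_distance(m, axis) == pytest.approx(0.0)

    def test_matches_projection_formula_oracle(self, rng):
        pts = rng.normal(size=(10, 3)) * 8.0
        m = self._model_with_ligand_at(pts)
        point = np.array([1.0, -2.0, 0.5])
        direction = np.array([1.0, 1.0, 2.0])
        axis = Axis(point, direction)
        u = direction / np.linalg.norm(direction)
        oracle = min(np.linalg.norm((p - point) - ((p - point) @ u) * u) for p in pts)
        assert ligand_axis_distance(m, axis) == pytest.approx(oracle, abs=1e-10)

    def test_empty_marker_selection_rejected(self):
        m = self._model_with_ligand_at([(1.0, 0.0, 0.0)])
        with pytest.raises(ValueError, match="empty"):
            ligand_axis_distance(m, Axis(np.zeros(3), np.array([0, 0, 1.0])),
                                 marker_atom_names=["ZZ"])
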