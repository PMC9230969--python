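import numpy as np
import pytest

from structphylo.msta import (
    GAP,
    CoreCriterion,
    MultipleStructAlignment,
    core_columns,
    guide_tree,
    progressive_merge,
    trim_to_core,
)
from structphylo.pairalign import tm_matrix
from structphylo.phylo import rf_distance
from structphylo.structio import DistanceMatrix, SequenceRecord, StructureModel
from structphylo.superpose import RigidTransform
from structphylo.synthetic import SimulationParams, simulate_family


def _copies(model, ids):
    return [StructureModel(i, model.seq, model.coords.copy()) for i in ids]


def _identity_frames(models):
    return {m.id: RigidTransform(np.eye(3), np.zeros(3)) for m in models}


class TestGuideTree:
    def test_two_models_single_cherry(self):
        tm = DistanceMatrix(["a", "b"], np.array([[1.0, 0.8], [0.8, 1.0]]))
        t = guide_tree(tm)
        assert t.leaf_labels == ["a", "b"]

    def test_recovers_generator_split(self):
        models, truth = simulate_family(SimulationParams(n_taxa=4, seed=2))
        t = guide_tree(tm_matrix(models))
        rf, _ = rf_distance(t, truth.true_tree)
        assert rf == 0

    def test_identical_models_near_zero_branches(self, toy_model):
        tm = tm_matrix(_copies(toy_model, ["a", "b", "c"]))
        t = guide_tree(tm)
        assert sum(t.branch_lengths()) == pytest.approx(0.0, abs=1e-9)


class TestProgressiveMerge:
    def test_identical_models_fully_occupied_zero_distance(self, toy_model):
        models = _copies(toy_model, ["a", "b", "c"])
        msa = progressive_merge(models, guide_tree(tm_matrix(models)))
        assert msa.n_columns == toy_model.L
        assert np.all(msa.columns != GAP)
        assert np.nanmax(msa.col_maxdist) == pytest.approx(0.0, abs=1e-6)

    def test_zero_noise_family_reproduces_homology_map(self):
        models, truth = simulate_family(
            SimulationParams(n_taxa=4, noise_sigma=0.0, mut_rate=0.0, seed=3)
        )
        msa = progressive_merge(models, guide_tree(tm_matrix(models)))
        core_columns(msa)
        pred = {tuple(msa.columns[c]) for c in np.nonzero(msa.core_mask)[0]}
        true_cols = {tuple(r) for r in truth.true_columns()}
        assert true_cols <= pred

    def test_insertion_occupies_private_columns(self):
        plan = {"t01": [], "t02": [], "t03": [(150, 60, None)], "t04": []}
        models, truth = simulate_family(
            SimulationParams(n_taxa=4, seed=4, domain_plan=plan)
        )
        msa = progressive_merge(models, guide_tree(tm_matrix(models)))
        k3 = msa.model_ids.index("t03")
        ins = next((s, e) for s, e, lab in truth.true_domains["t03"] if lab != "core")
        others = [k for k in range(4) if k != k3]
        for c in range(msa.n_columns):
            idx = msa.columns[c, k3]
            if idx != GAP and ins[0] <= idx < ins[1]:
                assert all(msa.columns[c, k] == GAP for k in others)

    def test_column_order_strictly_increasing_per_model(self, family6, tm6):
        models, _ = family6
        msa = progressive_merge(models, guide_tree(tm6))
        msa.validate()  # raises on violation
        for k in range(len(msa.model_ids)):
            occ = msa.columns[msa.columns[:, k] != GAP, k]
            assert np.all(np.diff(occ) > 0)

    def test_leaf_mismatch_rejected(self, toy_model):
        models = _copies(toy_model, ["a", "b", "c"])
        t = guide_tree(tm_matrix(models))
        with pytest.raises(ValueError, match="leaves"):
            progressive_merge(models[:2], t)

    def test_subset_core_contains_full_set_core(self, family6, tm6):
        models, _ = family6
        msa_full = progressive_merge(models, guide_tree(tm6))
        core_columns(msa_full)
        sub = models[:4]
        tm_sub = tm_matrix(sub)
        msa_sub = progressive_merge(sub, guide_tree(tm_sub))
        core_columns(msa_sub)
        sub_ids = [m.id for m in sub]
        cols_full = {
            tuple(msa_full.columns[c, [msa_full.model_ids.index(i) for i in sub_ids]])
            for c in np.nonzero(msa_full.core_mask)[0]
        }
        cols_sub = {
            tuple(msa_sub.columns[c, [msa_sub.model_ids.index(i) for i in sub_ids]])
            for c in np.nonzero(msa_sub.core_mask)[0]
        }
        missing = len(cols_full - cols_sub)
        assert missing <= 0.05 * max(1, len(cols_full))


class TestCoreColumns:
    def _toy_msa(self, maxdists, occupancy=None):
        """Three 3-residue models; one column per entry of maxdists."""
        n = len(maxdists)
        ids = ["a", "b", "c"]
        cols = np.tile(np.arange(n)[:, None], (1, 3))
        if occupancy is not None:
            cols[~occupancy] = GAP
        models = {
            i: StructureModel(i, "A" * n, np.arange(3 * n, dtype=float).reshape(n, 3))
            for i in ids
        }
        msa = MultipleStructAlignment(
            ids, cols, {i: RigidTransform(np.eye(3), np.zeros(3)) for i in ids}, models
        )
        msa.col_maxdist = np.array(maxdists, float)
        return msa

    def test_threshold_is_strict(self):
        msa = self._toy_msa([3.9, 4.1, 4.0, 0.5])
        mask = core_columns(msa, CoreCriterion())
        assert mask.tolist() == [True, False, False, True]

    def test_occupancy_requirement(self):
        occ = np.ones((3, 3), bool)
        occ[1, 2] = False
        msa = self._toy_msa([1.0, 1.0, 1.0], occupancy=occ)
        assert core_columns(msa, CoreCriterion()).tolist() == [True, False, True]
        assert core_columns(
            msa, CoreCriterion(require_full_occupancy=False)
        ).tolist() == [True, True, True]

    def test_mask_monotone_in_threshold(self, family6, tm6):
        models, _ = family6
        msa = progressive_merge(models, guide_tree(tm6))
        loose = core_columns(msa, CoreCriterion(max_pairwise_dist=6.0)).copy()
        tight = core_columns(msa, CoreCriterion(max_pairwise_dist=4.0)).copy()
        assert np.all(loose[tight])  # tight core subset of loose core

    def test_generator_precision_recall(self, family6, tm6):
        models, truth = family6
        msa = progressive_merge(models, guide_tree(tm6))
        mask = core_columns(msa)
        true_cols = {tuple(r) for r in truth.true_columns()}
        pred = {tuple(msa.columns[c]) for c in np.nonzero(mask)[0]}
        tp = len(true_cols & pred)
        assert tp / max(1, len(pred)) >= 0.9
        assert tp / len(true_cols) >= 0.9


class TestTrimToCore:
    def test_identical_models_trim_is_full_alignment(self, toy_model):
        models = _copies(toy_model, ["a", "b"])
        msa = progressive_merge(models, guide_tree(tm_matrix(models)))
        core_columns(msa)
        rows = trim_to_core(msa, [SequenceRecord(m.id, m.seq) for m in models])
        assert all(r.seq == toy_model.seq for r in rows)

    def test_mask_application_on_toy_columns(self):
        msa = TestCoreColumns()._toy_msa([1.0] * 4 + [9.0] * 6)
        core_columns(msa)
        rows = trim_to_core(msa, [SequenceRecord(i, "ABCDEFGHIJ") for i in "abc"])
        assert all(r.seq == "ABCD" for r in rows)

    def test_length_mismatch_names_model(self, toy_model):
        models = _copies(toy_model, ["a", "b"])
        msa = progressive_merge(models, guide_tree(tm_matrix(models)))
        core_columns(msa)
        seqs = [SequenceRecord("a", toy_model.seq), SequenceRecord("b", "SHORT")]
        with pytest.raises(ValueError, match="b"):
            trim_to_core(msa, seqs)
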