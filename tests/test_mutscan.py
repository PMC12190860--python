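import numpy as np
import pandas as pd
import pytest

from allonet import (
    AA_ORDER,
    ConformationalEnsemble,
    aggregate_energy_decomposition,
    build_toy_structure,
    builtin_contact_scorer,
    export_heatmap,
    identify_interface_residues,
    scan_mutations,
)
from allonet.ensemble_io import AtomRecord, ReferenceStructure
from allonet.mutscan import FunctionScorer, read_heatmap

from conftest import make_iid_ensemble


def _two_residue_complex(separations):
    """Chain A LEU facing chain B LEU at given per-frame CB separations."""
    atoms = []
    for chain, base_x in (("A", 0.0), ("B", 10.0)):
        atoms.append(AtomRecord(chain, "1", "LEU", "CA", "C",
                                np.array([base_x, 0.0, 0.0])))
        atoms.append(AtomRecord(chain, "1", "LEU", "CB", "C",
                                np.array([base_x, 1.5, 0.0])))
        # second residue per chain so the scan has context
        atoms.append(AtomRecord(chain, "2", "ALA", "CA", "C",
                                np.array([base_x, 20.0, 0.0])))
        atoms.append(AtomRecord(chain, "2", "ALA", "CB", "C",
                                np.array([base_x, 21.5, 0.0])))
    ref = ReferenceStructure(atoms=atoms)
    base = ref.reference_coordinates()
    frames = np.stack([base] * len(separations))
    for f, sep in enumerate(separations):
        frames[f, 4:6, 0] = base[4:6, 0] - (10.0 - sep)
    return ConformationalEnsemble(reference=ref, frames=frames)


class TestIdentifyInterface:
    def test_far_apart_chains_give_empty_interface(self):
        ens = _two_residue_complex([50.0, 50.0])
        assert identify_interface_residues(ens, {"A"}, {"B"}) == []

    def test_pinned_contact_included(self):
        ens = _two_residue_complex([4.0, 4.0])
        assert identify_interface_residues(ens, {"A"}, {"B"}) == ["A:1"]

    def test_recovers_planted_interface(self, toy_complex):
        ens, truth = toy_complex
        found = identify_interface_residues(ens, {"A"}, {"B"},
                                            cutoff=5.0,
                                            min_occupancy=0.5)
        assert found == truth.planted_interface

    def test_overlapping_groups_rejected(self, toy_complex):
        ens, _ = toy_complex
        with pytest.raises(ValueError):
            identify_interface_residues(ens, {"A"}, {"A", "B"})


class TestScanMutations:
    def test_wildtype_column_exactly_zero(self, toy_complex):
        ens, truth = toy_complex
        scorer = builtin_contact_scorer(burial_weight=0.5,
                                        partner_chains={"B"})
        table = scan_mutations(ens, scorer, truth.planted_interface,
                               n_samples=50)
        for i, wt in enumerate(table.wild_types):
            assert table.ddg[i, AA_ORDER.index(wt)] == 0.0

    def test_constant_scorer_mean_and_zero_se(self, toy_complex):
        ens, _ = toy_complex
        c = 1.75

        def fn(e, f, pos, aa):
            wt = e.reference.residue_one_letter()[pos]
            return 0.0 if aa == wt else c

        table = scan_mutations(ens, FunctionScorer(fn), ["A:1"],
                               n_samples=20)
        wt_col = AA_ORDER.index(table.wild_types[0])
        mask = np.arange(20) != wt_col
        assert np.allclose(table.ddg[0, mask], c)
        assert np.allclose(table.ddg_se[0, mask], 0.0)

    def test_two_frame_scan_is_mean_of_frames(self):
        ens = _two_residue_complex([4.0, 50.0])  # contact in frame 1 only
        e = np.zeros((20, 20))
        li, ai = AA_ORDER.index("L"), AA_ORDER.index("A")
        e[li, li] = -1.0
        e[ai, li] = e[li, ai] = -0.4
        scorer = builtin_contact_scorer(e, burial_weight=0.0,
                                        partner_chains={"B"})
        table = scan_mutations(ens, scorer, ["A:1"])
        # frame 1: L->A loses e(L,L), gains e(A,L): +0.6; frame 2: 0
        assert table.ddg[0, ai] == pytest.approx(0.3)

    def test_nonstandard_position_rejected(self):
        atoms = [
            AtomRecord("A", "1", "MSE", "CA", "C", np.zeros(3)),
            AtomRecord("A", "2", "GLY", "CA", "C",
                       np.array([3.8, 0.0, 0.0])),
        ]
        ref = ReferenceStructure(atoms=atoms)
        ens = ConformationalEnsemble(
            reference=ref, frames=ref.reference_coordinates()[None])
        scorer = builtin_contact_scorer()
        with pytest.raises(ValueError, match="A:1"):
            scan_mutations(ens, scorer, ["A:1"])


class TestContactScorer:
    def test_no_cross_contacts_no_burial_scores_zero(self):
        ens = _two_residue_complex([50.0, 50.0])
        scorer = builtin_contact_scorer(burial_weight=0.0,
                                        partner_chains={"B"})
        table = scan_mutations(ens, scorer, ["A:1"])
        assert np.allclose(table.ddg, 0.0)

    def test_zero_table_reduces_to_burial_term(self):
        ens = _two_residue_complex([4.0, 4.0])
        w = 2.0
        scorer = builtin_contact_scorer(np.zeros((20, 20)),
                                        burial_weight=w,
                                        partner_chains={"B"})
        table = scan_mutations(ens, scorer, ["A:1"])
        h = scorer._h
        wt = AA_ORDER.index("L")
        counts, burial = scorer._position_environment(ens, 0)
        expected = w * (h[wt] - h) * burial.mean()
        mask = np.arange(20) != wt
        assert np.allclose(table.ddg[0, mask], expected[mask])

    def test_single_contact_pair_arithmetic(self):
        ens = _two_residue_complex([4.0])
        e = np.zeros((20, 20))
        li, ai = AA_ORDER.index("L"), AA_ORDER.index("A")
        e[li, li] = -1.0
        e[ai, li] = e[li, ai] = -0.4
        scorer = builtin_contact_scorer(e, burial_weight=0.0,
                                        partner_chains={"B"})
        assert scorer.score(ens, 0, 0, "A") == pytest.approx(0.6)

    def test_asymmetric_table_rejected(self):
        e = np.zeros((20, 20))
        e[0, 1] = 1.0
        with pytest.raises(ValueError):
            builtin_contact_scorer(e)


class TestScanProperties:
    def test_concatenation_linearity(self, toy_complex):
        ens, truth = toy_complex
        half = ens.n_frames // 2
        a = ConformationalEnsemble(reference=ens.reference,
                                   frames=ens.frames[:half])
        b = ConformationalEnsemble(reference=ens.reference,
                                   frames=ens.frames[half:2 * half])
        both = ConformationalEnsemble(
            reference=ens.reference, frames=ens.frames[:2 * half])
        positions = truth.planted_interface
        scorer = builtin_contact_scorer(burial_weight=0.5,
                                        partner_chains={"B"})
        t_a = scan_mutations(a, scorer, positions, n_samples=half)
        scorer = builtin_contact_scorer(burial_weight=0.5,
                                        partner_chains={"B"})
        t_b = scan_mutations(b, scorer, positions, n_samples=half)
        scorer = builtin_contact_scorer(burial_weight=0.5,
                                        partner_chains={"B"})
        t_ab = scan_mutations(both, scorer, positions,
                              n_samples=2 * half)
        assert np.allclose(t_ab.ddg, (t_a.ddg + t_b.ddg) / 2.0,
                           atol=1e-12)

    def test_chain_relabeling_invariance(self, toy_complex):
        ens, truth = toy_complex
        positions = truth.planted_interface
        scorer = builtin_contact_scorer(burial_weight=0.5,
                                        partner_chains={"B"})
        base = scan_mutations(ens, scorer, positions, n_samples=20)

        renamed_atoms = [
            AtomRecord("X" if a.chain_id == "A" else "Y",
                       a.residue_number, a.residue_name, a.atom_name,
                       a.element, a.position)
            for a in ens.reference.atoms
        ]
        renamed = ConformationalEnsemble(
            reference=ReferenceStructure(atoms=renamed_atoms),
            frames=ens.frames)
        scorer2 = builtin_contact_scorer(burial_weight=0.5,
                                         partner_chains={"Y"})
        table2 = scan_mutations(
            renamed, scorer2,
            [p.replace("A:", "X:") for p in positions], n_samples=20)
        assert np.allclose(base.ddg, table2.ddg, atol=1e-12)

    def test_se_scales_as_inverse_sqrt_n(self):
        ens = make_iid_ensemble(6, 800, 1.2, seed=17)
        # bring chains together: split the chain into two pseudo-chains
        atoms = [
            AtomRecord("B" if int(a.residue_number) > 3 else "A",
                       a.residue_number, a.residue_name, a.atom_name,
                       a.element, a.position)
            for a in ens.reference.atoms
        ]
        ens = ConformationalEnsemble(
            reference=ReferenceStructure(atoms=atoms),
            frames=ens.frames)
        ns = [50, 100, 200, 400, 800]
        mean_se = []
        for n in ns:
            scorer = builtin_contact_scorer(burial_weight=1.0,
                                            partner_chains={"B"},
                                            cutoff=6.0)
            table = scan_mutations(ens, scorer, ["A:3"], n_samples=n)
            wt = AA_ORDER.index(table.wild_types[0])
            mask = np.arange(20) != wt
            mean_se.append(table.ddg_se[0, mask].mean())
        slope = np.polyfit(np.log(ns), np.log(mean_se), 1)[0]
        assert slope == pytest.approx(-0.5, abs=0.1)


class TestEnergyDecomposition:
    @staticmethod
    def _table(values, labels=("A:1", "A:2", "A:3")):
        return pd.DataFrame({
            "residue": list(labels),
            "total": values,
            "vdw": [v / 2 for v in values],
            "elec": [v / 3 for v in values],
        })

    def test_duplicated_tables_mean_equals_table(self):
        t = self._table([-3.0, 1.0, 0.5])
        agg = aggregate_energy_decomposition([t, t.copy(), t.copy()])
        assert np.allclose(agg.mean["total"], [-3.0, 1.0, 0.5])
        assert np.allclose(agg.se.to_numpy(), 0.0)

    def test_opposite_tables_average_to_zero(self):
        t1 = self._table([2.0, -1.0, 0.5])
        t2 = self._table([-2.0, 1.0, -0.5])
        agg = aggregate_energy_decomposition([t1, t2])
        assert np.allclose(agg.mean.to_numpy(), 0.0)

    def test_gaussian_sampling_recovers_truth(self):
        rng = np.random.default_rng(21)
        truth = np.array([-5.0, 2.0, 0.0])
        tables = [self._table(truth + rng.standard_normal(3))
                  for _ in range(100)]
        agg = aggregate_energy_decomposition(tables)
        within = np.abs(agg.mean["total"] - truth) <= \
            3 * agg.se["total"].to_numpy()
        assert within.mean() >= 0.66

    def test_label_mismatch_names_discrepancy(self):
        t1 = self._table([1.0, 2.0, 3.0])
        t2 = self._table([1.0, 2.0, 3.0], labels=("A:1", "A:9", "A:3"))
        with pytest.raises(ValueError, match="A:9"):
            aggregate_energy_decomposition([t1, t2])

    def test_ranking_orders_by_total(self):
        t = self._table([1.0, -4.0, 0.2])
        agg = aggregate_energy_decomposition([t])
        assert list(agg.ranked().index) == ["A:2", "A:3", "A:1"]


class TestHeatmapExport:
    def test_orientation_and_round_trip(self, tmp_path, toy_complex):
        ens, truth = toy_complex
        scorer = builtin_contact_scorer(burial_weight=0.5,
                                        partner_chains={"B"})
        table = scan_mutations(ens, scorer,
                               truth.planted_interface[:2],
                               n_samples=10)
        path = tmp_path / "heat.csv"
        export_heatmap(table, path)
        back = read_heatmap(path)
        assert back.shape == (20, 2)
        assert np.abs(back.to_numpy().T - table.ddg).max() < 1e-9

    def test_all_zero_table_renders(self, tmp_path):
        ens = _two_residue_complex([50.0, 50.0])
        scorer = builtin_contact_scorer(burial_weight=0.0,
                                        partner_chains={"B"})
        table = scan_mutations(ens, scorer, ["A:1"])
        export_heatmap(table, tmp_path / "zero.csv", render_image=True)
        assert (tmp_path / "zero.png").exists()
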