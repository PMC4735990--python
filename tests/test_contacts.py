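"""Atom hydropathy classes, contact partitioning, complementarity."""

import numpy as np
import pytest

from conftest import attribution_oracle, make_structure
from phspec.contacts import (
    LigandGroup,
    analyze_complex,
    classify_atoms,
    complementarity,
    contact_surfaces,
    define_phosphate_groups,
    load_atom_class_table,
    load_legitimacy_table,
    normalized_complementarity,
)
from phspec.synthetic import ToyLigandSpec, generate_toy_complex

PROBE = 1.4


class TestAtomClasses:
    def test_chemistry_forced_assignments(self):
        st = make_structure(
            [[0, 0, 0], [4, 0, 0], [8, 0, 0], [12, 0, 0]],
            [1.55, 1.7, 1.55, 1.52],
            elements=["N", "C", "N", "O"],
            names=["NZ", "CD1", "N", "O"],
            res_names=["LYS", "LEU", "GLY", "GLY"],
        )
        classes = classify_atoms(st)
        assert classes == ["donor", "hydrophobic", "donor", "acceptor"]

    def test_phosphate_and_hydroxyl_oxygens(self):
        # P with a bonded O (1.5 Å) and a C-O hydroxyl far from any P
        st = make_structure(
            [[0, 0, 0], [1.5, 0, 0], [10, 0, 0], [11.4, 0, 0]],
            [1.8, 1.52, 1.7, 1.52],
            elements=["P", "O", "C", "O"],
            names=["P1", "O11", "C2", "O2"],
            het=[True] * 4,
            res_names=["IPX"] * 4,
        )
        classes = classify_atoms(st)
        assert classes == ["neutral", "acceptor", "hydrophobic",
                           "donor_acceptor"]

    def test_unmatched_protein_atom_neutral_with_warning(self):
        st = make_structure([[0, 0, 0]], [1.7], names=["QQ"],
                            res_names=["GLY"])
        with pytest.warns(UserWarning, match="no class"):
            assert classify_atoms(st) == ["neutral"]

    def test_every_table_entry_is_a_known_class(self):
        table = load_atom_class_table()
        legit = load_legitimacy_table()
        for cls in table.values():
            assert (cls, cls) in legit


class TestLegitimacyTable:
    def test_hydrophilic_hydrophobic_always_illegitimate(self):
        legit = load_legitimacy_table()
        for h in ("donor", "acceptor", "donor_acceptor"):
            assert not legit[(h, "hydrophobic")]
            assert not legit[("hydrophobic", h)]

    def test_donor_acceptor_pairing(self):
        legit = load_legitimacy_table()
        assert legit[("donor", "acceptor")]
        assert not legit[("donor", "donor")]
        assert not legit[("acceptor", "acceptor")]
        assert legit[("neutral", "hydrophobic")]

    def test_violating_edit_rejected(self, tmp_path):
        bad = tmp_path / "legit.tsv"
        bad.write_text(
            "\tdonor\tacceptor\tdonor_acceptor\thydrophobic\tneutral\n"
            "donor\t0\t1\t1\t1\t1\n"
            "acceptor\t1\t0\t1\t0\t1\n"
            "donor_acceptor\t1\t1\t1\t0\t1\n"
            "hydrophobic\t1\t0\t0\t1\t1\n"
            "neutral\t1\t1\t1\t1\t1\n"
        )
        with pytest.raises(ValueError, match="hydrophilic-hydrophobic"):
            load_legitimacy_table(bad)


class TestComplementarity:
    @pytest.mark.parametrize("s_legit, s_illegit, expected", [
        (31.3, 10.6, 20.7),
        (114.8, 8.5, 106.3),
        (85.8, 0.3, 85.5),
        (33.6, 0.0, 33.6),
        (102.1, 3.1, 99.0),
        (0.0, 0.0, 0.0),
    ])
    def test_c_is_legit_minus_illegit(self, s_legit, s_illegit, expected):
        assert complementarity(s_legit, s_illegit) == pytest.approx(expected)

    def test_negative_area_rejected(self):
        with pytest.raises(ValueError):
            complementarity(-1.0, 0.0)

    def test_normalization(self):
        assert normalized_complementarity(0.0, 50.0) == 0.0
        assert normalized_complementarity(50.0, 50.0) == 1.0
        with pytest.raises(ValueError):
            normalized_complementarity(10.0, 0.0)


class TestPhosphateGroups:
    def _ligand(self, n_phos):
        tc = generate_toy_complex(
            10, ToyLigandSpec(depths=[-5.0] * n_phos), seed=2)
        return tc

    @pytest.mark.parametrize("n_phos", [3, 4])
    def test_one_group_per_phosphorus(self, n_phos):
        tc = self._ligand(n_phos)
        groups = define_phosphate_groups(tc.structure, tc.ligand_mask)
        assert len(groups) == n_phos
        # each group: P plus its four oxygens, disjoint
        all_atoms = np.concatenate([g.atom_indices for g in groups])
        assert len(all_atoms) == len(set(all_atoms)) == 5 * n_phos

    def test_labels_follow_phosphorus_numbering(self):
        tc = self._ligand(3)
        labels = [g.label for g in
                  define_phosphate_groups(tc.structure, tc.ligand_mask)]
        assert labels == ["P1", "P2", "P3"]

    def test_shared_oxygen_goes_to_nearest_phosphate(self):
        # O at 1.5 Å from P1 and 1.7 Å from P2: bonded range of both
        st = make_structure(
            [[0, 0, 0], [1.5, 0, 0], [3.2, 0, 0]],
            [1.8, 1.52, 1.8],
            elements=["P", "O", "P"],
            names=["P1", "O1", "P2"],
            het=[True] * 3, res_names=["IPX"] * 3,
        )
        with pytest.warns(UserWarning, match="oxygens"):
            groups = define_phosphate_groups(st, np.ones(3, bool))
        assert list(groups[0].atom_indices) == [0, 1]
        assert list(groups[1].atom_indices) == [2]

    def test_no_phosphorus_gives_no_groups(self):
        st = make_structure([[0, 0, 0]], [1.52], elements=["O"],
                            het=[True], res_names=["IPX"], names=["O1"])
        assert define_phosphate_groups(st, np.ones(1, bool)) == []


class TestContactSurfaces:
    def test_remote_group_has_zero_contact(self):
        tc = generate_toy_complex(30, ToyLigandSpec(depths=[-25.0]), seed=4)
        rep = analyze_complex(tc.structure, ["IPX"], n_points=2048)
        g = rep.groups[0]
        assert g.s_legit == 0.0 and g.s_illegit == 0.0

    def test_hydrophilic_pocket_gives_no_illegitimate_area(self):
        tc = generate_toy_complex(
            50,
            ToyLigandSpec(depths=[0.5], pocket_classes=["donor"],
                          pocket_radius=12.0),
            seed=6,
        )
        rep = analyze_complex(tc.structure, ["IPX"], n_points=2048)
        g = rep.groups[0]
        assert g.buried_area > 5.0  # actually in contact
        assert g.s_illegit == 0.0

    def test_hydrophobic_pocket_starves_legitimate_area(self):
        # the hydrophilic (oxygen) part of a phosphate buried in an
        # all-hydrophobic pocket makes exclusively illegitimate contacts
        tc = generate_toy_complex(
            50,
            ToyLigandSpec(depths=[0.5], pocket_classes=["hydrophobic"],
                          pocket_radius=12.0),
            seed=6,
        )
        st = tc.structure
        oxygens = [i for i in np.flatnonzero(tc.ligand_mask)
                   if st.elements[i] == "O"]
        group = LigandGroup("P1-O", np.array(oxygens))
        g = contact_surfaces(group, st, tc.ligand_mask, probe=PROBE,
                             n_points=2048)
        assert g.buried_area > 5.0
        assert g.s_legit == 0.0

    def test_three_atom_complex_matches_dense_oracle(self):
        # one phosphate O equidistant between a Lys NZ and a Leu CD1
        st = make_structure(
            [[-2.8, 0, 0], [2.8, 0, 0], [0, 0, 0], [0, 1.5, 0]],
            [1.55, 1.7, 1.8, 1.52],
            elements=["N", "C", "P", "O"],
            names=["NZ", "CD1", "P1", "O11"],
            res_names=["LYS", "LEU", "IPX", "IPX"],
            het=[False, False, True, True],
        )
        classes = classify_atoms(st)
        legit = load_legitimacy_table()
        ligand_mask = st.is_hetero
        group = LigandGroup("P1", np.array([2, 3]))
        mine = contact_surfaces(group, st, ligand_mask, classes=classes,
                                probe=PROBE, n_points=8192)
        ora = attribution_oracle(group, st, ligand_mask, classes, legit,
                                 PROBE, 20_000, np.random.default_rng(8))
        assert mine.buried_area == pytest.approx(ora[2], rel=0.02)
        assert mine.s_legit == pytest.approx(ora[0], abs=0.02 * ora[2])
        assert mine.s_illegit == pytest.approx(ora[1], abs=0.02 * ora[2])

    def test_conservation_attributed_equals_burial(self):
        tc = generate_toy_complex(
            40, ToyLigandSpec(depths=[1.5, 0.0]), seed=13)
        rep = analyze_complex(tc.structure, ["IPX"], n_points=4096)
        for g in rep.groups:
            assert g.s_legit + g.s_illegit == pytest.approx(
                g.buried_area, abs=1e-6)

    def test_random_complexes_match_oracle_within_two_percent(self):
        legit = load_legitimacy_table()
        rng = np.random.default_rng(17)
        checked = 0
        for seed in range(20):
            tc = generate_toy_complex(
                35,
                ToyLigandSpec(depths=[float(d) for d in
                              rng.uniform(-1.0, 2.5, size=2)]),
                seed=100 + seed,
            )
            classes = classify_atoms(tc.structure)
            groups = define_phosphate_groups(tc.structure, tc.ligand_mask)
            for g in groups:
                mine = contact_surfaces(g, tc.structure, tc.ligand_mask,
                                        classes=classes, probe=PROBE,
                                        n_points=4096)
                ora = attribution_oracle(g, tc.structure, tc.ligand_mask,
                                         classes, legit, PROBE, 40_000, rng)
                tol = max(0.02 * max(mine.buried_area, ora[2]), 0.35)
                assert abs(mine.s_legit - ora[0]) <= tol
                assert abs(mine.s_illegit - ora[1]) <= tol
                checked += 1
        assert checked >= 20

    def test_solvent_facing_group_has_minimum_nc(self):
        # the C1-analogue points into solvent; buried groups score higher
        tc = generate_toy_complex(
            60,
            ToyLigandSpec(depths=[-3.0, 1.5, 1.5],
                          pocket_classes=[None, "donor", "donor"],
                          pocket_radius=10.0),
            seed=21,
        )
        rep = analyze_complex(tc.structure, ["IPX"], n_points=2048)
        ncs = {g.label: g.normalized_complementarity for g in rep.groups}
        assert min(ncs, key=ncs.get) == "P1"

    def test_report_frame_columns(self):
        tc = generate_toy_complex(30, ToyLigandSpec(depths=[1.0]), seed=3)
        frame = analyze_complex(tc.structure, ["IPX"], complex_id="toy",
                                n_points=1024).to_frame()
        assert list(frame.columns) == [
            "complex_id", "group", "S_legit", "S_illegit", "C", "NC",
            "reference_area",
        ]
        assert np.allclose(frame["C"], frame["S_legit"] - frame["S_illegit"])
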