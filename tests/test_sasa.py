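"""Lee-Richards SASA engine, exposure fractions, apo/complex burial."""

import numpy as np
import pytest

from conftest import make_structure, sampling_sasa_oracle
from phspec.sasa import (
    delta_sasa,
    exposure_fractions,
    lee_richards_areas,
    lee_richards_sasa,
    load_reference_areas,
)

PROBE = 1.4


@pytest.fixture(scope="module")
def packed_cluster():
    rng = np.random.default_rng(0)
    coords = rng.uniform(0.0, 12.0, size=(50, 3))
    radii = rng.uniform(1.2, 1.9, size=50)
    return coords, radii


class TestSphereGeometry:
    def test_isolated_sphere_closed_form(self):
        area = lee_richards_areas(np.zeros((1, 3)), np.array([1.7]),
                                  PROBE, 0.1)
        exact = 4.0 * np.pi * (1.7 + PROBE) ** 2
        assert area[0] == pytest.approx(exact, rel=5e-3)

    def test_disjoint_spheres_are_additive(self):
        iso = lee_richards_areas(np.zeros((1, 3)), np.array([1.7]), PROBE, 0.1)
        coords = np.array([[0.0, 0.0, 0.0], [10.0, 0.0, 0.0]])
        both = lee_richards_areas(coords, np.array([1.7, 1.7]), PROBE, 0.1)
        assert both.sum() == pytest.approx(2.0 * iso[0], rel=1e-12)

    @pytest.mark.parametrize("axis", [0, 1, 2])
    def test_two_sphere_lens_closed_form(self, axis):
        # spherical cap: each sphere keeps area 2*pi*r*(r + d/2)
        d, r_exp = 3.0, 1.7 + PROBE
        coords = np.zeros((2, 3))
        coords[1, axis] = d
        areas = lee_richards_areas(coords, np.array([1.7, 1.7]), PROBE, 0.05)
        exact = 2.0 * np.pi * r_exp * (r_exp + d / 2.0)
        assert areas[0] == pytest.approx(exact, rel=5e-3)
        assert areas[1] == pytest.approx(exact, rel=5e-3)

    def test_fully_engulfed_sphere_has_zero_area(self):
        coords = np.zeros((2, 3))
        areas = lee_richards_areas(coords, np.array([0.5, 2.5]), PROBE, 0.05)
        assert areas[0] == pytest.approx(0.0, abs=1e-9)

    def test_cluster_matches_dense_sampling_oracle(self, packed_cluster):
        coords, radii = packed_cluster
        mine = lee_richards_areas(coords, radii, PROBE, 0.1)
        oracle = sampling_sasa_oracle(coords, radii, PROBE, 10_000,
                                      np.random.default_rng(1))
        assert mine.sum() == pytest.approx(oracle.sum(), rel=1e-2)


class TestEngineInvariants:
    def test_area_nonincreasing_as_spheres_approach(self):
        radii = np.array([1.7, 1.7])
        totals = []
        for d in np.linspace(7.0, 1.0, 13):
            coords = np.array([[0.0, 0.0, 0.0], [d, 0.0, 0.0]])
            totals.append(lee_richards_areas(coords, radii, PROBE, 0.05).sum())
        assert all(b <= a + 1e-6 for a, b in zip(totals, totals[1:]))

    def test_refinement_convergence(self, packed_cluster):
        coords, radii = packed_cluster
        coarse = lee_richards_areas(coords, radii, PROBE, 0.1).sum()
        fine = lee_richards_areas(coords, radii, PROBE, 0.05).sum()
        assert abs(fine - coarse) / fine < 0.002

    def test_translation_invariance(self, packed_cluster):
        coords, radii = packed_cluster
        base = lee_richards_areas(coords, radii, PROBE, 0.1)
        shifted = lee_richards_areas(coords + np.array([11.3, -7.1, 3.9]),
                                     radii, PROBE, 0.1)
        assert abs(base.sum() - shifted.sum()) <= 1e-3

    def test_rotation_invariance(self, packed_cluster):
        coords, radii = packed_cluster
        theta = 0.7
        rot = np.array([
            [np.cos(theta), -np.sin(theta), 0.0],
            [np.sin(theta), np.cos(theta), 0.0],
            [0.0, 0.0, 1.0],
        ])
        base = lee_richards_areas(coords, radii, PROBE, 0.05).sum()
        rotated = lee_richards_areas(coords @ rot.T, radii, PROBE, 0.05).sum()
        assert rotated == pytest.approx(base, rel=1e-3)

    def test_per_residue_sums_equal_per_atom(self):
        rng = np.random.default_rng(5)
        st = make_structure(rng.uniform(0, 8, (12, 3)), np.full(12, 1.6),
                            res_seq=np.repeat([1, 2, 3], 4),
                            res_names=["GLY"] * 12)
        result = lee_richards_sasa(st, PROBE, 0.1)
        assert result.per_residue_area.sum() == pytest.approx(
            result.per_atom_area.sum(), abs=1e-6)

    def test_coincident_duplicate_removed_with_warning(self):
        st = make_structure([[0, 0, 0], [0, 0, 0]], [1.7, 1.7])
        with pytest.warns(UserWarning, match="duplicate"):
            result = lee_richards_sasa(st, PROBE, 0.1)
        exact = 4.0 * np.pi * (1.7 + PROBE) ** 2
        assert result.total() == pytest.approx(exact, rel=5e-3)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            lee_richards_areas(np.zeros((1, 3)), np.ones(1), -0.1, 0.1)
        with pytest.raises(ValueError):
            lee_richards_areas(np.zeros((1, 3)), np.ones(1), 1.4, 0.0)


class TestExposureFractions:
    def _single_residue(self, area_target):
        # a lone GLY "residue" whose SASA we can steer via the radius
        st = make_structure([[0.0, 0.0, 0.0]],
                            [np.sqrt(area_target / (4 * np.pi)) - PROBE],
                            res_names=["GLY"], names=["CA"])
        return lee_richards_sasa(st, PROBE, 0.02)

    def test_buried_residue_fraction_zero(self):
        ref = load_reference_areas()
        sasa = self._single_residue(ref["GLY"])
        sasa.per_residue_area[:] = 0.0
        sasa.per_atom_area[:] = 0.0
        expo = exposure_fractions(sasa)
        assert expo.fractions[0] == 0.0

    def test_fraction_clipped_at_one(self):
        ref = load_reference_areas()
        expo = exposure_fractions(self._single_residue(1.05 * ref["GLY"]))
        assert expo.fractions[0] == 1.0

    def test_half_reference_area_gives_half_fraction(self):
        ref = load_reference_areas()
        expo = exposure_fractions(self._single_residue(0.5 * ref["GLY"]))
        assert expo.fractions[0] == pytest.approx(0.5, rel=0.02)

    def test_unknown_residue_flagged_and_excluded(self):
        st = make_structure([[0, 0, 0], [8, 0, 0]], [1.7, 1.7],
                            res_names=["GLY", "XYZ"], names=["CA", "CA"])
        sasa = lee_richards_sasa(st, PROBE, 0.1)
        with pytest.warns(UserWarning, match="XYZ"):
            expo = exposure_fractions(sasa)
        assert expo.undefined[1]
        assert np.isnan(expo.fractions[1])
        assert np.isfinite(expo.smoothed[0])


class TestDeltaSasa:
    def _protein_and_ligand(self):
        prot = make_structure(
            [[0, 0, 0], [6, 0, 0], [12, 0, 0]], [1.7] * 3,
            res_names=["GLY"] * 3, names=["CA"] * 3)
        return prot

    def test_identical_structures_bury_nothing(self):
        prot = self._protein_and_ligand()
        apo = lee_richards_sasa(prot, PROBE, 0.1)
        again = lee_richards_sasa(prot, PROBE, 0.1)
        d = delta_sasa(apo, again)
        assert np.allclose(d.buried, 0.0)
        assert not d.binding_site.any()

    def test_ligand_on_one_residue_flags_only_it(self):
        from phspec.pipeline import _concat

        prot = self._protein_and_ligand()
        lig = make_structure([[6, 3.2, 0]], [1.8], elements=["P"],
                             het=[True], res_names=["IPX"], names=["P1"],
                             res_seq=[99])
        apo = lee_richards_sasa(prot, PROBE, 0.1)
        holo = lee_richards_sasa(_concat(prot, lig), PROBE, 0.1)
        d = delta_sasa(apo, holo)
        assert d.binding_site[1]
        assert not d.binding_site[0] and not d.binding_site[2]

    def test_flag_threshold_monotonicity(self):
        from phspec.pipeline import _concat

        prot = self._protein_and_ligand()
        lig = make_structure([[6, 3.2, 0]], [1.8], elements=["P"],
                             het=[True], res_names=["IPX"], names=["P1"],
                             res_seq=[99])
        apo = lee_richards_sasa(prot, PROBE, 0.1)
        holo = lee_richards_sasa(_concat(prot, lig), PROBE, 0.1)
        flagged = [
            delta_sasa(apo, holo, flag_threshold=t).binding_site.sum()
            for t in (0.1, 1.0, 5.0, 50.0)
        ]
        assert all(b >= a for a, b in zip(flagged[1:], flagged))

    def test_atom_mismatch_is_hard_error(self):
        prot = self._protein_and_ligand()
        apo = lee_richards_sasa(prot, PROBE, 0.1)
        smaller = lee_richards_sasa(prot.subset([True, True, False]),
                                    PROBE, 0.1)
        with pytest.raises(ValueError, match="missing"):
            delta_sasa(apo, smaller)
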