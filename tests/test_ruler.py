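"""Centroids, ruler distances, calibration, and length-class prediction."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dicer_ruler import (CalibrationModel, RulerMeasurement, ScaffoldSpec,
                         fit_calibration, generate_scaffold, measure_ruler,
                         predict_length, relevance_flag, replicate_stats,
                         site_centroid)
from dicer_ruler.residue_map import ResidueMap, SiteDefinition, SiteEntry
from dicer_ruler.ruler import (SiteResolutionError, fmt_angstrom,
                               round_half_away, verify_reported_mean)
from dicer_ruler.structure_io import Atom, Residue, Structure

from conftest import TABLE2, build_species_scaffold


def structure_at(points, numbers=None, aa="E"):
    numbers = numbers or range(1, len(points) + 1)
    residues = [Residue("A", n, aa, atoms=[Atom("CA", "C", p)])
                for n, p in zip(numbers, points)]
    return Structure(id="s", residues=residues)


def site_of(numbers, name="RIII_A", aa="E", with_unresolved=0):
    entries = [SiteEntry("A", n, aa) for n in numbers]
    entries += [SiteEntry("A", None, "?")] * with_unresolved
    return SiteDefinition(name, entries)


class TestSiteCentroid:
    def test_single_residue_site_is_its_calpha(self):
        s = structure_at([[1.0, 2.0, 3.0]])
        c = site_centroid(s, site_of([1]))
        np.testing.assert_array_equal(c, [1.0, 2.0, 3.0])

    def test_two_residue_midpoint(self):
        s = structure_at([[0.0, 0.0, 0.0], [2.0, 0.0, 0.0]])
        c = site_centroid(s, site_of([1, 2]))
        np.testing.assert_array_equal(c, [1.0, 0.0, 0.0])

    def test_unresolved_entries_are_skipped(self, rng):
        pts = rng.uniform(-5, 5, (3, 3))
        s = structure_at(pts)
        c = site_centroid(s, site_of([1, 2, 3], with_unresolved=1))
        np.testing.assert_allclose(c, pts.mean(axis=0))

    def test_all_unresolved_is_an_error(self):
        s = structure_at([[0.0, 0.0, 0.0]])
        with pytest.raises(SiteResolutionError):
            site_centroid(s, site_of([], with_unresolved=2))

    def test_all_heavy_policy_averages_over_atoms(self):
        res = Residue("A", 1, "E", atoms=[
            Atom("CA", "C", [0.0, 0.0, 0.0]),
            Atom("CB", "C", [2.0, 0.0, 0.0]),
            Atom("H", "H", [100.0, 0.0, 0.0]),  # hydrogens never counted
        ])
        s = Structure(id="s", residues=[res])
        c = site_centroid(s, site_of([1]), atom_policy="all_heavy")
        np.testing.assert_array_equal(c, [1.0, 0.0, 0.0])


class TestMeasureRuler:
    def test_reference_species_geometry(self):
        """A scaffold with the reference enzyme's pocket distances yields
        the published pair and their mean, 60.3 Å."""
        structure, rmap, _ = build_species_scaffold("dmel", seed=1)
        m = measure_ruler(structure, rmap)
        assert m.d_3p_RIIIA == pytest.approx(61.0, abs=1e-9)
        assert m.d_5p_RIIIB == pytest.approx(59.6, abs=1e-9)
        assert m.mean_distance == pytest.approx(60.3, abs=1e-9)

    @pytest.mark.parametrize("species, expected_mean",
                             [("bter", 62.2), ("lmig", 62.3)])
    def test_other_species_means(self, species, expected_mean):
        structure, rmap, _ = build_species_scaffold(species, seed=2)
        m = measure_ruler(structure, rmap)
        assert m.mean_distance == pytest.approx(expected_mean, abs=1e-9)

    def test_coincident_centroids_give_zero(self):
        pts = [[5.0, 5.0, 5.0]] * 4
        numbers = [801, 901, 1201, 1401]
        s = structure_at(pts, numbers=numbers, aa="A")
        rmap = ResidueMap("z", [
            site_of([801], name="pocket_3prime", aa="A"),
            site_of([901], name="pocket_5prime", aa="A"),
            site_of([1201], name="RIII_A", aa="A"),
            site_of([1401], name="RIII_B", aa="A"),
        ])
        m = measure_ruler(s, rmap)
        assert m.d_3p_RIIIA == m.d_5p_RIIIB == m.mean_distance == 0.0

    def test_missing_site_error_names_the_site(self):
        structure, rmap, _ = build_species_scaffold("dmel")
        partial = ResidueMap("dmel", [s for s in rmap.sites
                                      if s.site_name != "RIII_B"])
        with pytest.raises(SiteResolutionError, match="RIII_B"):
            measure_ruler(structure, partial)

    def test_rigid_invariance(self):
        """The ruler is a Euclidean distance: any global rotation and
        translation of the structure leaves it unchanged."""
        from scipy.spatial.transform import Rotation
        structure, rmap, _ = build_species_scaffold("tni", seed=9)
        base = measure_ruler(structure, rmap)
        rng = np.random.default_rng(4)
        for _ in range(5):
            R = Rotation.random(rng=rng).as_matrix()
            t = rng.uniform(-30, 30, 3)
            moved = structure.copy()
            for res in moved.residues:
                for a in res.atoms:
                    a.position = R @ a.position + t
            m = measure_ruler(moved, rmap)
            assert m.d_3p_RIIIA == pytest.approx(base.d_3p_RIIIA, abs=1e-9)
            assert m.d_5p_RIIIB == pytest.approx(base.d_5p_RIIIB, abs=1e-9)


class TestReplicateStats:
    def _m(self, value):
        return RulerMeasurement("s", value, value, value)

    def test_identical_runs_have_zero_sd(self):
        mean, sd = replicate_stats([self._m(60.3)] * 3)
        assert (mean, sd) == (60.3, 0.0)

    def test_sample_sd_closed_form(self):
        # sd of {60.0, 60.3, 60.6} with n-1 denominator is exactly 0.3
        mean, sd = replicate_stats([self._m(v) for v in (60.0, 60.3, 60.6)])
        assert mean == pytest.approx(60.3)
        assert sd == pytest.approx(0.3)

    def test_single_run(self):
        assert replicate_stats([self._m(59.8)]) == (59.8, 0.0)

    def test_empty_list_is_an_error(self):
        with pytest.raises(ValueError):
            replicate_stats([])


class TestCalibration:
    def test_two_point_line_is_exact(self):
        model = fit_calibration([(60.0, 21), (62.0, 22)])
        assert model.fit_slope == pytest.approx(0.5)
        assert model.rise == pytest.approx(2.0)

    def test_published_five_point_fit_against_closed_form(self):
        """OLS slope over the five (mean distance, length) pairs, checked
        against the closed-form least-squares solution."""
        points = [(TABLE2[s][2], TABLE2[s][3]) for s in TABLE2]
        model = fit_calibration(points)
        d = np.array([p[0] for p in points])
        L = np.array([p[1] for p in points])
        closed_form = (np.sum((d - d.mean()) * (L - L.mean()))
                       / np.sum((d - d.mean()) ** 2))
        assert model.fit_slope == pytest.approx(closed_form, abs=1e-12)
        assert round(model.fit_slope, 3) == 0.490

    def test_degenerate_fit_is_an_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_calibration([(60.0, 20), (60.0, 22)])

    def test_recovery_from_noisy_rounded_data(self, rng):
        """Synthetic (distance, length) pairs from a known line plus
        rounding noise: the fitted slope lands within 10% at n=20."""
        true_slope, true_intercept = 0.5, -9.0
        d = rng.uniform(56.0, 64.0, 20)
        L = np.round(true_slope * d + true_intercept)
        model = fit_calibration(list(zip(d, L)))
        assert model.fit_slope == pytest.approx(true_slope, rel=0.10)


class TestPredictLength:
    MODEL = CalibrationModel(d_ref=60.3, L_ref=21, rise=2.0)

    @pytest.mark.parametrize("distance, expected", [
        (59.8, 21), (62.2, 22), (62.3, 22), (58.3, 20), (60.3, 21),
    ])
    def test_published_length_classes(self, distance, expected):
        assert predict_length(distance, self.MODEL).predicted_nt == expected

    @pytest.mark.parametrize("distance, expected", [
        (59.8, 21), (62.2, 22), (62.3, 22), (58.3, 20),
    ])
    def test_crystallographic_rise_gives_same_classes(self, distance,
                                                      expected):
        model = CalibrationModel(d_ref=60.3, L_ref=21, rise=2.81)
        assert predict_length(distance, model).predicted_nt == expected

    def test_anchor_identity(self):
        p = predict_length(self.MODEL.d_ref, self.MODEL)
        assert p.predicted_nt == self.MODEL.L_ref
        assert p.delta_vs_ref == 0.0
        assert not p.significant

    def test_linear_fit_mode(self):
        model = fit_calibration([(60.0, 21), (62.0, 22)])
        assert predict_length(62.0, model).predicted_nt == 22

    def test_out_of_range_is_flagged_not_raised(self):
        p = predict_length(75.0, self.MODEL)
        assert not p.in_range
        assert p.predicted_nt > 24

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(min_value=50.0, max_value=70.0),
           st.floats(min_value=50.0, max_value=70.0))
    def test_monotone_in_distance(self, d1, d2):
        lo, hi = sorted([d1, d2])
        assert (predict_length(lo, self.MODEL).predicted_nt
                <= predict_length(hi, self.MODEL).predicted_nt)

    def test_nonpositive_distance_is_an_error(self):
        with pytest.raises(ValueError):
            predict_length(0.0, self.MODEL)


class TestRelevanceFlag:
    @pytest.mark.parametrize("delta, expected", [
        (0.4, False),  # below the 0.5 Å relevance threshold
        (0.5, False),  # boundary: "exceeding" is strict
        (-0.6, True),  # absolute value
        (0.6, True),
    ])
    def test_threshold_semantics(self, delta, expected):
        assert relevance_flag(delta) is expected

    def test_nonpositive_threshold_is_an_error(self):
        with pytest.raises(ValueError):
            relevance_flag(0.1, threshold=0.0)


class TestRoundingAndSerialization:
    @pytest.mark.parametrize("x, expected", [
        (0.5, 1), (-0.5, -1), (1.5, 2), (0.4, 0), (-2.6, -3), (0.0, 0),
    ])
    def test_half_away_rounding(self, x, expected):
        assert round_half_away(x) == expected

    def test_angstrom_serialization_is_one_decimal(self):
        assert fmt_angstrom((53.6 + 63.1) / 2.0) == 58.3
        assert fmt_angstrom(60.0) == 60.0

    def test_verify_reported_mean_flags_inconsistency(self):
        # internally consistent published row
        mean, ok = verify_reported_mean(61.0, 59.6, 60.3)
        assert ok and fmt_angstrom(mean) == 60.3
        # the inconsistent row: recomputed 60.0 vs reported 59.8
        mean, ok = verify_reported_mean(58.8, 61.2, 59.8)
        assert not ok
        assert fmt_angstrom(mean) == 60.0
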