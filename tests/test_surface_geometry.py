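"""SASA, BSA, accessibility classes, planarity and shape indices."""
import math

import numpy as np
import pytest

from ppiface.config import DEFAULT_CONFIG
from ppiface.oracles import plane_rmsd_by_grid_search
from ppiface.structure_model import Atom, ComplexPair, Residue
from ppiface.surface_geometry import (DegenerateGeometryError, InputError,
                                      InsufficientSurfaceError, accessibility,
                                      buried_surface_area, classify_accessibility,
                                      planarity, sasa, shape_indices)
from ppiface.interface_analysis import detect_interface


def res_at(chain, seq, coord, element="C", name="CA"):
    return Residue(chain, seq, "", "GLY", [Atom(name, element, np.asarray(coord, float))])


def two_sphere_sasa_exact(r1, r2, d, probe=1.4):
    """Closed-form SASA of two intersecting spheres (inflated radii)."""
    R1, R2 = r1 + probe, r2 + probe
    if d >= R1 + R2:
        return 4 * math.pi * (R1 ** 2 + R2 ** 2)
    h1 = R1 - (d ** 2 + R1 ** 2 - R2 ** 2) / (2 * d)
    h2 = R2 - (d ** 2 + R2 ** 2 - R1 ** 2) / (2 * d)
    return 4 * math.pi * R1 ** 2 - 2 * math.pi * R1 * h1 \
        + 4 * math.pi * R2 ** 2 - 2 * math.pi * R2 * h2


class TestSasa:
    def test_isolated_carbon_matches_closed_form_within_1pct(self):
        result = sasa([res_at("A", 1, [0, 0, 0])], probe=1.4, n_points=10000)
        exact = 4 * math.pi * (1.70 + 1.4) ** 2
        assert result.total == pytest.approx(exact, rel=0.01)

    def test_distant_atoms_are_additive(self):
        both = sasa([res_at("A", 1, [0, 0, 0]), res_at("A", 2, [50, 0, 0])],
                    n_points=2000)
        single = sasa([res_at("A", 1, [0, 0, 0])], n_points=2000)
        assert both.total == pytest.approx(2 * single.total, rel=1e-12)

    @pytest.mark.parametrize("d", [2.0, 3.5, 5.0])
    def test_two_overlapping_spheres_match_cap_formula_within_1pct(self, d):
        result = sasa([res_at("A", 1, [0, 0, 0]), res_at("A", 2, [d, 0, 0])],
                      probe=1.4, n_points=10000)
        assert result.total == pytest.approx(two_sphere_sasa_exact(1.7, 1.7, d),
                                             rel=0.01)

    def test_per_residue_sums_atoms_and_empty_chain_errors(self):
        r = Residue("A", 1, "", "GLY", [Atom("CA", "C", [0, 0, 0]),
                                        Atom("O", "O", [2.0, 0, 0])])
        out = sasa([r], n_points=1000)
        assert out.per_residue[r.key] == pytest.approx(out.per_atom.sum())
        with pytest.raises(InputError):
            sasa([])

    def test_sasa_converges_with_point_count(self):
        rng = np.random.default_rng(11)
        residues = [res_at("A", i + 1, rng.uniform(-3, 3, 3)) for i in range(8)]
        totals = {k: sasa(residues, n_points=k).total for k in (250, 500, 1000, 2000)}
        ref = sasa(residues, n_points=16000).total
        errs = [abs(totals[k] - ref) for k in (250, 500, 1000, 2000)]
        assert errs[-1] < errs[0]


class TestBsa:
    def test_disjoint_chains_bury_nothing(self):
        pair = ComplexPair("t", [res_at("A", 1, [0, 0, 0])],
                           [res_at("B", 1, [30, 0, 0])])
        assert buried_surface_area(pair, n_points=2000) == pytest.approx(0.0, abs=1e-9)

    def test_bsa_is_symmetric_under_chain_swap(self, homodimer_pair):
        cfg = DEFAULT_CONFIG.replace(sasa_points=400)
        assert accessibility(homodimer_pair, cfg).bsa == pytest.approx(
            accessibility(homodimer_pair.swapped(), cfg).bsa, rel=1e-9)

    def test_bsa_invariant_under_rigid_motion(self):
        rng = np.random.default_rng(7)
        pair = ComplexPair(
            "t",
            [res_at("A", i + 1, rng.uniform(-3, 3, 3)) for i in range(8)],
            [res_at("B", i + 1, rng.uniform(-3, 3, 3) + [4.5, 0, 0]) for i in range(8)])
        theta = 0.7
        R = np.array([[math.cos(theta), -math.sin(theta), 0],
                      [math.sin(theta), math.cos(theta), 0],
                      [0, 0, 1.0]])
        b0 = accessibility(pair).bsa
        b1 = accessibility(pair.transformed(R, np.array([10.0, -2.0, 3.0]))).bsa
        assert b1 == pytest.approx(b0, rel=1e-6)
        assert b0 > 0


class TestAccessibilityClasses:
    def test_fully_buried_residue_is_core_and_inaccessible(self):
        c = classify_accessibility(30.0, 0.0)
        assert (c.region, c.exposure, c.solvent_inaccessible) == ("core", "buried", True)

    def test_exposed_residue_is_periphery(self):
        c = classify_accessibility(90.0, 80.0)
        assert (c.region, c.exposure, c.solvent_inaccessible) == ("periphery", "exposed", False)

    def test_exact_threshold_goes_to_periphery(self, config):
        c = classify_accessibility(50.0, config.core_threshold)
        assert c.region == "periphery"
        c2 = classify_accessibility(50.0, config.inaccessible_threshold)
        assert not c2.solvent_inaccessible

    def test_out_of_range_rsa_is_an_input_error(self):
        with pytest.raises(InputError):
            classify_accessibility(50.0, 151.0)
        with pytest.raises(InputError):
            classify_accessibility(-1.0, 10.0)


class TestPlanarity:
    def test_coplanar_points_give_zero(self):
        residues = [res_at("A", i + 1, c) for i, c in enumerate(
            [[0, 0, 0], [3, 0, 0], [0, 3, 0], [3, 3, 0]])]
        assert planarity(residues).rmsd_from_plane == pytest.approx(0.0, abs=1e-12)

    def test_alternating_unit_offsets_give_exactly_one(self):
        residues = [res_at("A", i + 1, c) for i, c in enumerate(
            [[0, 0, 1], [4, 0, -1], [4, 4, 1], [0, 4, -1]])]
        assert planarity(residues).rmsd_from_plane == pytest.approx(1.0, abs=1e-12)

    def test_matches_grid_search_oracle_on_random_points(self):
        rng = np.random.default_rng(3)
        coords = rng.normal(0, 2, (10, 3))
        residues = [res_at("A", i + 1, c) for i, c in enumerate(coords)]
        mine = planarity(residues).rmsd_from_plane
        assert mine == pytest.approx(plane_rmsd_by_grid_search(coords), abs=1e-3)

    def test_invariant_under_rotation_and_translation(self):
        rng = np.random.default_rng(5)
        coords = rng.normal(0, 2, (12, 3))
        theta = 1.1
        R = np.array([[1, 0, 0],
                      [0, math.cos(theta), -math.sin(theta)],
                      [0, math.sin(theta), math.cos(theta)]])
        a = planarity([res_at("A", i + 1, c) for i, c in enumerate(coords)])
        b = planarity([res_at("A", i + 1, c @ R.T + [7, -2, 1])
                       for i, c in enumerate(coords)])
        assert b.rmsd_from_plane == pytest.approx(a.rmsd_from_plane, abs=1e-9)

    def test_degenerate_inputs_raise(self):
        with pytest.raises(DegenerateGeometryError):
            planarity([res_at("A", 1, [0, 0, 0]), res_at("A", 2, [1, 0, 0])])
        collinear = [res_at("A", i + 1, [i * 2.0, 0, 0]) for i in range(5)]
        with pytest.raises(DegenerateGeometryError):
            planarity(collinear)


def _wall(chain, z, nx, ny, sp, x0=0.0, y0=0.0):
    out = []
    k = 1
    for i in range(nx):
        for j in range(ny):
            out.append(res_at(chain, k, [x0 + i * sp, y0 + j * sp, z]))
            k += 1
    return out


class TestShapeIndices:
    def test_parallel_flat_sheets_at_contact_are_highly_complementary(self):
        gap = 0.2
        pair = ComplexPair("walls", _wall("A", 1.7 + gap / 2, 12, 12, 0.6),
                           _wall("B", -(1.7 + gap / 2), 12, 12, 0.6))
        si = shape_indices(pair, detect_interface(pair),
                           bsa=accessibility(pair).bsa)
        assert si.nsc >= 0.9
        assert si.method_tag == "lc-sc-adapted"

    def test_concave_shell_fits_sphere_better_than_flat_wall(self):
        from ppiface.synthetic_complexes import _fibonacci_hemisphere
        sphere = [res_at("S", 1, [0, 0, 0])]
        gap = 0.3
        shell = [res_at("T", i + 1, d * (1.7 + gap + 1.7))
                 for i, d in enumerate(_fibonacci_hemisphere(120))]
        flat = _wall("T", -(1.7 + gap + 1.7), 7, 7, 0.8, x0=-2.4, y0=-2.4)
        nsc = {}
        for name, partner in (("shell", shell), ("flat", flat)):
            pair = ComplexPair(name, sphere, partner)
            si = shape_indices(pair, detect_interface(pair), bsa=50.0)
            nsc[name] = si.nsc
        assert nsc["shell"] > nsc["flat"]

    def test_tiny_interface_raises_insufficient_surface(self):
        pair = ComplexPair("t", [res_at("A", 1, [0, 0, 0])],
                           [res_at("B", 1, [0, 0, 28.0])])
        with pytest.raises(InsufficientSurfaceError):
            shape_indices(pair, detect_interface(pair, cutoff=30.0), bsa=10.0)
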