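"""Inaccessible-probe-radius morphology, enclosed residues, sub-pockets."""
import math

import numpy as np
import pytest

from ppiface.concavity import (ConcavityGrid, GridConfigError,
                               MissingAnnotationError, OutOfGridError,
                               build_concavity_grid, cluster_enclosed,
                               find_enclosed_residues, interface_concavity,
                               residue_concavity)
from ppiface.config import DEFAULT_CONFIG
from ppiface.interface_analysis import InterfaceResidue
from ppiface.oracles import dbscan_by_reachability, rinaccess_oracle_disagreements
from ppiface.structure_model import Atom, ComplexPair, Residue
from ppiface.synthetic_complexes import (SyntheticSpec, expected_pocket_rinaccess,
                                         generate)


def res_at(chain, seq, coord):
    return Residue(chain, seq, "", "GLY", [Atom("CA", "C", np.asarray(coord, float))])


@pytest.fixture(scope="module")
def pocket_grid_04(pocket_pair):
    return build_concavity_grid(pocket_pair.chain_a, DEFAULT_CONFIG.probe_radii,
                                spacing=0.4)


class TestGridConstruction:
    def test_spacing_must_resolve_smallest_probe(self):
        res = [res_at("A", 1, [0, 0, 0])]
        with pytest.raises(GridConfigError):
            build_concavity_grid(res, (0.5, 1.0), spacing=1.2)
        with pytest.raises(GridConfigError):
            build_concavity_grid(res, (0.5, 1.0), spacing=-1.0)

    def test_flat_surface_point_is_never_enclosed(self, pocket_pair, pocket_grid_04):
        # 2 Å above the slab top, far from the pocket: exposed
        value = pocket_grid_04.value_at(np.array([6.0, 6.0, 2.0]))
        assert math.isinf(value) or value >= pocket_grid_04.probe_radii[-1]

    def test_enclosed_sets_are_nested_in_probe_radius(self, pocket_grid_04):
        small = pocket_grid_04.enclosed_at(2.0)
        large = pocket_grid_04.enclosed_at(4.0)
        assert not np.any(small & ~large)

    def test_rinaccess_values_are_on_the_ladder(self, pocket_grid_04):
        vals = pocket_grid_04.rinaccess[np.isfinite(pocket_grid_04.rinaccess)]
        assert set(np.unique(vals)) <= set(pocket_grid_04.probe_radii)


class TestHemispherePocket:
    def test_ligand_atom_reads_first_ladder_value_above_pocket_radius(
            self, pocket_pair, pocket_grid_04):
        rc = residue_concavity(pocket_pair.chain_b[0], pocket_grid_04)
        assert rc.deepest == expected_pocket_rinaccess(3.0, DEFAULT_CONFIG.probe_radii)

    def test_halving_spacing_moves_at_most_one_ladder_step(self, pocket_pair,
                                                           pocket_grid_04):
        coarse = build_concavity_grid(pocket_pair.chain_a,
                                      DEFAULT_CONFIG.probe_radii, spacing=0.8)
        fine_v = residue_concavity(pocket_pair.chain_b[0], pocket_grid_04).deepest
        coarse_v = residue_concavity(pocket_pair.chain_b[0], coarse).deepest
        assert abs(coarse_v - fine_v) <= 0.5 + 1e-9

    def test_rigid_motion_changes_value_at_most_one_step(self, pocket_pair):
        theta = 0.35
        R = np.array([[math.cos(theta), 0, math.sin(theta)],
                      [0, 1, 0],
                      [-math.sin(theta), 0, math.cos(theta)]])
        moved = pocket_pair.transformed(R, np.array([3.3, -1.7, 2.9]))
        g0 = build_concavity_grid(pocket_pair.chain_a, DEFAULT_CONFIG.probe_radii, 0.4)
        g1 = build_concavity_grid(moved.chain_a, DEFAULT_CONFIG.probe_radii, 0.4)
        v0 = residue_concavity(pocket_pair.chain_b[0], g0).deepest
        v1 = residue_concavity(moved.chain_b[0], g1).deepest
        assert abs(v0 - v1) <= 0.5 + 1e-9


class TestOracleEquivalence:
    def test_small_cluster_matches_probe_placement_oracle(self):
        rng = np.random.default_rng(2)
        centers = rng.uniform(-4, 4, (25, 3))
        radii = np.full(25, 1.7)
        residues = [res_at("X", i + 1, c) for i, c in enumerate(centers)]
        ladder = tuple(0.5 * i for i in range(1, 9))
        grid = build_concavity_grid(residues, ladder, spacing=0.4)
        bad, n = rinaccess_oracle_disagreements(grid, centers, radii, ladder,
                                                candidate_spacing=0.2, stride=11)
        assert n > 300
        assert bad == 0


class TestResidueAggregation:
    def _toy_grid(self):
        rin = np.full((4, 4, 4), np.inf)
        rin[1, 1, 1] = 2.0
        rin[2, 1, 1] = 4.0
        rin[1, 2, 1] = 6.0
        return ConcavityGrid(origin=np.zeros(3), spacing=1.0,
                             occupancy=np.zeros((4, 4, 4), bool),
                             rinaccess=rin, probe_radii=(2.0, 4.0, 6.0, 8.0))

    def test_deepest_is_min_over_atoms(self):
        grid = self._toy_grid()
        res = Residue("A", 1, "", "GLY", [Atom("CA", "C", [1, 1, 1]),
                                          Atom("C", "C", [2, 1, 1]),
                                          Atom("O", "O", [1, 2, 1])])
        rc = residue_concavity(res, grid)
        assert rc.per_atom == {"CA": 2.0, "C": 4.0, "O": 6.0}
        assert rc.deepest == 2.0

    def test_halfway_coordinate_ties_to_lower_voxel_index(self):
        grid = self._toy_grid()
        assert grid.voxel_index(np.array([1.5, 1.0, 1.0])) == (1, 1, 1)

    def test_atom_outside_padded_grid_raises(self):
        grid = self._toy_grid()
        with pytest.raises(OutOfGridError):
            residue_concavity(res_at("A", 1, [99.0, 0, 0]), grid)

    def test_interface_mean_and_deepest_arithmetic(self):
        grid = self._toy_grid()
        residues = [res_at("A", 1, [1, 1, 1]), res_at("A", 2, [2, 1, 1]),
                    res_at("A", 3, [1, 2, 1])]
        out = interface_concavity(residues, grid)
        assert out["mean"] == pytest.approx(4.0)     # {2, 4, 6}
        assert out["deepest"] == pytest.approx(2.0)

    def test_constant_values_give_constant_mean(self):
        grid = self._toy_grid()
        residues = [res_at("A", i, [1, 1, 1]) for i in (1, 2, 3)]
        out = interface_concavity(residues, grid)
        assert out["mean"] == out["deepest"] == pytest.approx(2.0)

    def test_flat_residues_average_at_ladder_cap(self):
        grid = self._toy_grid()
        out = interface_concavity([res_at("A", 1, [3, 3, 3])], grid)
        assert out["mean"] == grid.probe_radii[-1]


class TestEnclosedResidues:
    def _ann(self, deepest, rsa_inaccessible):
        ir = InterfaceResidue(residue=res_at("A", 1, [0, 0, 0]), side="smaller")
        ir.deepest_concavity = deepest
        ir.solvent_inaccessible = rsa_inaccessible
        return ir

    @pytest.mark.parametrize("deepest,inaccessible,expected", [
        (3.5, True, True),
        (3.5, False, False),    # fails the accessibility arm
        (4.0, True, True),      # boundary: "4 Å or less" is inclusive
        (4.5, True, False),
    ])
    def test_rule_boundaries(self, deepest, inaccessible, expected):
        ann = [self._ann(deepest, inaccessible)]
        enclosed = find_enclosed_residues(ann)
        assert (len(enclosed) == 1) is expected
        assert ann[0].enclosed is expected

    def test_missing_annotations_raise_listing_residues(self):
        ir = InterfaceResidue(residue=res_at("A", 7, [0, 0, 0]), side="smaller")
        with pytest.raises(MissingAnnotationError, match="7"):
            find_enclosed_residues([ir])


class TestSubPocketClustering:
    def _enclosed_at(self, coords):
        out = []
        for i, c in enumerate(coords):
            ir = InterfaceResidue(residue=res_at("A", i + 1, c), side="smaller")
            ir.deepest_concavity, ir.solvent_inaccessible, ir.enclosed = 2.0, True, True
            out.append(ir)
        return out

    def test_three_mutual_neighbours_form_one_cluster(self):
        ann = self._enclosed_at([[0, 0, 0], [3, 0, 0], [0, 3, 0]])
        clusters = cluster_enclosed(ann, eps=8.0, min_samples=3)
        assert len(clusters) == 1
        assert clusters[0].n_members == 3

    def test_two_points_below_min_samples_are_noise(self):
        ann = self._enclosed_at([[0, 0, 0], [3, 0, 0]])
        assert cluster_enclosed(ann, eps=8.0, min_samples=3) == []

    def test_empty_input_gives_empty_list(self):
        assert cluster_enclosed([], eps=8.0, min_samples=3) == []

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_density_reachability_oracle(self, seed):
        rng = np.random.default_rng(seed)
        coords = rng.uniform(0, 40, (40, 3))
        ann = self._enclosed_at(coords)
        clusters = cluster_enclosed(ann, eps=8.0, min_samples=3)
        labels = dbscan_by_reachability(coords, eps=8.0, min_samples=3)
        mine = {frozenset(cl.members) for cl in clusters}
        keys = [a.key for a in ann]
        oracle = {}
        for k, lab in zip(keys, labels):
            if lab != -1:
                oracle.setdefault(lab, set()).add(k)
        assert mine == {frozenset(v) for v in oracle.values()}
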