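"""Grid-based multiscale morphology: the inaccessible-probe-radius measure.

For a ladder of spherical probe radii, a grid point near a chain's surface
is *enclosed* at radius ρ when no probe of radius ρ can be placed without
overlapping the chain while still covering that point.  The inaccessible
probe radius R_inaccess of a point is the smallest ladder radius at which
it is enclosed — equivalently, the smallest structuring-ball radius whose
morphological closing of the molecular volume contains the point.  Smaller
values mean deeper pockets; points no probe can be excluded from stay at ∞
(flat or convex surroundings).

Implementation: the exact signed distance field to the van-der-Waals union
gives the ball dilation analytically; the erosion step uses a Euclidean
distance transform on the grid.  A half-voxel legality slack compensates
rasterization (the distance field is 1-Lipschitz, so a legal continuous
probe centre inside a voxel implies its centre passes the slackened test).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from sklearn.cluster import DBSCAN

from .config import Config, DEFAULT_CONFIG
from .structure_model import ComplexPair, Residue, write_pdb
from .interface_analysis import InterfaceResidue


class GridConfigError(ValueError):
    pass


class OutOfGridError(ValueError):
    pass


class MissingAnnotationError(ValueError):
    pass


@dataclass
class ConcavityGrid:
    """Per-voxel inaccessible probe radius around one chain's surface."""
    origin: np.ndarray                 # Å, centre of voxel [0,0,0]
    spacing: float                     # Å
    occupancy: np.ndarray              # bool, inside the vdW union
    rinaccess: np.ndarray              # Å, ladder value or inf
    probe_radii: Tuple[float, ...]

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.occupancy.shape

    def voxel_index(self, coord: np.ndarray) -> Tuple[int, int, int]:
        """Nearest voxel; exact half-way ties go to the lower index."""
        frac = (np.asarray(coord, float) - self.origin) / self.spacing
        idx = np.ceil(frac - 0.5).astype(int)
        if np.any(idx < 0) or np.any(idx >= np.array(self.shape)):
            raise OutOfGridError(f"coordinate {coord} outside padded grid")
        return tuple(int(i) for i in idx)

    def value_at(self, coord: np.ndarray) -> float:
        """R_inaccess at the voxel nearest to ``coord``.

        An atom hugging the partner surface can land on a voxel rasterized
        as occupied; in that case the nearest unoccupied voxel within a
        3-voxel neighbourhood is read instead (closest Euclidean centre,
        ties to the lower index)."""
        idx = self.voxel_index(coord)
        if not self.occupancy[idx]:
            return float(self.rinaccess[idx])
        shape = np.array(self.shape)
        for reach in (1, 2, 3):
            lo = np.maximum(np.array(idx) - reach, 0)
            hi = np.minimum(np.array(idx) + reach + 1, shape)
            block = self.occupancy[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
            free = np.argwhere(~block)
            if len(free):
                cand = free + lo
                order = np.lexsort((cand[:, 2], cand[:, 1], cand[:, 0]))
                cand = cand[order]
                centres = self.origin + cand * self.spacing
                d2 = np.sum((centres - np.asarray(coord, float)) ** 2, axis=1)
                best = cand[int(np.argmin(d2))]  # first min: lower index wins ties
                return float(self.rinaccess[tuple(best)])
        return float("inf")

    def enclosed_at(self, rho: float) -> np.ndarray:
        """Voxels enclosed at radius ρ; monotone in ρ by construction."""
        return (~self.occupancy) & (self.rinaccess <= rho + 1e-9)


def _atom_arrays(residues: Sequence[Residue]):
    centers, radii = [], []
    for r in residues:
        for a in r.heavy_atoms:
            centers.append(a.coord)
            radii.append(a.vdw_radius)
    return np.asarray(centers, float), np.asarray(radii, float)


def signed_distance_field(centers: np.ndarray, radii: np.ndarray,
                          points: np.ndarray, k: int = 24) -> np.ndarray:
    """min_i(|p − c_i| − r_i): negative inside the vdW union.  k-nearest
    centres suffice because vdW radii differ by < 0.3 Å."""
    tree = cKDTree(centers)
    k = min(k, len(centers))
    d, idx = tree.query(points, k=k)
    if k == 1:
        d, idx = d[:, None], idx[:, None]
    return (d - radii[idx]).min(axis=1)


def build_concavity_grid(partner_chain: Sequence[Residue],
                         probe_radii: Optional[Sequence[float]] = None,
                         spacing: float = 0.8,
                         padding: Optional[float] = None) -> ConcavityGrid:
    """Rasterize the partner chain and compute R_inaccess for every voxel.

    For each ladder radius ρ (ascending): candidate probe centres are the
    voxels with d_mol ≥ ρ − spacing/2 (legality slack); a voxel outside the
    molecule is accessible when some candidate centre lies within ρ of it
    (distance transform), else enclosed.  R_inaccess is the first ρ at
    which the voxel is enclosed; assignment at the first radius only makes
    the enclosed sets nested by construction.
    """
    ladder = tuple(sorted(probe_radii if probe_radii is not None
                          else DEFAULT_CONFIG.probe_radii))
    # a voxel must be finer than the smallest probe sphere's diameter, or the
    # smallest ladder radii could never be resolved on the grid
    if spacing <= 0 or spacing > 2.0 * ladder[0]:
        raise GridConfigError(
            f"spacing {spacing} must be in (0, smallest probe diameter {2 * ladder[0]}]")
    centers, radii = _atom_arrays(partner_chain)
    if len(centers) == 0:
        raise ValueError("partner chain has no heavy atoms")
    pad = padding if padding is not None else ladder[-1] + 2.0
    lo = centers.min(axis=0) - radii.max() - pad
    hi = centers.max(axis=0) + radii.max() + pad
    axes = [np.arange(lo[k], hi[k] + spacing, spacing) for k in range(3)]
    shape = tuple(len(ax) for ax in axes)
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    d_mol = signed_distance_field(centers, radii, pts).reshape(shape)

    occupancy = d_mol <= 0.0
    rinaccess = np.full(shape, np.inf)
    slack = 0.5 * spacing
    outside = ~occupancy
    for rho in ladder:
        legal = d_mol >= rho - slack
        if legal.any():
            dist_to_legal = ndimage.distance_transform_edt(
                ~legal, sampling=(spacing,) * 3)
            enclosed = outside & (dist_to_legal > rho)
        else:
            enclosed = outside.copy()
        assign = enclosed & np.isinf(rinaccess)
        rinaccess[assign] = rho
    return ConcavityGrid(origin=lo, spacing=spacing, occupancy=occupancy,
                         rinaccess=rinaccess, probe_radii=ladder)


@dataclass
class ResidueConcavity:
    per_atom: Dict[str, float]     # atom name -> Å (inf = never enclosed)
    deepest: float                 # min over atoms

    def __post_init__(self):
        if self.per_atom:
            assert self.deepest == min(self.per_atom.values())


def residue_concavity(residue: Residue, grid: ConcavityGrid) -> ResidueConcavity:
    """Deepest-bound-atom aggregation: each heavy atom reads the R_inaccess
    of its nearest voxel; the residue value is the minimum."""
    per_atom: Dict[str, float] = {}
    for a in residue.heavy_atoms:
        per_atom[a.name] = grid.value_at(a.coord)
    if not per_atom:
        raise ValueError(f"residue {residue.key} has no heavy atoms")
    return ResidueConcavity(per_atom=per_atom, deepest=min(per_atom.values()))


def interface_concavity(side_residues: Sequence[Residue],
                        grid: ConcavityGrid) -> Dict[str, float]:
    """Whole-interface aggregation from one side against the partner grid:
    arithmetic mean of per-residue deepest values (∞ mapped to the largest
    ladder radius for averaging) and the global deepest value."""
    if not side_residues:
        raise ValueError("empty interface side")
    cap = grid.probe_radii[-1]
    deepest_values = []
    for res in side_residues:
        deepest_values.append(residue_concavity(res, grid).deepest)
    capped = [min(v, cap) for v in deepest_values]
    return {"mean": float(np.mean(capped)),
            "deepest": float(min(capped))}


def annotate_concavity(interface_residues: Sequence[InterfaceResidue],
                       grid: ConcavityGrid) -> None:
    """Fill ``deepest_concavity`` on annotations whose side faces `grid`."""
    for ir in interface_residues:
        ir.deepest_concavity = residue_concavity(ir.residue, grid).deepest


def find_enclosed_residues(interface_residues: Sequence[InterfaceResidue],
                           config: Config = DEFAULT_CONFIG) -> List[InterfaceResidue]:
    """Enclosed iff deepest-atom R_inaccess ≤ 4 Å (inclusive) AND the
    residue is solvent inaccessible in the complex."""
    missing = [ir.key for ir in interface_residues
               if ir.deepest_concavity is None or ir.solvent_inaccessible is None]
    if missing:
        raise MissingAnnotationError(
            f"missing concavity/accessibility annotations for: {missing}")
    enclosed = []
    for ir in interface_residues:
        ir.enclosed = (ir.deepest_concavity <= config.enclosed_concavity_max + 1e-12
                       and bool(ir.solvent_inaccessible))
        if ir.enclosed:
            enclosed.append(ir)
    return enclosed


@dataclass
class EnclosedCluster:
    members: List[Tuple]            # residue keys
    centroid: np.ndarray
    n_members: int
    eps: float
    min_samples: int


def cluster_enclosed(enclosed: Sequence[InterfaceResidue],
                     eps: float = 8.0, min_samples: int = 3) -> List[EnclosedCluster]:
    """DBSCAN over residue heavy-atom centroids; noise points belong to no
    cluster.  An interface possesses a sub-pocket cluster iff the result is
    non-empty."""
    if not enclosed:
        return []
    coords = np.array([ir.residue.centroid() for ir in enclosed])
    labels = DBSCAN(eps=eps, min_samples=min_samples).fit_predict(coords)
    clusters = []
    for lab in sorted(set(labels) - {-1}):
        sel = labels == lab
        members = [enclosed[i].key for i in np.flatnonzero(sel)]
        clusters.append(EnclosedCluster(members=members,
                                        centroid=coords[sel].mean(axis=0),
                                        n_members=int(sel.sum()),
                                        eps=eps, min_samples=min_samples))
    return clusters


def write_concavity_pdb(pair: ComplexPair, grid: ConcavityGrid, path,
                        side_chain_id: Optional[str] = None) -> None:
    """Export per-atom concavity in the B-factor column (∞ written as the
    ladder maximum) for visualization."""
    cap = grid.probe_radii[-1]
    bfactors = {}
    for chain in (pair.chain_a, pair.chain_b):
        if side_chain_id is not None and chain[0].chain_id != side_chain_id:
            continue
        for res in chain:
            try:
                rc = residue_concavity(res, grid)
            except OutOfGridError:
                continue
            for name, v in rc.per_atom.items():
                bfactors[(res.key, name)] = min(v, cap)
    write_pdb(pair, path, bfactors=bfactors)


def concavity_csv_rows(residues: Sequence[Residue], grid: ConcavityGrid) -> List[dict]:
    rows = []
    cap = grid.probe_radii[-1]
    for res in residues:
        rc = residue_concavity(res, grid)
        for name, v in rc.per_atom.items():
            rows.append({"chain": res.chain_id, "seq_num": res.seq_num,
                         "icode": res.icode, "atom": name,
                         "rinaccess": min(v, cap),
                         "is_flat": math.isinf(v)})
    return rows
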