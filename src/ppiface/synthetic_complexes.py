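"""Deterministic toy complexes with analytically known interface geometry.

Six archetypes cover the qualitative interface classes the pipeline must
distinguish, plus degenerate fixtures for exercising filters and closed-form
checks:

* ``peptide_in_groove``   — ideal α-helix seated in a snug U-groove carved
                            from a pseudo-atom slab (single segment, deep
                            concavity, well packed).
* ``flat_homodimer``      — two identical flat sheets face to face with a
                            displaced middle run forcing two segments
                            (multi-segment, planar, loosely packed).
* ``heteropair_discontinuous`` — non-identical chains, discontinuous contact.
* ``slab_with_pocket``    — single wall chain with a hemispherical cavity of
                            exactly known radius, plus a one-residue probe
                            "ligand" chain seated at the pocket bottom.
* ``coplanar_interface``  — every interface Cα exactly on z = 0.
* ``subthreshold_pair``   — interfaces designed to fail the residue-product
                            or buried-surface-area dataset filters.

Same (spec, seed) always yields bit-identical coordinates; randomness enters
only through the optional Gaussian jitter (default σ = 0).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List

import numpy as np

from .structure_model import Atom, ComplexPair, Residue, VDW_RADII

KINDS = (
    "peptide_in_groove", "flat_homodimer", "heteropair_discontinuous",
    "slab_with_pocket", "coplanar_interface", "subthreshold_pair",
)


class SyntheticSpecError(ValueError):
    pass


@dataclass(frozen=True)
class SyntheticSpec:
    kind: str
    params: Dict[str, float] = field(default_factory=dict)
    seed: int = 0
    jitter_sigma: float = 0.0

    def __post_init__(self):
        if self.kind not in KINDS:
            raise SyntheticSpecError(f"unknown synthetic kind: {self.kind!r}")


# ---------------------------------------------------------------------------
# Ideal-geometry peptide backbone (NeRF internal-coordinate chain extension)
# ---------------------------------------------------------------------------

_BOND_N_CA = 1.458
_BOND_CA_C = 1.525
_BOND_C_N = 1.329
_BOND_C_O = 1.231
_ANG_C_N_CA = 121.7
_ANG_N_CA_C = 111.2
_ANG_CA_C_N = 116.2
_ANG_CA_C_O = 120.8


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Position atom d given frame atoms a-b-c, bond |cd|, angle b-c-d and
    torsion a-b-c-d (NeRF construction)."""
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array([-bond * math.cos(ang),
                   bond * math.sin(ang) * math.cos(tor),
                   bond * math.sin(ang) * math.sin(tor)])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def build_peptide(n_res: int, phi: float = -57.0, psi: float = -47.0,
                  chain_id: str = "P", resname: str = "ALA",
                  start_seq: int = 1) -> List[Residue]:
    """Ideal peptide backbone (N, CA, C, O) at fixed φ/ψ, ω = 180°."""
    if n_res < 1:
        raise SyntheticSpecError("n_res must be >= 1")
    coords: List[dict] = []
    # seed triad for residue 0
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = n0 + np.array([_BOND_N_CA, 0.0, 0.0])
    ang = math.radians(_ANG_N_CA_C)
    c0 = ca0 + _BOND_CA_C * np.array([math.cos(math.pi - ang), math.sin(math.pi - ang), 0.0])
    coords.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, n_res):
        prev = coords[-1]
        n = _place(prev["N"], prev["CA"], prev["C"], _BOND_C_N, _ANG_CA_C_N, psi)
        ca = _place(prev["CA"], prev["C"], n, _BOND_N_CA, _ANG_C_N_CA, 180.0)  # omega
        c = _place(prev["C"], n, ca, _BOND_CA_C, _ANG_N_CA_C, phi)
        coords.append({"N": n, "CA": ca, "C": c})
    # carbonyl oxygens: anti to the next residue's N about the CA-C bond
    for i, res in enumerate(coords):
        if i + 1 < len(coords):
            res["O"] = _place(coords[i + 1]["N"], res["CA"], res["C"],
                              _BOND_C_O, _ANG_CA_C_O, 180.0)
        else:
            res["O"] = _place(res["N"], res["CA"], res["C"],
                              _BOND_C_O, _ANG_CA_C_O, psi + 180.0)
    residues = []
    for i, res in enumerate(coords):
        atoms = [Atom("N", "N", res["N"]), Atom("CA", "C", res["CA"]),
                 Atom("C", "C", res["C"]), Atom("O", "O", res["O"])]
        residues.append(Residue(chain_id, start_seq + i, "", resname, atoms))
    return residues


def _principal_axis_to_x(residues: List[Residue]) -> List[Residue]:
    """Rigidly move a chain so its Cα principal axis is +x through the origin."""
    ca = np.array([r.atom("CA").coord for r in residues])
    center = ca.mean(axis=0)
    u, s, vt = np.linalg.svd(ca - center)
    axis = vt[0]
    if axis[0] < 0:
        axis = -axis
    # rotation taking `axis` to x-hat (stable Rodrigues construction)
    x = np.array([1.0, 0.0, 0.0])
    v = np.cross(axis, x)
    c = float(axis @ x)
    if np.linalg.norm(v) < 1e-12:
        R = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        R = np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))
    out = []
    for r in residues:
        atoms = [Atom(a.name, a.element, R @ (a.coord - center), a.occupancy)
                 for a in r.atoms]
        out.append(Residue(r.chain_id, r.seq_num, r.icode, r.name, atoms))
    return out


# ---------------------------------------------------------------------------
# Pseudo-atom slabs (glycine-like 4-atom residues on a cubic lattice)
# ---------------------------------------------------------------------------

_QUARTET = (
    ("N", "N", np.array([+0.4, +0.4, +0.4])),
    ("CA", "C", np.array([-0.4, -0.4, +0.4])),
    ("C", "C", np.array([+0.4, -0.4, -0.4])),
    ("O", "O", np.array([-0.4, +0.4, -0.4])),
)


def _quartet_residue(chain_id: str, seq: int, center: np.ndarray) -> Residue:
    atoms = [Atom(name, elem, center + off) for name, elem, off in _QUARTET]
    return Residue(chain_id, seq, "", "GLY", atoms)


def _slab(chain_id: str, xr, yr, zr, spacing: float, keep=None) -> List[Residue]:
    residues = []
    seq = 1
    xs = np.arange(xr[0], xr[1] + 1e-9, spacing)
    ys = np.arange(yr[0], yr[1] + 1e-9, spacing)
    zs = np.arange(zr[0], zr[1] + 1e-9, spacing)
    for x in xs:
        for y in ys:
            for z in zs:
                center = np.array([x, y, z])
                res = _quartet_residue(chain_id, seq, center)
                if keep is None or keep(res):
                    res.seq_num = seq
                    residues.append(res)
                    seq += 1
    return residues


def _fibonacci_hemisphere(n: int) -> np.ndarray:
    """Deterministic unit vectors on the lower (z <= 0) hemisphere."""
    pts = []
    golden = (1 + 5 ** 0.5) / 2
    for k in range(n):
        z = -(k + 0.5) / n          # in (-1, 0)
        r = math.sqrt(max(0.0, 1 - z * z))
        th = 2 * math.pi * k / golden
        pts.append([r * math.cos(th), r * math.sin(th), z])
    return np.array(pts)


# ---------------------------------------------------------------------------
# Archetype constructors
# ---------------------------------------------------------------------------

def _peptide_in_groove(p: Dict) -> ComplexPair:
    """Helix along x, lower half moulded into the slab: the groove is the
    negative imprint of the helix surface plus a small clearance, so the
    peptide sits in a snug, deeply concave channel."""
    n = int(p.get("helix_length", 12))
    clearance = float(p.get("clearance", 0.3))
    spacing = float(p.get("slab_spacing", 1.6))
    helix = _principal_axis_to_x(build_peptide(n, chain_id="P"))
    coords = np.array([a.coord for r in helix for a in r.atoms])
    radii = np.array([a.vdw_radius for r in helix for a in r.atoms])
    r_out = float(np.max(np.hypot(coords[:, 1], coords[:, 2]) + radii))
    half_len = float(np.max(np.abs(coords[:, 0]))) + 2.0

    from scipy.spatial import cKDTree
    tree = cKDTree(coords)
    reach = float(radii.max()) + 1.7 + clearance + 0.1

    def keep(res: Residue) -> bool:
        for a in res.atoms:
            for j in tree.query_ball_point(a.coord, reach):
                if (np.linalg.norm(a.coord - coords[j])
                        < radii[j] + a.vdw_radius + clearance):
                    return False
        return True

    wall = _slab("G", (-half_len, half_len), (-r_out - 5.0, r_out + 5.0),
                 (-r_out - 4.0, 0.0), spacing, keep=keep)
    return ComplexPair("synthetic:peptide_in_groove", helix, wall, method="SYNTHETIC")


def _flat_homodimer(p: Dict) -> ComplexPair:
    n = int(p.get("n_res", 36))
    run = int(p.get("contact_run", 12))
    spacing = float(p.get("spacing", 1.75))
    lift = float(p.get("displaced_offset", 7.0))

    def sheet(chain_id: str, sign: float, x0: float) -> List[Residue]:
        # two rows of residues so the interface Cα set spans a genuine 2D
        # sheet; sequence numbering runs row 1 then row 2
        residues = []
        for i in range(2 * n):
            row, col = divmod(i, n)
            x = x0 + col * spacing
            y = row * 3.0
            dz = sign * lift if run <= col < n - run else 0.0
            atoms = [
                Atom("N", "N", np.array([x - 1.0, y + 1.2, sign * 1.9 + dz])),
                Atom("CA", "C", np.array([x, y, sign * 0.4 + dz])),
                Atom("C", "C", np.array([x + 1.0, y + 1.2, sign * 1.9 + dz])),
                Atom("O", "O", np.array([x, y - 1.2, sign * 1.9 + dz])),
            ]
            residues.append(Residue(chain_id, i + 1, "", "GLY", atoms))
        return residues

    return ComplexPair("synthetic:flat_homodimer",
                       sheet("A", +1.0, 0.0), sheet("B", -1.0, spacing / 2),
                       method="SYNTHETIC")


def _heteropair_discontinuous(p: Dict) -> ComplexPair:
    n = int(p.get("n_res", 40))
    run = int(p.get("contact_run", 12))
    spacing = 1.75
    lift = 7.0
    top = []
    for i in range(n):
        x = i * spacing
        dz = lift if run <= i < n - run else 0.0
        atoms = [
            Atom("N", "N", np.array([x - 1.0, 1.2, 1.9 + dz])),
            Atom("CA", "C", np.array([x, 0.0, 0.4 + dz])),
            Atom("C", "C", np.array([x + 1.0, 1.2, 1.9 + dz])),
            Atom("O", "O", np.array([x, -1.2, 1.9 + dz])),
        ]
        top.append(Residue("A", i + 1, "", "ALA", atoms))
    # larger flat partner: two rows of glycine quartets beneath the whole span
    bottom = []
    seq = 1
    for y in (0.0, 3.0):
        for i in range(n // 2 + 6):
            x = (i - 3) * 2 * spacing + spacing / 2
            bottom.append(_quartet_residue("B", seq, np.array([x, y, -1.6])))
            bottom[-1].seq_num = seq
            seq += 1
    return ComplexPair("synthetic:heteropair_discontinuous", top, bottom,
                       method="SYNTHETIC")


def _slab_with_pocket(p: Dict) -> ComplexPair:
    R = float(p.get("pocket_radius", 3.0))
    half = float(p.get("half_width", max(8.0, R + 5.0)))
    depth = float(p.get("depth", max(6.0, R + 3.0)))
    spacing = float(p.get("slab_spacing", 1.4))
    c0 = np.zeros(3)

    def keep(res: Residue) -> bool:
        for a in res.atoms:
            if np.linalg.norm(a.coord - c0) < R + a.vdw_radius + 0.7:
                return False
        return True

    wall = _slab("W", (-half, half), (-half, half), (-depth, 0.0), spacing, keep=keep)
    # smooth hemispherical liner: carbon atoms whose vdW surface sits exactly
    # at radius R from the pocket centre
    liner_n = max(60, int(2 * math.pi * (R + 1.7) ** 2 / 0.6 ** 2))
    seq = wall[-1].seq_num
    dirs = _fibonacci_hemisphere(liner_n)
    liner_atoms = [Atom("CA", "C", d * (R + VDW_RADII["C"])) for d in dirs]
    for i in range(0, len(liner_atoms), 4):
        group = liner_atoms[i:i + 4]
        seq += 1
        wall.append(Residue("W", seq, "", "GLY", group))
    ligand = [Residue("L", 1, "", "GLY",
                      [Atom("CA", "C", np.array([0.0, 0.0, -(R - 0.4)]))])]
    return ComplexPair("synthetic:slab_with_pocket", wall, ligand, method="SYNTHETIC")


def _coplanar_interface(p: Dict) -> ComplexPair:
    n = int(p.get("n_res", 8))

    def row(chain_id: str, y: float, o_side: float) -> List[Residue]:
        residues = []
        for i in range(n):
            x = i * 3.5
            atoms = [
                Atom("N", "N", np.array([x - 1.2, y + o_side * 1.2, 0.0])),
                Atom("CA", "C", np.array([x, y, 0.0])),
                Atom("C", "C", np.array([x + 1.2, y + o_side * 1.2, 0.0])),
                Atom("O", "O", np.array([x, y + o_side * 2.2, 0.0])),
            ]
            residues.append(Residue(chain_id, i + 1, "", "GLY", atoms))
        return residues

    return ComplexPair("synthetic:coplanar_interface",
                       row("A", 0.0, -1.0), row("B", 4.5, +1.0), method="SYNTHETIC")


def _subthreshold_pair(p: Dict) -> ComplexPair:
    mode = p.get("mode", "small_product")
    if mode == "small_product":
        n_a = int(p.get("n_a", 4))
        n_b = int(p.get("n_b", 5))

        def row(chain_id, n, y):
            return [Residue(chain_id, i + 1, "", "GLY", [
                Atom("N", "N", np.array([i * 3.5 - 1.2, y, 1.2])),
                Atom("CA", "C", np.array([i * 3.5, y, 0.0])),
                Atom("C", "C", np.array([i * 3.5 + 1.2, y, 1.2])),
                Atom("O", "O", np.array([i * 3.5, y, -1.2])),
            ]) for i in range(n)]

        return ComplexPair("synthetic:subthreshold_small_product",
                           row("A", n_a, 0.0), row("B", n_b, 4.5),
                           method="SYNTHETIC")
    if mode == "low_bsa":
        # 5x5 interface residues (product 25 passes the count filter) touching
        # only through sparse oxygen atoms at exactly 5.0 Å: total burial < 100 Å²
        n = int(p.get("n", 5))
        gap = float(p.get("contact_distance", 5.0))

        def sparse_row(chain_id, y_front, direction):
            residues = []
            for i in range(n):
                x = i * 6.0
                y_back = y_front - direction * 2.8
                atoms = [
                    Atom("N", "N", np.array([x - 1.2, y_back, 1.2])),
                    Atom("CA", "C", np.array([x, y_back, 0.0])),
                    Atom("C", "C", np.array([x + 1.2, y_back, 1.2])),
                    Atom("O", "O", np.array([x, y_front, 0.0])),
                ]
                residues.append(Residue(chain_id, i + 1, "", "GLY", atoms))
            return residues

        return ComplexPair("synthetic:subthreshold_low_bsa",
                           sparse_row("A", 0.0, +1.0),
                           sparse_row("B", gap, -1.0),
                           method="SYNTHETIC")
    raise SyntheticSpecError(f"unknown subthreshold mode: {mode!r}")


_BUILDERS = {
    "peptide_in_groove": _peptide_in_groove,
    "flat_homodimer": _flat_homodimer,
    "heteropair_discontinuous": _heteropair_discontinuous,
    "slab_with_pocket": _slab_with_pocket,
    "coplanar_interface": _coplanar_interface,
    "subthreshold_pair": _subthreshold_pair,
}


def generate(spec: SyntheticSpec) -> ComplexPair:
    """Build the archetype; deterministic for fixed (spec, seed)."""
    pair = _BUILDERS[spec.kind](dict(spec.params))
    if spec.jitter_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        for chain in (pair.chain_a, pair.chain_b):
            for res in chain:
                for atom in res.atoms:
                    atom.coord = atom.coord + rng.normal(0.0, spec.jitter_sigma, 3)
    return pair


def expected_properties(spec: SyntheticSpec) -> Dict:
    """Ground-truth labels for each archetype, asserted by the test suite."""
    p = dict(spec.params)
    if spec.kind == "peptide_in_groove":
        return {"segmentation": "single", "n_segments_smaller": 1,
                "smaller_chain": "P", "filter_fate": "pass"}
    if spec.kind == "flat_homodimer":
        # three segments: the two rows' trailing/leading contact runs are
        # contiguous in sequence numbering and merge into one middle segment
        return {"segmentation": "multi", "n_segments_smaller": 3,
                "filter_fate": "pass", "type_label": "identical_symmetric",
                "planarity_below": 1.0}
    if spec.kind == "heteropair_discontinuous":
        return {"segmentation": "multi", "n_segments_smaller": 2,
                "filter_fate": "pass", "type_label": "heteropair"}
    if spec.kind == "slab_with_pocket":
        R = float(p.get("pocket_radius", 3.0))
        return {"pocket_radius": R, "smaller_chain": "L"}
    if spec.kind == "coplanar_interface":
        return {"planarity": 0.0}
    if spec.kind == "subthreshold_pair":
        fate = ("removed_small_product" if p.get("mode", "small_product") == "small_product"
                else "removed_low_bsa")
        return {"filter_fate": fate}
    raise SyntheticSpecError(spec.kind)


def expected_pocket_rinaccess(pocket_radius: float, probe_radii) -> float:
    """First ladder radius strictly greater than the pocket radius: a probe
    resting on the pocket mouth cannot touch the bottom once it no longer
    fits inside."""
    for rho in probe_radii:
        if rho > pocket_radius:
            return rho
    return math.inf
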