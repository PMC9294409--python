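"""Interface residue detection, segmentation, secondary structure, contacts.

A residue is part of the interface iff any of its heavy atoms lies within
the cutoff (default 5 Å, inclusive) of any partner-chain heavy atom.
Hydrogens are ignored for detection because they are usually absent from
crystal structures.

The contact classifier implements documented geometric rules of this
package (method tag "simplified-geometric"); its counts must not be
confused with Arpeggio's.  Machine-readable rules are exported by
``contact_rules()``.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .config import Config, DEFAULT_CONFIG
from .structure_model import CONTACT_TYPES, ComplexPair, Residue

CONTACT_METHOD_TAG = "simplified-geometric"


class NormalizationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Interface detection
# ---------------------------------------------------------------------------

@dataclass
class Interface:
    """Interface residue sets for one pair, with side labels."""
    pair: ComplexPair
    cutoff: float
    residues_a: List[Residue]
    residues_b: List[Residue]

    @property
    def smaller_chain(self) -> str:
        """Side contributing the fewest residues; ties break to the
        lexicographically smaller chain id."""
        na, nb = len(self.residues_a), len(self.residues_b)
        ida, idb = self.pair.chain_a_id, self.pair.chain_b_id
        if na != nb:
            return ida if na < nb else idb
        return min(ida, idb)

    @property
    def larger_chain(self) -> str:
        ids = {self.pair.chain_a_id, self.pair.chain_b_id}
        return (ids - {self.smaller_chain}).pop()

    def side_residues(self, chain_id: str) -> List[Residue]:
        if chain_id == self.pair.chain_a_id:
            return self.residues_a
        if chain_id == self.pair.chain_b_id:
            return self.residues_b
        raise KeyError(chain_id)

    @property
    def smaller_residues(self) -> List[Residue]:
        return self.side_residues(self.smaller_chain)

    @property
    def larger_residues(self) -> List[Residue]:
        return self.side_residues(self.larger_chain)

    def is_empty(self) -> bool:
        return not (self.residues_a or self.residues_b)


def detect_interface(pair: ComplexPair, cutoff: float = 5.0) -> Interface:
    """Heavy-atom distance test, inclusive at the cutoff boundary."""
    coords_b = np.array([a.coord for r in pair.chain_b for a in r.heavy_atoms])
    coords_a = np.array([a.coord for r in pair.chain_a for a in r.heavy_atoms])
    if len(coords_a) == 0 or len(coords_b) == 0:
        raise ValueError("both chains need heavy atoms")
    tree_b = cKDTree(coords_b)
    tree_a = cKDTree(coords_a)

    def hits(chain, tree):
        out = []
        for res in chain:
            pts = res.heavy_coords()
            d, _ = tree.query(pts)
            if np.any(d <= cutoff + 1e-12):
                out.append(res)
        return out

    return Interface(pair=pair, cutoff=cutoff,
                     residues_a=hits(pair.chain_a, tree_b),
                     residues_b=hits(pair.chain_b, tree_a))


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

@dataclass
class Segment:
    chain_id: str
    start: Tuple[int, str]          # (seq_num, icode) of first member
    end: Tuple[int, str]
    members: List[Tuple[int, str]]
    gap_threshold: int


def segment_interface(positions: Sequence[Tuple[int, str]],
                      gap_threshold: int = 4,
                      chain_id: str = "") -> List[Segment]:
    """Greedy left-to-right grouping of interface sequence positions.

    The gap between consecutive interface positions is the count of
    intervening author-numbering positions (a chain break of n missing
    residues therefore counts as a gap of n); distinct insertion codes at
    the same seq_num are adjacent (gap 0).  A new segment starts when the
    gap strictly exceeds the threshold.
    """
    pos = sorted(set((int(s), str(ic)) for s, ic in positions))
    if not pos:
        return []
    segments: List[List[Tuple[int, str]]] = [[pos[0]]]
    for prev, cur in zip(pos, pos[1:]):
        gap = cur[0] - prev[0] - 1 if cur[0] != prev[0] else 0
        if gap > gap_threshold:
            segments.append([cur])
        else:
            segments[-1].append(cur)
    return [Segment(chain_id=chain_id, start=s[0], end=s[-1], members=s,
                    gap_threshold=gap_threshold) for s in segments]


def residue_positions(residues: Sequence[Residue]) -> List[Tuple[int, str]]:
    return [(r.seq_num, r.icode) for r in residues]


def classify_segmentation(n_segments_smaller: int) -> str:
    """Single (continuous) iff the smaller side forms exactly one segment."""
    return "single" if n_segments_smaller == 1 else "multi"


# ---------------------------------------------------------------------------
# Secondary structure (Kabsch–Sander-style hydrogen-bond assignment)
# ---------------------------------------------------------------------------

_KS_Q = 0.084 * 332.0   # kcal/mol·Å, electrostatic H-bond energy prefactor
_KS_CUTOFF = -0.5


def ks_hbond_energy(r_on: float, r_ch: float, r_oh: float, r_cn: float) -> float:
    """E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol."""
    return _KS_Q * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)


def assign_secondary_structure(chain: Sequence[Residue]) -> Dict[Tuple, str]:
    """Three-state assignment: helix (i→i+4 bonded runs), sheet (bridge
    ladders), else loop.

    The amide hydrogen is constructed geometrically on each N, displaced
    1.01 Å along the previous residue's C→O direction reversed, as in the
    classical assignment.  Residues with incomplete backbone, prolines (as
    donors) and chains shorter than 5 residues fall back to loop.
    """
    keys = [r.key for r in chain]
    out = {k: "loop" for k in keys}
    n = len(chain)
    if n < 5:
        return out

    N = [r.atom("N") for r in chain]
    CA = [r.atom("CA") for r in chain]
    C = [r.atom("C") for r in chain]
    O = [r.atom("O") for r in chain]
    complete = [all(x is not None for x in (N[i], CA[i], C[i], O[i])) for i in range(n)]

    H: List[Optional[np.ndarray]] = [None] * n
    for i in range(1, n):
        if complete[i] and complete[i - 1] and chain[i].name.upper() != "PRO":
            co = C[i - 1].coord - O[i - 1].coord
            nrm = np.linalg.norm(co)
            if nrm > 1e-9:
                H[i] = N[i].coord + 1.01 * co / nrm

    def hb(donor: int, acceptor: int) -> bool:
        """N-H of `donor` bonded to C=O of `acceptor`?"""
        if donor <= 0 or donor >= n or acceptor < 0 or acceptor >= n:
            return False
        if abs(donor - acceptor) < 2:
            return False
        if H[donor] is None or not complete[acceptor]:
            return False
        o, c = O[acceptor].coord, C[acceptor].coord
        nn, h = N[donor].coord, H[donor]
        r_on = float(np.linalg.norm(o - nn))
        r_oh = float(np.linalg.norm(o - h))
        r_ch = float(np.linalg.norm(c - h))
        r_cn = float(np.linalg.norm(c - nn))
        if min(r_on, r_oh, r_ch, r_cn) < 0.5:
            return False
        return ks_hbond_energy(r_on, r_ch, r_oh, r_cn) < _KS_CUTOFF

    # helices: two consecutive 4-turns mark residues i+1..i+5 as helix
    turn4 = [hb(i + 4, i) for i in range(n)]
    helix = [False] * n
    for i in range(n - 1):
        if turn4[i] and turn4[i + 1]:
            for j in range(i + 1, min(i + 6, n)):
                helix[j] = True

    # sheets: Kabsch–Sander parallel/antiparallel bridges, |i−j| >= 3
    def hbAC(acceptor: int, donor: int) -> bool:
        return hb(donor, acceptor)

    sheet = [False] * n
    for i in range(n):
        for j in range(i + 3, n):
            parallel = ((hbAC(i - 1, j) and hbAC(j, i + 1))
                        or (hbAC(j - 1, i) and hbAC(i, j + 1)))
            anti = ((hbAC(i, j) and hbAC(j, i))
                    or (hbAC(i - 1, j + 1) and hbAC(j - 1, i + 1)))
            if parallel or anti:
                sheet[i] = True
                sheet[j] = True

    for i, key in enumerate(keys):
        if not complete[i]:
            out[key] = "loop"
        elif helix[i]:
            out[key] = "helix"
        elif sheet[i]:
            out[key] = "sheet"
    return out


# ---------------------------------------------------------------------------
# Simplified non-covalent contact typing
# ---------------------------------------------------------------------------

_RING_TEMPLATES = {
    "HIS": [("CG", "ND1", "CD2", "CE1", "NE2")],
    "PHE": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "TYR": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "TRP": [("CG", "CD1", "NE1", "CE2", "CD2"),
            ("CE2", "CD2", "CE3", "CZ3", "CH2", "CZ2")],
}

_POS_CHARGED = {("LYS", "NZ"), ("ARG", "NH1"), ("ARG", "NH2"), ("ARG", "NE"),
                ("HIS", "ND1"), ("HIS", "NE2")}
_NEG_CHARGED = {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2")}

# side-chain carbons treated as apolar (not bonded to N/O); backbone C and
# amide/carboxyl carbons are excluded
_POLAR_CARBONS = {("ASN", "CG"), ("ASP", "CG"), ("GLN", "CD"), ("GLU", "CD"),
                  ("ARG", "CZ")}

_SIDE_AMIDES = {"ASN": ("CG", "OD1", "ND2"), "GLN": ("CD", "OE1", "NE2")}

_CONTACT_RULES = {
    "vdw": {"criterion": "d <= r_i + r_j + 0.5", "margin": 0.5},
    "vdw_clash": {"criterion": "d < r_i + r_j - 0.4", "margin": -0.4},
    "proximal": {"criterion": "d <= 5.0 and no other atom-pair type", "cutoff": 5.0},
    "hbond_polar": {"criterion": "N/O donor-acceptor pair, d <= 3.5", "cutoff": 3.5},
    "weak_hbond": {"criterion": "carbon donor to N/O acceptor, d <= 3.8", "cutoff": 3.8},
    "ionic": {"criterion": "Lys/Arg/His N+ to Asp/Glu O-, d <= 4.0", "cutoff": 4.0},
    "hydrophobic": {"criterion": "apolar C to apolar C, d <= 4.5", "cutoff": 4.5},
    "carbonyl": {"criterion": "carbonyl C to carbonyl O, d <= 3.6", "cutoff": 3.6},
    "aromatic_ring": {"criterion": "ring centroid to ring centroid <= 5.5", "cutoff": 5.5},
    "atom_ring": {"criterion": "heavy atom to ring centroid <= 4.5", "cutoff": 4.5},
    "amide_ring": {"criterion": "amide centroid to ring centroid <= 5.5", "cutoff": 5.5},
    "amide_amide": {"criterion": "amide centroid to amide centroid <= 5.0", "cutoff": 5.0},
    "carbon_pi": {"criterion": "carbon atom to ring centroid <= 4.5", "cutoff": 4.5},
}


def contact_rules() -> dict:
    """Machine-readable contact rule table for provenance."""
    return {"method_tag": CONTACT_METHOD_TAG, "rules": _CONTACT_RULES}


def _is_apolar_carbon(resname: str, atom_name: str) -> bool:
    if not atom_name.startswith("C") or atom_name in ("C",):
        return False
    return (resname.upper(), atom_name) not in _POLAR_CARBONS


def _ring_centroids(residues: Sequence[Residue]) -> List[np.ndarray]:
    cents = []
    for res in residues:
        for names in _RING_TEMPLATES.get(res.name.upper(), ()):
            atoms = [res.atom(nm) for nm in names]
            if all(a is not None for a in atoms):
                cents.append(np.mean([a.coord for a in atoms], axis=0))
    return cents


def _amide_centroids(residues: Sequence[Residue]) -> List[np.ndarray]:
    cents = []
    by_key = {r.key: r for r in residues}
    ordered = sorted(residues, key=lambda r: (r.seq_num, r.icode))
    for prev, nxt in zip(ordered, ordered[1:]):
        c, o, nn = prev.atom("C"), prev.atom("O"), nxt.atom("N")
        if all(a is not None for a in (c, o, nn)) and nxt.seq_num - prev.seq_num <= 1:
            cents.append(np.mean([c.coord, o.coord, nn.coord], axis=0))
    for res in residues:
        names = _SIDE_AMIDES.get(res.name.upper())
        if names:
            atoms = [res.atom(nm) for nm in names]
            if all(a is not None for a in atoms):
                cents.append(np.mean([a.coord for a in atoms], axis=0))
    return cents


@dataclass
class ContactCount:
    counts: Dict[str, int]
    normalized: Dict[str, float]         # per 100 Å² BSA
    bsa: float
    method_tag: str = CONTACT_METHOD_TAG


def count_contacts(pair: ComplexPair, interface: Interface, bsa: float,
                   config: Config = DEFAULT_CONFIG) -> ContactCount:
    """Type every inter-chain heavy-atom contact by the documented rules.

    An atom pair collects every type whose criterion it satisfies, except
    that ``proximal`` applies only to pairs within 5 Å that match no other
    atom-pair rule.  Ring- and amide-centroid contacts are counted per
    centroid pair.  Counts are normalized as count × 100 / BSA.
    """
    if bsa <= 0:
        raise NormalizationError("BSA must be > 0 for per-100 Å² normalization")
    ra = interface.residues_a or pair.chain_a
    rb = interface.residues_b or pair.chain_b

    def table(residues):
        rows = []
        for res in residues:
            for a in res.heavy_atoms:
                rows.append((res, a))
        return rows

    ta, tb = table(ra), table(rb)
    ca = np.array([a.coord for _, a in ta])
    cb = np.array([a.coord for _, a in tb])
    counts = {t: 0 for t in CONTACT_TYPES}

    pairs = cKDTree(ca).query_ball_tree(cKDTree(cb), r=5.0 + 1e-9)
    for i, js in enumerate(pairs):
        res_i, at_i = ta[i]
        for j in js:
            res_j, at_j = tb[j]
            d = float(np.linalg.norm(ca[i] - cb[j]))
            rr = at_i.vdw_radius + at_j.vdw_radius
            typed = False
            if d <= rr + 0.5:
                counts["vdw"] += 1
                typed = True
            if d < rr - 0.4:
                counts["vdw_clash"] += 1
                typed = True
            ei, ej = at_i.element.upper(), at_j.element.upper()
            polar_i, polar_j = ei in "NO", ej in "NO"
            if polar_i and polar_j and d <= 3.5:
                counts["hbond_polar"] += 1
                typed = True
            if d <= 3.8 and ((ei == "C" and polar_j) or (ej == "C" and polar_i)):
                counts["weak_hbond"] += 1
                typed = True
            ki = (res_i.name.upper(), at_i.name)
            kj = (res_j.name.upper(), at_j.name)
            if d <= 4.0 and ((ki in _POS_CHARGED and kj in _NEG_CHARGED)
                             or (kj in _POS_CHARGED and ki in _NEG_CHARGED)):
                counts["ionic"] += 1
                typed = True
            if d <= 4.5 and _is_apolar_carbon(res_i.name, at_i.name) \
                    and _is_apolar_carbon(res_j.name, at_j.name):
                counts["hydrophobic"] += 1
                typed = True
            carbonyl_c_i = at_i.name == "C" or ki in _POLAR_CARBONS
            carbonyl_c_j = at_j.name == "C" or kj in _POLAR_CARBONS
            carbonyl_o_i = at_i.name in ("O", "OD1", "OE1")
            carbonyl_o_j = at_j.name in ("O", "OD1", "OE1")
            if d <= 3.6 and ((carbonyl_c_i and carbonyl_o_j)
                             or (carbonyl_c_j and carbonyl_o_i)):
                counts["carbonyl"] += 1
                typed = True
            if not typed and d <= 5.0:
                counts["proximal"] += 1

    rings_a, rings_b = _ring_centroids(ra), _ring_centroids(rb)
    amides_a, amides_b = _amide_centroids(ra), _amide_centroids(rb)

    def centroid_pairs(xs, ys, cutoff):
        c = 0
        for x in xs:
            for y in ys:
                if np.linalg.norm(x - y) <= cutoff:
                    c += 1
        return c

    counts["aromatic_ring"] += centroid_pairs(rings_a, rings_b, 5.5)
    counts["amide_ring"] += centroid_pairs(amides_a, rings_b, 5.5)
    counts["amide_ring"] += centroid_pairs(amides_b, rings_a, 5.5)
    counts["amide_amide"] += centroid_pairs(amides_a, amides_b, 5.0)
    for rings, partner in ((rings_a, tb), (rings_b, ta)):
        for cent in rings:
            for res, at in partner:
                if np.linalg.norm(at.coord - cent) <= 4.5:
                    counts["atom_ring"] += 1
                    if at.element.upper() == "C":
                        counts["carbon_pi"] += 1

    normalized = {t: counts[t] * 100.0 / bsa for t in CONTACT_TYPES}
    return ContactCount(counts=counts, normalized=normalized, bsa=bsa)


# ---------------------------------------------------------------------------
# Interface residue annotation and hotspot density
# ---------------------------------------------------------------------------

@dataclass
class InterfaceResidue:
    """Per-residue interface annotation, filled in stages by the pipeline."""
    residue: Residue
    side: str                                  # "smaller" | "larger"
    region: Optional[str] = None               # "core" | "periphery"
    rsa_monomer: Optional[float] = None
    rsa_complex: Optional[float] = None
    solvent_inaccessible: Optional[bool] = None
    ss_class: Optional[str] = None             # "helix" | "sheet" | "loop"
    deepest_concavity: Optional[float] = None  # Å (may be inf = flat/exposed)
    enclosed: Optional[bool] = None
    ddg: Optional[float] = None                # kcal/mol
    is_hotspot: Optional[bool] = None

    @property
    def key(self):
        return self.residue.key


def hotspot_density(interface_residues: Sequence[InterfaceResidue],
                    ddg_table: Dict[Tuple, float], bsa: float,
                    threshold: float = 1.0) -> Tuple[Optional[int], Optional[float]]:
    """Hotspots per 100 Å² BSA; a residue is a hotspot iff |ΔΔG| is strictly
    greater than the threshold.  Residues without a ΔΔG entry are flagged
    (ddg stays None) and excluded from the count; with no entries at all the
    density is absent and a warning is issued."""
    if bsa <= 0:
        raise NormalizationError("BSA must be > 0")
    n_with = 0
    n_hot = 0
    for ir in interface_residues:
        ddg = ddg_table.get(ir.key)
        if ddg is None:
            ir.ddg = None
            ir.is_hotspot = None
            continue
        n_with += 1
        ir.ddg = float(ddg)
        ir.is_hotspot = abs(ir.ddg) > threshold
        if ir.is_hotspot:
            n_hot += 1
    if n_with == 0:
        warnings.warn("no ΔΔG entries map to interface residues; "
                      "hotspot density undefined")
        return None, None
    return n_hot, n_hot * 100.0 / bsa
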