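"""Structure data model: atoms, residues, two-chain complexes, and I/O.

Coordinate convention is Å, right-handed, exactly as stored in the input file
(no re-orientation, no renumbering: author residue numbering with insertion
codes is preserved verbatim throughout the package).  Hydrogens are kept but
flagged; waters and non-polymer hetero ligands are dropped on reading.

The van der Waals radius table below is the single source used for both SASA
and the concavity grids.
"""
from __future__ import annotations

import csv
import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import gemmi
import numpy as np

# Single-source vdW radii (Å).  Unlisted elements fall back to DEFAULT_VDW_RADIUS.
VDW_RADII: Dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "H": 1.20,
}
DEFAULT_VDW_RADIUS = 1.70

STANDARD_AA_3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

BACKBONE_ATOMS = ("N", "CA", "C", "O")


class StructureFormatError(ValueError):
    """The input file could not be parsed as PDB or mmCIF."""


class ChainNotFoundError(KeyError):
    """A requested chain is absent; the message names the chain."""


@dataclass
class Atom:
    """One atom: label, element, position (Å), occupancy."""

    name: str
    element: str
    coord: np.ndarray
    occupancy: float = 1.0

    def __post_init__(self):
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name}: coord must be a finite 3-vector")
        if not self.element:
            raise ValueError(f"atom {self.name}: element must be non-empty")

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"

    @property
    def vdw_radius(self) -> float:
        return VDW_RADII.get(self.element.upper(), DEFAULT_VDW_RADIUS)


@dataclass
class Residue:
    """One residue with author numbering; (chain_id, seq_num, icode) is its key."""

    chain_id: str
    seq_num: int
    icode: str
    name: str                      # 3-letter residue name
    atoms: List[Atom] = field(default_factory=list)

    def __post_init__(self):
        if not self.atoms:
            raise ValueError(f"residue {self.key}: atoms must be non-empty")

    @property
    def key(self) -> Tuple[str, int, str]:
        return (self.chain_id, self.seq_num, self.icode)

    @property
    def aa(self) -> str:
        """One-letter code; 'X' for nonstandard polymer members."""
        return STANDARD_AA_3TO1.get(self.name.upper(), "X")

    @property
    def heavy_atoms(self) -> List[Atom]:
        return [a for a in self.atoms if a.is_heavy]

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def has_backbone(self) -> bool:
        return all(self.atom(n) is not None for n in BACKBONE_ATOMS)

    def heavy_coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.heavy_atoms], dtype=float)

    def centroid(self) -> np.ndarray:
        return self.heavy_coords().mean(axis=0)


@dataclass
class ComplexPair:
    """A pairwise complex: exactly two interacting polypeptide chains."""

    id: str
    chain_a: List[Residue]
    chain_b: List[Residue]
    method: str = ""
    resolution: Optional[float] = None
    model_index: int = 0

    def __post_init__(self):
        for label, chain in (("A", self.chain_a), ("B", self.chain_b)):
            if not chain:
                raise ValueError(f"{self.id}: chain {label} is empty")
            keys = [r.key for r in chain]
            if len(set(keys)) != len(keys):
                raise ValueError(f"{self.id}: duplicate residue keys in chain {label}")

    @property
    def chain_a_id(self) -> str:
        return self.chain_a[0].chain_id

    @property
    def chain_b_id(self) -> str:
        return self.chain_b[0].chain_id

    def chain(self, chain_id: str) -> List[Residue]:
        if chain_id == self.chain_a_id:
            return self.chain_a
        if chain_id == self.chain_b_id:
            return self.chain_b
        raise ChainNotFoundError(chain_id)

    def sequence(self, chain_id: str) -> str:
        return "".join(r.aa for r in self.chain(chain_id))

    def swapped(self) -> "ComplexPair":
        return ComplexPair(self.id, self.chain_b, self.chain_a,
                           self.method, self.resolution, self.model_index)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "ComplexPair":
        """Rigid-body copy (used by invariance tests)."""
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)

        def _move(chain):
            return [Residue(r.chain_id, r.seq_num, r.icode, r.name,
                            [Atom(a.name, a.element, R @ a.coord + t, a.occupancy)
                             for a in r.atoms])
                    for r in chain]

        return ComplexPair(self.id, _move(self.chain_a), _move(self.chain_b),
                           self.method, self.resolution, self.model_index)


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def _is_amino_acid(name: str) -> bool:
    if name.upper() in STANDARD_AA_3TO1:
        return True
    info = gemmi.find_tabulated_residue(name)
    return info is not None and info.is_amino_acid()


def _pick_altlocs(raw_atoms) -> List:
    """Keep the highest-occupancy conformer per atom name; ties break to the
    alphabetically first altloc."""
    by_name: Dict[str, list] = {}
    for a in raw_atoms:
        by_name.setdefault(a.name, []).append(a)
    picked = []
    for name, group in by_name.items():
        group.sort(key=lambda a: (-(a.occ if a.occ is not None else 1.0), a.altloc or ""))
        picked.append(group[0])
    picked.sort(key=lambda a: a.serial if a.serial else 0)
    return picked


def read_complex(path, chain_pair: Sequence[str]) -> ComplexPair:
    """Read one two-chain complex from a PDB or mmCIF file.

    Heavy atoms and hydrogens are both retained (hydrogens flagged via
    ``Atom.is_heavy``); waters and non-polypeptide HETATM ligands are
    dropped.  For NMR ensembles only the first model is used.
    """
    path = Path(path)
    if len(chain_pair) != 2:
        raise ValueError("chain_pair must name exactly two chains")
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise StructureFormatError(f"{path}: no models")
    st.setup_entities()

    try:
        method = st.info["_exptl.method"]
    except (KeyError, AttributeError):
        method = ""
    resolution = st.resolution if st.resolution and st.resolution > 0 else None
    model = st[0]  # first model only (relevant for NMR ensembles)
    if len(model) == 0:
        raise StructureFormatError(f"{path}: no chains parsed (not PDB/mmCIF?)")

    chains: List[List[Residue]] = []
    for want in chain_pair:
        gchain = None
        for ch in model:
            if ch.name == want:
                gchain = ch
                break
        if gchain is None:
            raise ChainNotFoundError(
                f"{path}: chain '{want}' not found (have {[c.name for c in model]})")
        residues: List[Residue] = []
        for gres in gchain:
            if gres.is_water() or not _is_amino_acid(gres.name):
                continue
            atoms = []
            for ga in _pick_altlocs(list(gres)):
                atoms.append(Atom(ga.name, ga.element.name or "C",
                                  np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                                  ga.occ if ga.occ is not None else 1.0))
            if atoms:
                residues.append(Residue(want, gres.seqid.num,
                                        (gres.seqid.icode or " ").strip() or "",
                                        gres.name, atoms))
        if not residues:
            raise ChainNotFoundError(f"{path}: chain '{want}' has no polypeptide residues")
        chains.append(residues)

    return ComplexPair(id=f"{path.stem}:{chain_pair[0]}-{chain_pair[1]}",
                       chain_a=chains[0], chain_b=chains[1],
                       method=method, resolution=resolution, model_index=0)


# ---------------------------------------------------------------------------
# PDB writing (fixed-column format; round-trips through read_complex)
# ---------------------------------------------------------------------------

def write_pdb(pair: ComplexPair, path, bfactors: Optional[Dict] = None) -> None:
    """Write the pair as a standard fixed-column PDB file.

    ``bfactors`` optionally maps (residue key, atom name) to a value written
    in the B-factor column (used to export per-atom concavity).
    """
    lines = []
    if pair.method:
        lines.append(f"EXPDTA    {pair.method.upper()}")
    if pair.resolution is not None:
        lines.append(f"REMARK   2 RESOLUTION. {pair.resolution:6.2f} ANGSTROMS.")
    serial = 1
    for chain in (pair.chain_a, pair.chain_b):
        for res in chain:
            for a in res.atoms:
                name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
                b = 0.0
                if bfactors:
                    b = float(bfactors.get((res.key, a.name), 0.0))
                lines.append(
                    f"ATOM  {serial:5d} {name:<4s} {res.name:<3s} {res.chain_id:1s}"
                    f"{res.seq_num:4d}{res.icode or ' ':1s}   "
                    f"{a.coord[0]:8.3f}{a.coord[1]:8.3f}{a.coord[2]:8.3f}"
                    f"{a.occupancy:6.2f}{b:6.2f}          {a.element.upper():>2s}")
                serial += 1
        lines.append(f"TER   {serial:5d}      {chain[-1].name:<3s} "
                     f"{chain[-1].chain_id:1s}{chain[-1].seq_num:4d}")
        serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Interface descriptor record
# ---------------------------------------------------------------------------

CONTACT_TYPES = (
    "vdw", "vdw_clash", "proximal", "hbond_polar", "weak_hbond", "ionic",
    "hydrophobic", "carbonyl", "aromatic_ring", "atom_ring", "amide_ring",
    "amide_amide", "carbon_pi",
)


@dataclass
class InterfaceRecord:
    """Full descriptor vector for one pairwise interface."""

    id: str
    chain_a: str = ""
    chain_b: str = ""
    method: str = ""
    resolution: Optional[float] = None
    n_residues_a: int = 0
    n_residues_b: int = 0
    n_interface_a: int = 0
    n_interface_b: int = 0
    smaller_side: str = ""
    n_segments_smaller: int = 0
    n_segments_larger: int = 0
    segmentation: str = ""                 # "single" | "multi"
    planarity: Optional[float] = None      # Å, RMSD of interface Cα from fitted plane
    bsa: float = 0.0                       # Å²
    nsc: Optional[float] = None
    nip: Optional[float] = None
    shape_method_tag: str = ""
    mean_concavity: Optional[float] = None     # Å, smaller side vs larger side's grid
    deepest_concavity: Optional[float] = None  # Å, smaller side
    deepest_concavity_larger: Optional[float] = None  # Å, interlocking partner value
    n_enclosed: int = 0
    n_clusters: int = 0
    n_hotspots: Optional[int] = None
    hotspot_density: Optional[float] = None    # per 100 Å² BSA
    helix_fraction: Optional[float] = None     # smaller-side interface residues
    sheet_fraction: Optional[float] = None
    loop_fraction: Optional[float] = None
    core_fraction: Optional[float] = None
    type_label: Optional[str] = None
    contacts: Dict[str, int] = field(default_factory=dict)
    contacts_per_100: Dict[str, float] = field(default_factory=dict)
    clusters: List[dict] = field(default_factory=list)   # nested JSON only
    residues: List[dict] = field(default_factory=list)   # per-residue annotations, JSON only

    # Documented, stable CSV column order.
    SCALAR_COLUMNS = (
        "id", "chain_a", "chain_b", "method", "resolution",
        "n_residues_a", "n_residues_b", "n_interface_a", "n_interface_b",
        "smaller_side", "n_segments_smaller", "n_segments_larger", "segmentation",
        "planarity", "bsa", "nsc", "nip", "shape_method_tag",
        "mean_concavity", "deepest_concavity", "deepest_concavity_larger",
        "n_enclosed", "n_clusters", "n_hotspots", "hotspot_density",
        "helix_fraction", "sheet_fraction", "loop_fraction", "core_fraction",
        "type_label",
    )

    @classmethod
    def csv_columns(cls) -> List[str]:
        cols = list(cls.SCALAR_COLUMNS)
        cols += [f"contact_{t}" for t in CONTACT_TYPES]
        cols += [f"contact_{t}_per100" for t in CONTACT_TYPES]
        return cols

    def csv_row(self) -> List:
        def cell(v):
            return "" if v is None else v
        row = [cell(getattr(self, c)) for c in self.SCALAR_COLUMNS]
        row += [cell(self.contacts.get(t)) for t in CONTACT_TYPES]
        row += [cell(self.contacts_per_100.get(t)) for t in CONTACT_TYPES]
        return row

    def to_json_dict(self) -> dict:
        d = dataclasses.asdict(self)

        def _clean(obj):
            if isinstance(obj, dict):
                return {k: _clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [_clean(v) for v in obj]
            if isinstance(obj, np.ndarray):
                return [float(x) for x in obj]
            if isinstance(obj, (np.floating,)):
                return float(obj)
            if isinstance(obj, (np.integer,)):
                return int(obj)
            if isinstance(obj, float) and math.isinf(obj):
                return "inf"
            return obj

        return _clean(d)

    @classmethod
    def from_json_dict(cls, d: dict) -> "InterfaceRecord":
        d = dict(d)

        def _restore(obj):
            if obj == "inf":
                return math.inf
            if isinstance(obj, dict):
                return {k: _restore(v) for k, v in obj.items()}
            if isinstance(obj, list):
                return [_restore(v) for v in obj]
            return obj

        return cls(**{k: _restore(v) for k, v in d.items()})


def write_interface_record(record: InterfaceRecord, path) -> None:
    """Write one record as a flat CSV row plus a full nested JSON file.

    ``path`` is a stem or either of the two filenames; both ``<stem>.csv``
    and ``<stem>.json`` are produced.  Absent values become empty CSV cells
    (never 0).  Re-reading the JSON reproduces the record exactly for
    integers/strings and to better than 1e-9 for floats.
    """
    stem = Path(path)
    if stem.suffix in (".csv", ".json"):
        stem = stem.with_suffix("")
    try:
        with open(stem.with_suffix(".csv"), "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(InterfaceRecord.csv_columns())
            w.writerow(record.csv_row())
        with open(stem.with_suffix(".json"), "w") as fh:
            json.dump(record.to_json_dict(), fh, indent=1)
    except OSError as exc:
        raise IOError(f"cannot write interface record to {stem}: {exc}") from exc


def read_interface_record(path) -> InterfaceRecord:
    stem = Path(path)
    if stem.suffix in (".csv", ".json"):
        stem = stem.with_suffix("")
    with open(stem.with_suffix(".json")) as fh:
        return InterfaceRecord.from_json_dict(json.load(fh))
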