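"""Dataset assembly: filters, redundancy clustering, typing, descriptors.

Filter order is fixed: (a) interface residues with missing backbone heavy
atoms, (b) overlapping interfaces (two pairs sharing interface residues on
the same chain instance), (c) interface residue product nA × nB < 25,
(d) BSA < 100 Å².  Each interface is counted once, under its first failing
rule, so the report's counts always sum to the input count.

Redundancy clustering mirrors the two-stage reduction: chains are grouped
at 95% global-alignment identity, and identical pairs are further split by
a Ratcliff/Obershelp interface-sequence similarity below 75%.  The cluster
representative is the member with the best structure-quality score.
"""
from __future__ import annotations

import difflib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from Bio import Align

from .config import Config, DEFAULT_CONFIG
from . import concavity as _concavity
from . import interface_analysis as _ia
from . import surface_geometry as _sg
from .structure_model import (ComplexPair, InterfaceRecord, read_complex,
                              write_interface_record)

logger = logging.getLogger("ppiface.pipeline")


# ---------------------------------------------------------------------------
# Sequence comparison
# ---------------------------------------------------------------------------

def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1.0
    a.mismatch_score = 0.0
    a.open_gap_score = -0.5
    a.extend_gap_score = -0.5
    return a


def sequence_identity(seq_a: str, seq_b: str) -> float:
    """Global-alignment identity: matches / alignment length × 100.

    Scoring: match +1, mismatch 0, gap −0.5 (open and extend)."""
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    aln = _aligner().align(seq_a, seq_b)[0]
    counts = aln.counts()
    return 100.0 * counts.identities / aln.length


def interface_similarity(iface_a: str, iface_b: str) -> float:
    """Ratcliff/Obershelp ratio 2M / (len(a)+len(b)); two empty interface
    strings are defined as identical (1.0)."""
    if not iface_a and not iface_b:
        return 1.0
    return difflib.SequenceMatcher(None, iface_a, iface_b, autojunk=False).ratio()


def _alignment_columns(seq_a: str, seq_b: str):
    """Map sequence positions (0-based) to alignment columns for both
    sequences of the best global alignment."""
    aln = _aligner().align(seq_a, seq_b)[0]
    col_a: Dict[int, int] = {}
    col_b: Dict[int, int] = {}
    col = 0
    # walk the aligned coordinate arrays segment by segment
    coords = aln.coordinates
    pa, pb = coords[0], coords[1]
    for seg in range(len(pa) - 1):
        la, lb = pa[seg + 1] - pa[seg], pb[seg + 1] - pb[seg]
        ln = max(la, lb)
        for k in range(ln):
            if k < la:
                col_a[pa[seg] + k] = col + k
            if k < lb:
                col_b[pb[seg] + k] = col + k
        col += ln
    return col_a, col_b


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

@dataclass
class PipelineEntry:
    """One candidate interface with everything the filters need."""
    id: str
    pair: ComplexPair
    interface: _ia.Interface
    bsa: float
    source: str = ""                  # structure instance identifier
    enzyme_flags: Dict[str, bool] = field(default_factory=dict)
    ddg_table: Dict[Tuple, float] = field(default_factory=dict)

    def __post_init__(self):
        if not self.source:
            self.source = self.id.split(":")[0]

    def chain_instance(self, chain_id: str) -> Tuple[str, str]:
        return (self.source, chain_id)


@dataclass
class FilterReport:
    input_count: int
    removed_missing_interface_atoms: List[str]
    removed_overlapping: List[str]
    removed_small_product: List[str]
    removed_low_bsa: List[str]
    surviving: List[str]

    def counts(self) -> Dict[str, int]:
        return {
            "input": self.input_count,
            "missing_interface_atoms": len(self.removed_missing_interface_atoms),
            "overlapping": len(self.removed_overlapping),
            "small_product": len(self.removed_small_product),
            "low_bsa": len(self.removed_low_bsa),
            "surviving": len(self.surviving),
        }

    def to_json(self) -> dict:
        d = self.counts()
        d["removed_missing_interface_atoms"] = self.removed_missing_interface_atoms
        d["removed_overlapping"] = self.removed_overlapping
        d["removed_small_product"] = self.removed_small_product
        d["removed_low_bsa"] = self.removed_low_bsa
        d["surviving_ids"] = self.surviving
        return d


def apply_filters(entries: Sequence[PipelineEntry],
                  config: Config = DEFAULT_CONFIG) -> FilterReport:
    """Apply the four dataset filters in their fixed order a→d."""
    # overlap relation computed over the whole input batch
    iface_keys: Dict[str, Dict[Tuple, Set[Tuple]]] = {}
    for e in entries:
        sides = {}
        for chain_id, residues in ((e.pair.chain_a_id, e.interface.residues_a),
                                   (e.pair.chain_b_id, e.interface.residues_b)):
            sides[e.chain_instance(chain_id)] = {r.key for r in residues}
        iface_keys[e.id] = sides
    overlapping_ids: Set[str] = set()
    for i, a in enumerate(entries):
        for b in entries[i + 1:]:
            for inst, keys_a in iface_keys[a.id].items():
                keys_b = iface_keys[b.id].get(inst)
                if keys_b and keys_a & keys_b:
                    overlapping_ids.add(a.id)
                    overlapping_ids.add(b.id)

    rep = FilterReport(input_count=len(entries),
                       removed_missing_interface_atoms=[],
                       removed_overlapping=[], removed_small_product=[],
                       removed_low_bsa=[], surviving=[])
    for e in entries:
        iface_res = list(e.interface.residues_a) + list(e.interface.residues_b)
        if any(not r.has_backbone for r in iface_res):
            rep.removed_missing_interface_atoms.append(e.id)
        elif e.id in overlapping_ids:
            rep.removed_overlapping.append(e.id)
        elif len(e.interface.residues_a) * len(e.interface.residues_b) \
                < config.min_residue_product:
            rep.removed_small_product.append(e.id)
        elif e.bsa < config.min_bsa:
            rep.removed_low_bsa.append(e.id)
        else:
            rep.surviving.append(e.id)
    return rep


# ---------------------------------------------------------------------------
# Redundancy clustering
# ---------------------------------------------------------------------------

@dataclass
class RedundancyItem:
    id: str
    seq_a: str
    seq_b: str
    iface_seq_a: str                 # interface one-letter string, sequence order
    iface_seq_b: str
    quality: Tuple                   # sortable quality score, larger is better


@dataclass
class RedundancyCluster:
    members: List[str]
    representative: str
    identity_level: float            # % cutoff used
    interface_similarity: float      # fraction cutoff used


def quality_score(pair: ComplexPair, completeness: Optional[float] = None) -> Tuple:
    """Monotone proxy for structure quality: X-ray over other methods, then
    −resolution, then backbone completeness."""
    if completeness is None:
        residues = list(pair.chain_a) + list(pair.chain_b)
        completeness = sum(r.has_backbone for r in residues) / len(residues)
    is_xray = 1 if "X-RAY" in pair.method.upper() else 0
    res_term = -(pair.resolution if pair.resolution is not None else 99.0)
    return (is_xray, res_term, completeness)


def _pair_identity(a: RedundancyItem, b: RedundancyItem) -> Tuple[float, bool]:
    """Best chain pairing identity: the worse chain of the better pairing,
    plus which pairing (False = A↔A/B↔B, True = swapped)."""
    direct = min(sequence_identity(a.seq_a, b.seq_a),
                 sequence_identity(a.seq_b, b.seq_b))
    crossed = min(sequence_identity(a.seq_a, b.seq_b),
                  sequence_identity(a.seq_b, b.seq_a))
    if crossed > direct:
        return crossed, True
    return direct, False


def cluster_redundancy(items: Sequence[RedundancyItem],
                       config: Config = DEFAULT_CONFIG) -> List[RedundancyCluster]:
    """Greedy quality-ordered clustering.

    Items are visited in descending quality (ties by id, so the outcome is
    invariant to input order).  An item joins the first cluster whose seed
    passes both tests — ≥ 95% identity on both chains under the best chain
    pairing, and ≥ 75% interface-sequence similarity on both sides — else
    it seeds a new cluster.  The seed (best quality) is the representative.
    """
    order = sorted(items, key=lambda it: it.id)          # tie-break: id ascending
    order = sorted(order, key=lambda it: it.quality, reverse=True)
    clusters: List[Dict] = []
    for it in order:
        placed = False
        for cl in clusters:
            seed: RedundancyItem = cl["seed"]
            ident, swapped = _pair_identity(it, seed)
            if ident < config.identity_cutoff:
                continue
            if swapped:
                sim = min(interface_similarity(it.iface_seq_a, seed.iface_seq_b),
                          interface_similarity(it.iface_seq_b, seed.iface_seq_a))
            else:
                sim = min(interface_similarity(it.iface_seq_a, seed.iface_seq_a),
                          interface_similarity(it.iface_seq_b, seed.iface_seq_b))
            if sim < config.interface_similarity_cutoff:
                continue
            cl["members"].append(it.id)
            placed = True
            break
        if not placed:
            clusters.append({"seed": it, "members": [it.id]})
    return [RedundancyCluster(members=cl["members"],
                              representative=cl["seed"].id,
                              identity_level=config.identity_cutoff,
                              interface_similarity=config.interface_similarity_cutoff)
            for cl in clusters]


# ---------------------------------------------------------------------------
# Interface typing
# ---------------------------------------------------------------------------

@dataclass
class InterfaceTypeLabel:
    label: str                       # one of the five classes
    identity_pct: Optional[float]
    symmetric_overlap: Optional[float]


def classify_interface_type(pair: ComplexPair, interface: _ia.Interface,
                            enzyme_flags: Optional[Dict[str, bool]] = None,
                            config: Config = DEFAULT_CONFIG) -> InterfaceTypeLabel:
    """Assign exactly one of: protein_peptide, enzyme_peptide, heteropair,
    identical_symmetric, identical_nonsymmetric.

    Peptidic: the shorter chain has ≤ 30 residues; the peptide's partner
    being flagged as an enzyme makes it enzyme_peptide.  Identical pairs
    (≥ 95% identity) are symmetric when the Jaccard overlap of interface
    positions, mapped through the chain alignment, is ≥ 0.7.
    """
    enzyme_flags = enzyme_flags or {}
    len_a, len_b = len(pair.chain_a), len(pair.chain_b)
    if min(len_a, len_b) <= config.peptide_length_cutoff:
        peptide_chain = pair.chain_a_id if len_a <= len_b else pair.chain_b_id
        partner = pair.chain_b_id if peptide_chain == pair.chain_a_id else pair.chain_a_id
        if partner not in enzyme_flags:
            warnings.warn(f"{pair.id}: no enzyme annotation for chain {partner}; "
                          "assuming protein_peptide")
        label = "enzyme_peptide" if enzyme_flags.get(partner) else "protein_peptide"
        return InterfaceTypeLabel(label=label, identity_pct=None, symmetric_overlap=None)

    seq_a, seq_b = pair.sequence(pair.chain_a_id), pair.sequence(pair.chain_b_id)
    ident = sequence_identity(seq_a, seq_b)
    if ident < config.identity_cutoff:
        return InterfaceTypeLabel(label="heteropair", identity_pct=ident,
                                  symmetric_overlap=None)
    col_a, col_b = _alignment_columns(seq_a, seq_b)
    idx_a = {r.key: i for i, r in enumerate(pair.chain_a)}
    idx_b = {r.key: i for i, r in enumerate(pair.chain_b)}
    set_a = {col_a[idx_a[r.key]] for r in interface.residues_a if idx_a[r.key] in col_a}
    set_b = {col_b[idx_b[r.key]] for r in interface.residues_b if idx_b[r.key] in col_b}
    union = set_a | set_b
    overlap = len(set_a & set_b) / len(union) if union else 0.0
    label = ("identical_symmetric" if overlap >= config.symmetry_overlap_cutoff
             else "identical_nonsymmetric")
    return InterfaceTypeLabel(label=label, identity_pct=ident,
                              symmetric_overlap=overlap)


# ---------------------------------------------------------------------------
# Full descriptor computation for one pair
# ---------------------------------------------------------------------------

def compute_record(pair: ComplexPair, config: Config = DEFAULT_CONFIG,
                   ddg_table: Optional[Dict[Tuple, float]] = None,
                   enzyme_flags: Optional[Dict[str, bool]] = None,
                   type_label: Optional[str] = None) -> InterfaceRecord:
    """Run every descriptor stage for one pair and assemble the record."""
    iface = _ia.detect_interface(pair, config.interface_cutoff)
    rec = InterfaceRecord(id=pair.id, chain_a=pair.chain_a_id,
                          chain_b=pair.chain_b_id, method=pair.method,
                          resolution=pair.resolution,
                          n_residues_a=len(pair.chain_a),
                          n_residues_b=len(pair.chain_b),
                          n_interface_a=len(iface.residues_a),
                          n_interface_b=len(iface.residues_b))
    if iface.is_empty():
        rec.segmentation = ""
        return rec
    rec.smaller_side = iface.smaller_chain

    seg_small = _ia.segment_interface(_ia.residue_positions(iface.smaller_residues),
                                      config.gap_threshold, iface.smaller_chain)
    seg_large = _ia.segment_interface(_ia.residue_positions(iface.larger_residues),
                                      config.gap_threshold, iface.larger_chain)
    rec.n_segments_smaller = len(seg_small)
    rec.n_segments_larger = len(seg_large)
    rec.segmentation = _ia.classify_segmentation(len(seg_small))

    try:
        rec.planarity = _sg.planarity(
            list(iface.residues_a) + list(iface.residues_b)).rmsd_from_plane
    except _sg.DegenerateGeometryError:
        rec.planarity = None

    acc = _sg.accessibility(pair, config)
    rec.bsa = acc.bsa

    ss = {}
    for chain in (pair.chain_a, pair.chain_b):
        ss.update(_ia.assign_secondary_structure(chain))

    annotations: List[_ia.InterfaceResidue] = []
    for side, residues in (("smaller", iface.smaller_residues),
                           ("larger", iface.larger_residues)):
        for res in residues:
            ir = _ia.InterfaceResidue(residue=res, side=side)
            ir.rsa_monomer = min(acc.rsa_monomer.get(res.key, 0.0), 150.0)
            ir.rsa_complex = min(acc.rsa_complex.get(res.key, 0.0), 150.0)
            cls = _sg.classify_accessibility(ir.rsa_monomer, ir.rsa_complex, config)
            ir.region = cls.region
            ir.solvent_inaccessible = cls.solvent_inaccessible
            ir.ss_class = ss.get(res.key, "loop")
            annotations.append(ir)

    smaller_ann = [ir for ir in annotations if ir.side == "smaller"]
    larger_ann = [ir for ir in annotations if ir.side == "larger"]

    # concavity: each side read against the partner side's grid
    grid_larger = _concavity.build_concavity_grid(
        pair.chain(iface.larger_chain), config.probe_radii, config.grid_spacing)
    grid_smaller = _concavity.build_concavity_grid(
        pair.chain(iface.smaller_chain), config.probe_radii, config.grid_spacing)
    _concavity.annotate_concavity(smaller_ann, grid_larger)
    _concavity.annotate_concavity(larger_ann, grid_smaller)
    conc = _concavity.interface_concavity(iface.smaller_residues, grid_larger)
    rec.mean_concavity = conc["mean"]
    rec.deepest_concavity = conc["deepest"]
    conc_l = _concavity.interface_concavity(iface.larger_residues, grid_smaller)
    rec.deepest_concavity_larger = conc_l["deepest"]

    enclosed = _concavity.find_enclosed_residues(annotations, config)
    rec.n_enclosed = len(enclosed)
    clusters = _concavity.cluster_enclosed(enclosed, config.dbscan_eps,
                                           config.dbscan_min_samples)
    rec.n_clusters = len(clusters)
    rec.clusters = [{"members": [list(k) for k in cl.members],
                     "centroid": [float(x) for x in cl.centroid],
                     "n_members": cl.n_members} for cl in clusters]

    if rec.bsa > 0:
        cc = _ia.count_contacts(pair, iface, rec.bsa, config)
        rec.contacts = dict(cc.counts)
        rec.contacts_per_100 = dict(cc.normalized)
        try:
            si = _sg.shape_indices(pair, iface, config, bsa=rec.bsa)
            rec.nsc, rec.nip = si.nsc, si.nip
            rec.shape_method_tag = si.method_tag
        except _sg.InsufficientSurfaceError:
            pass

    if ddg_table and rec.bsa > 0:
        n_hot, density = _ia.hotspot_density(annotations, ddg_table, rec.bsa,
                                             config.hotspot_ddg_threshold)
        rec.n_hotspots, rec.hotspot_density = n_hot, density

    n_small = len(smaller_ann)
    if n_small:
        for klass, attr in (("helix", "helix_fraction"), ("sheet", "sheet_fraction"),
                            ("loop", "loop_fraction")):
            setattr(rec, attr,
                    sum(ir.ss_class == klass for ir in smaller_ann) / n_small)
        rec.core_fraction = sum(ir.region == "core" for ir in smaller_ann) / n_small

    if type_label is None:
        type_label = classify_interface_type(pair, iface, enzyme_flags, config).label
    rec.type_label = type_label

    rec.residues = [{
        "chain": ir.residue.chain_id, "seq_num": ir.residue.seq_num,
        "icode": ir.residue.icode, "aa": ir.residue.aa, "side": ir.side,
        "region": ir.region, "ss_class": ir.ss_class,
        "rsa_monomer": ir.rsa_monomer, "rsa_complex": ir.rsa_complex,
        "deepest_concavity": (None if ir.deepest_concavity is None
                              else min(ir.deepest_concavity, config.probe_radii[-1])),
        "enclosed": ir.enclosed, "ddg": ir.ddg, "is_hotspot": ir.is_hotspot,
    } for ir in annotations]
    return rec


# ---------------------------------------------------------------------------
# Batch driver
# ---------------------------------------------------------------------------

def read_ddg_table(path) -> Dict[Tuple, float]:
    """CSV/TSV with columns chain, seq_num, icode, ddg_kcal_mol."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, dtype={"chain": str, "icode": str})
    out = {}
    for _, row in df.iterrows():
        icode = row.get("icode", "")
        icode = "" if pd.isna(icode) else str(icode).strip()
        out[(str(row["chain"]), int(row["seq_num"]), icode)] = float(row["ddg_kcal_mol"])
    return out


def run_pipeline(manifest_path, out_dir, config: Config = DEFAULT_CONFIG) -> Dict:
    """Batch run: manifest CSV of (structure path, chains, annotations) →
    descriptor table, filter report and cluster membership files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = pd.read_csv(manifest_path)
    entries: List[PipelineEntry] = []
    for _, row in manifest.iterrows():
        pair = read_complex(row["structure_path"], (str(row["chain_a"]), str(row["chain_b"])))
        iface = _ia.detect_interface(pair, config.interface_cutoff)
        bsa = _sg.accessibility(pair, config).bsa
        flags = {}
        for col, chain_key in (("enzyme_a", "chain_a"), ("enzyme_b", "chain_b")):
            if col in row and not pd.isna(row[col]):
                flags[str(row[chain_key])] = bool(int(row[col]))
        ddg = {}
        if "ddg_path" in row and isinstance(row["ddg_path"], str) and row["ddg_path"]:
            ddg = read_ddg_table(row["ddg_path"])
        entries.append(PipelineEntry(id=pair.id, pair=pair, interface=iface,
                                     bsa=bsa, source=str(row["structure_path"]),
                                     enzyme_flags=flags, ddg_table=ddg))
    logger.info("loaded %d pairs", len(entries))

    report = apply_filters(entries, config)
    logger.info("filter counts: %s", report.counts())
    surviving = [e for e in entries if e.id in set(report.surviving)]

    records = []
    for e in surviving:
        rec = compute_record(e.pair, config, ddg_table=e.ddg_table or None,
                             enzyme_flags=e.enzyme_flags)
        records.append(rec)
        logger.info("described %s: %s, BSA %.1f", rec.id, rec.segmentation, rec.bsa)

    items = []
    for e in surviving:
        def iface_seq(residues):
            return "".join(r.aa for r in sorted(residues,
                                                key=lambda r: (r.seq_num, r.icode)))
        items.append(RedundancyItem(
            id=e.id, seq_a=e.pair.sequence(e.pair.chain_a_id),
            seq_b=e.pair.sequence(e.pair.chain_b_id),
            iface_seq_a=iface_seq(e.interface.residues_a),
            iface_seq_b=iface_seq(e.interface.residues_b),
            quality=quality_score(e.pair)))
    clusters = cluster_redundancy(items, config)
    logger.info("%d redundancy clusters", len(clusters))

    df = pd.DataFrame([dict(zip(InterfaceRecord.csv_columns(), r.csv_row()))
                       for r in records])
    df.to_csv(out_dir / "descriptors.csv", index=False)
    with open(out_dir / "filter_report.json", "w") as fh:
        json.dump(report.to_json(), fh, indent=1)
    rows = []
    for i, cl in enumerate(clusters):
        for m in cl.members:
            rows.append({"cluster": i, "member": m,
                         "representative": cl.representative,
                         "is_representative": m == cl.representative})
    pd.DataFrame(rows).to_csv(out_dir / "clusters.csv", index=False)
    for rec in records:
        write_interface_record(rec, out_dir / f"record_{rec.id.replace(':', '_').replace('/', '_')}")
    return {"report": report, "records": records, "clusters": clusters}
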