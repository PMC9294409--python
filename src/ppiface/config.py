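"""Tunable parameters for the interface-characterization pipeline.

Every threshold used anywhere in the package lives here, with its unit and
default.  Defaults follow common structural-bioinformatics practice; see
docs/methods.md for the rationale behind each value.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Tuple

import yaml


def _default_probe_ladder() -> Tuple[float, ...]:
    """Multiscale probe-radius ladder: 0.5 to 10.0 Å in 0.5 Å steps."""
    return tuple(round(0.5 * i, 1) for i in range(1, 21))


@dataclass(frozen=True)
class Config:
    # --- interface detection ---------------------------------------------
    interface_cutoff: float = 5.0       # Å, heavy-atom distance defining interface residues

    # --- solvent accessibility -------------------------------------------
    probe_radius: float = 1.4           # Å, water probe for SASA
    sasa_points: int = 960              # sphere sample points per atom (deterministic)
    core_threshold: float = 25.0        # % RSA in complex below which a residue is interface core
    inaccessible_threshold: float = 7.0  # % RSA in complex below which a residue is solvent inaccessible
    # exposure classes: buried < inaccessible_threshold <= intermediate < core_threshold <= exposed

    # --- segmentation ------------------------------------------------------
    gap_threshold: int = 4              # max non-interacting residues bridged inside a segment

    # --- concavity grid ----------------------------------------------------
    grid_spacing: float = 0.8           # Å, voxel edge
    probe_radii: Tuple[float, ...] = field(default_factory=_default_probe_ladder)
    grid_padding_extra: float = 2.0     # Å added beyond the largest probe radius
    groove_band: Tuple[float, float] = (0.5, 2.0)  # Å, "groove magnitude" concavity band

    # --- enclosed residues / sub-pocket clustering --------------------------
    enclosed_concavity_max: float = 4.0  # Å, deepest-atom R_inaccess cutoff (<=)
    dbscan_eps: float = 8.0             # Å
    dbscan_min_samples: int = 3

    # --- hotspots ------------------------------------------------------------
    hotspot_ddg_threshold: float = 1.0  # kcal/mol, |ddG| strictly above -> hotspot

    # --- dataset filters ------------------------------------------------------
    min_residue_product: int = 25       # nA * nB below this -> removed
    min_bsa: float = 100.0              # Å², BSA below this -> removed

    # --- redundancy / typing ---------------------------------------------------
    identity_cutoff: float = 95.0       # % sequence identity for "identical" chains
    interface_similarity_cutoff: float = 0.75  # Ratcliff/Obershelp ratio
    peptide_length_cutoff: int = 30     # residues; shorter chain at or below -> peptidic interface
    symmetry_overlap_cutoff: float = 0.7  # Jaccard of aligned interface position sets

    # --- shape indices -----------------------------------------------------------
    sc_weight: float = 0.5              # Å^-2, Gaussian distance weight in the NSc score
    sc_sample_density: float = 2.0      # surface sample points per Å²
    nip_shell: float = 5.0              # Å, shell width for the interface-packing gap volume

    # --- statistics -----------------------------------------------------------------
    alpha: float = 0.05                 # significance level for Tukey reject flags

    def replace(self, **kwargs) -> "Config":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["probe_radii"] = list(self.probe_radii)
        d["groove_band"] = list(self.groove_band)
        return d

    @classmethod
    def from_yaml(cls, path) -> "Config":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("probe_radii", "groove_band"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


DEFAULT_CONFIG = Config()
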