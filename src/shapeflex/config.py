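"""Run configuration, van der Waals radii and deterministic seed derivation.

Defaults follow the method's published operating point: ensembles of 10
conformers, 2 alignment runs per conformer, 500 MMFF94 minimization cycles.
Everything is overridable from YAML or CLI flags (flag > YAML > default).
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from typing import Any, Mapping

import yaml

# Bondi vdW radii (Angstrom), extended with common heteroelements.
# Radii for elements absent from the table fall back to DEFAULT_VDW_RADIUS.
BONDI_VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "He": 1.40,
    "B": 1.92,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "Ne": 1.54,
    "Si": 2.10,
    "P": 1.80,
    "S": 1.80,
    "Cl": 1.75,
    "Ar": 1.88,
    "As": 1.85,
    "Se": 1.90,
    "Br": 1.85,
    "Te": 2.06,
    "I": 1.98,
}

DEFAULT_VDW_RADIUS = 1.75


def vdw_radius(element: str, radii: Mapping[str, float] | None = None) -> float:
    table = BONDI_VDW_RADII if radii is None else radii
    return float(table.get(element, DEFAULT_VDW_RADIUS))


@dataclass
class RunConfig:
    """All tunable parameters of the alignment pipeline.

    Units are Angstrom for distances and points/A^2 for density.
    """

    # surface cloud
    density: float = 10.0          # surface points per A^2
    min_cloud_size: int = 50       # reject clouds smaller than this
    vdw_radii: dict[str, float] = field(default_factory=lambda: dict(BONDI_VDW_RADII))

    # rigid registration
    match_radius: float = 0.7      # gfit/hfit correspondence radius
    icp_lambda: float = 0.5        # class-mismatch weight of colored ICP
    icp_max_iter: int = 40
    icp_corr_dist: float = 1.5     # ICP correspondence cutoff
    voxel_size: float = 0.8        # downsampling voxel for global registration
    fpfh_radius: float = 2.2       # FPFH neighborhood radius
    ransac_iterations: int = 1500
    hfit_exclude: str = "class1"   # "class1" (all apolar) or "nonpolar_h"

    # flexible alignment
    neighborhood_radius: float = 4.0   # target sub-cloud radius around a fragment
    max_fragment_translation: float = 3.0  # displacement cap (A)
    max_fragment_rotation_deg: float = 60.0
    min_fragment_heavy_atoms: int = 1
    minimize_cycles: int = 500
    flex_cycles: int = 3           # fragment-optimization sweeps per attempt
    restraint_k: float = 100.0     # kcal/mol/A^2, reassembly position restraints
    restraint_max_displacement: float = 0.3  # flat-bottom width (A)
    fragment_objective: str = "total"  # "total" (gfit+hfit) or "gfit"
    final_global_reregister: bool = False
    energy_window: float = 100.0   # accepted-pose MMFF94 energy window (kcal/mol)

    # ensembles / experiments
    n_conformers: int = 10
    runs: int = 2
    prune_rms: float = 1.0         # conformer pruning threshold (heavy atoms)
    seed: int = 0
    rmsd_scope: str = "heavy"      # "heavy" or "all"

    def replace(self, **kw: Any) -> "RunConfig":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(data))


def derive_seed(master: int, *labels: Any) -> int:
    """Deterministically derive a sub-seed below 2**31 from a master seed.

    Used to give every conformer/run/molecule its own independent stream
    while keeping the whole pipeline reproducible from one integer.
    """
    key = ":".join([str(int(master))] + [str(x) for x in labels])
    digest = hashlib.sha256(key.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)
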