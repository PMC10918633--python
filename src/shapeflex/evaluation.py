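"""Pose grading: symmetry-aware RMSD and self-/cross-alignment benchmarks.

Two RMSD flavors grade a predicted pose against a reference sharing its
frame:

* ``rmsd_in_place`` — atoms matched over all graph automorphisms (element
  and bond aware), coordinates left untouched; this is the score that
  matters for overlay reproduction, since superposing first would hide
  alignment errors.
* ``rmsd_best_fit`` — the same automorphism search but with a Kabsch
  superposition per matching; measures pure conformational difference.

The benchmark harness mirrors the standard protocol: generate a conformer
ensemble per reference, align it (rigidly or flexibly) onto the reference's
surface cloud, keep the best-scored pose, and report the in-place RMSD
distribution with the 0.5/1/2 A range fractions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem

from .chem import Molecule3D, generate_conformers
from .config import RunConfig, derive_seed
from .flex import ensemble_trials
from .registration import align_rigid, kabsch
from .surface import cloud_of

logger = logging.getLogger(__name__)

RMSD_RANGES = (0.5, 1.0, 2.0)  # A, pose-quality thresholds


@dataclass
class RmsdReport:
    value: float
    mode: str        # "in_place" | "best_fit_symmetry"
    atom_scope: str  # "heavy" | "all"

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("RMSD cannot be negative")


def _strip_hydrogens(mol: Molecule3D) -> Molecule3D:
    keep = [i for i, e in enumerate(mol.elements) if e != "H"]
    remap = {old: new for new, old in enumerate(keep)}
    bonds = [
        (remap[i], remap[j], order)
        for i, j, order in mol.bonds
        if i in remap and j in remap
    ]
    return Molecule3D(
        [mol.elements[i] for i in keep],
        [mol.charges[i] for i in keep],
        mol.coords[keep],
        bonds,
        name=mol.name,
    )


def _automorphism_matches(a: Molecule3D, b: Molecule3D, max_matches: int = 10000):
    """All element/bond-preserving atom maps of b onto a (RDKit matching)."""
    if sorted(a.elements) != sorted(b.elements):
        raise ValueError("molecules differ in formula; RMSD undefined")
    rd_a = a.to_rdkit()
    rd_b = b.to_rdkit()
    matches = rd_a.GetSubstructMatches(
        rd_b, uniquify=False, useChirality=False, maxMatches=max_matches
    )
    if not matches:
        raise ValueError("molecules are not graph-isomorphic; RMSD undefined")
    return matches  # match[i] = atom of `a` paired with atom i of `b`


def _scoped(a: Molecule3D, b: Molecule3D, scope: str) -> tuple[Molecule3D, Molecule3D]:
    if scope == "heavy":
        return _strip_hydrogens(a), _strip_hydrogens(b)
    if scope == "all":
        return a, b
    raise ValueError(f"unknown scope {scope!r}")


def rmsd_in_place(a: Molecule3D, b: Molecule3D, scope: str = "heavy") -> RmsdReport:
    """Minimum RMSD over graph automorphisms, coordinates fixed (no fit)."""
    sa, sb = _scoped(a, b, scope)
    best = np.inf
    pa = sa.coords
    pb = sb.coords
    for match in _automorphism_matches(sa, sb):
        d = pa[list(match)] - pb
        best = min(best, float(np.sqrt(np.mean(np.sum(d * d, axis=1)))))
    return RmsdReport(best, mode="in_place", atom_scope=scope)


def rmsd_best_fit(a: Molecule3D, b: Molecule3D, scope: str = "heavy") -> RmsdReport:
    """Minimum Kabsch-superposed RMSD over graph automorphisms."""
    sa, sb = _scoped(a, b, scope)
    best = np.inf
    pa = sa.coords
    pb = sb.coords
    for match in _automorphism_matches(sa, sb):
        q = pa[list(match)]
        T = kabsch(pb, q)
        d = T.apply(pb) - q
        best = min(best, float(np.sqrt(np.mean(np.sum(d * d, axis=1)))))
    return RmsdReport(best, mode="best_fit_symmetry", atom_scope=scope)


# ---- benchmark harness ----------------------------------------------


@dataclass
class BenchmarkTable:
    """Per-molecule results plus aggregate RMSD statistics."""

    per_molecule: pd.DataFrame
    settings: dict = field(default_factory=dict)
    n_excluded: int = 0

    @property
    def mean_rmsd(self) -> float:
        return float(self.per_molecule["rmsd"].mean())

    @property
    def fractions(self) -> dict[float, float]:
        col = self.per_molecule["rmsd"]
        out = {}
        for thr in RMSD_RANGES:
            out[thr] = float((col <= thr).mean()) if len(col) else 0.0
        return out

    def to_json_dict(self) -> dict:
        return {
            "mean_rmsd": self.mean_rmsd,
            "fractions": {str(k): v for k, v in self.fractions.items()},
            "n_molecules": int(len(self.per_molecule)),
            "n_excluded": self.n_excluded,
            "settings": self.settings,
        }


def _best_rigid_pose(
    ref_cloud, conformers, runs: int, seed: int, cfg: RunConfig
):
    best = None
    for k, conf in enumerate(conformers):
        for run in range(runs):
            trial_seed = derive_seed(seed, "trial", k, run)
            T, scores, posed = align_rigid(conf, ref_cloud, runs=1, seed=trial_seed, config=cfg)
            if best is None or scores.total > best[0]:
                best = (scores.total, scores, posed)
    return best


def self_alignment_experiment(
    fixtures: list[Molecule3D],
    n_conformers: int = 10,
    runs: int = 2,
    method: str = "rigid",
    seed: int = 0,
    config: RunConfig | None = None,
) -> BenchmarkTable:
    """Align generated ensembles onto each reference's own shape.

    For each reference: generate an ETKDG/MMFF ensemble, align every
    conformer x run onto the reference cloud, keep the best-scored pose and
    grade it by in-place RMSD against the reference. Failures are excluded
    from the aggregate and counted.
    """
    if method not in ("rigid", "flexible"):
        raise ValueError("method must be 'rigid' or 'flexible'")
    cfg = config or RunConfig()
    rows, excluded = [], 0
    for ref in fixtures:
        try:
            mol_seed = derive_seed(seed, "mol", ref.name)
            ensemble = generate_conformers(
                ref, n_conformers, prune_rms=cfg.prune_rms, seed=mol_seed
            )
            ref_cloud = cloud_of(ref, cfg)
            if method == "rigid":
                conformers = [ensemble.conformer(k) for k in range(len(ensemble))]
                _total, scores, pose = _best_rigid_pose(ref_cloud, conformers, runs, mol_seed, cfg)
            else:
                trials = ensemble_trials(ensemble, ref_cloud, runs=runs, config=cfg, seed=mol_seed)
                best = max(trials, key=lambda t: t[2].scores.total)
                scores, pose = best[2].scores, best[2].posed_molecule
            rmsd = rmsd_in_place(pose, ref, scope=cfg.rmsd_scope).value
            rows.append(
                {
                    "name": ref.name,
                    "rmsd": rmsd,
                    "gfit": scores.gfit,
                    "hfit": scores.hfit,
                    "total": scores.total,
                }
            )
        except Exception as exc:
            logger.warning("excluding %s: %s", ref.name, exc)
            excluded += 1
    return BenchmarkTable(
        per_molecule=pd.DataFrame(rows),
        settings={"n_conformers": n_conformers, "runs": runs, "method": method, "seed": seed},
        n_excluded=excluded,
    )


def self_alignment_paired(
    fixtures: list[Molecule3D],
    n_conformers: int = 10,
    runs: int = 2,
    seed: int = 0,
    config: RunConfig | None = None,
) -> tuple[BenchmarkTable, BenchmarkTable]:
    """Rigid and flexible benchmarks from one shared set of trials.

    Every flexible trial embeds its rigid baseline (same derived seed the
    rigid-only protocol would use), so both tables can be extracted from a
    single pass: the rigid table picks the best rigid-scored baseline pose,
    the flexible table the best flexible-scored result.
    """
    cfg = config or RunConfig()
    rows_r, rows_f, excluded = [], [], 0
    for ref in fixtures:
        try:
            mol_seed = derive_seed(seed, "mol", ref.name)
            ensemble = generate_conformers(
                ref, n_conformers, prune_rms=cfg.prune_rms, seed=mol_seed
            )
            ref_cloud = cloud_of(ref, cfg)
            trials = ensemble_trials(ensemble, ref_cloud, runs=runs, config=cfg, seed=mol_seed)
            best_f = max(trials, key=lambda t: t[2].scores.total)[2]
            best_r = max(trials, key=lambda t: t[2].rigid_baseline.total)[2]
            rows_f.append(
                {
                    "name": ref.name,
                    "rmsd": rmsd_in_place(best_f.posed_molecule, ref, scope=cfg.rmsd_scope).value,
                    "gfit": best_f.scores.gfit,
                    "hfit": best_f.scores.hfit,
                    "total": best_f.scores.total,
                    "accepted": best_f.accepted,
                }
            )
            rows_r.append(
                {
                    "name": ref.name,
                    "rmsd": rmsd_in_place(best_r.rigid_pose, ref, scope=cfg.rmsd_scope).value,
                    "gfit": best_r.rigid_baseline.gfit,
                    "hfit": best_r.rigid_baseline.hfit,
                    "total": best_r.rigid_baseline.total,
                }
            )
        except Exception as exc:
            logger.warning("excluding %s: %s", ref.name, exc)
            excluded += 1
    settings = {"n_conformers": n_conformers, "runs": runs, "seed": seed}
    return (
        BenchmarkTable(pd.DataFrame(rows_r), {**settings, "method": "rigid"}, excluded),
        BenchmarkTable(pd.DataFrame(rows_f), {**settings, "method": "flexible"}, excluded),
    )


def cross_alignment_experiment(
    overlay: list[Molecule3D],
    n_conformers: int = 10,
    runs: int = 2,
    method: str = "flexible",
    seed: int = 0,
    config: RunConfig | None = None,
) -> BenchmarkTable:
    """Align each ligand's conformers onto every partner ligand's shape.

    The references must share one coordinate frame (an overlay). For each
    ligand, the best-scored pose against each partner is computed, and the
    reported pose is the one with the lowest in-place RMSD to the ligand's
    own reference geometry — an evaluation-only selection that mirrors the
    best-predicted-ensemble protocol and deliberately peeks at the answer.
    The table also carries the mean over all ligand-pair alignments.
    """
    if len(overlay) < 2:
        raise ValueError("overlay needs at least two ligands")
    if method not in ("rigid", "flexible"):
        raise ValueError("method must be 'rigid' or 'flexible'")
    cfg = config or RunConfig()
    rows, pair_rmsds, excluded = [], [], 0
    for i, ref in enumerate(overlay):
        try:
            mol_seed = derive_seed(seed, "mol", i, ref.name)
            ensemble = generate_conformers(
                ref, n_conformers, prune_rms=cfg.prune_rms, seed=mol_seed
            )
            candidates = []
            for j, partner in enumerate(overlay):
                if j == i:
                    continue
                partner_cloud = cloud_of(partner, cfg)
                pair_seed = derive_seed(mol_seed, "partner", j)
                if method == "rigid":
                    conformers = [ensemble.conformer(k) for k in range(len(ensemble))]
                    _total, scores, pose = _best_rigid_pose(
                        partner_cloud, conformers, runs, pair_seed, cfg
                    )
                else:
                    trials = ensemble_trials(
                        ensemble, partner_cloud, runs=runs, config=cfg, seed=pair_seed
                    )
                    best = max(trials, key=lambda t: t[2].scores.total)[2]
                    scores, pose = best.scores, best.posed_molecule
                rmsd = rmsd_in_place(pose, ref, scope=cfg.rmsd_scope).value
                candidates.append((rmsd, j, scores, pose))
                pair_rmsds.append(rmsd)
            rmsd, j, scores, _pose = min(candidates, key=lambda c: (c[0], c[1]))
            rows.append(
                {
                    "name": ref.name,
                    "rmsd": rmsd,
                    "best_partner": overlay[j].name,
                    "gfit": scores.gfit,
                    "hfit": scores.hfit,
                    "total": scores.total,
                }
            )
        except Exception as exc:
            logger.warning("excluding %s: %s", ref.name, exc)
            excluded += 1
    table = BenchmarkTable(
        per_molecule=pd.DataFrame(rows),
        settings={
            "n_conformers": n_conformers,
            "runs": runs,
            "method": method,
            "seed": seed,
            "mean_pair_rmsd": float(np.mean(pair_rmsds)) if pair_rmsds else float("nan"),
        },
        n_excluded=excluded,
    )
    return table
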