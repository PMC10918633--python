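"""Colored point-cloud representation of the van der Waals surface.

A molecule's shape is the boundary of the union of atom-centered spheres
with element-specific vdW radii. We sample each sphere with a deterministic
Fibonacci lattice, drop points buried inside any other atom's sphere, and
label every surviving point with the pharmacophoric class of its nearest
atom:

    class 1 — apolar: nonpolar hydrogens and halogens except fluorine
    class 2 — polar, H-bond capable: N, O, S, F and H bonded to N/O
    class 3 — skeleton: C, P, B
    class 4 — everything else

The lattice is laid out in an atom-local frame built from bonded-neighbor
directions, so the cloud rotates rigidly with the molecule (no random seed
involved) and two poses of the same conformer yield point-for-point
corresponding clouds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .chem import Molecule3D
from .config import RunConfig, vdw_radius

CLASS_APOLAR = 1
CLASS_POLAR = 2
CLASS_SKELETON = 3
CLASS_OTHER = 4

_HALOGENS_CLASS1 = {"Cl", "Br", "I", "At"}
_POLAR_ELEMENTS = {"N", "O", "S", "F"}
_SKELETON_ELEMENTS = {"C", "P", "B"}

_BURIAL_TOL = 1e-6  # strict-interiority tolerance (Angstrom)


class EmptyCloudError(RuntimeError):
    """Surface sampling produced no exposed points."""


@dataclass
class AtomClassAssignment:
    """Per-atom pharmacophoric class labels in {1, 2, 3, 4}."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if not np.all(np.isin(self.labels, [1, 2, 3, 4])):
            raise ValueError("class labels must be in {1,2,3,4}")


@dataclass
class ColoredPointCloud:
    """Points on the exposed union-of-spheres surface with class labels.

    `normals` (outward sphere normals) and `owner_element` are filled in by
    the sampler; clouds constructed by hand in tests may leave them None,
    in which case registration estimates normals on the fly.
    """

    points: np.ndarray          # (N, 3) Angstrom
    class_label: np.ndarray     # (N,) in {1,2,3,4}
    owner_atom: np.ndarray      # (N,) index of the generating/nearest atom
    density: float              # points per A^2 used at generation
    normals: np.ndarray | None = None
    owner_element: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.class_label = np.asarray(self.class_label, dtype=int)
        self.owner_atom = np.asarray(self.owner_atom, dtype=int)
        n = len(self.points)
        if len(self.class_label) != n or len(self.owner_atom) != n:
            raise ValueError("label/owner arrays must match point count")
        if self.normals is not None:
            self.normals = np.asarray(self.normals, dtype=float).reshape(-1, 3)
            if len(self.normals) != n:
                raise ValueError("normals must match point count")
        if self.owner_element is not None:
            self.owner_element = np.asarray(self.owner_element, dtype=object)

    def __len__(self) -> int:
        return len(self.points)

    def transformed(self, matrix: np.ndarray) -> "ColoredPointCloud":
        pts = self.points @ matrix[:3, :3].T + matrix[:3, 3]
        normals = None if self.normals is None else self.normals @ matrix[:3, :3].T
        return ColoredPointCloud(
            pts, self.class_label.copy(), self.owner_atom.copy(), self.density,
            normals=normals, owner_element=self.owner_element,
        )

    def subset(self, mask: np.ndarray) -> "ColoredPointCloud":
        return ColoredPointCloud(
            self.points[mask], self.class_label[mask], self.owner_atom[mask], self.density,
            normals=None if self.normals is None else self.normals[mask],
            owner_element=None if self.owner_element is None else self.owner_element[mask],
        )

    def save_xyz(self, path: str) -> None:
        with open(path, "w") as fh:
            for p, c, o in zip(self.points, self.class_label, self.owner_atom):
                fh.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f} {c} {o}\n")

    @classmethod
    def load_xyz(cls, path: str, density: float = 0.0) -> "ColoredPointCloud":
        data = np.loadtxt(path, ndmin=2)
        return cls(data[:, :3], data[:, 3].astype(int), data[:, 4].astype(int), density)


def assign_pharmacophore_classes(mol: Molecule3D) -> AtomClassAssignment:
    """Label each atom with its pharmacophoric class.

    Hydrogens are polar (class 2) when bonded to N or O, otherwise apolar
    (class 1); fluorine counts as polar while Cl/Br/I are apolar.
    """
    labels = np.empty(mol.n_atoms, dtype=int)
    for i, el in enumerate(mol.elements):
        if el == "H":
            nbr_elements = {mol.elements[j] for j in mol.neighbors(i)}
            labels[i] = CLASS_POLAR if nbr_elements & {"N", "O"} else CLASS_APOLAR
        elif el in _HALOGENS_CLASS1:
            labels[i] = CLASS_APOLAR
        elif el in _POLAR_ELEMENTS:
            labels[i] = CLASS_POLAR
        elif el in _SKELETON_ELEMENTS:
            labels[i] = CLASS_SKELETON
        else:
            labels[i] = CLASS_OTHER
    return AtomClassAssignment(labels)


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors (golden-spiral lattice)."""
    k = np.arange(n, dtype=float)
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * k + 1.0) / n
    theta = 2.0 * np.pi * k / golden
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _atom_local_frame(mol: Molecule3D, i: int) -> np.ndarray:
    """Rotation matrix (columns = axes) tied to the atom's bonded environment.

    Built from directions to bonded neighbors so it co-rotates with the
    molecule. Falls back to the lab frame for isolated/degenerate atoms.
    """
    nbrs = mol.neighbors(i)
    vecs: list[np.ndarray] = []
    for j in nbrs:
        v = mol.coords[j] - mol.coords[i]
        nv = np.linalg.norm(v)
        if nv > 1e-8:
            vecs.append(v / nv)
    if len(vecs) == 1 and nbrs:
        # terminal atom: borrow a second direction from the neighbor's own
        # neighbors to pin the azimuth
        j = nbrs[0]
        for k in mol.neighbors(j):
            if k == i:
                continue
            w = mol.coords[k] - mol.coords[j]
            nw = np.linalg.norm(w)
            if nw > 1e-8:
                vecs.append(w / nw)
                break
    if not vecs:
        return np.eye(3)
    z = vecs[0]
    x = None
    for w in vecs[1:]:
        cand = w - np.dot(w, z) * z
        if np.linalg.norm(cand) > 1e-6:
            x = cand / np.linalg.norm(cand)
            break
    if x is None:
        # collinear environment: any orthonormal completion (lab-axis seeded)
        ref = np.array([1.0, 0.0, 0.0]) if abs(z[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        x = ref - np.dot(ref, z) * z
        x /= np.linalg.norm(x)
    y = np.cross(z, x)
    return np.column_stack([x, y, z])


def sample_vdw_surface(mol: Molecule3D, density: float, radii=None) -> ColoredPointCloud:
    """Sample the exposed union-of-spheres surface at `density` points/A^2.

    Every returned point lies exactly on its owner atom's vdW sphere and is
    not strictly inside any other atom's sphere.
    """
    if density <= 0:
        raise ValueError("density must be positive")
    if mol.n_atoms == 0:
        raise ValueError("empty molecule")
    classes = assign_pharmacophore_classes(mol).labels
    r_atom = np.array([vdw_radius(e, radii) for e in mol.elements])

    points: list[np.ndarray] = []
    owners: list[np.ndarray] = []
    normals: list[np.ndarray] = []
    centers = mol.coords
    tree = cKDTree(centers)
    r_max = float(r_atom.max())
    for i in range(mol.n_atoms):
        r = r_atom[i]
        n_pts = max(int(round(density * 4.0 * np.pi * r * r)), 1)
        frame = _atom_local_frame(mol, i)
        local = _fibonacci_sphere(n_pts) @ frame.T
        pts = centers[i] + r * local
        # buried-point test against all atoms whose sphere could reach
        nearby = tree.query_ball_point(centers[i], r + r_max + 1e-9)
        keep = np.ones(len(pts), dtype=bool)
        for j in nearby:
            if j == i:
                continue
            d = np.linalg.norm(pts - centers[j], axis=1)
            if j < i:
                # boundary points survive only on the lower-indexed sphere so
                # exactly superimposed atoms contribute one surface, not two
                keep &= d >= r_atom[j] + _BURIAL_TOL
            else:
                keep &= d >= r_atom[j] - _BURIAL_TOL
        if keep.any():
            points.append(pts[keep])
            owners.append(np.full(int(keep.sum()), i, dtype=int))
            normals.append(local[keep])

    if not points:
        raise EmptyCloudError(f"no exposed surface points for '{mol.name}'")
    pts = np.vstack(points)
    own = np.concatenate(owners)
    elements = np.asarray(mol.elements, dtype=object)
    return ColoredPointCloud(
        pts, classes[own], own, density,
        normals=np.vstack(normals), owner_element=elements[own],
    )


def cloud_of(mol: Molecule3D, config: RunConfig | None = None) -> ColoredPointCloud:
    """Full colored surface cloud of a molecule under a run configuration."""
    cfg = config or RunConfig()
    cloud = sample_vdw_surface(mol, cfg.density, radii=cfg.vdw_radii)
    if len(cloud) < cfg.min_cloud_size:
        raise EmptyCloudError(
            f"cloud of '{mol.name}' has {len(cloud)} points "
            f"(< min_cloud_size={cfg.min_cloud_size}); raise the density"
        )
    return cloud
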