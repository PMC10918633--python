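"""Rigid registration of colored surface clouds and fitness scoring.

Three stages mirror the rigid alignment workflow:

1. ``global_register`` — coarse, pose-free alignment: FPFH descriptors are
   computed on voxel-downsampled clouds, matched in feature space, and a
   seeded RANSAC over 3-point correspondence samples recovers a rigid
   transform, polished by a short geometric ICP.
2. ``refine_colored`` — class-aware ICP: correspondences are chosen among
   nearest neighbors by a cost blending squared distance and pharmacophore
   class mismatch, and mismatched pairs are down-weighted in the update.
3. ``compute_fitness`` — Tversky-style source-coverage scores: *gfit* is the
   fraction of source points with a target point within the match radius
   (1.0 when the source shape is perfectly embedded in the target), *hfit*
   the fraction of non-apolar source points whose matched target point
   carries the same class.

The target cloud is always kept fixed; transforms move the source.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .chem import Molecule3D
from .config import RunConfig, derive_seed
from .surface import CLASS_APOLAR, ColoredPointCloud, cloud_of

logger = logging.getLogger(__name__)


class RegistrationError(RuntimeError):
    """Registration could not be performed (degenerate or undersized cloud)."""


@dataclass
class RigidTransform:
    """Proper rigid motion as a 4x4 homogeneous matrix (rotation + translation)."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValueError("expected a 4x4 matrix")
        R = m[:3, :3]
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("rotation block is not orthogonal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise ValueError("rotation block is not proper (det != +1)")
        if not np.allclose(m[3], [0.0, 0.0, 0.0, 1.0]):
            raise ValueError("last row must be [0,0,0,1]")
        self.matrix = m

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(4))

    @classmethod
    def from_rotation_translation(cls, R: np.ndarray, t: np.ndarray) -> "RigidTransform":
        m = np.eye(4)
        m[:3, :3] = R
        m[:3, 3] = np.asarray(t, dtype=float)
        return cls(m)

    @property
    def rotation(self) -> np.ndarray:
        return self.matrix[:3, :3]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:3, 3]

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply `other` first, then `self`."""
        return RigidTransform(self.matrix @ other.matrix)

    def inverse(self) -> "RigidTransform":
        R = self.rotation.T
        return RigidTransform.from_rotation_translation(R, -R @ self.translation)

    def rotation_angle_deg(self) -> float:
        return float(np.degrees(np.linalg.norm(Rotation.from_matrix(self.rotation).as_rotvec())))


@dataclass
class FitnessScores:
    """Source-coverage shape score (gfit) and class-match score (hfit)."""

    gfit: float
    hfit: float

    def __post_init__(self) -> None:
        self.gfit = float(min(max(self.gfit, 0.0), 1.0))
        self.hfit = float(min(max(self.hfit, 0.0), 1.0))

    @property
    def total(self) -> float:
        return self.gfit + self.hfit


def kabsch(P: np.ndarray, Q: np.ndarray, weights: np.ndarray | None = None) -> RigidTransform:
    """Weighted least-squares rigid transform mapping points P onto Q."""
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    w = np.ones(len(P)) if weights is None else np.asarray(weights, dtype=float)
    w = w / w.sum()
    cp = w @ P
    cq = w @ Q
    H = (P - cp).T @ ((Q - cq) * w[:, None])
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    # re-orthonormalize defensively against accumulated rounding
    Ru, _, Rvt = np.linalg.svd(R)
    R = Ru @ Rvt
    if np.linalg.det(R) < 0:
        Ru[:, -1] *= -1
        R = Ru @ Rvt
    t = cq - R @ cp
    return RigidTransform.from_rotation_translation(R, t)


# ---- FPFH features ---------------------------------------------------


def estimate_normals(points: np.ndarray, k: int = 12) -> np.ndarray:
    """PCA surface normals (arbitrary but consistent orientation: outward
    from the cloud centroid)."""
    pts = np.asarray(points, dtype=float)
    tree = cKDTree(pts)
    _, idx = tree.query(pts, k=min(k, len(pts)))
    normals = np.empty_like(pts)
    centroid = pts.mean(axis=0)
    for i in range(len(pts)):
        nb = pts[idx[i]] - pts[idx[i]].mean(axis=0)
        _, _, vt = np.linalg.svd(nb, full_matrices=False)
        n = vt[-1]
        if np.dot(n, pts[i] - centroid) < 0:
            n = -n
        normals[i] = n
    return normals


def fpfh_features(points: np.ndarray, normals: np.ndarray, radius: float, n_bins: int = 11) -> np.ndarray:
    """Fast Point Feature Histograms (33-d) of an oriented point set."""
    pts = np.asarray(points, dtype=float)
    nrm = np.asarray(normals, dtype=float)
    n = len(pts)
    tree = cKDTree(pts)
    pairs = tree.query_pairs(radius, output_type="ndarray")
    if len(pairs) == 0:
        return np.zeros((n, 3 * n_bins))
    # evaluate both directions of every pair
    src = np.concatenate([pairs[:, 0], pairs[:, 1]])
    dst = np.concatenate([pairs[:, 1], pairs[:, 0]])
    d = pts[dst] - pts[src]
    dist = np.linalg.norm(d, axis=1)
    good = dist > 1e-12
    src, dst, d, dist = src[good], dst[good], d[good], dist[good]
    dn = d / dist[:, None]

    u = nrm[src]
    v = np.cross(dn, u)
    vn = np.linalg.norm(v, axis=1)
    ok = vn > 1e-8
    v[ok] /= vn[ok][:, None]
    v[~ok] = 0.0
    w = np.cross(u, v)
    nt = nrm[dst]
    alpha = np.einsum("ij,ij->i", v, nt)
    phi = np.einsum("ij,ij->i", u, dn)
    theta = np.arctan2(np.einsum("ij,ij->i", w, nt), np.einsum("ij,ij->i", u, nt))

    def binned(x, lo, hi):
        b = np.floor((x - lo) / (hi - lo) * n_bins).astype(int)
        return np.clip(b, 0, n_bins - 1)

    ba = binned(alpha, -1.0, 1.0)
    bp = binned(phi, -1.0, 1.0)
    bt = binned(theta, -np.pi, np.pi)

    spfh = np.zeros((n, 3 * n_bins))
    np.add.at(spfh, (src, ba), 1.0)
    np.add.at(spfh, (src, n_bins + bp), 1.0)
    np.add.at(spfh, (src, 2 * n_bins + bt), 1.0)
    counts = np.zeros(n)
    np.add.at(counts, src, 1.0)
    norm = np.maximum(counts, 1.0)
    spfh /= norm[:, None]

    # weighted neighbor pooling: FPFH_i = SPFH_i + mean_j SPFH_j / d_ij
    fpfh = spfh.copy()
    wgt = 1.0 / np.maximum(dist, 1e-6)
    pooled = np.zeros_like(spfh)
    wsum = np.zeros(n)
    np.add.at(pooled, src, spfh[dst] * wgt[:, None])
    np.add.at(wsum, src, wgt)
    have = wsum > 0
    fpfh[have] += pooled[have] / wsum[have][:, None]
    return fpfh


def voxel_downsample(cloud: ColoredPointCloud, voxel: float) -> ColoredPointCloud:
    """Keep one representative point per occupied voxel (deterministic)."""
    keys = np.floor(cloud.points / voxel).astype(np.int64)
    _, first = np.unique(keys, axis=0, return_index=True)
    mask = np.zeros(len(cloud), dtype=bool)
    mask[np.sort(first)] = True
    return cloud.subset(mask)


def _cloud_normals(cloud: ColoredPointCloud) -> np.ndarray:
    if cloud.normals is not None:
        return cloud.normals
    return estimate_normals(cloud.points)


# ---- global registration --------------------------------------------


def global_register(
    source: ColoredPointCloud,
    target: ColoredPointCloud,
    seed: int = 0,
    config: RunConfig | None = None,
) -> RigidTransform:
    """Coarse pose-free alignment via FPFH matching + seeded RANSAC.

    Deterministic for a fixed seed. Raises ``RegistrationError`` when either
    cloud is below the configured minimum size.
    """
    cfg = config or RunConfig()
    if len(source) < cfg.min_cloud_size or len(target) < cfg.min_cloud_size:
        raise RegistrationError(
            f"cloud too small for registration "
            f"({len(source)}/{len(target)} < {cfg.min_cloud_size} points)"
        )
    rng = np.random.default_rng(int(seed) % (2**31 - 1))

    ds_s = voxel_downsample(source, cfg.voxel_size)
    ds_t = voxel_downsample(target, cfg.voxel_size)
    fs = fpfh_features(ds_s.points, _cloud_normals(ds_s), cfg.fpfh_radius)
    ft = fpfh_features(ds_t.points, _cloud_normals(ds_t), cfg.fpfh_radius)

    # mutual nearest neighbors in feature space
    t_tree = cKDTree(ft)
    s_tree = cKDTree(fs)
    _, s2t = t_tree.query(fs)
    _, t2s = s_tree.query(ft)
    mutual = t2s[s2t] == np.arange(len(fs))
    s_idx = np.nonzero(mutual)[0]
    t_idx = s2t[s_idx]
    if len(s_idx) < 10:  # fall back to one-way matches on tiny overlap
        s_idx = np.arange(len(fs))
        t_idx = s2t

    ps = ds_s.points[s_idx]
    pt = ds_t.points[t_idx]
    n_corr = len(ps)

    n_iter = int(cfg.ransac_iterations)
    triples = rng.integers(0, n_corr, size=(n_iter, 3))
    ok = (
        (triples[:, 0] != triples[:, 1])
        & (triples[:, 0] != triples[:, 2])
        & (triples[:, 1] != triples[:, 2])
    )
    triples = triples[ok]
    # edge-length compatibility prefilter
    a, b, c = triples[:, 0], triples[:, 1], triples[:, 2]
    edge_tol = max(0.9 * cfg.voxel_size, 0.3)

    def _edges(p):
        return np.stack(
            [
                np.linalg.norm(p[a] - p[b], axis=1),
                np.linalg.norm(p[b] - p[c], axis=1),
                np.linalg.norm(p[a] - p[c], axis=1),
            ],
            axis=1,
        )

    es, et = _edges(ps), _edges(pt)
    compat = np.all(np.abs(es - et) < edge_tol, axis=1) & np.all(es > 1e-6, axis=1)
    triples = triples[compat]

    inlier_thresh = 1.5 * cfg.voxel_size
    best_T: RigidTransform | None = None
    best_inliers = -1
    for tri in triples:
        try:
            T = kabsch(ps[tri], pt[tri])
        except np.linalg.LinAlgError:  # pragma: no cover - degenerate triple
            continue
        resid = np.linalg.norm(T.apply(ps) - pt, axis=1)
        n_in = int(np.sum(resid < inlier_thresh))
        if n_in > best_inliers:
            best_inliers = n_in
            best_T = T

    if best_T is None or best_inliers < 3:
        # degenerate feature matching: fall back to centroid alignment
        logger.warning("RANSAC found no consensus; falling back to centroid shift")
        t = target.points.mean(axis=0) - source.points.mean(axis=0)
        return RigidTransform.from_rotation_translation(np.eye(3), t)

    # consensus re-fit, then short geometric ICP polish on downsampled clouds
    for _ in range(3):
        resid = np.linalg.norm(best_T.apply(ps) - pt, axis=1)
        inl = resid < inlier_thresh
        if inl.sum() >= 3:
            best_T = kabsch(ps[inl], pt[inl])
    best_T = _icp_geometric(ds_s.points, ds_t.points, best_T, max_iter=20, corr_dist=2.0 * cfg.voxel_size)
    return best_T


def _icp_geometric(
    src_pts: np.ndarray, tgt_pts: np.ndarray, init: RigidTransform, max_iter: int, corr_dist: float
) -> RigidTransform:
    tree = cKDTree(tgt_pts)
    T = init
    prev = np.inf
    for _ in range(max_iter):
        moved = T.apply(src_pts)
        dist, idx = tree.query(moved, distance_upper_bound=corr_dist)
        valid = np.isfinite(dist)
        if valid.sum() < 3:
            break
        T = kabsch(src_pts[valid], tgt_pts[idx[valid]])
        mean_res = float(dist[valid].mean())
        if abs(prev - mean_res) < 1e-9:
            break
        prev = mean_res
    return T


# ---- colored refinement ---------------------------------------------


def refine_colored(
    source: ColoredPointCloud,
    target: ColoredPointCloud,
    init: RigidTransform,
    config: RunConfig | None = None,
) -> RigidTransform:
    """Class-aware ICP refinement starting from ``init``.

    Correspondence cost is ``d^2 + lambda * s^2 * [class differs]`` over the
    k nearest target neighbors (s = 1 A), and class-mismatched pairs enter
    the Kabsch update with weight ``1 - lambda``. The returned transform is
    whichever of {init, refined} scores the higher fitness total, so
    refinement never degrades the alignment.
    """
    cfg = config or RunConfig()
    lam = float(cfg.icp_lambda)
    tree = cKDTree(target.points)
    k = min(6, len(target))
    penalty = lam * 1.0  # A^2 added to squared distance on class mismatch

    T = init
    prev_res = np.inf
    matched_any = False
    for it in range(cfg.icp_max_iter):
        moved = T.apply(source.points)
        dist, idx = tree.query(moved, k=k, distance_upper_bound=cfg.icp_corr_dist)
        if k == 1:
            dist, idx = dist[:, None], idx[:, None]
        finite = np.isfinite(dist)
        idx_safe = np.where(finite, idx, 0)
        mismatch = target.class_label[idx_safe] != source.class_label[:, None]
        cost = np.where(finite, dist**2 + penalty * mismatch, np.inf)
        choice = np.argmin(cost, axis=1)
        rows = np.arange(len(moved))
        chosen_ok = finite[rows, choice]
        if chosen_ok.sum() < 3:
            if not matched_any:
                logger.warning("no correspondences within %.2f A; keeping init", cfg.icp_corr_dist)
                return init
            break
        matched_any = True
        src_sel = source.points[chosen_ok]
        tgt_sel = target.points[idx_safe[rows, choice][chosen_ok]]
        w = np.where(mismatch[rows, choice][chosen_ok], max(1.0 - lam, 0.05), 1.0)
        T = kabsch(src_sel, tgt_sel, weights=w)
        res = float(np.mean(np.linalg.norm(T.apply(src_sel) - tgt_sel, axis=1)))
        if abs(prev_res - res) < 1e-10:
            break
        prev_res = res

    # never return something worse than the starting pose
    f_init = compute_fitness(source, target, init, cfg.match_radius, config=cfg)
    f_ref = compute_fitness(source, target, T, cfg.match_radius, config=cfg)
    return T if f_ref.total >= f_init.total else init


# ---- fitness ---------------------------------------------------------


def compute_fitness(
    source: ColoredPointCloud,
    target: ColoredPointCloud,
    T: RigidTransform,
    match_radius: float | None = None,
    config: RunConfig | None = None,
) -> FitnessScores:
    """Tversky (alpha = 0) source-coverage scores of `T(source)` vs `target`.

    gfit: fraction of source points with a target point within match_radius.
    hfit: fraction of class-matched points among matched source points,
    computed over source points outside the apolar class (configurable to
    exclude only nonpolar hydrogens instead).
    """
    if len(source) == 0:
        raise ValueError("empty source cloud")
    cfg = config or RunConfig()
    radius = cfg.match_radius if match_radius is None else float(match_radius)
    if radius <= 0:
        raise ValueError("match_radius must be positive")

    moved = T.apply(source.points)
    tree = cKDTree(target.points)
    dist, idx = tree.query(moved, distance_upper_bound=radius)
    matched = np.isfinite(dist)
    gfit = float(matched.sum()) / float(len(source))

    if cfg.hfit_exclude == "nonpolar_h" and source.owner_element is not None:
        scope = ~((source.class_label == CLASS_APOLAR) & (source.owner_element == "H"))
    else:
        scope = source.class_label != CLASS_APOLAR
    denom = int(scope.sum())
    if denom == 0:
        hfit = 0.0
    else:
        ok = matched & scope
        idx_safe = np.where(matched, idx, 0)
        same = target.class_label[idx_safe] == source.class_label
        hfit = float(np.sum(ok & same)) / float(denom)
    return FitnessScores(gfit=gfit, hfit=hfit)


# ---- full rigid pipeline --------------------------------------------


def align_rigid(
    source_mol: Molecule3D,
    target_cloud: ColoredPointCloud,
    runs: int = 1,
    seed: int = 0,
    config: RunConfig | None = None,
) -> tuple[RigidTransform, FitnessScores, Molecule3D]:
    """Rigidly align a molecule onto a fixed target cloud.

    The cloud→global→colored-refine→score pipeline is executed `runs` times
    with independently derived seeds and the best total score is kept (ties
    broken by the lower run index). Returns the winning transform, its
    scores, and the posed molecule.
    """
    if runs < 1:
        raise ValueError("runs must be >= 1")
    cfg = config or RunConfig()
    source_cloud = cloud_of(source_mol, cfg)
    best: tuple[RigidTransform, FitnessScores] | None = None
    for run in range(runs):
        run_seed = derive_seed(seed, "rigid", run)
        T0 = global_register(source_cloud, target_cloud, seed=run_seed, config=cfg)
        T = refine_colored(source_cloud, target_cloud, T0, config=cfg)
        scores = compute_fitness(source_cloud, target_cloud, T, cfg.match_radius, config=cfg)
        if best is None or scores.total > best[1].total:
            best = (T, scores)
    T, scores = best
    posed = source_mol.with_coords(T.apply(source_mol.coords))
    return T, scores, posed
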