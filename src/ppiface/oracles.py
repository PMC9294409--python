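"""Independent brute-force oracles for dual-route validation.

These deliberately share no code with the implementation paths they check:
probe placement enumerates candidate centres directly against atom
distances, DBSCAN is re-derived from density reachability by breadth-first
expansion, and segmentation is re-derived by expanding position runs.
They are slow by design and only meant for small fixtures.
"""
from __future__ import annotations

import math
from typing import List, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree


def brute_force_rinaccess(centers: np.ndarray, radii: np.ndarray,
                          query_points: np.ndarray,
                          probe_radii: Sequence[float],
                          candidate_spacing: float,
                          legality_slack: float = 0.0) -> np.ndarray:
    """Direct probe-placement R_inaccess at each query point.

    Candidate probe centres are enumerated on a fine cubic grid; a centre is
    legal at radius ρ iff no atom centre lies within r_atom + ρ of it, and a
    point is accessible at ρ iff some legal centre lies within ρ.  The
    returned value is the smallest ladder radius at which the point is NOT
    accessible (∞ if accessible at every ladder radius).  Points inside the
    vdW union return NaN.

    ``legality_slack`` relaxes the legality test to d >= ρ − slack; running
    the oracle with slack 0 and with slack ≈ half the candidate spacing
    brackets the continuous answer from below and above (a legal continuous
    centre inside a candidate cell passes the slackened test because the
    distance field is 1-Lipschitz).
    """
    centers = np.asarray(centers, float)
    radii = np.asarray(radii, float)
    query_points = np.asarray(query_points, float)
    ladder = sorted(probe_radii)
    pad = ladder[-1] + 2.0
    lo = centers.min(axis=0) - radii.max() - pad
    hi = centers.max(axis=0) + radii.max() + pad
    axes = [np.arange(lo[k], hi[k] + candidate_spacing, candidate_spacing)
            for k in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    cand = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    # distance from every candidate centre to the nearest atom surface
    d = np.full(len(cand), np.inf)
    for c, r in zip(centers, radii):
        d = np.minimum(d, np.linalg.norm(cand - c, axis=1) - r)
    dq = np.full(len(query_points), np.inf)
    for c, r in zip(centers, radii):
        dq = np.minimum(dq, np.linalg.norm(query_points - c, axis=1) - r)

    out = np.full(len(query_points), np.inf)
    inside = dq <= 0.0
    out[inside] = np.nan
    undecided = ~inside
    for rho in ladder:
        legal = cand[d >= rho - legality_slack]
        if len(legal) == 0:
            out[undecided] = rho
            break
        tree = cKDTree(legal)
        near, _ = tree.query(query_points[undecided])
        blocked = near > rho
        idx = np.flatnonzero(undecided)[blocked]
        out[idx] = rho
        undecided = undecided.copy()
        undecided[idx] = False
        if not undecided.any():
            break
    return out


def rinaccess_oracle_disagreements(grid, centers, radii,
                                   probe_radii: Sequence[float],
                                   candidate_spacing: float = 0.2,
                                   band: Tuple[float, float] = (0.4, 3.0),
                                   stride: int = 5) -> Tuple[int, int]:
    """Compare a concavity grid against the brute-force probe oracle.

    Voxels in the surface-adjacent band (d_mol within ``band``, skipping the
    sub-voxel rasterization skin) are compared at every ``stride``-th point.
    A voxel agrees when its ladder-step index is within ±1 of either oracle
    bound (strict legality, and legality slackened by half the candidate
    spacing — the two bracket the continuous answer), or when any voxel in
    its 3³ neighbourhood is (±1 voxel boundary discrepancy).
    Returns (n_disagreeing, n_compared).
    """
    ladder = np.array(sorted(probe_radii))

    def step_idx(v):
        v = np.where(np.isinf(v), ladder[-1] + 0.5, v)
        return np.searchsorted(ladder, v - 1e-9)

    shape = grid.shape
    ax = [grid.origin[k] + np.arange(shape[k]) * grid.spacing for k in range(3)]
    gx, gy, gz = np.meshgrid(*ax, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    d = np.full(len(pts), np.inf)
    for c, r in zip(centers, radii):
        d = np.minimum(d, np.linalg.norm(pts - c, axis=1) - r)
    d = d.reshape(shape)
    vox = np.argwhere((d >= band[0]) & (d <= band[1]))[::stride]
    q = grid.origin + vox * grid.spacing
    lower = brute_force_rinaccess(centers, radii, q, ladder, candidate_spacing)
    upper = brute_force_rinaccess(centers, radii, q, ladder, candidate_spacing,
                                  legality_slack=candidate_spacing * math.sqrt(3) / 2)
    bad = 0
    for v, s_lo, s_hi in zip(vox, step_idx(lower), step_idx(upper)):
        lo = np.maximum(v - 1, 0)
        hi = np.minimum(v + 2, shape)
        block = step_idx(grid.rinaccess[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]].ravel())
        if min(np.abs(block - s_lo).min(), np.abs(block - s_hi).min()) > 1:
            bad += 1
    return bad, len(vox)


def dbscan_by_reachability(points: np.ndarray, eps: float,
                           min_samples: int) -> np.ndarray:
    """DBSCAN labels re-derived from first principles.

    Core points have >= min_samples neighbours within eps (self included);
    clusters are connected components of core points under eps-adjacency,
    plus any border point within eps of a member core point.  Noise is -1.
    Label numbering follows first-touched point order.
    """
    points = np.asarray(points, float)
    n = len(points)
    d = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=2)
    neighbours = [np.flatnonzero(d[i] <= eps) for i in range(n)]
    core = np.array([len(nb) >= min_samples for nb in neighbours])
    labels = np.full(n, -1)
    cluster = 0
    for i in range(n):
        if not core[i] or labels[i] != -1:
            continue
        queue = [i]
        labels[i] = cluster
        while queue:
            p = queue.pop()
            if not core[p]:
                continue
            for q in neighbours[p]:
                if labels[q] == -1:
                    labels[q] = cluster
                    queue.append(q)
        cluster += 1
    return labels


def segments_by_expansion(positions: Sequence[Tuple[int, str]],
                          gap_threshold: int) -> List[List[Tuple[int, str]]]:
    """Group sorted interface positions by pairwise run expansion: start
    from singleton groups and repeatedly merge adjacent groups whose
    boundary gap (intervening author-numbering positions) is within the
    threshold."""
    pos = sorted(set((int(s), str(ic)) for s, ic in positions))
    groups = [[p] for p in pos]
    merged = True
    while merged:
        merged = False
        for i in range(len(groups) - 1):
            a, b = groups[i][-1], groups[i + 1][0]
            gap = b[0] - a[0] - 1 if b[0] != a[0] else 0
            if gap <= gap_threshold:
                groups[i:i + 2] = [groups[i] + groups[i + 1]]
                merged = True
                break
    return groups


def anova_f_by_sums_of_squares(groups: Sequence[Sequence[float]]) -> Tuple[float, int, int]:
    """Classical one-way ANOVA F from explicit sums of squares."""
    groups = [np.asarray(g, float) for g in groups]
    all_x = np.concatenate(groups)
    grand = all_x.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = len(all_x) - len(groups)
    return (ss_between / df_b) / (ss_within / df_w), df_b, df_w


def plane_rmsd_by_grid_search(coords: np.ndarray, n_dirs: int = 8000) -> float:
    """Best-fit plane RMSD by scanning unit normals on a spherical grid,
    refined once around the best direction."""
    coords = np.asarray(coords, float)
    centered = coords - coords.mean(axis=0)

    def fib(n, around=None, spread=1.0):
        k = np.arange(n) + 0.5
        z = 1 - 2 * k / n
        r = np.sqrt(np.maximum(0, 1 - z ** 2))
        th = math.pi * (3 - math.sqrt(5)) * np.arange(n)
        dirs = np.column_stack([r * np.cos(th), r * np.sin(th), z])
        if around is not None:
            dirs = around[None, :] + spread * dirs
            dirs /= np.linalg.norm(dirs, axis=1)[:, None]
        return dirs

    best = None
    best_dir = None
    for dirs in (fib(n_dirs),):
        proj = centered @ dirs.T
        rms = np.sqrt(np.mean(proj ** 2, axis=0))
        i = int(np.argmin(rms))
        best, best_dir = float(rms[i]), dirs[i]
    for spread in (0.1, 0.01, 0.001):
        dirs = fib(2000, around=best_dir, spread=spread)
        proj = centered @ dirs.T
        rms = np.sqrt(np.mean(proj ** 2, axis=0))
        i = int(np.argmin(rms))
        if rms[i] < best:
            best, best_dir = float(rms[i]), dirs[i]
    return best
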