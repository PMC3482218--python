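"""Voronoi atomic volumes and interface packing density.

The packing density of an interface is

    rho = sum(standard volumes) / sum(real Voronoi volumes)

over the atoms at the interface. Real volumes come from a radical-plane
(power) tessellation weighted by vdW radii (plain bisector planes as a
config mode); cells of surface atoms are closed by solvent pseudo-sites
placed on the accessible surface, so that every protein atom ends up with
a finite cell. A seeded Monte-Carlo nearest-site integrator provides an
independent numeric oracle for the cell volumes.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog
from scipy.spatial import ConvexHull, HalfspaceIntersection, cKDTree
from scipy.spatial import QhullError

from .sasa import DEFAULT_PROBE, _asa_core, canonical_frame
from .structure_io import Structure

log = logging.getLogger(__name__)

SOLVENT_RADIUS = 1.40
DEFAULT_SHELL_OFFSET = 2.8     # solvent sites at atom center + (r + offset)
DEFAULT_CAP_POINTS = 192       # dot resolution used to find exposed directions
DEFAULT_MIN_SITE_DIST = 1.5    # thinning distance between solvent sites


# ----------------------------------------------------------------------
# generic power-diagram cell volumes

def _box_halfspaces(lo, hi):
    rows = []
    for k in range(3):
        e = np.zeros(3)
        e[k] = 1.0
        rows.append(np.append(e, -hi[k]))    # x_k <= hi_k
        rows.append(np.append(-e, lo[k]))    # x_k >= lo_k
    return np.array(rows)


def _interior_point(halfspaces, guess):
    A, b = halfspaces[:, :3], halfspaces[:, 3]
    if (A @ guess + b < -1e-9).all():
        return guess
    # Chebyshev center: maximize slack radius
    norms = np.linalg.norm(A, axis=1)
    res = linprog(c=[0, 0, 0, -1],
                  A_ub=np.column_stack([A, norms]), b_ub=-b,
                  bounds=[(None, None)] * 3 + [(0, None)], method="highs")
    if not res.success or res.x[3] < 1e-9:
        return None
    return res.x[:3]


def power_cell_volumes(points, radii=None, mode: str = "radical",
                       box=None, targets=None, cutoff: float = 8.0,
                       box_margin: float = 4.0):
    """Cell volumes of a (power) tessellation, clipped to a bounding box.

    Returns (volumes, bounded) arrays aligned with `targets` (default: all
    sites). `bounded` is False where the cell touches the outer box, i.e.
    the cell is only closed by the artificial clipping and its volume must
    not enter packing sums. mode 'radical' weights planes by r^2 (power
    diagram); 'bisector' uses unweighted midplanes. Both coincide for
    equal radii.
    """
    pts = np.asarray(points, float)
    n = len(pts)
    if n < 5:
        raise ValueError("need at least 5 sites for a 3D tessellation")
    if mode not in ("radical", "bisector"):
        raise ValueError(f"unknown mode {mode!r}")
    w = np.zeros(n)
    if mode == "radical" and radii is not None:
        w = np.asarray(radii, float) ** 2
    if box is None:
        lo = pts.min(axis=0) - box_margin
        hi = pts.max(axis=0) + box_margin
    else:
        lo, hi = np.asarray(box[0], float), np.asarray(box[1], float)
    box_hs = _box_halfspaces(lo, hi)
    if targets is None:
        targets = np.arange(n)
    tree = cKDTree(pts)
    diag = float(np.linalg.norm(hi - lo))
    vols = np.full(len(targets), np.nan)
    bounded = np.zeros(len(targets), bool)
    for t, i in enumerate(targets):
        cut = cutoff
        while True:
            nbrs = [j for j in tree.query_ball_point(pts[i], cut) if j != i]
            rows = []
            for j in nbrs:
                a = 2.0 * (pts[j] - pts[i])
                rhs = (pts[j] @ pts[j]) - (pts[i] @ pts[i]) + w[i] - w[j]
                rows.append(np.append(a, -rhs))
            hs = np.vstack([rows, box_hs]) if rows else box_hs
            interior = _interior_point(hs, pts[i])
            if interior is None:
                # empty (swallowed) power cell
                vols[t], bounded[t] = 0.0, True
                break
            try:
                inter = HalfspaceIntersection(hs, interior)
                verts = inter.intersections
                hull = ConvexHull(verts)
            except QhullError as exc:
                if cut < diag:
                    cut *= 1.8
                    continue
                raise ValueError(f"degenerate tessellation at site {i}") from exc
            vmax = float(np.linalg.norm(verts - pts[i], axis=1).max())
            if vmax > cut / 2.0 - 1.0 and cut < diag:
                cut *= 1.8
                continue
            vols[t] = hull.volume
            on_box = (np.abs(verts - lo) < 1e-8).any() or \
                     (np.abs(verts - hi) < 1e-8).any()
            bounded[t] = not on_box
            break
    return vols, bounded


# ----------------------------------------------------------------------
# solvent capping and protein volumes

@dataclass
class VolumeSet:
    """Real (tessellation) volumes for the protein atoms of one structure."""
    volumes: np.ndarray          # A^3 per protein atom; NaN where pathological
    bounded: np.ndarray          # False where the cell was only closed by the box
    mode: str
    n_solvent_sites: int
    shell_offset: float
    sites: np.ndarray            # protein atoms + solvent pseudo-sites
    site_radii: np.ndarray
    n_protein: int
    box: tuple


def solvent_sites(s: Structure, shell_offset: float = DEFAULT_SHELL_OFFSET,
                  n_points: int = DEFAULT_CAP_POINTS,
                  min_dist: float = DEFAULT_MIN_SITE_DIST,
                  probe: float = DEFAULT_PROBE) -> np.ndarray:
    """Deterministic solvent pseudo-sites on the accessible surface.

    Exposed dot directions are pushed to atom center + (r + shell_offset)
    and thinned so no two kept sites are closer than `min_dist`. Sites are
    returned in the canonical molecular frame (same frame as
    `canonical_frame(s.coords)`) so that derived volumes are invariant to
    rigid transforms of the input.
    """
    coords, radii = canonical_frame(s.coords), s.radii
    _, dirs = _asa_core(coords, radii, probe, n_points,
                        return_exposed_dirs=True, canonicalize=False)
    raw = []
    for i, d in enumerate(dirs):
        if len(d):
            raw.append(coords[i] + (radii[i] + shell_offset) * d)
    if not raw:
        return np.empty((0, 3))
    raw = np.vstack(raw)
    # greedy deterministic thinning on a grid
    cell = min_dist
    grid: dict[tuple, list] = {}
    kept = []
    for p in raw:
        key = tuple((p // cell).astype(int))
        ok = True
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    for q in grid.get((key[0] + dx, key[1] + dy, key[2] + dz), ()):
                        if np.dot(p - q, p - q) < min_dist ** 2:
                            ok = False
                            break
                    if not ok:
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            grid.setdefault(key, []).append(p)
            kept.append(p)
    return np.array(kept)


def voronoi_volumes(s: Structure, mode: str = "radical",
                    shell_offset: float = DEFAULT_SHELL_OFFSET,
                    cap_points: int = DEFAULT_CAP_POINTS,
                    min_site_dist: float = DEFAULT_MIN_SITE_DIST,
                    box_margin: float = 4.0) -> VolumeSet:
    """Per-atom real Voronoi volumes with solvent capping.

    Volumes are returned for protein atoms only; solvent pseudo-sites exist
    only to close the cells of surface atoms. Deterministic for fixed input.
    """
    key = ("vol", mode, shell_offset, cap_points, min_site_dist)
    if key in s._cache:
        return s._cache[key]
    if len(s.atoms) < 5:
        raise ValueError("need at least 5 atoms")
    coords, radii = canonical_frame(s.coords), s.radii
    if np.linalg.matrix_rank(coords - coords.mean(axis=0), tol=1e-6) < 3:
        raise ValueError("degenerate all-coplanar atom set")
    solv = solvent_sites(s, shell_offset, cap_points, min_site_dist)
    sites = np.vstack([coords, solv]) if len(solv) else coords.copy()
    srad = np.concatenate([radii, np.full(len(solv), SOLVENT_RADIUS)])
    lo = sites.min(axis=0) - box_margin
    hi = sites.max(axis=0) + box_margin
    vols, bounded = power_cell_volumes(
        sites, srad, mode=mode, box=(lo, hi), targets=np.arange(len(coords)))
    n_open = int((~bounded).sum())
    if n_open:
        log.warning("%d protein atoms have capped-open cells (excluded from rho)",
                    n_open)
    vs = VolumeSet(vols, bounded, mode, len(solv), shell_offset,
                   sites, srad, len(coords), (tuple(lo), tuple(hi)))
    s._cache[key] = vs
    return vs


@dataclass
class PackingResult:
    window_index: int
    rho: float
    n_interface_atoms: int
    n_excluded_atoms: int


def packing_density(b, v: VolumeSet, s: Structure,
                    include_het: bool = False) -> PackingResult:
    """rho = sum standard volumes / sum real volumes over interface atoms.

    Atoms with capped-open or pathological cells are excluded from both
    sums so numerator and denominator stay consistent.
    """
    serial_to_idx = {a.serial: i for i, a in enumerate(s.atoms)}
    idx = sorted(serial_to_idx[ser] for ser in b.interface_serials)
    if not idx:
        raise ValueError(f"window {b.window_index}: empty interface")
    num = den = 0.0
    n_used = n_excl = 0
    for i in idx:
        a = s.atoms[i]
        if a.is_het and not include_het:
            n_excl += 1
            continue
        vol = v.volumes[i]
        if not v.bounded[i] or not np.isfinite(vol) or vol <= 0:
            n_excl += 1
            continue
        num += a.standard_volume
        den += vol
        n_used += 1
    if n_used == 0 or den <= 0:
        log.warning("window %d: no usable interface volumes, rho missing",
                    b.window_index)
        return PackingResult(b.window_index, float("nan"), len(idx), n_excl)
    return PackingResult(b.window_index, num / den, len(idx), n_excl)


# ----------------------------------------------------------------------
# Monte-Carlo oracle

def mc_power_volumes(sites, radii, box, n_samples: int, seed: int,
                     mode: str = "radical", targets=None,
                     chunk: int = 200_000):
    """Seeded Monte-Carlo nearest-site volume integration.

    Samples uniform points in `box` and assigns each to the site of least
    power distance (|x-p|^2 - r^2; plain squared distance in bisector
    mode). Returns (volumes, standard errors) for `targets`. Candidate
    sites come from a k-nearest Euclidean query with an exactness check,
    falling back to brute force for the rare ambiguous sample.
    """
    if n_samples < 1e5:
        raise ValueError("n_samples must be >= 1e5")
    sites = np.asarray(sites, float)
    w = np.asarray(radii, float) ** 2 if (mode == "radical" and radii is not None) \
        else np.zeros(len(sites))
    lo, hi = np.asarray(box[0], float), np.asarray(box[1], float)
    vol_box = float(np.prod(hi - lo))
    rng = np.random.default_rng(seed)
    tree = cKDTree(sites)
    k = min(16, len(sites))
    counts = np.zeros(len(sites), dtype=np.int64)
    done = 0
    while done < n_samples:
        m = min(chunk, n_samples - done)
        x = rng.uniform(lo, hi, size=(m, 3))
        d, j = tree.query(x, k=k)
        if k == 1:
            d, j = d[:, None], j[:, None]
        power = d ** 2 - w[j]
        best = np.argmin(power, axis=1)
        assign = j[np.arange(m), best]
        # exactness: any site beyond d_k cannot beat best if
        # d_k^2 - wmax_possible > best_power
        if k == len(sites):
            ambiguous = np.zeros(m, bool)
        else:
            ambiguous = d[:, -1] ** 2 - w.max() < power[np.arange(m), best]
        for a in np.nonzero(ambiguous)[0]:
            p_all = ((sites - x[a]) ** 2).sum(axis=1) - w
            assign[a] = int(np.argmin(p_all))
        counts += np.bincount(assign, minlength=len(sites))
        done += m
    frac = counts / n_samples
    vols = frac * vol_box
    se = np.sqrt(np.clip(frac * (1 - frac), 0, None) / n_samples) * vol_box
    if targets is not None:
        targets = np.asarray(targets, int)
        return vols[targets], se[targets]
    return vols, se


def mc_volume_oracle(s: Structure, box=None, n_samples: int = 1_000_000,
                     seed: int = 0, mode: str = "radical",
                     volume_set: VolumeSet | None = None):
    """Monte-Carlo volumes for a structure's protein atoms.

    Uses the same capped site set as :func:`voronoi_volumes` so the two
    code paths estimate the same cells. When `box` is a tight sub-box the
    returned volumes are the cell portions inside it (use for cells known
    to lie within the box).
    """
    v = volume_set or voronoi_volumes(s, mode=mode)
    box = box or v.box
    return mc_power_volumes(v.sites, v.site_radii, box, n_samples, seed,
                            mode=mode, targets=np.arange(v.n_protein))
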