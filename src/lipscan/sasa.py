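"""Solvent-accessible surface areas and buried-interface polarity.

The engine is a deterministic dot-surface method: a fixed golden-spiral
point set on every expanded sphere (vdW radius + probe), with points culled
by neighbouring spheres found through a KD-tree. For a window split, the
area an atom buries is its ASA in its isolated part (fragment alone or
remainder alone) minus its ASA in the whole structure; the interface totals
split that buried area into polar and apolar contributions, whose ratio is
the polarity ratio PR.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import Structure, WindowSplit

log = logging.getLogger(__name__)

DEFAULT_PROBE = 1.40
DEFAULT_N_POINTS = 960
DEFAULT_EPSILON = 0.1   # A^2; minimum buried area for interface membership


def sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral point set on the unit sphere (n x 3)."""
    if n < 1:
        raise ValueError("need at least one sphere point")
    k = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * k + 1.0) / n
    phi = k * math.pi * (3.0 - math.sqrt(5.0))
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


@dataclass
class AreaSet:
    """Per-atom solvent-accessible areas (A^2), keyed by atom serial."""
    serials: np.ndarray
    asa: np.ndarray
    probe_radius: float
    n_points: int

    def by_serial(self) -> dict[int, float]:
        return {int(s): float(a) for s, a in zip(self.serials, self.asa)}


def canonical_frame(coords: np.ndarray) -> np.ndarray:
    """Rotate/translate coordinates into a molecule-fixed canonical frame.

    The dot quadrature uses a fixed lab-frame point set, so areas would
    drift under rigid-body motion of the input; evaluating in the
    principal-axes frame (eigenvalue-ordered, skewness-sign-fixed,
    right-handed) makes every derived scalar invariant to rigid
    transforms. Degenerate (symmetric) inputs fall back to the centered
    coordinates unchanged.
    """
    coords = np.asarray(coords, float)
    ctr = coords.mean(axis=0)
    x = coords - ctr
    if len(x) < 3:
        return x
    cov = x.T @ x / len(x)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if np.min(np.abs(np.diff(evals))) < 1e-9 * max(evals.max(), 1.0):
        return x
    for k in range(2):
        proj = x @ evecs[:, k]
        s = float((proj ** 3).sum())
        if abs(s) < 1e-9:
            s = proj[int(np.argmax(np.abs(proj)))]
        if s < 0:
            evecs[:, k] = -evecs[:, k]
    evecs[:, 2] = np.cross(evecs[:, 0], evecs[:, 1])
    return x @ evecs


def canonical_coords(s: Structure) -> np.ndarray:
    """Structure coordinates in the canonical frame, cached."""
    if "canonical" not in s._cache:
        s._cache["canonical"] = canonical_frame(s.coords)
    return s._cache["canonical"]


def _check_coincident(coords: np.ndarray, serials) -> None:
    tree = cKDTree(coords)
    pairs = tree.query_pairs(1e-6)
    if pairs:
        i, j = sorted(pairs)[0]
        raise ValueError(
            f"coincident atom centers: serials {serials[i]} and {serials[j]}")


def _asa_core(coords, radii, probe, n_points, targets=None,
              return_exposed_dirs=False, canonicalize=True):
    """ASA for `targets` (default all) occluded by every atom in `coords`.

    Computed in the canonical molecular frame so the returned areas (and
    exposed directions, which are then in that frame) are invariant to
    rigid-body transforms of the input.
    """
    coords = np.asarray(coords, float)
    if canonicalize:
        coords = canonical_frame(coords)
    radii = np.asarray(radii, float)
    R = radii + probe
    n = len(coords)
    if targets is None:
        targets = np.arange(n)
    pts = sphere_points(n_points)
    tree = cKDTree(coords)
    rmax = R.max() if n else 0.0
    out = np.zeros(len(targets))
    dirs = [] if return_exposed_dirs else None
    for t, i in enumerate(targets):
        nbrs = [j for j in tree.query_ball_point(coords[i], R[i] + rmax)
                if j != i and np.linalg.norm(coords[j] - coords[i]) < R[i] + R[j]]
        surf = coords[i] + R[i] * pts
        if nbrs:
            nb = np.asarray(nbrs)
            d2 = ((surf[:, None, :] - coords[nb][None, :, :]) ** 2).sum(-1)
            exposed = (d2 >= (R[nb] ** 2)[None, :]).all(axis=1)
        else:
            exposed = np.ones(n_points, bool)
        out[t] = 4.0 * math.pi * R[i] ** 2 * exposed.mean()
        if return_exposed_dirs is not False and dirs is not None:
            dirs.append(pts[exposed])
    if return_exposed_dirs:
        return out, dirs
    return out


def compute_asa(atoms, probe: float = DEFAULT_PROBE,
                n_points: int = DEFAULT_N_POINTS,
                context=None) -> AreaSet:
    """ASA of a set of annotated atoms (a Structure or a list of Atom).

    `context`, when given, supplies extra occluding atoms whose own areas
    are not reported. Deterministic for fixed n_points: the sphere point
    set is a fixed golden spiral, no RNG anywhere.
    """
    if n_points < 60:
        raise ValueError("n_points must be >= 60")
    if probe < 0:
        raise ValueError("probe radius must be >= 0")
    atom_list = atoms.atoms if isinstance(atoms, Structure) else list(atoms)
    coords = np.array([a.coords for a in atom_list], float)
    radii = np.array([a.vdw_radius for a in atom_list], float)
    serials = np.array([a.serial for a in atom_list], int)
    if context:
        ctx = list(context)
        coords = np.vstack([coords, np.array([a.coords for a in ctx], float)])
        radii = np.concatenate([radii, [a.vdw_radius for a in ctx]])
    _check_coincident(coords, list(serials) + [f"ctx{i}" for i in
                                               range(len(coords) - len(serials))])
    asa = _asa_core(coords, radii, probe, n_points,
                    targets=np.arange(len(serials)))
    return AreaSet(serials, asa, probe, n_points)


@dataclass
class InterfaceBurial:
    """Areas buried between one window fragment and the chain remainder."""
    window_index: int
    serials: np.ndarray            # all atoms considered (fragment + remainder)
    buried: np.ndarray             # A^2, clipped at 0, aligned with serials
    interface_serials: frozenset   # atoms with buried > epsilon
    a_pol: float
    a_apol: float
    epsilon: float = DEFAULT_EPSILON
    probe: float = DEFAULT_PROBE


def structure_asa(s: Structure, probe: float = DEFAULT_PROBE,
                  n_points: int = DEFAULT_N_POINTS) -> np.ndarray:
    """Full-structure per-atom ASA, cached on the structure."""
    key = ("asa", probe, n_points)
    if key not in s._cache:
        _check_coincident(s.coords, [a.serial for a in s.atoms])
        s._cache[key] = _asa_core(canonical_coords(s), s.radii, probe,
                                  n_points, canonicalize=False)
    return s._cache[key]


def interface_burial(s: Structure, w: WindowSplit,
                     probe: float = DEFAULT_PROBE,
                     epsilon: float = DEFAULT_EPSILON,
                     n_points: int = DEFAULT_N_POINTS,
                     include_het_in_totals: bool = False) -> InterfaceBurial:
    """Per-atom area buried by the fragment/remainder interaction.

    buried(atom) = ASA(atom in its isolated part) - ASA(atom in the full
    structure), clipped at zero. Only remainder atoms within occlusion
    range of the fragment can change, so the isolated-remainder pass is
    restricted to those; everything else is exactly zero.
    """
    if not w.valid:
        raise ValueError(f"window {w.window_index} is invalid (chain break)")
    # all three passes share the whole-structure canonical frame, so the
    # quadrature error cancels exactly for atoms whose occluders don't change
    coords, radii = canonical_coords(s), s.radii
    full = structure_asa(s, probe, n_points)
    frag = np.asarray(w.fragment_atoms, int)
    rem = np.asarray(w.remainder_atoms, int)

    iso_frag = _asa_core(coords[frag], radii[frag], probe, n_points,
                         canonicalize=False)

    # remainder atoms whose occluder set changes when the fragment is removed
    cutoff = 2.0 * radii.max() + 2.0 * probe
    tree = cKDTree(coords[rem])
    near = np.unique(np.concatenate(
        [np.asarray(hits, int) for hits in
         tree.query_ball_point(coords[frag], cutoff)] or [np.array([], int)]))
    iso_rem = np.zeros(len(rem))
    iso_rem[:] = full[rem]
    if len(near):
        iso_rem[near] = _asa_core(coords[rem], radii[rem], probe, n_points,
                                  targets=near, canonicalize=False)

    serials = np.array([s.atoms[i].serial for i in np.concatenate([frag, rem])])
    buried = np.concatenate([np.clip(iso_frag - full[frag], 0.0, None),
                             np.clip(iso_rem - full[rem], 0.0, None)])
    idx = np.concatenate([frag, rem])
    on_iface = buried > epsilon
    polar = s.polar_mask[idx]
    het = s.het_mask[idx]
    count = on_iface & (include_het_in_totals | ~het)
    a_pol = float(buried[count & polar].sum())
    a_apol = float(buried[count & ~polar].sum())
    return InterfaceBurial(w.window_index, serials, buried,
                           frozenset(int(x) for x in serials[on_iface]),
                           a_pol, a_apol, epsilon, probe)


def polarity_ratio(b: InterfaceBurial) -> float:
    """PR = buried polar area / buried apolar area.

    Degenerate interfaces map to sentinels: +inf when only polar area is
    buried, NaN (missing) when nothing is buried.
    """
    if b.a_apol > 0:
        return b.a_pol / b.a_apol
    if b.a_pol > 0:
        log.warning("window %d: apolar buried area is zero, PR = +inf",
                    b.window_index)
        return math.inf
    return math.nan
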