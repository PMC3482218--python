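"""Synthetic structures and independent numeric oracles.

Everything here exists so that each computational stage can be exercised
and cross-checked without downloading coordinates: cubic-lattice
pseudo-proteins with analytically known Voronoi cells, ideal helices with
single-centroid side chains (deliberately non-physical but carrying
residue-appropriate polarity), helix bundles with engineered chain breaks,
planted PR/rho tracks with known peak structure, and slow brute-force
oracles for ASA.
"""
from __future__ import annotations

import math
from dataclasses import replace

import numpy as np

from ._tables import radii_table, volume_table
from .profiles import ProfilePair
from .structure_io import (DEFAULT_POLAR_ELEMENTS, Atom, Residue, Structure,
                           _annotate)

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL"}

# approximate side-chain centroid distance from CA, by residue (A)
_SC_LENGTH = {
    "ALA": 1.5, "ARG": 4.1, "ASN": 2.5, "ASP": 2.5, "CYS": 2.1,
    "GLN": 3.1, "GLU": 3.1, "HIS": 3.2, "ILE": 2.3, "LEU": 2.6,
    "LYS": 3.5, "MET": 2.9, "PHE": 3.4, "PRO": 1.9, "SER": 1.9,
    "THR": 1.9, "TRP": 3.9, "TYR": 3.8, "VAL": 2.0}


# ----------------------------------------------------------------------
# cubic lattice pseudo-protein

def make_lattice(n_per_side: int, spacing: float = 2.0,
                 radius: float = 1.87) -> Structure:
    """n^3 single-atom residues on a cubic grid; interior cells = spacing^3."""
    if n_per_side < 2:
        raise ValueError("n_per_side must be >= 2")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    atoms, residues = [], []
    serial = 0
    for ix in range(n_per_side):
        for iy in range(n_per_side):
            for iz in range(n_per_side):
                serial += 1
                atoms.append(Atom(serial, "CA", "C", (serial, ""), "LAT",
                                  (ix * spacing, iy * spacing, iz * spacing),
                                  radius, "apolar", 20.0))
                residues.append(Residue(serial, "", "LAT", (serial - 1,)))
    return Structure("A", residues, atoms, None, None,
                     f"lattice{n_per_side}")


def lattice_center_index(n_per_side: int) -> int:
    """Atom index of the central lattice site (odd n only)."""
    if n_per_side % 2 == 0:
        raise ValueError("central site requires odd n_per_side")
    m = n_per_side // 2
    return (m * n_per_side + m) * n_per_side + m


# ----------------------------------------------------------------------
# NeRF chain building

def _place_atom(a, b, c, bond: float, angle: float, torsion: float):
    """Standard NeRF placement of atom d bonded to c (angle b-c-d, torsion a-b-c-d)."""
    ang, tor = math.radians(angle), math.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array([-bond * math.cos(ang),
                   bond * math.sin(ang) * math.cos(tor),
                   bond * math.sin(ang) * math.sin(tor)])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def _build_backbone(n_res: int, phi: float, psi: float, omega: float = 180.0):
    """Backbone N/CA/C coordinates for a regular (phi, psi) conformation."""
    b_NCa, b_CaC, b_CN = 1.458, 1.525, 1.329
    a_CNCa, a_NCaC, a_CaCN = 121.7, 111.2, 116.2
    N = [np.array([0.0, 0.0, 0.0])]
    CA = [np.array([b_NCa, 0.0, 0.0])]
    C = [_place_atom(np.array([0.0, 1.0, 0.0]), N[0], CA[0],
                     b_CaC, a_NCaC, 52.0)]
    for i in range(1, n_res):
        N.append(_place_atom(N[-1], CA[-1], C[-1], b_CN, a_CaCN, psi))
        CA.append(_place_atom(CA[-1], C[-1], N[-1], b_NCa, a_CNCa, omega))
        C.append(_place_atom(C[-1], N[-1], CA[-1], b_CaC, a_NCaC, phi))
    return N, CA, C


def _carbonyl_o(CA_i, C_i, N_next):
    u1 = (C_i - CA_i) / np.linalg.norm(C_i - CA_i)
    u2 = (C_i - N_next) / np.linalg.norm(C_i - N_next)
    d = u1 + u2
    d /= np.linalg.norm(d)
    return C_i + 1.231 * d


def _sc_centroid(N_i, CA_i, C_i, length: float):
    """Side-chain centroid along the ideal C-beta direction."""
    b = CA_i - N_i
    c = C_i - CA_i
    a = np.cross(b, c)
    d = -0.58273431 * a + 0.56802827 * b - 0.54067466 * c
    return CA_i + length * d / np.linalg.norm(d)


def _build_peptide(sequence: str, phi: float, psi: float,
                   protein_id: str, first_number: int = 1,
                   origin=np.zeros(3), flip: bool = False) -> Structure:
    sequence = sequence.upper()
    for ch in sequence:
        if ch not in ONE_TO_THREE:
            raise ValueError(f"unknown residue letter {ch!r}")
    n = len(sequence)
    Nc, CAc, Cc = _build_backbone(n, phi, psi)
    # virtual next N for the last carbonyl oxygen
    virt = _place_atom(Nc[-1], CAc[-1], Cc[-1], 1.329, 116.2, psi)
    R = np.diag([-1.0, -1.0, 1.0]) if flip else np.eye(3)
    atoms, residues = [], []
    serial = 0
    for i, ch in enumerate(sequence):
        res3 = ONE_TO_THREE[ch]
        nn = Nc[i + 1] if i + 1 < n else virt
        coords = {"N": Nc[i], "CA": CAc[i], "C": Cc[i],
                  "O": _carbonyl_o(CAc[i], Cc[i], nn)}
        if res3 != "GLY":
            coords["SC"] = _sc_centroid(Nc[i], CAc[i], Cc[i],
                                        _SC_LENGTH[res3])
        idxs = []
        for name in ("N", "CA", "C", "O", "SC"):
            if name not in coords:
                continue
            serial += 1
            xyz = R @ coords[name] + origin
            atoms.append(_annotate(serial, name, None, (first_number + i, ""),
                                   res3, tuple(float(v) for v in xyz),
                                   DEFAULT_POLAR_ELEMENTS))
            idxs.append(serial - 1)
        residues.append(Residue(first_number + i, "", res3, tuple(idxs)))
    return Structure("A", residues, atoms, None, None, protein_id)


def make_helix(sequence: str, protein_id: str = "helix") -> Structure:
    """Ideal alpha-helix (phi=-57, psi=-47) with centroid side chains."""
    if len(sequence) < 8:
        raise ValueError("sequence must be at least 8 residues")
    return _build_peptide(sequence, -57.0, -47.0, protein_id)


def make_extended(sequence: str, protein_id: str = "extended") -> Structure:
    """Fully extended (phi=psi=180) peptide; essentially nothing is buried."""
    if len(sequence) < 2:
        raise ValueError("sequence must be at least 2 residues")
    return _build_peptide(sequence, 180.0, 180.0, protein_id)


def make_bundle(sequences: list[str], separation: float = 9.5,
                numbering_gap: int = 10,
                protein_id: str = "bundle") -> Structure:
    """Several ideal helices side by side, as one chain with breaks.

    Segments alternate direction (antiparallel bundle) and author numbering
    jumps by `numbering_gap` between segments, so windows spanning a break
    are invalid by both the distance and the numbering rule.
    """
    atoms, residues = [], []
    serial = 0
    next_number = 1
    for k, seq in enumerate(sequences):
        origin = np.array([k * separation, 0.0, 0.0])
        seg = _build_peptide(seq, -57.0, -47.0, f"seg{k}",
                             first_number=next_number, origin=origin,
                             flip=bool(k % 2))
        offset = len(atoms)
        for a in seg.atoms:
            serial += 1
            atoms.append(replace(a, serial=serial))
        for r in seg.residues:
            residues.append(Residue(r.number, r.icode, r.name,
                                    tuple(i + offset for i in r.atom_indices)))
        next_number += len(seq) + numbering_gap
    return Structure("A", residues, atoms, None, None, protein_id)


def make_two_body(distance: float, polar: bool = False,
                  radius: float = 1.87) -> Structure:
    """Two single-atom residues at a controlled distance (cap-formula tests)."""
    el = "N" if polar else "C"
    cls = "polar" if polar else "apolar"
    a1 = Atom(1, "CA", el, (1, ""), "LAT", (0.0, 0.0, 0.0), radius, cls, 20.0)
    a2 = Atom(2, "CA", el, (2, ""), "LAT", (distance, 0.0, 0.0), radius, cls, 20.0)
    return Structure("A", [Residue(1, "", "LAT", (0,)),
                           Residue(2, "", "LAT", (1,))],
                     [a1, a2], None, None, "twobody")


# ----------------------------------------------------------------------
# planted profile tracks

def planted_profile(n: int = 60, seed: int = 0,
                    peak_centers=(15, 40), peak_width: int = 3,
                    peak_height: float = 1.0, base: float = 0.45,
                    noise: float = 0.02, rho_base: float = 0.85,
                    rho_coupling: float = 0.45,
                    protein_id: str = "planted") -> ProfilePair:
    """Synthetic PR/rho tracks with Gaussian polarity peaks.

    rho is built as an anti-correlated mirror of PR plus noise, so planted
    peaks sit in packing basins. Seed-deterministic.
    """
    rng = np.random.default_rng(seed)
    x = np.arange(n, dtype=float)
    pr = base + noise * rng.standard_normal(n)
    for c in peak_centers:
        pr += (peak_height - base) * np.exp(-0.5 * ((x - c) / peak_width) ** 2)
    rho = rho_base - rho_coupling * (pr - base) + 0.3 * noise * \
        rng.standard_normal(n)
    nums = np.arange(4, 4 + n)
    labels = [str(v) for v in nums]
    return ProfilePair(protein_id, nums, labels, ["ALA"] * n, pr, rho)


# ----------------------------------------------------------------------
# independent ASA oracle (dense latitude/longitude quadrature, brute force)

def sasa_oracle(atoms, probe: float = 1.4, resolution: float = 0.1):
    """Slow, independent per-atom ASA by dense surface quadrature.

    Uses a latitude/longitude grid with sin-weighted band areas and
    brute-force occlusion checks (no tree, no golden spiral), providing a
    code path independent of the production engine.
    """
    if resolution > 0.1:
        raise ValueError("oracle resolution must be <= 0.1 A")
    atom_list = atoms.atoms if isinstance(atoms, Structure) else list(atoms)
    coords = np.array([a.coords for a in atom_list], float)
    radii = np.array([a.vdw_radius for a in atom_list], float)
    R = radii + probe
    out = np.zeros(len(atom_list))
    for i in range(len(atom_list)):
        Ri = R[i]
        n_theta = max(8, int(math.ceil(math.pi * Ri / resolution)))
        acc = 0.0
        for t in range(n_theta):
            theta = (t + 0.5) * math.pi / n_theta
            band = 2.0 * math.pi * Ri ** 2 * (
                math.cos(t * math.pi / n_theta) -
                math.cos((t + 1) * math.pi / n_theta))
            circ = 2.0 * math.pi * Ri * math.sin(theta)
            n_phi = max(6, int(math.ceil(circ / resolution)))
            phi = (np.arange(n_phi) + 0.5) * 2.0 * math.pi / n_phi
            pts = coords[i] + Ri * np.column_stack([
                np.sin(theta) * np.cos(phi),
                np.sin(theta) * np.sin(phi),
                np.full(n_phi, math.cos(theta))])
            exposed = np.ones(n_phi, bool)
            for j in range(len(atom_list)):
                if j == i:
                    continue
                d2 = ((pts - coords[j]) ** 2).sum(axis=1)
                exposed &= d2 >= R[j] ** 2
            acc += band * exposed.mean()
        out[i] = acc
    return out
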