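"""Reading protein structures and splitting them into probe windows.

A :class:`Structure` is a single chain of one model: waters and hydrogens
removed, alternate locations resolved to one conformer, every retained atom
annotated with a van der Waals radius, a polar/apolar class and a standard
(reference) volume from the packaged tables.

The sliding-window machinery cuts the chain into an L-residue *fragment*
and the *remainder* (everything else, including any admitted heteroatom
environment); the pair of parts is what the interface analysis consumes.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

from ._tables import known_residue_names, radii_table, volume_table

log = logging.getLogger(__name__)

WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}
DEFAULT_POLAR_ELEMENTS = frozenset({"N", "O"})
#: Ca-Ca distance above which consecutive residues are considered broken apart
DEFAULT_BREAK_THRESHOLD = 4.5

# canonical intra-residue atom order: backbone first, then side chain by name
_BACKBONE_ORDER = {"N": 0, "CA": 1, "C": 2, "O": 3, "OXT": 4}


@dataclass(frozen=True)
class Atom:
    """One heavy atom with the annotations the interface analysis needs."""
    serial: int
    name: str
    element: str
    residue_seq: tuple[int, str]   # author number + insertion code
    residue_name: str
    coords: tuple[float, float, float]
    vdw_radius: float
    polarity_class: str            # 'polar' | 'apolar'
    standard_volume: float
    volume_is_fallback: bool = False
    is_het: bool = False           # environment-only atom (never in a fragment)

    @property
    def residue_label(self) -> str:
        num, icode = self.residue_seq
        return f"{num}{icode}".strip()


@dataclass(frozen=True)
class Residue:
    number: int
    icode: str
    name: str
    atom_indices: tuple[int, ...]

    @property
    def label(self) -> str:
        return f"{self.number}{self.icode}".strip()


@dataclass
class Structure:
    """One annotated chain; the unit consumed by every downstream module."""
    chain_id: str
    residues: list[Residue]
    atoms: list[Atom]
    source_path: str | None = None
    resolution: float | None = None
    protein_id: str = "protein"
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    # -- array views -------------------------------------------------
    @property
    def coords(self) -> np.ndarray:
        if "coords" not in self._cache:
            self._cache["coords"] = np.array([a.coords for a in self.atoms], float)
        return self._cache["coords"]

    @property
    def radii(self) -> np.ndarray:
        if "radii" not in self._cache:
            self._cache["radii"] = np.array([a.vdw_radius for a in self.atoms], float)
        return self._cache["radii"]

    @property
    def polar_mask(self) -> np.ndarray:
        if "polar" not in self._cache:
            self._cache["polar"] = np.array(
                [a.polarity_class == "polar" for a in self.atoms], bool)
        return self._cache["polar"]

    @property
    def het_mask(self) -> np.ndarray:
        if "het" not in self._cache:
            self._cache["het"] = np.array([a.is_het for a in self.atoms], bool)
        return self._cache["het"]

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def sequence_one_letter(self) -> str:
        return "".join(
            gemmi.find_tabulated_residue(r.name).one_letter_code.upper()
            if gemmi.find_tabulated_residue(r.name) else "X"
            for r in self.residues)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Rigid-body copy (for invariance checks)."""
        new_atoms = []
        for a in self.atoms:
            xyz = rotation @ np.asarray(a.coords) + translation
            new_atoms.append(replace(a, coords=tuple(float(v) for v in xyz)))
        return Structure(self.chain_id, list(self.residues), new_atoms,
                         self.source_path, self.resolution, self.protein_id)


@dataclass(frozen=True)
class WindowSplit:
    """Fragment residues i..i+L-1 (1-based over resolved residues) vs the rest."""
    window_index: int
    length: int
    fragment_residues: tuple[int, ...]     # residue indices (0-based internal)
    remainder_residues: tuple[int, ...]
    fragment_atoms: tuple[int, ...]        # atom indices
    remainder_atoms: tuple[int, ...]
    assigned_residue: int                  # residue index of window pos ceil(L/2)
    valid: bool


def assigned_offset(L: int) -> int:
    """0-based offset of the assigned residue inside a window.

    The profile value of an 8-residue probe is reported at its 4th
    residue; the same 4th-residue anchor is kept for any probe of length
    >= 7 so that profiles of neighbouring window lengths stay in register
    (a 9-residue probe assigned to its 5th residue would lag the
    8-residue profile by half a position). Shorter probes use the
    near-center residue ceil(L/2).
    """
    return min(3, math.ceil(L / 2) - 1)


# ----------------------------------------------------------------------
# annotation

def _annotate(serial, name, element, resseq, resname, xyz, polar_elements,
              is_het=False) -> Atom:
    rad_spec, rad_fb = radii_table()
    vol_spec, vol_fb = volume_table()
    key = (resname, name)
    if key in rad_spec:
        el_tab, radius = rad_spec[key]
        element = element or el_tab
    else:
        element = (element or name[:1]).upper()
        if element not in rad_fb:
            raise ValueError(f"unknown element {element!r} for atom "
                             f"{resname} {resseq} {name}")
        radius = rad_fb[element]
        log.warning("no radius table entry for %s/%s: element fallback %s=%.2f",
                    resname, name, element, radius)
    fallback = key not in vol_spec
    if fallback:
        vol = vol_fb.get(element)
        if vol is None:
            raise ValueError(f"no standard volume for element {element!r}")
        log.warning("no standard volume for %s/%s: element fallback %.1f",
                    resname, name, vol)
    else:
        vol = vol_spec[key]
    pclass = "polar" if element in polar_elements else "apolar"
    return Atom(serial, name, element, resseq, resname, tuple(xyz),
                radius, pclass, vol, fallback, is_het)


def _polar_elements(sulfur_polar: bool) -> frozenset:
    return frozenset(DEFAULT_POLAR_ELEMENTS | ({"S"} if sulfur_polar else set()))


# ----------------------------------------------------------------------
# loading

def load_structure(path, chain: str | None = None, het_policy: str = "exclude",
                   altloc_policy: str = "highest_occupancy",
                   sulfur_polar: bool = False,
                   protein_id: str | None = None) -> Structure:
    """Read a PDB (or mmCIF) file and return one annotated chain.

    het_policy 'exclude' drops all heteroatoms; 'environment' admits them as
    occluders/tessellation sites only (flagged, never part of window
    fragments or profile positions). Waters and hydrogens are always removed.
    Alternate locations keep the highest-occupancy conformer (tie -> first
    altloc letter).
    """
    if het_policy not in ("exclude", "environment"):
        raise ValueError(f"unknown het_policy {het_policy!r}")
    if altloc_policy != "highest_occupancy":
        raise ValueError(f"unknown altloc_policy {altloc_policy!r}")
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    if len(st) == 0:
        raise ValueError(f"{path}: no models")
    model = st[0]
    chain_names = [ch.name for ch in model]
    if chain is None:
        if len(chain_names) > 1:
            raise ValueError(
                f"{path}: multiple chains {chain_names}; pass a chain selector")
        chain = chain_names[0]
    if chain not in chain_names:
        raise ValueError(f"{path}: chain {chain!r} not found; have {chain_names}")
    ch = model[chain]

    known = known_residue_names()
    polar_elements = _polar_elements(sulfur_polar)
    # collect residues keyed by (seqid, icode, name); merge duplicates
    polymer: dict[tuple, dict] = {}
    het_atoms: list[Atom] = []
    serial = 0
    for res in ch:
        if res.name in WATER_NAMES:
            continue
        is_polymer = res.name in known
        if not is_polymer and het_policy == "exclude":
            continue
        # resolve altlocs within this residue
        groups: dict[str, list] = {}
        for at in res:
            if at.element.is_hydrogen:
                continue
            groups.setdefault(at.name, []).append(at)
        chosen = []
        for name, alts in groups.items():
            if len(alts) == 1:
                chosen.append(alts[0])
            else:
                chosen.append(sorted(
                    alts, key=lambda a: (-a.occ, a.altloc or "A"))[0])
        key = (res.seqid.num, res.seqid.icode.strip(), res.name)
        for at in chosen:
            serial += 1
            el = at.element.name.upper() if at.element.name else ""
            atom = _annotate(serial, at.name, el,
                             (res.seqid.num, res.seqid.icode.strip()),
                             res.name, (at.pos.x, at.pos.y, at.pos.z),
                             polar_elements, is_het=not is_polymer)
            if is_polymer:
                polymer.setdefault(key, {})[at.name] = atom
            else:
                het_atoms.append(atom)

    if not polymer:
        raise ValueError(f"{path}: chain {chain!r} has no polymer atoms")

    # canonical order: residues by (seqid, icode); atoms backbone-first
    def atom_sort_key(name):
        return (_BACKBONE_ORDER.get(name, 10), name)

    residues: list[Residue] = []
    atoms: list[Atom] = []
    for key in sorted(polymer, key=lambda k: (k[0], k[1])):
        num, icode, name = key
        idxs = []
        for aname in sorted(polymer[key], key=atom_sort_key):
            idxs.append(len(atoms))
            atoms.append(polymer[key][aname])
        residues.append(Residue(num, icode, name, tuple(idxs)))
    for a in het_atoms:
        atoms.append(a)
    # renumber serials to the canonical order
    atoms = [replace(a, serial=i + 1) for i, a in enumerate(atoms)]
    residues = [r for r in residues]

    resolution = st.resolution if st.resolution and st.resolution > 0 else None
    pid = protein_id or (st.name.strip() or "protein")
    return Structure(chain, residues, atoms, str(path), resolution, pid)


def write_pdb(s: Structure, path) -> None:
    """Write the structure back out as a minimal single-chain PDB file."""
    st = gemmi.Structure()
    st.name = s.protein_id
    model = gemmi.Model("1")
    ch = gemmi.Chain(s.chain_id or "A")
    for r in s.residues:
        res = gemmi.Residue()
        res.name = r.name
        res.seqid = gemmi.SeqId(r.number, r.icode or " ")
        res.het_flag = "A"
        for ai in r.atom_indices:
            a = s.atoms[ai]
            at = gemmi.Atom()
            at.name = a.name
            at.element = gemmi.Element(a.element)
            at.pos = gemmi.Position(*a.coords)
            at.occ = 1.0
            res.add_atom(at)
        ch.add_residue(res)
    model.add_chain(ch)
    het = [a for a in s.atoms if a.is_het]
    if het:
        hch = gemmi.Chain(s.chain_id or "A")
        # het atoms appended to the same chain as HETATM records
        for a in het:
            res = gemmi.Residue()
            res.name = a.residue_name
            res.seqid = gemmi.SeqId(a.residue_seq[0], a.residue_seq[1] or " ")
            res.het_flag = "H"
            at = gemmi.Atom()
            at.name = a.name
            at.element = gemmi.Element(a.element)
            at.pos = gemmi.Position(*a.coords)
            at.occ = 1.0
            res.add_atom(at)
            ch.add_residue(res)
    st.add_model(model)
    st.write_pdb(str(path))


# ----------------------------------------------------------------------
# windows

def _ca_index(s: Structure, res: Residue) -> int | None:
    for ai in res.atom_indices:
        if s.atoms[ai].name == "CA":
            return ai
    return None


def split_window(s: Structure, i: int, L: int = 8,
                 break_threshold: float = DEFAULT_BREAK_THRESHOLD) -> WindowSplit:
    """Cut out residues i..i+L-1 (1-based) as the fragment.

    The window is invalid when any adjacent residue pair inside it is broken:
    Ca-Ca distance above ``break_threshold`` or a jump in author numbering
    combined with a physical gap. Cut peptide bonds are left uncapped.
    """
    N = s.n_residues
    if not 1 <= i <= N - L + 1:
        raise ValueError(f"window start {i} out of range 1..{N - L + 1}")
    frag_res = tuple(range(i - 1, i - 1 + L))
    rem_res = tuple(j for j in range(N) if j < i - 1 or j >= i - 1 + L)
    frag_atoms, rem_atoms = [], []
    frag_set = set(frag_res)
    for ri, r in enumerate(s.residues):
        tgt = frag_atoms if ri in frag_set else rem_atoms
        tgt.extend(r.atom_indices)
    # environment heteroatoms always belong to the remainder
    rem_atoms.extend(idx for idx, a in enumerate(s.atoms) if a.is_het)

    valid = True
    for a, b in zip(frag_res[:-1], frag_res[1:]):
        ra, rb = s.residues[a], s.residues[b]
        ca_a, ca_b = _ca_index(s, ra), _ca_index(s, rb)
        if ca_a is not None and ca_b is not None:
            d = float(np.linalg.norm(np.asarray(s.atoms[ca_a].coords) -
                                     np.asarray(s.atoms[ca_b].coords)))
            if d > break_threshold:
                valid = False
                break
        elif rb.number - ra.number != 1:
            valid = False
            break
    return WindowSplit(i, L, frag_res, rem_res, tuple(frag_atoms),
                       tuple(rem_atoms), frag_res[assigned_offset(L)], valid)
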