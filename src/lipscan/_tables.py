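"""Packaged chemistry tables: vdW radii and standard (reference) atomic volumes.

Radii follow the Chothia convention used by classic accessibility programs
(trigonal C 1.76 A, tetrahedral C 1.87 A, N 1.65 A, O 1.40 A, S 1.85 A).
Standard volumes are ProtOr-style united-atom group volumes derived from
small-molecule crystal packing. Rows with residue_name '*' are element-level
fallbacks; group_type 'SYN' marks synthetic entries for fixture pseudo-atoms.
"""
from __future__ import annotations

import csv
from functools import lru_cache
from importlib import resources


def _read(name: str):
    with resources.files("lipscan.data").joinpath(name).open() as fh:
        return list(csv.DictReader(fh, delimiter="\t"))


@lru_cache(maxsize=1)
def radii_table() -> tuple[dict, dict]:
    """Return ((residue, atom) -> (element, radius), element -> fallback radius)."""
    specific, fallback = {}, {}
    for row in _read("vdw_radii.tsv"):
        if row["residue_name"] == "*":
            fallback[row["element"]] = float(row["radius"])
        else:
            specific[(row["residue_name"], row["atom_name"])] = (
                row["element"], float(row["radius"]))
    return specific, fallback


@lru_cache(maxsize=1)
def volume_table() -> tuple[dict, dict]:
    """Return ((residue, atom) -> volume, element -> fallback volume)."""
    specific, fallback = {}, {}
    for row in _read("standard_volumes.tsv"):
        if row["residue_name"] == "*":
            fallback[row["atom_name"]] = float(row["volume"])
        else:
            specific[(row["residue_name"], row["atom_name"])] = float(row["volume"])
    return specific, fallback


@lru_cache(maxsize=1)
def known_residue_names() -> frozenset:
    return frozenset(r["residue_name"] for r in _read("vdw_radii.tsv")
                     if r["residue_name"] != "*")
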