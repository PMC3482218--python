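"""Generate packaged TSV tables: vdw_radii.tsv and standard_volumes.tsv.

ProtOr-style united-atom group volumes (small-molecule-crystal reference set)
and Chothia-convention vdW radii (trigonal C 1.76, tetrahedral C 1.87,
N 1.65, O 1.40, S 1.85).
"""
import os

# type -> (radius, volume)
TYPES = {
    "C3H0": (1.76, 9.7),
    "C3H1": (1.76, 21.3),
    "C4H1": (1.87, 14.4),
    "C4H2": (1.87, 24.3),
    "C4H3": (1.87, 36.7),
    "N3H0": (1.65, 8.7),
    "N3H1": (1.65, 15.7),
    "N3H2": (1.65, 22.7),
    "N4H3": (1.65, 21.4),
    "O1H0": (1.40, 15.9),
    "O2H1": (1.40, 18.0),
    "S2H0": (1.85, 29.2),
    "S2H1": (1.85, 36.7),
}

AA = ["ALA","ARG","ASN","ASP","CYS","GLN","GLU","GLY","HIS","ILE",
      "LEU","LYS","MET","PHE","PRO","SER","THR","TRP","TYR","VAL"]

SIDE = {
    "ALA": {"CB": "C4H3"},
    "ARG": {"CB": "C4H2", "CG": "C4H2", "CD": "C4H2", "NE": "N3H1",
            "CZ": "C3H0", "NH1": "N3H2", "NH2": "N3H2"},
    "ASN": {"CB": "C4H2", "CG": "C3H0", "OD1": "O1H0", "ND2": "N3H2"},
    "ASP": {"CB": "C4H2", "CG": "C3H0", "OD1": "O1H0", "OD2": "O1H0"},
    "CYS": {"CB": "C4H2", "SG": "S2H1"},
    "GLN": {"CB": "C4H2", "CG": "C4H2", "CD": "C3H0", "OE1": "O1H0", "NE2": "N3H2"},
    "GLU": {"CB": "C4H2", "CG": "C4H2", "CD": "C3H0", "OE1": "O1H0", "OE2": "O1H0"},
    "GLY": {},
    "HIS": {"CB": "C4H2", "CG": "C3H0", "ND1": "N3H1", "CD2": "C3H1",
            "CE1": "C3H1", "NE2": "N3H1"},
    "ILE": {"CB": "C4H1", "CG1": "C4H2", "CG2": "C4H3", "CD1": "C4H3"},
    "LEU": {"CB": "C4H2", "CG": "C4H1", "CD1": "C4H3", "CD2": "C4H3"},
    "LYS": {"CB": "C4H2", "CG": "C4H2", "CD": "C4H2", "CE": "C4H2", "NZ": "N4H3"},
    "MET": {"CB": "C4H2", "CG": "C4H2", "SD": "S2H0", "CE": "C4H3"},
    "PHE": {"CB": "C4H2", "CG": "C3H0", "CD1": "C3H1", "CD2": "C3H1",
            "CE1": "C3H1", "CE2": "C3H1", "CZ": "C3H1"},
    "PRO": {"CB": "C4H2", "CG": "C4H2", "CD": "C4H2"},
    "SER": {"CB": "C4H2", "OG": "O2H1"},
    "THR": {"CB": "C4H1", "OG1": "O2H1", "CG2": "C4H3"},
    "TRP": {"CB": "C4H2", "CG": "C3H0", "CD1": "C3H1", "CD2": "C3H0",
            "NE1": "N3H1", "CE2": "C3H0", "CE3": "C3H1", "CZ2": "C3H1",
            "CZ3": "C3H1", "CH2": "C3H1"},
    "TYR": {"CB": "C4H2", "CG": "C3H0", "CD1": "C3H1", "CD2": "C3H1",
            "CE1": "C3H1", "CE2": "C3H1", "CZ": "C3H0", "OH": "O2H1"},
    "VAL": {"CB": "C4H1", "CG1": "C4H3", "CG2": "C4H3"},
}

POLAR_RES = {"SER","THR","ASN","GLN","ASP","GLU","LYS","ARG","HIS","TYR"}
SC_VOL = {}
for r in ["ALA","SER","CYS","THR","VAL","PRO"]:
    SC_VOL[r] = 36.7
for r in ["LEU","ILE","ASN","ASP","MET"]:
    SC_VOL[r] = 45.0
for r in ["GLN","GLU","LYS","HIS","PHE","ARG"]:
    SC_VOL[r] = 55.0
for r in ["TRP","TYR"]:
    SC_VOL[r] = 65.0


def backbone(res):
    d = {"N": "N3H0" if res == "PRO" else "N3H1",
         "CA": "C4H2" if res == "GLY" else "C4H1",
         "C": "C3H0", "O": "O1H0", "OXT": "O1H0"}
    return d


def element_of(atom, typ):
    return typ[0]


rows = []
for res in AA:
    atoms = dict(backbone(res))
    atoms.update(SIDE[res])
    for at, typ in atoms.items():
        r, v = TYPES[typ]
        rows.append((res, at, typ[0], typ, r, v))
# synthetic fixture entries
for res in AA:
    if res == "GLY":
        continue
    el = "N" if res in POLAR_RES else "C"
    rows.append((res, "SC", el, "SYN", 2.20, SC_VOL[res]))
rows.append(("LAT", "CA", "C", "SYN", 1.87, 20.0))

out = os.path.join(os.path.dirname(__file__), "..", "src", "lipscan", "data")
os.makedirs(out, exist_ok=True)

with open(os.path.join(out, "vdw_radii.tsv"), "w") as f:
    f.write("residue_name\tatom_name\telement\tradius\n")
    for res, at, el, typ, r, v in rows:
        f.write(f"{res}\t{at}\t{el}\t{r:.2f}\n")
    # element-level fallbacks
    for el, r in [("C", 1.87), ("N", 1.65), ("O", 1.40), ("S", 1.85), ("P", 1.90)]:
        f.write(f"*\t*\t{el}\t{r:.2f}\n")

with open(os.path.join(out, "standard_volumes.tsv"), "w") as f:
    f.write("residue_name\tatom_name\tgroup_type\tvolume\n")
    for res, at, el, typ, r, v in rows:
        f.write(f"{res}\t{at}\t{typ}\t{v:.1f}\n")
    for el, v in [("C", 20.0), ("N", 16.0), ("O", 16.0), ("S", 30.0), ("P", 25.0)]:
        f.write(f"*\t{el}\tELEM\t{v:.1f}\n")

print("wrote", out, len(rows), "rows")
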