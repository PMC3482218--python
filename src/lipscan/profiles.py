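"""Sliding-window property profiles and their projection onto alignments.

For every valid L-residue window the buried-interface polarity ratio (PR)
and the interface packing density (rho) are computed and assigned to the
window's central residue (the 4th for the default L=8). Windows spanning
chain breaks contribute missing values; nothing is interpolated.
"""
from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import AlignIO

from . import packing, sasa
from .structure_io import Structure, assigned_offset, split_window


@dataclass
class ProfilePair:
    """Per-assigned-residue PR and rho tracks for one protein."""
    protein_id: str
    residue_numbers: np.ndarray        # author numbers of assigned residues
    residue_labels: list[str]          # author number + insertion code
    residue_names: list[str]
    pr: np.ndarray                     # NaN = missing, +inf = no apolar area
    rho: np.ndarray                    # NaN = missing
    window_length: int = 8
    probe: float = sasa.DEFAULT_PROBE
    seq_index: np.ndarray | None = None  # 0-based structure residue indices

    def __post_init__(self):
        if len({l for l in self.residue_labels}) != len(self.residue_labels):
            raise ValueError("duplicate assigned positions in profile")

    def __len__(self) -> int:
        return len(self.pr)

    def finite_pairs(self) -> np.ndarray:
        """Mask of positions where both PR and rho are finite."""
        return np.isfinite(self.pr) & np.isfinite(self.rho)

    def to_frame(self) -> pd.DataFrame:
        flags = []
        for p, r in zip(self.pr, self.rho):
            f = []
            if math.isinf(p):
                f.append("PR_INF")
            if math.isnan(p):
                f.append("PR_MISSING")
            if math.isnan(r):
                f.append("RHO_MISSING")
            flags.append(",".join(f) or ".")
        return pd.DataFrame({
            "protein_id": self.protein_id,
            "author_residue_number": self.residue_labels,
            "residue_name": self.residue_names,
            "PR": self.pr, "rho": self.rho, "flags": flags})

    def to_tsv(self, path_or_buf) -> None:
        self.to_frame().to_csv(path_or_buf, sep="\t", index=False,
                               float_format="%.6f", lineterminator="\n")

    def to_tsv_string(self) -> str:
        buf = io.StringIO()
        self.to_tsv(buf)
        return buf.getvalue()

    @classmethod
    def from_tsv(cls, path, window_length: int = 8,
                 probe: float = sasa.DEFAULT_PROBE) -> "ProfilePair":
        df = pd.read_csv(path, sep="\t", dtype={"author_residue_number": str})
        labels = df["author_residue_number"].tolist()
        nums = np.array([int("".join(c for c in l if c.isdigit() or c == "-"))
                         for l in labels])
        return cls(str(df["protein_id"].iloc[0]), nums, labels,
                   df["residue_name"].tolist(),
                   df["PR"].to_numpy(float), df["rho"].to_numpy(float),
                   window_length, probe)


def scan_profiles(s: Structure, L: int = 8,
                  probe: float = sasa.DEFAULT_PROBE,
                  n_points: int = sasa.DEFAULT_N_POINTS,
                  mode: str = "radical",
                  epsilon: float = sasa.DEFAULT_EPSILON,
                  include_het: bool = False) -> ProfilePair:
    """Slide an L-residue probe along the chain and build both tracks."""
    N = s.n_residues
    if N < L:
        raise ValueError(f"chain has {N} residues, need at least L={L}")
    vols = packing.voronoi_volumes(s, mode=mode)
    off = assigned_offset(L)
    nums, labels, names, prs, rhos, seq_idx = [], [], [], [], [], []
    for i in range(1, N - L + 2):
        w = split_window(s, i, L)
        res = s.residues[w.assigned_residue]
        nums.append(res.number)
        labels.append(res.label)
        names.append(res.name)
        seq_idx.append(w.assigned_residue)
        if not w.valid:
            prs.append(math.nan)
            rhos.append(math.nan)
            continue
        b = sasa.interface_burial(s, w, probe, epsilon, n_points,
                                  include_het_in_totals=include_het)
        prs.append(sasa.polarity_ratio(b))
        if b.interface_serials:
            rhos.append(packing.packing_density(b, vols, s,
                                                include_het=include_het).rho)
        else:
            rhos.append(math.nan)
    return ProfilePair(s.protein_id, np.array(nums), labels, names,
                       np.array(prs), np.array(rhos), L, probe,
                       np.array(seq_idx))


# ----------------------------------------------------------------------
# alignment projection

@dataclass
class AlignedProfileMatrix:
    """Profile values laid out on the columns of a multiple alignment."""
    pr: pd.DataFrame               # index: alignment column, columns: protein ids
    rho: pd.DataFrame
    alignment_id: str = ""


def _read_alignment(msa):
    if hasattr(msa, "__iter__") and not isinstance(msa, (str, bytes)):
        try:
            return msa  # already a MultipleSeqAlignment
        except TypeError:
            pass
    for fmt in ("fasta", "clustal"):
        try:
            return AlignIO.read(str(msa), fmt)
        except ValueError:
            continue
    raise ValueError(f"could not parse alignment {msa!r} as FASTA or CLUSTAL")


def project_onto_alignment(profile_list: list[ProfilePair],
                           msa, structures: dict[str, Structure] | None = None
                           ) -> AlignedProfileMatrix:
    """Map each profile onto alignment columns; gaps propagate as missing.

    Every profile's protein id must appear once in the alignment and the
    ungapped alignment sequence must match the structure's one-letter
    sequence (checked when `structures` is provided; mismatching positions
    are reported).
    """
    aln = _read_alignment(msa)
    ids = [rec.id for rec in aln]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate ids in alignment: {ids}")
    ncol = aln.get_alignment_length()
    pr_mat = pd.DataFrame(np.nan, index=range(ncol),
                          columns=[p.protein_id for p in profile_list])
    rho_mat = pr_mat.copy()
    for prof in profile_list:
        recs = [r for r in aln if r.id == prof.protein_id]
        if not recs:
            raise ValueError(f"protein {prof.protein_id!r} not in alignment")
        seq = str(recs[0].seq)
        ungapped_cols = [c for c, ch in enumerate(seq) if ch not in "-."]
        if structures and prof.protein_id in structures:
            sseq = structures[prof.protein_id].sequence_one_letter()
            aseq = "".join(seq[c] for c in ungapped_cols).upper()
            if len(aseq) != len(sseq):
                raise ValueError(
                    f"{prof.protein_id}: alignment has {len(aseq)} residues, "
                    f"structure has {len(sseq)}")
            bad = [i for i, (a, b) in enumerate(zip(aseq, sseq)) if a != b]
            if bad:
                raise ValueError(
                    f"{prof.protein_id}: sequence/structure mismatch at "
                    f"positions {bad[:10]}")
        if prof.seq_index is None:
            raise ValueError("profile lacks structure residue indices")
        for k, ridx in enumerate(prof.seq_index):
            col = ungapped_cols[int(ridx)]
            pr_mat.loc[col, prof.protein_id] = prof.pr[k]
            rho_mat.loc[col, prof.protein_id] = prof.rho[k]
    return AlignedProfileMatrix(pr_mat, rho_mat,
                                getattr(msa, "name", str(msa)))


def plot_profiles(p: ProfilePair, path=None):
    """Basic convenience renderer (matplotlib optional)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, (ax1, ax2) = plt.subplots(2, 1, sharex=True, figsize=(8, 5))
    x = p.residue_numbers
    ax1.plot(x, np.where(np.isinf(p.pr), np.nan, p.pr), lw=1)
    ax1.axhline(0.8, ls="--", c="grey")
    ax1.axhline(0.5, ls=":", c="grey")
    ax1.set_ylabel("PR")
    ax2.plot(x, p.rho, lw=1, c="tab:orange")
    ax2.set_ylabel("rho")
    ax2.set_xlabel("assigned residue")
    fig.suptitle(p.protein_id)
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
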