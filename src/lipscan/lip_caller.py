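"""Quantitative LIP calling from PR/rho profile pairs.

A LIP (light interface of high polarity) is seeded by profile positions
with PR >= 0.8 (more polar than an average protein surface), extended over
flanking positions with PR above the 0.5 core baseline, and must be
associated with a packing-density minimum below the protein-specific
cutoff mean(rho) - 2 SD. Two association modes exist: 'strict' demands a
below-cutoff position inside the candidate itself; 'wall' (default)
accepts a candidate overlapping a basin — a contiguous below-mean stretch
of the rho track that somewhere dips below the cutoff — so candidates
sitting on the wall of a deep minimum are retained.
"""
from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .profiles import ProfilePair


@dataclass(frozen=True)
class LipCallParams:
    theta_peak: float = 0.8
    theta_base: float = 0.5
    k_sd: float = 2.0
    packing_mode: str = "wall"        # 'wall' | 'strict'
    min_len: int = 1
    max_gap: int = 0                  # below-base positions bridgeable in a merge
    basin_boundary: str = "mean"      # 'mean' | 'mean_minus_sd'

    def __post_init__(self):
        if not self.theta_peak > self.theta_base > 0:
            raise ValueError("need theta_peak > theta_base > 0")
        if self.k_sd <= 0:
            raise ValueError("k_sd must be positive")
        if self.packing_mode not in ("wall", "strict"):
            raise ValueError(f"unknown packing_mode {self.packing_mode!r}")


@dataclass(frozen=True)
class PackingCutoff:
    mu: float
    sigma: float
    k_sd: float

    @property
    def cutoff(self) -> float:
        return self.mu - self.k_sd * self.sigma


@dataclass
class LIP:
    """One called (or rejected) interval over assigned profile positions."""
    start: int                  # author residue numbers, inclusive
    end: int
    start_idx: int              # profile track indices
    end_idx: int
    peak_positions: list[int]
    max_pr: float
    min_rho: float
    packing_pass: bool
    packing_mode: str

    @property
    def length(self) -> int:
        return self.end_idx - self.start_idx + 1


def packing_cutoff(p: ProfilePair, k_sd: float = 2.0) -> PackingCutoff:
    """Protein-specific low-packing cutoff: mean - k_sd * SD (population SD)."""
    vals = p.rho[np.isfinite(p.rho)]
    if len(vals) == 0:
        raise ValueError("rho track is entirely missing")
    if len(vals) < 2:
        raise ValueError("need at least 2 non-missing rho values")
    mu = float(vals.mean())
    sigma = float(vals.std(ddof=0))
    return PackingCutoff(mu, sigma, k_sd)


def _candidate_runs(pr: np.ndarray, params: LipCallParams):
    """Maximal runs of PR > theta_base that contain a PR >= theta_peak seed.

    Missing values terminate extension; +inf counts as above both
    thresholds. Runs separated by at most max_gap below-base positions are
    merged.
    """
    above = np.zeros(len(pr), bool)
    seed = np.zeros(len(pr), bool)
    for i, v in enumerate(pr):
        if math.isnan(v):
            continue
        above[i] = v > params.theta_base
        seed[i] = v >= params.theta_peak
    runs = []
    i = 0
    n = len(pr)
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            runs.append([i, j])
            i = j + 1
        else:
            i += 1
    # merge across small gaps (gap counts below-base positions between runs;
    # missing values never bridge)
    merged = []
    for run in runs:
        if merged and run[0] - merged[-1][1] - 1 <= params.max_gap:
            gap = range(merged[-1][1] + 1, run[0])
            if all(not math.isnan(pr[g]) for g in gap):
                merged[-1][1] = run[1]
                continue
        merged.append(run)
    out = []
    for a, b in merged:
        if b - a + 1 < params.min_len:
            continue
        if seed[a:b + 1].any():
            out.append((a, b, np.nonzero(seed[a:b + 1])[0] + a))
    return out


def find_polar_peaks(p: ProfilePair,
                     params: LipCallParams = LipCallParams()) -> list[LIP]:
    """Candidate intervals from the PR track alone (packing untested)."""
    cands = []
    for a, b, seeds in _candidate_runs(p.pr, params):
        seg_pr = p.pr[a:b + 1]
        seg_rho = p.rho[a:b + 1]
        finite_rho = seg_rho[np.isfinite(seg_rho)]
        cands.append(LIP(
            int(p.residue_numbers[a]), int(p.residue_numbers[b]), a, b,
            [int(p.residue_numbers[i]) for i in seeds],
            float(np.max(seg_pr)),
            float(finite_rho.min()) if len(finite_rho) else math.nan,
            False, params.packing_mode))
    return cands


def _basins(rho: np.ndarray, boundary: float, cutoff: float):
    """Maximal runs of rho < boundary that contain a position with rho < cutoff."""
    below = np.isfinite(rho) & (rho < boundary)
    out = []
    i, n = 0, len(rho)
    while i < n:
        if below[i]:
            j = i
            while j + 1 < n and below[j + 1]:
                j += 1
            if np.any(rho[i:j + 1] < cutoff):
                out.append((i, j))
            i = j + 1
        else:
            i += 1
    return out


def call_lips(p: ProfilePair, params: LipCallParams = LipCallParams(),
              return_rejected: bool = False):
    """Full LIP calling: polar candidates filtered by the packing test.

    Returns the passing LIPs sorted by start (and, optionally, every
    candidate with its pass flag for diagnostics).
    """
    co = packing_cutoff(p, params.k_sd)
    boundary = co.mu if params.basin_boundary == "mean" else co.mu - co.sigma
    basins = _basins(p.rho, boundary, co.cutoff)
    cands = find_polar_peaks(p, params)
    all_records = []
    for c in cands:
        if params.packing_mode == "strict":
            seg = p.rho[c.start_idx:c.end_idx + 1]
            ok = bool(np.any(np.isfinite(seg) & (seg < co.cutoff)))
        else:
            ok = any(b0 <= c.end_idx and b1 >= c.start_idx
                     for b0, b1 in basins)
        c.packing_pass = ok
        all_records.append(c)
    passing = sorted([c for c in all_records if c.packing_pass],
                     key=lambda c: c.start_idx)
    if return_rejected:
        return passing, all_records
    return passing


# ----------------------------------------------------------------------
# output formats

def lips_to_bed(lips: list[LIP], protein_id: str) -> str:
    """BED (0-based, half-open) on author numbering; score = 100 * max PR."""
    lines = []
    for l in lips:
        score = 1000 if math.isinf(l.max_pr) else int(round(100 * l.max_pr))
        lines.append(f"{protein_id}\t{l.start - 1}\t{l.end}\tLIP\t{score}\t.")
    return "\n".join(lines) + ("\n" if lines else "")


_FRAME_COLS = ["protein_id", "start", "end", "peaks", "max_PR", "min_rho",
               "packing_mode", "packing_pass"]


def lips_to_frame(lips: list[LIP], protein_id: str) -> pd.DataFrame:
    if not lips:
        return pd.DataFrame(columns=_FRAME_COLS)
    return pd.DataFrame([{
        "protein_id": protein_id, "start": l.start, "end": l.end,
        "peaks": ",".join(str(x) for x in l.peak_positions),
        "max_PR": l.max_pr, "min_rho": l.min_rho,
        "packing_mode": l.packing_mode, "packing_pass": l.packing_pass}
        for l in lips])


def summary_json(p: ProfilePair, params: LipCallParams) -> str:
    co = packing_cutoff(p, params.k_sd)
    passing, all_records = call_lips(p, params, return_rejected=True)
    return json.dumps({
        "protein_id": p.protein_id,
        "params": asdict(params),
        "packing_cutoff": {"mu": co.mu, "sigma": co.sigma,
                           "cutoff": co.cutoff},
        "n_positions": len(p),
        "lips": [asdict(l) for l in passing],
        "candidates": [asdict(l) for l in all_records],
    }, indent=2, default=str)
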