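"""Statistical validation: rank-sum region contrasts, PR-rho
anti-correlation and folded-state polarity baselines.

The region contrast asks whether buried-interface polarity in annotated
unstable (or LIP) segments is higher than in stable (or non-LIP) segments,
with a one-sided Mann-Whitney-Wilcoxon rank-sum test. The polarity
baselines reproduce the two reference quantities of the method: the
polarity ratio of protein cores (~0.5, buried area) and of solvent-exposed
surfaces (~0.75-0.8), computed over a set of structures.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .profiles import ProfilePair
from .sasa import (DEFAULT_N_POINTS, DEFAULT_PROBE, _asa_core,
                   canonical_coords, structure_asa)
from .structure_io import Structure

log = logging.getLogger(__name__)

_BACKBONE = {"N", "CA", "C", "O", "OXT"}


# ----------------------------------------------------------------------
# annotations

@dataclass
class RegionAnnotation:
    """Labeled author-numbered intervals (inclusive) for one protein."""
    protein_id: str
    intervals: list[tuple[int, int, str]]   # (start, end, label)

    def __post_init__(self):
        merged: dict[str, list[list[int]]] = {}
        for s, e, lab in sorted(self.intervals, key=lambda t: (t[2], t[0])):
            if s > e:
                raise ValueError(f"interval {s}-{e} reversed")
            runs = merged.setdefault(lab, [])
            if runs and s <= runs[-1][1] + 1:
                runs[-1][1] = max(runs[-1][1], e)
            else:
                runs.append([s, e])
        self.intervals = [(s, e, lab) for lab, runs in merged.items()
                          for s, e in runs]

    def positions(self, label: str) -> set[int]:
        return {x for s, e, lab in self.intervals if lab == label
                for x in range(s, e + 1)}

    @classmethod
    def from_tsv(cls, path) -> "list[RegionAnnotation]":
        df = pd.read_csv(path, sep="\t")
        out = []
        for pid, grp in df.groupby("protein_id"):
            out.append(cls(str(pid), [(int(r.start), int(r.end), str(r.label))
                                      for r in grp.itertuples()]))
        return out


@dataclass
class StatResult:
    u: float
    p_value: float
    n1: int
    n2: int
    alternative: str
    method: str          # 'exact' | 'normal_approx'


@dataclass
class PolarityBaselines:
    core_ratio: dict[str, float]      # per protein
    surface_ratio: dict[str, float]
    core_mean: float
    core_sd: float
    surface_mean: float
    surface_sd: float


# ----------------------------------------------------------------------
# rank-sum test

def mann_whitney_one_sided(a, b, alternative: str = "a_greater") -> StatResult:
    """One-sided Mann-Whitney-Wilcoxon rank-sum test.

    Exact null enumeration when n1 + n2 <= 20 and the pooled sample is
    tie-free; tie-corrected normal approximation otherwise.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    if alternative not in ("a_greater", "b_greater"):
        raise ValueError(f"unknown alternative {alternative!r}")
    pooled = np.concatenate([a, b])
    ties = len(np.unique(pooled)) < len(pooled)
    exact_ok = (len(pooled) <= 20) and not ties
    method = "exact" if exact_ok else "normal_approx"
    if ties and len(pooled) <= 20:
        log.info("ties present: falling back to normal approximation")
    res = sps.mannwhitneyu(
        a, b, alternative="greater" if alternative == "a_greater" else "less",
        method="exact" if exact_ok else "asymptotic")
    return StatResult(float(res.statistic), float(res.pvalue),
                      len(a), len(b), alternative, method)


def region_polarity_test(p: ProfilePair, ann: RegionAnnotation,
                         contrast: str = "unstable_vs_stable") -> StatResult:
    """Is interface polarity higher in the first group than in the second?

    Samples are the finite PR values at assigned positions inside each
    group's intervals; +inf sentinels are excluded with a warning.
    """
    groups = {"unstable_vs_stable": ("unstable", "stable"),
              "LIP_vs_nonLIP": ("LIP", "nonLIP")}
    if contrast not in groups:
        raise ValueError(f"unknown contrast {contrast!r}")
    lab1, lab2 = groups[contrast]
    lo, hi = int(p.residue_numbers.min()), int(p.residue_numbers.max())
    for s, e, lab in ann.intervals:
        if lab in (lab1, lab2) and (e < lo or s > hi):
            raise ValueError(
                f"annotation {s}-{e} ({lab}) outside profile range {lo}-{hi}")
    samples = []
    for lab in (lab1, lab2):
        pos = ann.positions(lab)
        vals = np.array([v for n, v in zip(p.residue_numbers, p.pr)
                         if int(n) in pos and not math.isnan(v)])
        n_inf = int(np.isinf(vals).sum())
        if n_inf:
            log.warning("%s: excluding %d infinite PR values from %s sample",
                        p.protein_id, n_inf, lab)
        samples.append(vals[np.isfinite(vals)])
    return mann_whitney_one_sided(samples[0], samples[1], "a_greater")


def profile_anticorrelation(p: ProfilePair) -> float:
    """Pearson r between the PR and rho tracks over finite paired positions."""
    m = p.finite_pairs()
    if m.sum() < 3:
        raise ValueError("need at least 3 paired finite positions")
    x, y = p.pr[m], p.rho[m]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("degenerate (constant) track: correlation undefined")
    return float(sps.pearsonr(x, y).statistic)


# ----------------------------------------------------------------------
# folded-state polarity baselines

def _reference_asa(s: Structure, probe: float, n_points: int) -> np.ndarray:
    """Per-atom ASA in a local tripeptide reference state.

    Each residue is evaluated with only its own atoms plus the two
    flanking residues as occluders (a tripeptide in its native local
    conformation): a reference in which local covalent shielding is
    retained but essentially no tertiary burial remains, so that
    max(0, reference - folded) isolates the area buried on folding.
    """
    coords, radii = canonical_coords(s), s.radii
    out = np.full(len(s.atoms), np.nan)
    for ri, res in enumerate(s.residues):
        ctx = list(res.atom_indices)
        for rj in (ri - 1, ri + 1):
            if 0 <= rj < len(s.residues):
                ctx.extend(s.residues[rj].atom_indices)
        ctx = np.asarray(ctx, int)
        own = np.asarray(res.atom_indices, int)
        pos = {int(a): k for k, a in enumerate(ctx)}
        vals = _asa_core(coords[ctx], radii[ctx], probe, n_points,
                         targets=np.array([pos[int(a)] for a in own]),
                         canonicalize=False)
        out[own] = vals[[pos[int(a)] for a in own]]
    return out


def reference_polarity(structures: list[Structure],
                       probe: float = DEFAULT_PROBE,
                       n_points: int = DEFAULT_N_POINTS) -> PolarityBaselines:
    """Core and surface polarity-ratio baselines over a set of structures.

    Core ratio: polar over apolar area buried on folding, where per-atom
    burial is max(0, reference ASA - folded ASA). Surface ratio: polar
    over apolar solvent-exposed area in the folded state.
    """
    if not structures:
        raise ValueError("need at least one structure")
    core, surf = {}, {}
    for s in structures:
        folded = structure_asa(s, probe, n_points)
        ref = _reference_asa(s, probe, n_points)
        buried = np.clip(ref - folded, 0.0, None)
        polar = s.polar_mask
        het = s.het_mask
        use = ~het

        def ratio(pol_sum, apol_sum):
            if apol_sum > 0:
                return pol_sum / apol_sum
            return math.inf if pol_sum > 0 else math.nan

        core[s.protein_id] = ratio(float(buried[use & polar].sum()),
                                   float(buried[use & ~polar].sum()))
        surf[s.protein_id] = ratio(float(folded[use & polar].sum()),
                                   float(folded[use & ~polar].sum()))

    def mean_sd(d):
        vals = np.array([v for v in d.values() if np.isfinite(v)])
        if len(vals) == 0:
            return math.nan, math.nan
        return float(vals.mean()), float(vals.std(ddof=0))

    cm, cs = mean_sd(core)
    sm, ss = mean_sd(surf)
    return PolarityBaselines(core, surf, cm, cs, sm, ss)
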