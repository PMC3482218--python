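# Methods

## The model

`lipscan` treats every contiguous L-residue segment of a monomeric chain
as a probe that forms a buried interface with the rest of the protein.
Two scalar properties of that interface are profiled along the sequence
and combined into a calling rule for light interfaces of high polarity
(LIPs), the segments expected to unfold locally.

**Polarity ratio.** For a window split the chain is cut (peptide bonds
left uncapped) into fragment and remainder. Each atom's buried area is
its solvent-accessible surface area (SASA) in its isolated part minus
its SASA in the intact structure, clipped at zero. Atoms with more than
ε = 0.1 Å² buried constitute the interface; their buried areas are
summed by polarity class and

    PR = A_polar / A_apolar.

Polar means element N or O; carbon is apolar; sulfur is apolar by
default and switchable (`sulfur_polar`) because both conventions exist
in accessibility software. If only polar area is buried PR is reported
as +inf (kept in the track, counted as above any threshold by the
caller, excluded from means and correlations); if nothing is buried the
position is missing. Missing values are never interpolated.

**Packing density.** Over the same interface atoms

    rho = sum(V_standard) / sum(V_real),

where `V_standard` is a per-(residue, atom) reference volume from a
ProtOr-style united-atom group-volume table (derived from contacts in
small-molecule crystals) and `V_real` is the atom's cell volume in a
radical-plane (power) tessellation of the structure. Atoms whose cells
are pathological or only closed by the outer clipping box are excluded
from numerator *and* denominator, keeping the two sums consistent. Note
that a global rescaling of the standard-volume table rescales the whole
ρ track and its mean and SD together, so LIP calls are insensitive to
the table's absolute calibration; what matters is profile shape.

**Profiles.** Values are assigned to the probe's 4th residue for L = 8
(and for any L ≥ 7; see design choices), windows slide over the resolved
residues, and windows spanning a chain break (consecutive Cα–Cα distance
> 4.5 Å, or a numbering jump with a physical gap) yield missing values.

**LIP calling.** Candidate intervals are maximal runs of positions with
PR > θ_base = 0.5 (the core baseline) containing at least one seed with
PR ≥ θ_peak = 0.8 (the surface-polarity level). Each candidate must then
be associated with a packing minimum below the protein-specific cutoff
c = mean(ρ) − k·SD(ρ) with k = 2 (population SD over non-missing
positions). Two association modes:

- `strict`: the candidate itself contains a position with ρ < c;
- `wall` (default): the candidate overlaps a *basin* — a maximal
  contiguous run of positions with ρ below the track mean that somewhere
  dips below c.

Wall mode exists because a polar peak can sit on the shoulder of a deep
packing minimum rather than at its center; the strict rule is retained
as the literal definition. Candidates failing the packing test are kept
in the diagnostics with `packing_pass=False` but not reported as LIPs.

**Statistics.** Region contrasts (unstable vs stable, LIP vs non-LIP
positions) use a one-sided Mann–Whitney–Wilcoxon rank-sum test: exact
null enumeration when n1+n2 ≤ 20 and the pooled sample is tie-free,
otherwise a tie-corrected normal approximation (the method used is
recorded in the result). PR–ρ anti-correlation is a Pearson r over
finite paired positions. The folded-state polarity baselines are
computed per structure as core ratio (polar/apolar area buried on
folding, burial = max(0, reference ASA − folded ASA)) and surface ratio
(polar/apolar exposed area of the folded state), summarized as mean ±
population SD over the input set.

## Numerical engines

**SASA** is a deterministic dot-surface method: a fixed golden-spiral
point set (default 960 points) on each expanded sphere (vdW radius +
1.40 Å probe), occluding neighbours found via a KD-tree. Coincident atom
centers are an error. Because the point set is fixed in space, areas
would drift under rigid-body motion of the input; all area computations
are therefore performed in a canonical molecular frame (principal axes,
eigenvalue-ordered, skewness-sign-fixed, right-handed), which makes
every derived scalar invariant to rotation and translation to machine
precision on generic structures (perfectly symmetric inputs fall back to
the centered frame). Burial passes for a window share the whole
structure's frame, so the quadrature error cancels exactly for atoms
whose occluders do not change; only remainder atoms within occlusion
range of the fragment are recomputed.

**Voronoi volumes** come from per-atom halfspace intersections
(radical-plane offsets weighted by r²; unweighted bisectors as a config
mode — the two coincide for equal radii). Cells of surface atoms are
closed by solvent pseudo-sites: exposed surface dots pushed to atom
center + (r + 2.8 Å), thinned to a minimum spacing of 1.5 Å, entering
the tessellation with the water radius 1.4 Å. An outer bounding box
guarantees boundedness; cells still touching that box are flagged
capped-open and excluded from ρ. A site whose power cell is empty
(swallowed) is flagged pathological. The neighbour cutoff for halfspace
construction starts at 8 Å and grows automatically until every cell
vertex is provably inside the searched radius.

**Independent oracles.** The SASA engine is cross-checked against a
dense latitude/longitude quadrature with brute-force occlusion (an
independent code path) and against biotite's Shrake–Rupley
implementation; the tessellation against the analytic cubic-lattice
cell (spacing³), box-volume conservation, and a seeded Monte-Carlo
nearest-power-site integrator; the exact rank-sum p-value against full
enumeration of group labelings; the LIP caller against brute-force
enumeration of all maximal qualifying intervals.

## Parameters

| parameter | default | meaning |
|---|---|---|
| L | 8 residues | probe length; 7–9 give nearly identical profiles |
| probe | 1.40 Å | water probe radius for SASA |
| n_points | 960 | dots per atom; 960 vs 3840 differ < 1 % |
| ε | 0.1 Å² | minimum buried area for interface membership |
| θ_peak | 0.8 | seed threshold (surface-level polarity) |
| θ_base | 0.5 | extension baseline (core-level polarity) |
| k_sd | 2.0 | packing cutoff depth, mean − k·SD |
| packing_mode | wall | minimum association rule (see above) |
| max_gap | 0 | sub-baseline positions bridgeable when merging candidates |
| shell offset | 2.8 Å | solvent pseudo-site distance beyond the vdW radius |
| break threshold | 4.5 Å | Cα–Cα distance defining a chain break |

Radii are Chothia-convention (trigonal C 1.76, tetrahedral C 1.87,
N 1.65, O 1.40, S 1.85 Å) and ship as a TSV (`data/vdw_radii.tsv`),
overridable by editing the table; standard volumes likewise
(`data/standard_volumes.tsv`, group types annotated). Atoms without a
table entry fall back to element-level values with a logged warning and
a per-atom flag.

## Design choices made here

- **Assigned residue for general L**: the 4th residue for any L ≥ 7,
  near-center ⌈L/2⌉ for shorter probes. Assigning the 9-residue probe to
  its 5th residue would lag the 8-residue profile by half a position and
  destroys the inter-window-length agreement that motivates the
  robustness claim; anchoring 7-, 8- and 9-residue probes at the same
  residue keeps their tracks in register.
- **Altloc policy**: highest occupancy, ties to the first altloc letter.
  Residues are canonically ordered by author number + insertion code and
  atoms by backbone-first name order, so profiles are byte-identical for
  atom-order-scrambled input files.
- **Heteroatoms**: excluded by default; `het_policy="environment"`
  admits them as occluders and tessellation sites only — never in window
  fragments, profile positions, or (by default) interface totals.
- **Reference state for the core baseline**: each residue's reference
  ASA is computed in a tripeptide-in-place context (the residue plus its
  two flanking residues in their native local conformation). This keeps
  local covalent shielding while removing tertiary burial, makes a fully
  extended chain bury essentially nothing, and avoids rebuilding
  idealized extended side chains, which is out of scope.
- **Merging rule**: candidates merge when their θ_base extensions
  overlap or touch; `max_gap` > 0 optionally bridges that many finite
  sub-baseline positions (missing values never bridge).

## The synthetic fixtures and what they do (not) show

The generators provide cubic-lattice pseudo-proteins (analytic Voronoi
cells), ideal α-helices (φ = −57°, ψ = −47°) and extended chains built
by natural-extension-of-reference-frame from standard backbone geometry,
antiparallel helix bundles with engineered chain breaks, and planted
PR/ρ tracks with known peak structure. Helix side chains are single
centroids carrying residue-appropriate polarity and size — deliberately
non-physical. Consequences:

- geometric and statistical engines are validated exactly (oracles,
  closed forms, enumeration), independent of chemical realism;
- profile-level behaviour (window robustness, anti-correlation,
  planted-peak recovery) is demonstrated on bundles whose polarity
  features are ~10 residues wide, i.e. LIP-scale. On structures whose
  polarity varies faster than the probe length the window-length
  agreement degrades, as it must — averaging windows cannot resolve
  sub-window features;
- absolute PR and ρ levels of centroid fixtures are *not* those of real
  proteins (centroid "side chains" under-represent apolar surface, so
  fixture PR baselines are high and the synthetic-set core baseline
  drifts above the ~0.5 of real protein cores). Published-value checks
  therefore require real coordinate files (tests/data/real_pdb/) and are
  reported as failures, with an explanatory message, when those files
  are not present.

## Problem sizes and determinism

Default test and validation runs use 20–28-residue helices, three-helix
bundles (~84 residues, ~420 atoms), 10⁵–10⁷ Monte-Carlo samples, and a
few hundred random tracks; a full scan of a 28×3 bundle takes a few
seconds per window length on one CPU. All randomness (Monte-Carlo
integration, random tracks, invariance transforms) is confined to
explicitly seeded generators; the pipeline itself contains no RNG and
repeated runs are byte-identical.

## Known limitations

- Single chain, first model only; no symmetry expansion, no structure
  repair, no NMR ensembles.
- The SASA and volume algorithms are numerically different from the
  slice-based and vertex-convention choices of classic accessibility /
  volume programs (differences at the 1–2 % level); profile *shape* is
  robust to this, absolute ρ calibration is not guaranteed.
- The exact rank-sum path refuses ties (falls back to the corrected
  approximation); no multiple-testing correction is applied — one
  pre-specified contrast per protein.
- BED output uses numeric author numbering; insertion codes appear only
  in the TSV outputs.
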