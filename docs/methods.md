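# Methods

## Scope and data model

The package analyses replicate protein–ligand MD trajectories supplied as
multi-model PDB (or plain XYZ) together with a lightweight description of
what to analyse: atom selections for the protein fit set, the ligand, the
three plane anchors and the probe atoms; torsion definitions as ordered
atom quadruples; and labelled proton pairs. Coordinates are always Å and
times ps; atom indices are 0-based internally while residue ids stay
1-based as in the source files. PDB parsing/writing is delegated to
biotite and the selection language to MDAnalysis; neither carries a time
axis for multi-model PDB, so frame times are filled as
`model_index × default_dt` (default 10 ps, the snapshot cadence used
throughout).

Analysis windows are half-open `(start, end]` on a stride grid. This
convention makes a 20 ns run sampled at 10 ps yield exactly 1,700 frames in
the (3 ns, 20 ns] window, and five replicates pool to 8,500 conformations —
the canonical pooled-analysis size for this system. The equilibration cut
(default 3 ns) and stride (default 10 ps) are configuration values, as is
the projection window start, since published analyses of this system have
used both 3 ns and 4 ns starts for different figures.

## Superposition and deviation metrics

Rigid superposition is the closed-form Kabsch SVD fit with the determinant
correction for proper rotations; degenerate (collinear, or fewer than 3
point) inputs raise rather than return an arbitrary rotation. RMSD series
superpose each frame on the fit selection before measuring over the metric
selection; RMSF measures each selected atom's root-mean-square deviation
from its position in the reference structure (the *starting* structure by
convention here, with the trajectory-mean variant as an option) after
per-frame superposition. Both are unweighted by default with optional
weights, since ligand-dominated selections make mass weighting a secondary
effect. For isotropic per-coordinate jitter σ the expected RMSF is σ√3,
which the tests use as a closed form.

## Plane projection

The projection solves the 3×3 linear system equating the line through the
probe with the plane through the three anchors. The returned `(u, v)` are
coordinates in the oblique basis `(p1 − p0, p2 − p0)` — dimensionless
multiples of the two rim edges, not Å. The projection direction is the
plane normal by default (orthogonal projection); a three-atom direction
selection instead projects along the normal of the plane those atoms span
per frame (e.g. the ligand's aromatic plane). Orthogonal projection was
chosen as the default because it is uniquely defined by the anchor
selection alone, and the tilted variant differs only by a shear of the
`(u, v)` scatter. Singularity is declared when the row-normalised system
determinant falls below 1e-10; parallel lines raise a dedicated error (and
are counted and excluded in time-series mode), never returned as NaN.
Every returned solution is checked against both parametric forms at 1e-8 Å.

## Stability measures

Contacts are counted per frame as (a ∈ A, b ∈ B) pairs within the cutoff
(default 3.5 Å), via a KD-tree with an exhaustive-scan oracle in the tests.
All atoms count by default — the counting is deliberately element-agnostic,
with a heavy-atom flag — because absolute counts depend strongly on whether
hydrogens are included and should be compared only within one convention.
The COM-drift series reports the inter-group centre distance minus its
value in the reference structure; the centre is the unweighted centroid by
default (analysis inputs often lack masses) with a mass-weighted mode.

## Dihedral sampling

Torsions use the atan2 formulation with IUPAC sign convention, range
(−180°, 180°]. Histograms use 36 circular bins of 10°, with the starting
value's bin recorded for plotting. The cross-replicate classification makes
the verbal notions operational: the pooled (replicate-averaged) density is
smoothed by a circular 3-bin moving average; basins are contiguous circular
regions above 5% of the pooled maximum; a replicate samples a basin when it
holds at least 1% of that replicate's frames. Zero replicates missing any
basin → *well sampled*; exactly one → *mostly well sampled*; two or more →
*poorly sampled* (also phrased "possible sampling problem" in the
literature). All four thresholds are exposed in configuration; the defaults
were chosen once as the smallest values that make the three labels
unambiguous on the constructed test mixtures.

The cos χ autocorrelation uses the biased estimator over all valid pairs,
normalised to C(0) = 1, with the mean subtracted by default (the
statistically standard autocovariance; a no-demean mode is provided for
tools that correlate the raw cosine). The maximum lag is capped at half the
series span. The relaxation time is the τ of a least-squares fit of
exp(−t/τ) — whose analytic time integral is τ itself — with the numeric
trapezoidal integral of the raw ACF reported as a secondary estimate. A
fitted τ above 100× the window is reported as "exceeds window" rather than
as a converged number: a torsion trapped in one well for the whole run has
no resolvable relaxation time at that window length. For a symmetric
two-state jump process with rate k the ACF is exp(−2kt), so the planted
τ = 1/(2k) gives an exact recovery target.

## Clustering and interconversion

Clustering is the greedy neighbour-count algorithm: repeatedly extract the
pool member with the most neighbours within the cutoff together with those
neighbours, then renumber clusters by size. The published description of
this family of algorithms is ambiguous between random and
most-neighbours seeding; this implementation is deterministic — on
neighbour-count ties the lowest original index wins — because reproducible
partitions matter more than faithfulness to an unspecified tie rule, and a
seeded randomised variant is available. Equivalence with an independently
written brute-force greedy reference (same tie rule) is asserted on
instances up to n = 30.

Conformation RMSD for MD clustering is computed on ligand atoms in the
common pocket frame (no per-pair superposition) by default, appropriate
when frames are already superposed on the protein; per-pair Kabsch
superposition is the option for internal-geometry clustering. Occupancy
timelines split the pooled assignment back per replicate; interconversion
counts consecutive-frame transitions among the top-k clusters (k = 4 by
default, matching the top-cluster analyses this mirrors), and a replicate
"interconverts" when any off-diagonal count is positive.

Docked-pose ranking applies the same clustering at 2.0 Å and ranks clusters
by mean docking score, flagging clusters within 2.5 kcal/mol of the best
mean as indistinguishable — the score resolution below which docking cannot
discriminate binding modes. Orientation is the cosine between the mimetic's
N→C anchor vector and the reference helix N→C axis: ≥ +0.3 parallel,
≤ −0.3 anti-parallel, otherwise perpendicular. The ±0.3 band (≈ ±72.5° from
the axis) cleanly separates the three planted orientation families while
leaving a wide perpendicular corridor for genuinely non-helix-like poses.

## NOE averaging

Ensemble distances are summarised as r_eff = ⟨r⁻³⟩^(−1/3), the
short-distance-dominated average appropriate for qualitative NOESY
comparison; an r⁻⁶ mode exists for intensity-weighted conventions but is
not the default. Jensen's inequality bounds r_eff between the minimum and
the arithmetic mean of the inputs, asserted property-style. The presence
cutoff defaults to 4.0 Å, a typical NOE observation range, and is exposed
in configuration.

## Synthetic generators

The generators produce data with exactly the statistical structure each
analysis assumes, plus the ground truth needed to close the loop:

- **Rotamer jumps** — a continuous-time Markov chain over torsion wells,
  sampled on the frame grid via exponential clocks, plus truncated Gaussian
  angular jitter (σ = 4°). Defaults in tests use the two-state symmetric
  process at k = 0.005/step over 10⁵ steps, the regime where the planted
  τ = 100 steps is recoverable to a few percent on a 20-seed aggregate.
- **Pocket trajectories** — a static toy scaffold (a pocket-rim ring of
  pseudo-Cα atoms including three anchors carrying the Tyr 56 / Met 62 /
  Val 93 identities, so real-system selection expressions resolve) plus a
  ligand hopping between planted conformations with 0.3 Å truncated
  Gaussian jitter. Default planted centres are 4 Å apart — comfortably
  above the 3σ separability floor, which is checked and recorded in the
  output metadata rather than enforced. Trajectories default to 2,001
  frames at 10 ps (a 20 ns run including the initial frame), so the
  (3 ns, 20 ns] window holds 1,700 frames.
- **Harmonic fluctuations** — an idealised helical backbone trace with
  per-atom isotropic jitter, truncated at 4σ, for RMSF closed-form tests.
- **Pose sets** — rod-like mimetics with planted parallel / anti-parallel /
  perpendicular orientations, within-group RMSD below the cluster spread,
  and optional planted scores. A labelled nine-conformer variant emulates
  the canonical docked starting set (conf 1, 2, 3, 7, 8 anti-parallel;
  conf 4, 9, 10, 11 parallel); its coordinates are synthetic stand-ins, not
  docking output.
- **Ring ensembles** — an amide proton near a ring whose H2/H6 protons
  swap proximity as the ring torsion rotates; uniform torsion (free
  rotation) versus a 15° wobble about 0° (locked) reproduces the two
  qualitative NOE patterns.

What passing tests on these generators shows — and what it does not: the
analyses provably recover planted cluster structure, jump rates, fluctuation
amplitudes, orientations and rotational regimes under Gaussian noise and
Markovian dynamics. Real trajectories add slow non-Markovian couplings,
anisotropic fluctuations, solvent effects and force-field bias that no test
here probes; absolute published values from real MD runs (contact counts,
specific NOE distances, specific cluster counts) are reproducible only with
those trajectories, and the package makes no claim to reproduce them from
synthetic inputs.

## Numerical choices and limitations

- Kabsch degeneracy: centered rank < 2 (collinear) raises; determinant
  correction guarantees proper rotations.
- Line–plane singularity at row-normalised |det| < 1e-10.
- Angle branch point: torsions and histogram bins use (−180°, 180°], so
  +179.9° and −179.9° land in circularly adjacent bins with no wrap
  artifact.
- Pairwise RMSD matrices are dense O(n²); pooled clustering at the full
  8,500-frame scale is memory-heavy in the no-superpose mode (~0.6 GB) and
  slow with per-pair superposition — subsample or stride the pool first.
  Tests and examples use pools of a few hundred conformations, which the
  planted-structure recovery results show is ample for these analyses.
- The pipeline removes partial outputs on stage failure and is
  byte-reproducible for identical config and inputs; plots are deliberately
  excluded from the determinism guarantee (none are produced by default).
- Binary trajectory formats (XTC/DCD) are out of scope; convert to
  multi-model PDB externally. PBC unwrapping and solvent handling are out
  of scope: inputs are assumed solvent-stripped and whole.
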