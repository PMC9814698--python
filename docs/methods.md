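# Methods

This note documents the models and procedures implemented in `peptraj`,
the choices made where the design was genuinely open, and what the
synthetic-data generators do and do not emulate.

## Coordinate model and conventions

Structures are held as a `Topology` (ordered atoms; author residue
numbering is authoritative — the 15-mer substrate peptides span residues
29–43 with the target lysine at 36) plus per-frame coordinate arrays in
ångströms.  Frame times are `frame_index × frame_interval_ps` with a
20 ps default write interval.  Multi-model PDB is the baseline
interchange format (read/written through biotite); DCD/XTC are read
through mdtraj behind the same contract.  Internally all indices are
0-based with half-open ranges; only author numbers appear in criteria
and outputs.  Alternate locations beyond the first are dropped with a
warning; insertion codes are not expected in the supported inputs.

## State detectors

**Hairpin.**  A frame is a hairpin iff stem-loop G33 Cα–P38 Cα < 7 Å and
end-to-end A29 Cα–P43 Cα < 15 Å.  Both inequalities are strict, reading
the thresholds literally as "< 7" and "< 15"; the boundary behaviour is
pinned by tests.  Lifetimes are maximal runs of hairpin-true frames; a
run still open at the last frame is closed there.

**S<sub>N</sub>2 TS-like.**  A complex frame is TS-like iff
d(Nε, methyl C) < 4 Å (strict), the attack angle Cδ–Nε···C lies in the
closed interval [79°, 139°], and the Nε···C–S angle lies in [150°, 180°].
Distance thresholds are strict and angle windows closed — the printed
"± 30°" edges are inside.  The per-simulation "TS count" is the number
of frames satisfying all three criteria; the alternative
entry-event reading is available as `event_table(min_len=1)`.
Long-lived events use `min_len = 8` frames (160 ps).

Relaxing any TS threshold can only add frames, never remove them; this
monotonicity is tested as an invariant.

## Superposition and clustering

Superposition uses the Kabsch algorithm: SVD of the cross-covariance
with determinant correction so the rotation is proper.  An independent
quaternion-method implementation serves as the test oracle.  Pairwise
RMSD between conformers is computed after per-pair superposition over
the fixed backbone set N, Cα, C (45 atoms for a 15-mer); Cβ is excluded.

Clustering is a k-hybrid scheme re-implemented here: farthest-point
(k-centers) seeding — the first centre drawn from the seeded generator,
subsequent centres maximally distant from the chosen set — followed by
up to 10 k-medoids sweeps, stopping when medoids are stable or the
summed point-to-medoid RMSD stops decreasing (the objective is monotone
per sweep).  k is fixed (2 or 3 in practice) rather than radius-derived.
All tie-breaks take the lowest pooled index, and final cluster labels
are ordered by descending size, so results are deterministic given the
seed.  Pooled sets larger than `max_exact` (default 4 000) are clustered
through a landmark approximation — a seeded random subset is clustered
exactly and all conformers assigned to the nearest medoid — and the
model is flagged accordingly; exact mode remains available for tests.
The medoid ("centroid structure") of a cluster is the member minimizing
summed RMSD to its co-members, verified against exhaustive search.

Subset robustness re-clusters random subsets (50/30/10 % by default),
matches subset clusters to full-run clusters by nearest medoid RMSD, and
reports medoid displacement and composition deltas.  Condition
enrichment across independent clustering runs uses the equal-variance
two-tailed t-test.

## Contact analysis

Two residues are in contact in a frame when any pair of their heavy
atoms is closer than 4.5 Å (strict; neighbour search via a k-d tree,
validated against an O(n²) scan).  The stated "4.5 Å³ sphere" in the
protocol we implement is read as a typographical slip for a 4.5 Å
radius, the only dimensionally consistent reading.  Within a chain the
two sequence neighbours on either side are ignored; peptide–enzyme pairs
are never excluded.  Contact frequencies are fractions of frames;
cross-condition pairs align by author residue number (A/R31 merge onto
residue 31) so profiles from the two peptides are directly differenceable.
The difference filter keeps pairs with |Δ| strictly above 0.35,
interpreting "over 35 %" as an absolute frequency difference (the
relative-change alternative is a config switch).  TS-conditioned
profiles restrict the frame set by a boolean mask from the TS detector.
The distance-to-reference analysis measures, per peptide residue, the
mean distance between the residue's backbone centroid and a reference
point inside the enzyme (Cα of residue 1625 by default, configurable).

## Steered-association forces

Two distance-dependent terms between mass-weighted group centres of mass:

- pulling, k = 0.5 kJ mol⁻¹ Å⁻²: force magnitude k·d along the
  inter-COM axis drawing the lysine amine group (NZ, HZ1, HZ2) towards
  the cofactor methyl group (SD, CE, H10); energy +½k·d²;
- repulsion, k = 0.3 kJ mol⁻¹ Å⁻²: the same magnitude with opposite
  sign between the peptide terminal groups (A29 N/CA/C and P43
  CG/CD/OXT); energy −½k·d².

Forces are distributed over group atoms by COM mass weights and satisfy
action–reaction exactly; energy–force consistency is verified by central
differences.  The repulsive term follows the stated formula
("−0.3 × distance"), whose magnitude *grows* with separation, although
the accompanying prose describes a force that weakens with distance;
the contradiction is surfaced here rather than resolved, and a
short-range-only variant (`repulse_distance_cap`) is provided for the
prose reading.  The pulling-group residue is taken as K36 — the one
mention of K37 in the protocol text is treated as a typo, since every
other statement names the target lysine 36.

Unfolding analysis tracks per-frame backbone RMSD to an extended
reference and the N–C distance (backbone N of residue 29 to backbone N
of residue 43), truncated at the first minimum-RMSD frame.  A replicate
counts as unfolding when RMSD at the argmin frame is below frame 0 and
as end-separating when the N–C distance there exceeds frame 0.

## Two-state FRET melt model

Transfer efficiency E(r) = R₀⁶/(R₀⁶ + r⁶) with R₀ = 33 Å
(EDANS/Dabcyl).  The unfolded and hairpin states carry effective
single distances r_U and r_H (defaults 27 Å and 12 Å; r_H < r_U), and
the hairpin fraction at absolute temperature T is
f_H = 1/(1 + exp(ΔG/RT)) with ΔG = ΔH°′ − TΔS°′ treated as
temperature-independent; R = 8.314 × 10⁻³ kJ mol⁻¹ K⁻¹.  Intensity is
scale · [f_H(1 − E(r_H)) + (1 − f_H)(1 − E(r_U))]: donor quantum yield
and instrument factors collapse into one scale parameter because only
relative intensities are observed.  Curves are stored in °C and
converted internally.  Endpoint normalization scales the second curve so
both coincide at the highest shared temperature, where conformational
differences have melted away.

Fitting estimates (ΔH°′, ΔS°′, scale) with R₀, r_U, r_H held fixed:
multi-started Levenberg–Marquardt least squares (four fixed starts), and
a residual bootstrap for percentile confidence intervals.  Bootstrap
residuals are inflated by √(n/(n−p)) (p = 3) to undo the variance
shrinkage of fitted residuals on short curves.  A curve with no
temperature dependence leaves ΔH°′/ΔS°′ unidentifiable and is flagged
rather than raised.  Numerically, f_H saturates to exactly 0 or 1 in
double precision once |ΔG/RT| exceeds ≈ 36, although the model value is
strictly inside (0, 1).

## Synthetic-data generators

The generators exist so every analysis stage has labelled ground truth.

**Templates.**  Backbone-only (N, Cα, C) 15-mers with 3.8 Å consecutive
Cα spacing.  The extended template is a straight chain (stem-loop 19 Å,
end-to-end 53.2 Å — violating both hairpin criteria); the hairpin
template is two antiparallel strands 5 Å apart with the target lysine at
the apex (stem-loop 6.3 Å, end-to-end 5 Å).  Backbone N and C atoms are
placed along the local chain tangent at bond-length offsets; no side
chains beyond the explicitly needed probe atoms.

**Solution ensembles.**  Per frame, a two-state Markov chain picks the
template; isotropic Gaussian noise (default 0.3 Å per coordinate) is
added independently per atom and frame.  Dwell times are geometric; a
prescribed stationary hairpin fraction and mean dwell determine the stay
probabilities.  Defaults mirror the study's solution design — 50
replicates × 3 500 frames (70 ns at 20 ps writes) per peptide — though
tests and the acceptance script run smaller ensembles (10–15 replicates,
200–900 frames) to keep desk-scale runtimes; recovery tolerances use the
Markov-chain standard error, inflated by the lag-1 autocorrelation
(1+ρ)/(1−ρ).

**Complex ensembles.**  Topology: peptide backbone, lysine-36 probe
atoms (CD, NZ, HZ1, HZ2), P43 terminal group (CG, CD, OXT), a cofactor
pseudo-residue (SD, CE, H10), and an enzyme stand-in of 12 three-atom
pseudo-residues named after peptide-contacting positions (including
1625, the distance-reference marker).  TS-like dynamics are a two-state
chain with geometric dwells; in TS frames the probe geometry satisfies
all three criteria exactly (3.5 Å, 109°, 180°), in non-TS frames the
distance criterion is violated (6 Å).  Defaults mirror the complex
design: 15 replicates × 5 000 frames (100 ns at 20 ps).  Residue-residue
contacts are plantable per pair at a target frequency, or tied to
TS-labelled frames for conditioned-profile tests.

**Unfolding ensembles.**  A planted fraction of replicates interpolates
linearly from hairpin to extended; the rest relax from a slight
hairpin–extended blend back to the pure hairpin, so their RMSD to the
extended reference rises monotonically and neither unfolding signature
appears.  This makes the planted morph fraction recoverable by the
trace classifier at binomial precision.

**What the generators do not emulate:** physical dynamics (no force
field, solvent or inertia), realistic conformational heterogeneity
within a state, correlated atomic fluctuations, or the absolute MD-scale
statistics of the original ensembles (cluster compositions 66–70 %,
docking successes 40/55 of 100, per-simulation TS counts 1117/305).
Passing tests therefore demonstrate that the analysis operators are
correct and self-consistent — detectors recover planted labels,
clustering recovers planted mixing, fits recover planted thermodynamics
— not that the package reproduces those MD-scale numbers, which would
require the original microsecond trajectories.

## Statistics

Equal-variance two-tailed t-test with pooled variance and
df = n₁ + n₂ − 2; zero pooled variance returns p = 1 (equal means) or
p = 0 (unequal, flagged).  SEM uses the n−1 standard deviation.
Binomial tails are exact sums; two-sided doubles the smaller tail and
caps at 1 (the spreadsheet convention).  No multiple-testing correction
is applied by default, matching the source workflow; a Bonferroni
option exists in config.  All randomness flows through seeded
`numpy.random.default_rng` generators, and the report layer echoes every
seed it uses.

## Known limitations

- Periodic-boundary imaging is not performed; analysis frames are
  assumed whole-molecule.
- The selection language is conjunctive only (no `or`/negation).
- Landmark clustering is an approximation; its assignment error is
  bounded only empirically (tests require ≥ 98 % agreement with planted
  labels on separated data).
- mmCIF output, bond perception and weighted RMSD are out of scope.
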