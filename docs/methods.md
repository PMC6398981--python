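# Methods notes

This note records the models, conventions and numerical choices behind each
analysis stage, what the synthetic generators do and do not emulate, and the
design decisions taken where more than one defensible convention exists.

## Coordinate handling

Structures are parsed with gemmi (PDB and mmCIF; model 1 only of multi-model
files). Author residue numbering is the universal coordinate system: all
residue references (D56, Q378, …) are author numbers as deposited, and no
renumbering is performed. Altloc duplicates are collapsed to the
highest-occupancy conformer, ties broken by the lexicographically smallest
altloc — deterministic and standard. Waters (HOH/WAT/DOD) and metals are kept
as hetero residues so the coordination stage can address them.

Cross-structure residue matching uses (residue number, insertion code) within
the selected chain pair, not sequence alignment. This is correct when
depositions of the same protein share author numbering (the usual case for a
multi-conformation series from one lab); cross-homolog comparisons need an
external alignment and are out of scope for the matcher.

## Superposition and per-residue deviations

`kabsch_superpose` solves the classic orthogonal-Procrustes problem via SVD of
the 3×3 cross-covariance, with the determinant correction that forbids
reflections. All matched pairs contribute — there are no outlier-rejection
cycles — so large local motions (a swinging TM1a) inflate the global RMSD
rather than being discarded; this matches how whole-structure RMSDs between
transporter conformations are conventionally reported. Degenerate inputs
(fewer than 3 pairs, collinear point sets, detected as a rank-deficient
cross-covariance with second singular value ≤ 1e-10 of the first) raise.

Per-residue deviations are distances after applying the fitted transform; by
construction their RMS equals the global RMSD, and the tests enforce this to
1e-9.

`segment_rotation_angle` measures a helix swing as the angle between the
segment's first principal axes in the two (already co-framed) structures.
PCA axes carry a sign ambiguity; it is resolved by orienting each axis along
the segment's N→C endpoint vector, and the result is folded into [0°, 90°].
The reference frame is the caller's choice; the natural default is the
all-common-Cα superposition, and a scaffold-only frame can be obtained by
superposing on a subset first. Segments need at least 4 Cα in both traces.

## Coarse-grained DDM

`distance_matrix` / `difference_matrix` / `coarse_grain` implement the
superposition-free analysis of internal rearrangement. Conventions:

* Difference matrices are restricted to the label intersection of the two
  structures (no NaN padding — padding silently changes RMS denominators when
  one structure models fewer residues).
* Coarse pooling is C(s,t) = √(mean over a∈s, b∈t, a≠b of Δ(a,b)²); diagonal
  blocks average over unordered within-segment pairs, and self-pairs are
  excluded everywhere since they are structural zeros that would dilute
  diagonal blocks. A single-residue segment yields a 0 diagonal entry.
* Segment definitions are data, not code: a TSV of (name, chain, start, end)
  rows, multiple rows per name allowed, 1-based inclusive author numbering.
  The packaged 14-segment DraNramp file is an approximate stand-in (marked
  synthetic in its filename) anchored on the conserved helix-breaking
  elements — the TM1 DPGN motif (56–59), the TM6 MPH motif (230–232) and the
  TM10 proline (386) — with typical TM spans; users with the deposited files
  should derive boundaries from their helix annotations instead.
* Heatmaps use a perceptually uniform colormap anchored at 0 = darkest, so
  stationary segment pairs read as dark.

The brute-force double-loop oracle in the tests pins the pooling semantics to
1e-12; rigid invariance of the whole pipeline is enforced to 1e-9 over random
bundles and random proper rigid transforms.

## Coordination spheres

Sphere membership: all O/N/S atoms within the cutoff of a unique center atom
(carbon and hydrogen never coordinate); waters included by default. The 3.5 Å
default cutoff captures contacts out to ~3.4 Å, which moderate-resolution
studies routinely count as coordinating. A bidentate carboxylate contributes
one entry per oxygen; `ligating_residues` reports unique residues separately
so both the atom-level coordination number ("seven ligands") and the residue
count are available. Selector mini-syntax: `chain/resnum/resname/atomname`
with `*` wildcards and `|` alternatives; a single bare field matches residue
name or element. Where a residue offers two plausible contact atoms (Gln
sidechain O vs N), distances are reported as the minimum over the
alternatives, which is the convention adopted for all prose-style
"residue-to-metal" distances.

## Conservation profiling

Percentages use all sequences in the denominator, with gap as its own
category, so the percentages of the 20 amino acids plus gap sum to 100 at
every column. Integer percentages round half-up. Motif and length filters act
on the ungapped, uppercased sequence ('.' and '-' are both gaps; lowercase
insert states are uppercased), with a 400–600 residue default length window —
the standard fragment filter for a ~440-residue transporter family. The
reference record is located by id substring (default patterns `Q9RTP8`,
`DraNramp`), overridable. Whether published percentages excluded gap-only
columns or rounded half-even is generally unknowable; comparisons against
printed integers should allow ±1 point.

## Transport quantification

* **Nernst**: ΔΨ = (RT/F)·ln([K⁺]out/[K⁺]in), reported in mV,
  inside-relative; ≈ ±59.16 mV per decade at 298.15 K.
* **Fura-2**: [M] = K_d·β·(R−R_min)/(R_max−R). K_d is metal- and
  condition-specific and must be supplied (no silent default). Ratios below
  R_min clamp to zero with a warning; at or above R_max the dye is saturated
  and the conversion raises.
* **Quench mode** (for Mn²⁺/Co²⁺, which quench both Fura-2 channels): the
  fraction quenched is averaged over both channels and normalised to the
  maximum quenching observed in the post-ionomycin plateau; whether to
  average or use a single channel is an instrument-level choice, exposed by
  simply passing a two-identical-channel trace when needed.
* **BCECF**: pH = pK_a + log₁₀((R−R_min)/(R_max−R)) with pK_a default 6.98;
  the channel-ratio orientation (rising or falling with pH) is a calibration
  flag, since instrument conventions differ. R_min/R_max are per-experiment
  calibration inputs.
* **Net proton import**: every imported proton is absorbed by internal buffer
  or dye, so net import equals the summed increase in protonated buffer + dye
  between the initial and final pH (protonated = C/(1+10^(pH−pKa)) per
  monoprotic species). Defaults: 0.5 mM MOPS (pK_a 7.20 at 25 °C) + 150 µM
  BCECF (pK_a 6.98) — the internal composition of the assay this stage
  models. Temperature corrections of pK_a are out of scope. The function is
  exactly antisymmetric and path-additive.
* **Initial rates**: OLS slope with standard error over (t₀, t₀+window],
  window default 30 s — short relative to the curvature of an uptake trace,
  long enough for a stable slope at 1 s sampling. At least 3 points required.
* **Michaelis–Menten**: unweighted nonlinear least squares
  (scipy `curve_fit`) of v = V_max·S/(K_M+S) with positivity bounds,
  initialised from the data (V_max ≈ max v, K_M from the half-max crossing);
  SEs from the covariance diagonal. Unweighted least squares matches common
  spreadsheet/numeric workflows. Anomalous high-substrate points (substrate
  inhibition) are handled by explicit exclusion, recorded in the fit result —
  no automatic outlier detection.

## Synthetic generators

`make_helical_bundle` uses ideal α-helix Cα geometry (rise 1.5 Å/residue,
100°/residue twist, 2.3 Å Cα helix radius — consecutive Cα ≈ 3.8 Å apart),
with helices antiparallel on a ring. This is sufficient for exercising
distance, superposition, and DDM machinery exactly; it does not emulate
loops, sidechains, helix kinks, or a membrane, so passing geometry tests
says nothing about parsing quirks of real depositions (covered instead by
the hand-written PDB fixtures and, when fetched, the deposited files).

`make_msa` produces ungapped alignments with exact per-column counts
(frequency mode rounds expectations, assigning the remainder to the most
frequent residue) and motifs written into every record; real alignments add
gaps, fragments and phylogenetic correlation, none of which matter for the
counting semantics under test.

`simulate_trace` forward-models: metal mode integrates uptake at constant
external substrate (internal accumulation is linear at rate
v = V_max·S/(K_M+S), capped below dye saturation), maps concentration to
ratio via the inverse calibration and emits channels with that ratio;
proton mode prescribes an exponential pH relaxation; quench mode a linear
ramp to full quenching at ionomycin. Noise is independent multiplicative
Gaussian per channel — no photobleaching, drift, or mixing artifacts. Ground
truth series are returned alongside every trace, and the seed changes only
the noise realisation.

Problem sizes used in the validation runs (50 random bundles for rigid
invariance, 30-residue/3-segment oracle instances, 100-replicate kinetics
recovery at σ = 3% with 8 substrate concentrations spanning K_M/10–10·K_M)
were chosen so each study completes in seconds while leaving the medians
stable to well under the tolerance being checked.

## Known limitations

* Residue matching by author number cannot compare homologs with different
  numbering; an alignment-based matcher is the obvious extension.
* The packaged 14-segment definition is approximate (see above); qualitative
  segment-level conclusions on real depositions should be checked against a
  structure-derived segmentation.
* Rotation angles are folded into [0°, 90°]; genuine swings beyond 90° are
  reported as their supplement.
* The kinetics fit is single-dataset; no global multi-trace or weighted
  fitting, and substrate inhibition is excluded, not modelled.
* Multi-model (NMR-style) files contribute only model 1; no symmetry or
  assembly expansion.
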