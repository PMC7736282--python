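# Methods

This note documents the models, conventions and numerical choices behind
`mtasekit`, in the spirit of a methods appendix: what each stage assumes,
which knobs matter, and what the synthetic tests do and do not demonstrate.

## Active-site shells

A structure is reduced to heavy atoms (hydrogens are normally absent from
crystal structures); waters, other heteroatoms and alternate location B are
dropped by default, altloc A kept.  "Side chain" means every heavy atom
outside {N, CA, C, O, OXT}.

Shells around a focal (catalytic) lysine:

* **Shell 1** — residues with at least one side-chain heavy atom within
  `first_cutoff` (default 4 Å) of *any* side-chain heavy atom of the focal
  residue.  A `focal_atom` flag restricts the focal selection to one named
  atom (e.g. Nζ), the convention used for contact lists around a terminal
  amine.
* **Shell 3** — residues whose nearest side-chain heavy atom lies more than
  `third_min` (default 6 Å) from the focal reference atom (Nζ for lysine).
* **Shell 2** — the remainder.  Two constructions are provided and
  labelled, because an intermediate shell has no unique definition: the
  default distance band (4–6 Å from the reference atom) and a graph
  expansion (4-Å neighbours of shell-1 members, excluding shell 1 and the
  focal residue; residues in neither expansion nor shell 3 stay
  unassigned in this mode).

Neighbor search uses a k-d tree and is tested for exact agreement with a
brute-force all-pairs scan, monotonicity in the cutoff, and invariance
under global rotation + translation.

Because no structure files ship with the package, the structure tests run
on generated toys and on a *synthetic active-site mimic*
(`synthetic.gen_activesite_mimic`): hand-placed, non-crystallographic
coordinates built so that the shell assignment reproduces the contact
lists reported for the vaccinia enzyme (first shell of K175 =
{D138, E207, R209}; 4-Å neighbours of K41's Nζ =
{L42, E207, Q198, A201}).  Passing these tests shows the geometry engine
implements the definitions correctly; it does not re-derive those lists
from the real crystal structure, which requires the PDB file as input.

## Sequence-similarity networks

The internal pairwise route aligns locally under BLOSUM62 with affine gaps
(open 11, extend 1) via Biopython's `PairwiseAligner` and converts scores
to E-values with the extreme-value formula `E = K·m·n·e^(−λS)` using the
gapped BLOSUM62-11-1 constants (λ = 0.267, K = 0.041).  This reproduces
the behaviour of an all-versus-all protein BLAST at desk scale; externally
computed 12-column tabular hits are accepted as the faithful route for
large families.  Percent identity is counted over aligned columns
(including gap columns in the denominator), matching the BLAST `pident`
convention.

Network construction: reciprocal hits are deduplicated keeping the lower
E-value; an edge requires `e_value < threshold` *strictly* (the boundary
value 1e-30 itself yields no edge); isolated nodes are retained and
connected components labelled.  Sub-networks report the median pairwise
identity of member hits.  MSA position mapping converts a 1-based ungapped
reference position to its alignment column; logo probabilities are
normalised over non-gap rows with the gap fraction reported separately
(all-gap columns are flagged, not silently zeroed).

## Thermal unfolding

Emission spectra are reduced to the barycentric mean
λ_bcm = Σλ·I(λ)/ΣI(λ), the intensity-weighted mean emission wavelength.
Melt curves are fitted by least squares to

* single: `I_N + (I_D − I_N)/(1 + exp((T_m1 − T)/a))`
* two-transition:
  `I_N + (I_2 − I_N)/(1 + exp((T_m1 − T)/a)) + (I_D − I_2)/(1 + exp((T_m2 − T)/b))`

with I_N/I_D the native/denatured baselines (nm), I_2 the intermediate
baseline, T_m1 < T_m2 the midpoints (°C, labels swapped if needed) and
a, b > 0 the cooperativity factors (°C).

Initialisation is multi-start: baselines from the mean of the first/last
10 % of points, midpoint candidates at the steepest-slope temperature
± {0, 5, 10} °C (pairs of candidates for the double model), a = b = 2 °C;
the lowest-RSS solution wins.  A fit is flagged unconverged — never
silently returned — when its total amplitude |I_D − I_N| is below 0.5 nm
(no resolvable transition; flat curves land here), when either step of the
double model has amplitude below 0.5 nm (a spurious split of one
transition), or when T_m1 leaves the observed temperature range.

Model selection uses small-sample-corrected AICc with an RSS floor of
10⁻⁶ nm RMS, so exact fits compare on parameter count rather than on
machine-precision residuals.  The two-transition model is preferred only
when it improves AICc by more than 2 units (the usual substantial-support
margin); ties and marginal gains fall back to the single model.  Without
the margin and the per-step amplitude guard, noisy single-transition melts
are occasionally split into two spurious transitions.

The unfolding red-shift is I_D − I_N from the fitted baselines by default;
a raw mode averages the first/last 10 % of the bcm trace instead, for
curves where baseline fitting is doubtful.  Replicates are fitted
independently and summarised as median + range.

## Coupled-assay activity

The initial rate is the OLS slope over an early window of the resorufin
trace.  Window choice is two-stage: (1) trailing saturation is trimmed by
cutting at the first sliding 5-point window whose local slope falls below
20 % of the steepest local slope; (2) within the remaining rise, the
longest prefix (≥ 5 points) with R² ≥ 0.98 is used.  Stage (1) exists
because the R² criterion alone tolerates several post-saturation points
and biases the slope low on saturating traces.  If no window qualifies the
first five points are used with a warning.  Zero-variance traces count as
perfectly linear (rate 0).

Activity ratios subtract the knock-out signal by default,
`(median(v) − median(ko)) / (median(wt) − median(ko))`, with a
no-subtraction mode; the alternative aggregation order (median of
per-replicate ratios) is also reported.  A variant is flagged below the
detection limit when its median rate does not exceed the knock-out median
by more than k·IQR of the knock-out replicates (k = 1, configurable).
With triplicates this flag is itself a noisy measurement: a truly dead
variant evades the flag in roughly a fifth of noise draws at 5 %
coefficient of variation, exactly as in the real assay — borderline
variants may therefore land in the penalty corner rather than the
inactive corner of the classification.  The assay is rejected outright
when the WT median does not exceed the knock-out median.  Saturation
checking flags any reaction whose rate reaches the fully-methylated
positive control's.

## ΔTm epistasis

Effects are WT-referenced: ΔT_m(mut) = T_m1(mutant) − T_m1(WT).  The
additive expectation of a multi-mutant is the sum of its constituent
single-mutant ΔT_m values (triples use the sum of three singles); the
deviation observed − expected is the epistasis, negative meaning worse
than additive.  Singles deviate zero by construction.  Multi-mutants
missing a constituent single are skipped with a warning.  Activity
epistasis is reported on the linear scale and, where all values are
positive, against a multiplicative (log-ratio) null; below-detection
activities enter as 0 and mark the result as a censored bound rather than
a point estimate.

## Trajectory metrics

Internal units are nm and ps (Å inputs from PDB/MDAnalysis are converted).
A hydrogen bond requires donor–acceptor distance ≤ 0.35 nm *and*
hydrogen–donor–acceptor angle ≤ 30°, the common MD-package defaults; both
are configurable.  Donors are N/O/F heavy atoms with an attached hydrogen
(bond table if present, otherwise nearest-polar-atom within 0.125 nm);
acceptors are N/O/F.  Occurrence networks count frames (pooled over
replicates, after an equilibration cut) with at least one
side-chain–side-chain bond per residue pair, in either direction;
intra-residue contacts are excluded.  Per-replicate counts are kept
alongside pooled ones.

The equilibration cut is either an explicit time or automatic: the first
time at which the running mean of the global backbone RMSD changes by less
than 5 % over a 1-ns window.

Side-chain rigidity: each frame is superposed onto a reference frame by
the Kabsch algorithm over a fit selection (whole-protein backbone by
default — deliberately, so that internal side-chain motion shows up in
the metric), then RMSD is taken over the side-chain heavy atoms of the
residue set; glycine in the set is an error.  Medians and interquartile
ranges are reported pooled and per replicate.  The superposition/RMSD
primitive is float64 end to end and is invariant under rigid motion to
~1e-13 nm; going through trajectory files adds the float32 coordinate
precision of the readers (~1e-6 nm), which is far below any physical
fluctuation of interest.

## Synthetic data

Generators are deterministic under a seed and return machine-readable
truth records.

* **Melt spectra** are two-Gaussian mixtures (folded centre bcm_N,
  unfolded centre bcm_D, width 25 nm, 260–460 nm grid) whose mixing
  fraction follows the same sigmoid the fit assumes, so the analytic bcm
  equals the model curve; three-state melts populate the intermediate
  sequentially (weights 1−f₁, f₁(1−f₂), f₁f₂).  Noise is multiplicative
  intensity noise calibrated per spectrum so the induced bcm standard
  deviation equals the requested nm value.  Defaults mirror the measured
  conditions: 25→90 °C at 1 °C steps, folded red-shift 7.8 nm, bcm noise
  0.1 nm.
* **Kinetic traces** are linear-then-plateau with replicate-level rate
  variation and additive measurement noise (both at cv 5 % by default);
  variant rate = ko + ratio·(wt − ko) over a 30-min window.
* **Toy structures** place single side-chain atoms at caller-chosen
  coordinates so neighbor sets are analytically known; the active-site
  mimic (above) is a special case.
* **Toy trajectories** are serine-like residues 1.2 nm apart with
  per-atom isotropic Gaussian fluctuation on side-chain atoms only
  (backbone fixed, so superposition is exact and the RMSD median has the
  closed form σ·√(χ²₃ₘ,₀.₅/m)); a schedule places chosen residue pairs in
  ideal H-bond geometry (0.29 nm, 10°) in chosen frames and out of cutoff
  otherwise.  This is harmonic noise, not physical dynamics: it validates
  the metrics, not any conformational claim.
* **Sequence families** substitute exactly round((1−identity)·L) positions
  of a random root per member, never touching the designated reference
  column, where a chosen subset carries a planted residue (e.g. an
  aspartate at the lysine-41 column).  No indels, so the family is its own
  alignment.
* **Study bundle** (`gen_study_bundle`) writes triplicate spectra and
  traces for a nine-variant panel whose planted (T_m1, red-shift,
  activity) triples emulate the qualitative structure of the mutagenesis
  campaign: a WT, a knock-out at the detection floor, penalised singles, a
  misfolded low-red-shift variant, a destabilised double with −2 °C
  epistasis and a rescue double with +4 °C epistasis.

What passing on synthetic data shows: correct implementation of the
estimators and decision rules at realistic noise.  What it does not show:
robustness to instrument drift, aggregation kinetics, non-two-state melts
beyond the fitted forms, force-field realism, or the sequence composition
of any real protein family.

## Pipeline sizes and determinism

The default test and acceptance workloads are sized for a laptop core:
100-replicate melt recovery, three 100-frame trajectory replicates for
occupancy, 500 frames for rigidity, ~200 random hit sets for network
equivalence, a 13-member family for the all-vs-all route.  All randomness
flows from explicit seeds; the pipeline records the package version,
config hash and seed in every summary header.
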