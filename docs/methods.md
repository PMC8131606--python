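# Methods

This note records the models behind each analysis, the defaults and why
they were chosen, what the synthetic generators do and do not emulate, and
the numerical choices that affect results.

## Structures, selections and numbering

Structures are held as flat per-atom arrays (names, residues, chains,
coordinates, role tags, radii).  PDB files are parsed and written through
biotite; multi-MODEL files become frame ensembles.  Frame series use a
minimal XYZ dialect (atom count, comment with `t=`, then element + three
coordinates) with all metadata supplied by a topology frame, so trajectory
files stay human-readable text.  Selections are conjunctive (chain ∧
residue range ∧ atom name ∧ role tag); an empty expression selects all
atoms.

Role tags classify atoms for the micelle analyses.  The lookup maps
water residue names (HOH/TIP3/...) to `water`, common ions to `ion`, and
detergent residues (LMT/DDM) to `detergent_tail` for the hydrocarbon tail
atoms C1–C12 and `detergent_head` otherwise (the maltoside headgroup,
including the O5 oxygen used as the head marker).

Atomic radii default to Bondi van der Waals values by element (C 1.70,
O 1.52, N 1.55, S 1.80 Å, 1.70 Å fallback) and can be overridden per atom;
no universal radius set is mandated by the mismatch literature, and the
choice shifts absolute SASA values by a few percent without affecting the
monomer/dimer comparisons the package is built for.

Ballesteros–Weinstein generic labels for bovine rhodopsin are generated
from the standard x.50 anchor residues (N55, D83, R135, W161, P215, P267,
P303) over the seven TM helix ranges; all residue numbers used elsewhere
in the package are author (PDB) numbering.

## Solvent-accessible surface areas

`compute_sasa` evaluates per-atom SASA of a solute selection with
biotite's sphere-point sampler: 960 deterministic Fibonacci points per
atom, probe radius 1.4 Å, per-atom radii from the frame.  Only the
selected atoms exist for the calculation — everything outside the
selection neither contributes area nor occludes.  Determinism matters
because the mismatch profile is a *difference* of two SASA evaluations;
960 points keeps the sampling error well below the 2% level at which the
Monte-Carlo cross-check is run.  The test suite validates the engine
against an independent 10⁵-point Monte-Carlo surface-sampling oracle on
random clusters.

Because the sphere-point set is fixed in the laboratory frame, per-atom
areas are exactly rotation/reflection *variant* at the sampling-noise
level (≲0.3 Å² per atom); totals agree to much better than the quoted 2%.
Tests that rely on exact symmetry of decompositions therefore isolate the
analytically pairwise terms (γ = 0).

## Residual hydrophobic mismatch

For each protein residue the residual exposure is

* hydrophobic residue: SA = SASA of the residue with solute = protein ∪
  detergent tails — the hydrophobic surface still exposed to headgroups or
  water;
* hydrophilic residue: SA = SASA(protein only) − SASA(protein ∪ tails),
  floored at zero — the polar surface buried in the hydrocarbon core.

ΔG = σ·SA with σ = 0.028 kcal/(mol·Å²).  The hydrophobic set is
{ALA, VAL, LEU, ILE, PRO, PHE, MET, TRP, GLY, CYS} (configurable); this is
the standard hydrophobicity split and the classification only decides
which of the two formulas applies.  Water and headgroups are never part of
the solute — their exposure is what the measure captures.

`aggregate_rhm` time-averages per-residue ΔG, restricts to a residue
selection (typically the TM5/TM6 ranges), and sums residues whose mean
exceeds a reporting threshold, 1 k<sub>B</sub>T at 303 K
(k<sub>B</sub>T = 0.602 kcal/mol) by default.  Thresholding before summing
is the default because the mismatch profile is sparse — a handful of
interface residues carry the signal and the sub-k<sub>B</sub>T remainder
is sampling noise; threshold 0 (sum everything selected) is available.
With per-replicate labels the spread of F across replicates is reported as
a sample standard deviation.  The dimerization penalty is
F<sub>DIMER</sub> − 2·F<sub>MONO</sub>; positive values mean the micelle
disfavours the dimer.

## MM-GBSA binding energetics

Single-trajectory variant: per frame, the unbound protomers are the dimer
frame with the partner's atoms deleted, so no conformational
reorganisation is included, and conformational entropy is neglected
throughout.  Per frame:

* E<sub>int</sub>: Coulomb (k<sub>e</sub> = 332.06 kcal·Å/(mol·e²),
  screened by the interior dielectric, 2) plus 12-6 Lennard-Jones
  (Lorentz–Berthelot combination from per-atom ε and r<sub>min</sub>/2)
  over all cross pairs, no cutoff.  Force-field parameters are supplied as
  a per-atom table (CSV: atom_index, charge_e, eps_kcal, rmin_half_A) and
  must cover the structure as given; hydrogens are not rebuilt.
* G<sub>polar</sub>: generalized Born with Still's interpolation
  f<sub>GB</sub> = √(r² + R<sub>i</sub>R<sub>j</sub>·exp(−r²/4R<sub>i</sub>R<sub>j</sub>))
  and prefactor (1/ε<sub>in</sub> − e<sup>−κf</sup>/ε<sub>w</sub>),
  ε<sub>in</sub> = 2, ε<sub>w</sub> = 80, κ = 0.316·√[salt] Å⁻¹ with
  0.154 M default.  Born radii come from the Hawkins–Cramer–Truhlar
  pairwise-descreening integral (intrinsic radius = vdW − 0.09 Å offset,
  scale 0.8).  This is a uniform-solvent GB: no membrane/micelle
  dielectric profile is modelled, a deliberate scope decision recorded in
  the report metadata — absolute binding energies from heterogeneous-
  dielectric solvers are not reproduced, and the package's claims about
  this module are property-based (analytic limits, conservation,
  invariances), not value reproduction.
* G<sub>nonpolar</sub> = γ·SASA with γ = −0.0072 kcal/mol/Å² as printed in
  the method this follows, sign included, overridable.

ΔG<sub>bind</sub> = E<sub>int</sub> + G<sub>DIMER</sub> − G<sub>PROA</sub>
− G<sub>PROB</sub>, averaged over an inclusive time window (default
25–150 ns for production trajectories).

**Decomposition.**  Every term is local (Born self-energy, per-atom SASA)
or pairwise (Coulomb, LJ, GB cross terms).  Local terms are assigned to
their atom; each pairwise term is split half/half between its two atoms at
evaluation time, so any partition of the dimer's atoms into groups sums
exactly to the total (the suite enforces 1e-6 kcal/mol).

**Error bars.**  The per-frame ΔG series is autocorrelated; the standard
error of the window mean uses the effective sample size N/g with the
statistical inefficiency g = 1 + 2·Σ<sub>t</sub>(1 − t/N)·ĉ<sub>t</sub>/ĉ<sub>0</sub>,
truncating the sum at the first nonpositive normalized autocovariance.
This truncated estimator is a documented choice; it reproduces the
closed-form inefficiency (1+φ)/(1−φ) of an AR(1) process within 25% at
N = 10⁴ and leaves i.i.d. series within 10% of full size.  A numerically
constant series is defined to have g = 1 and zero error.

## Dimer geometry and hydration

The splay angle α is the angle between the two protomers' TM5 axis
vectors, each from Cα 200 to Cα 234 (extracellular → intracellular), in
[0°, 180°]; it is symmetric in protomer order and rigid-body invariant.
Contact maps count a residue pair "in contact" in a frame when the
minimum heavy-atom distance is ≤ 4.5 Å — a common all-atom contact
criterion; the cutoff is configurable and no reproduction claim attaches
to it.  "Sidechain" means non-backbone heavy atoms (backbone = N, CA, C,
O, OXT); glycine has none and sidechain-scoped queries on it raise with a
pointer to the all-heavy scope.  Interior hydration counts water oxygens
within 7 Å of any sidechain heavy atom of the probe residues (264, 268,
272 on TM6; 127, 131 on TM3), once per monomer regardless of how many
probes a water is near.  Histograms use left-closed fixed-width bins
anchored at zero (the conventions behind "bin size 2" water-count and
"bin size 1 Å" distance distributions); pooling across monomers and
replicates is an explicit `combine` flag, never implicit.

## Scramblase end-point statistics

Traces are normalised to F₀, the mean over the 10 s immediately before
dithionite addition (recordings are expected to hold a ≥50 s stable
baseline).  The post-addition decay is fit to
F(t) = F_min + A_f·e^(−k_f t) + A_s·e^(−k_s t) by bounded least squares
(lmfit), with k_s parameterised as a fraction < 1 of k_f so the ordering
is structural, and deterministic initialisation (plateau from the tail,
fast rate from a log-linear fit to the early decay).  The slow component
is retained in the fit — its origin in the assay is unclear — but only
F_min and the fast component feed downstream statistics.

The occupancy statistic is p(≥1) = (0.55 − F_min)/(0.55 − F_min,norm),
normalised to a sample reconstituted at high protein/phospholipid ratio
(PPR > 0.48 mg/mmol required), with 0.55 the protein-free plateau
(constant by default, overridable per batch).  PPR* = PPR/x with
x = 2·F_min,norm discounts reconstitution-refractory vesicles.  The
mono-exponential model is parameterised p = 1 − exp(−PPR*/α) so that α is
a characteristic PPR*; under Poisson occupancy a monomer-functional
protein then shows half the α of a dimer-functional one, which is the
interpretive yardstick for construct/WT ratios (≈0.5 monomer, ≈1 same
state).  Ratio uncertainty propagates the two fits' relative standard
errors in quadrature.

Two estimator facts verified during design and reflected in the tests:

* the normalisation sample must be saturated (p ≈ 1); normalising to a
  ~2% unsaturated reference biases the fitted α ratio upward by ~8%
  noise-free.  The synthetic default PPR grid therefore ends in a
  saturating point (1.0 mg/mmol).
* at 2% trace noise on a 500 s, 1 Hz record the fit's own covariance puts
  ~8% standard error on t<sub>1/2,fast</sub> (degeneracy with the slow
  component), so per-fit 5% recovery is asserted on 1000 s records at
  ≤1% noise; ensemble-mean recovery of the 16.8 s half-time at 1% noise
  is well within ±1 s either way.

## FRET and single-molecule counting

**FRET_scaled.**  Buffer subtraction scales the buffer spectrum by the
sample/buffer area ratio over the Rayleigh scatter window (excitation
± 10 nm), constrained ≥ 1, before subtracting.  Protein loss after
detergent-withdrawal treatment is compensated by the 660–700 nm area
ratio of the donor-acceptor vs acceptor-only spectra under direct
650 nm acceptor excitation (buffer-subtracted when a matching buffer
spectrum is supplied).  FRET_scaled is then I₆₇₀(DA)/I₆₇₀(A) — intensities
read at the nearest grid point, no interpolation — minus the same ratio
for the mock-treated pair, so a mock pair evaluates to exactly zero and
the measure is invariant under global rescaling of all spectra.  Without
a mock pair the offset is zero and the result is flagged.

**Donor recovery.**  raw% = 100·(post − pre)/pre after acceptor
photobleaching; the signed donor-only control change is subtracted, so a
control that itself bleaches by ~10% *adds* ~10 points — the convention
that matches correcting for incidental donor recovery.  The sign
convention is documented here rather than asserted as the only reading.

**Step counting.**  Traces are fit piecewise-constant by greedy binary
segmentation with a per-changepoint penalty of 3·σ²·ln N (BIC-style),
σ being the robust noise level from the median absolute deviation of
first differences; segments shorter than 5 samples are not created.
Downward level changes exceeding 3σ are bleach steps.  A trace classifies
as its step count when it has 1–4 downward steps, no comparable upward
jumps, and ends bleached (final level at the minimum level within noise);
everything else is "uncountable" — a valid outcome standing in for the
manual call in the original assay, with thresholds configurable.
Distributions are reported over countable traces, with the uncountable
fraction separate.  On synthetic ground truth the detector holds
precision and recall ≥ 0.9 at SNR ≥ 8 with steps ≥ 20 samples apart.

## Synthetic generators

All generators are bit-reproducible given (parameters, seed).  They
emulate the *statistical and geometric structure* the analyses assume —
they are not physical simulations:

* `build_helix_dimer`: ideal Cα-trace helices (1.5 Å rise, 100°/residue,
  2.3 Å radius) for TM3/TM5/TM6/TM7 segments covering residues 120–139,
  200–236, 240–279, 285–309, one CB pseudo-sidechain bead per residue;
  protomer B is a rotated/translated copy whose TM5 axis makes exactly
  the requested splay angle with A's.  No loops, no real sidechains — so
  absolute SASA/RHM magnitudes are not comparable to all-atom systems,
  while every geometric and compositional contract is exercised.
* `build_micelle_system`: pseudo-detergents of 12 tail beads (C1–C12) and
  one head bead (O5).  `tails-in` points tails at the protein with heads
  outermost (monomer-like shielding); `vertical` stacks molecules along
  the bundle axis with heads anchored just outside mid-height surface
  atoms (the lipid-like, interface-exposing arrangement).  Placement is
  random with a steric clearance and retry budget — packing realism is a
  non-goal.
* `simulate_dithionite_traces`: the double-exponential bleach model with
  a unit pre-addition baseline, defaults F_min 0.45, fast t<sub>1/2</sub>
  16.8 s, slow component 10% of the amplitude at t<sub>1/2</sub> 170 s,
  1 Hz sampling, Gaussian noise 1% of F₀.
* `simulate_reconstitution_series`: vesicle occupancy ~ Poisson(c·PPR)
  in monomer mode and Poisson(c·PPR/2) in dimer mode, with
  c = 12.5 (mg/mmol)⁻¹ calibrated so the dimer-mode curve saturates
  (p ≈ 0.95) at the 0.48 mg/mmol high-PPR regime; a 45% refractory
  vesicle fraction (so the high-PPR plateau F_min ≈ 0.25 and x ≈ 0.5);
  scrambling vesicles bleach to zero residual by default.  Ensemble F_min
  is averaged over the drawn vesicles, so finite-n sampling noise is
  intrinsic.
* `simulate_spectra`: Gaussian donor (570 nm) and acceptor (670 nm) bands
  (σ 15 nm), Rayleigh peak at the excitation line (σ 2 nm), smooth buffer
  background added at 1.5× into samples, protein-loss scaling of the
  treated pair, sensitized emission proportional to the FRET boost, noise
  0.5% of the band peak.
* `simulate_step_traces`: fluorophore count Binomial(size, labelling p)
  conditioned ≥ 1, exponential bleach times (mean 6 s) redrawn until
  steps are ≥ 20 samples apart and away from the edges, unit steps,
  20 Hz, 30 s, Gaussian noise 1/SNR.

What passing tests on these fixtures shows: the estimators and pipelines
recover known ground truth under the stated noise models.  What they do
not show: performance on real data with correlated noise, drift,
photophysics (blinking), vesicle polydispersity, or real micelle packing.

## Package shape

The package is a plain library with narrative example scripts; no
command-line entry point is installed, since every workflow is a few
lines of Python over the documented API and the inputs are in-memory
objects or standard text files (PDB, XYZ, CSV).

## Problem sizes

Default test and acceptance runs use desk-scale inputs chosen to make the
statistical assertions sharp: 100 fitted traces for half-time recovery,
1000 vesicle draws per PPR point (5 nonzero points), 20 random clusters ×
10⁵ Monte-Carlo points for the SASA cross-check, N = 10⁴ for the ESS
checks, 200 spots for step-classification rates, toy 4–6-atom dimers for
the energy-conservation and invariance checks.

## Known limitations

* Uniform-dielectric GB: no membrane/micelle dielectric slab, no volume-
  integration Born radii; absolute binding energies differ from
  heterogeneous-dielectric implementations by construction.
* No PBC handling: frames are assumed whole and unwrapped.
* The contact cutoff and the uncountable-trace criteria are documented
  package choices, not reproductions of the original (unstated or manual)
  criteria.
* Cα/CB bead fixtures exercise contracts, not absolute magnitudes, for
  surface-area-based quantities.
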