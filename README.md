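# dimerlens

Analysis toolkit for membrane-protein dimerization studies of the kind
carried out on rhodopsin/opsin: why does a GPCR that dimerizes in a lipid
bilayer stay monomeric in detergent, and how do mutations at the TM5
interface change the dimer it forms?  The package implements the
computational layer such a study needs, end to end, for both the
simulation-derived and the fluorescence-assay readouts:

* **Residual hydrophobic mismatch (RHM)** — the energetic penalty a
  protein pays in a detergent micelle wherever hydrophobic residue surface
  is exposed to water/headgroups or hydrophilic surface is buried in the
  hydrocarbon core: ΔG<sub>res,i</sub> = σ<sub>res</sub>·SA<sub>res,i</sub>
  with σ<sub>res</sub> = 0.028 kcal/(mol·Å²), where SA<sub>res,i</sub> comes
  from solvent-accessible surface areas with the solute taken as the
  protein alone vs the protein plus the detergent tails (C1–C12).  Summed
  over interface residues above a 1 k<sub>B</sub>T threshold this gives the
  overall mismatch energy F, and F<sub>DIMER</sub> − 2·F<sub>MONO</sub> is
  the mismatch contribution to dimerization.
* **MM-GBSA binding energetics** — the single-trajectory end-point
  estimate ΔG<sub>bind</sub> = E<sub>int</sub> + G<sub>DIMER</sub> −
  (G<sub>PROA</sub> + G<sub>PROB</sub>) with CHARMM-style nonbonded terms
  (no cutoff), a pairwise-descreening generalized-Born polar term with
  Debye–Hückel salt screening (κ = 0.316·√[salt] Å⁻¹, interior dielectric
  2), a γ·SASA nonpolar term, exact per-group energy decomposition, and
  error bars from the effective sample size of the autocorrelated
  per-frame series.
* **Dimer geometry and hydration** — the TM5 splay angle α between the
  protomers (Cα 200 → Cα 234 axis vectors), Cα–Cα and minimum
  inter-residue distance series, residue-pair contact-frequency maps, and
  interior-water counts (water oxygens within 7 Å of the probe-residue
  sidechains), with fixed-width histograms.
* **Scramblase end-point statistics** — dithionite bleach-trace
  normalisation and double-exponential fitting (plateau F_min, fast
  t<sub>1/2</sub>), the p(≥1)-scramblase curve over the corrected
  protein/phospholipid ratio PPR* = PPR/(2·F_min,norm), the
  mono-exponential fit constant α, and construct/WT α ratios whose Poisson
  logic distinguishes monomer- from dimer-functional reconstitution.
* **FRET and single-molecule counting** — spectral FRET_scaled
  (Rayleigh-scaled buffer subtraction, 660–700 nm acceptor-loss
  correction, offset from mock-treated pairs), acceptor-photobleach donor
  recovery with donor-only control correction, and photobleaching
  step-count classification (1–4 steps or uncountable) by change-point
  fitting.
* **Synthetic data** — seed-deterministic generators for every input:
  helix-bundle dimers at a requested splay angle, pseudo-DDM micelles
  (tails-in or vertical), bleach traces, Poisson reconstitution series,
  emission spectra and stepwise photobleaching traces.

The package is a library; the `examples/` scripts are the guided tour.

## Worked example

`python examples/scramblase_assay.py` prints:

```
double-exponential fit: F_min = 0.453, t1/2 fast = 16.9 s, t1/2 slow = 152 s
(F_min is the assay end-point; 0.55 would mean no scramblase present)
dimer  : alpha = 0.321 mg/mmol (x factor 0.50)
monomer: alpha = 0.162 mg/mmol (x factor 0.50)
alpha_monomer / alpha_dimer = 0.49 +- 0.01
(~0.5 is the Poisson signature of a monomer-functional protein; ~1 means the same oligomeric state as the reference)
```

The fitted plateau and fast half-time recover the generator's ground truth
(0.45 and 16.8 s).  The α ratio of one half is the Poisson-occupancy
signature that tells a protein reconstituting as an active monomer apart
from one that must assemble into a dimer: at equal protein mass, monomer
units land on vesicles at twice the rate of assembled dimers, so the
characteristic PPR* halves.

Other tours: `splay_and_hydration.py` (splay angle, TM6–TM7 distance
histograms, interior waters), `rhm_micelle.py` (mismatch energies,
monomer vs dimer micelle arrangements), `binding_energy_decomposition.py`
(ΔG_bind with ESS error bars and per-chain decomposition),
`fret_and_steps.py` (FRET_scaled, donor recovery, step counting),
`tm6_tm7_distance.py` (Cα 252–308 distance from any PDB file).

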