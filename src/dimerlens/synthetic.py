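"""Seed-deterministic synthetic inputs for every analysis stage.

These generators emulate the statistical and geometric structure the
analyses assume — they are fixtures with controllable ground truth, not
physical simulations:

* :func:`build_helix_dimer` — two idealised Cα-trace helix-bundle
  protomers (TM3/TM5/TM6/TM7 segments, 1.5 Å rise and 100° twist per
  residue, one pseudo-sidechain bead per residue) whose TM5 axes are set
  to a requested splay angle;
* :func:`build_micelle_system` — pseudo-detergents (12 tail beads C1-C12,
  one head bead O5) packed around a protein, either tails-in (the
  monomer-like arrangement) or vertical (lipid-like, heads facing the
  mid-height interface, the dimer-like arrangement);
* :func:`jitter_trajectory` — i.i.d. Gaussian coordinate noise frames;
* :func:`simulate_dithionite_traces` — double-exponential bleach traces
  with a pre-addition baseline and Gaussian noise (defaults: fast
  t_1/2 = 16.8 s, protein-free plateau 0.55);
* :func:`simulate_reconstitution_series` — Poisson vesicle occupancy of
  monomer or dimer functional units over a PPR grid, reduced to ensemble
  F_min values;
* :func:`simulate_spectra` — Gaussian donor/acceptor emission bands with
  a Rayleigh scatter peak, buffer background, protein-loss scaling and a
  controllable sensitized-emission boost;
* :func:`simulate_step_traces` — stepwise photobleaching traces with
  binomial labelling and exponential bleach times at 20 Hz.

Identical parameters and seed give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .structure_io import MolecularFrame, TrajectoryEnsemble
from .scramblase import FluorescenceTrace, F_MIN_PROTEIN_FREE
from .fluorescence import EmissionSpectrum, SpectrumSet

__all__ = [
    "GeneratorConfig",
    "build_helix_dimer",
    "build_micelle_system",
    "jitter_trajectory",
    "simulate_dithionite_traces",
    "simulate_reconstitution_series",
    "simulate_spectra",
    "SimulatedStepTrace",
    "simulate_step_traces",
]

#: Poisson proportionality constant (monomer units per vesicle per unit
#: PPR), calibrated so a dimer-forming protein saturates (p(>=1) ~ 0.95)
#: at the high-PPR regime of 0.48 mg/mmol.
OCCUPANCY_PER_PPR = 12.5

_HELIX_RISE = 1.5       # Å per residue
_HELIX_TWIST = 100.0    # degrees per residue
_HELIX_RADIUS = 2.3     # Å, Cα radius of an ideal alpha helix

#: Helix segments of one protomer: (label, first_res, last_res, xy offset).
_SEGMENTS = (
    ("TM3", 120, 139, (-5.0, -5.0)),
    ("TM5", 200, 236, (0.0, 0.0)),
    ("TM6", 240, 279, (5.0, 0.0)),
    ("TM7", 285, 309, (2.5, -5.0)),
)

#: Deterministic residue-name cycle (mixed hydrophobic/hydrophilic).
_RESNAME_CYCLE = ("LEU", "ALA", "PHE", "SER", "VAL", "THR", "ILE", "ASN")


@dataclass
class GeneratorConfig:
    """Seed plus per-generator parameter blocks (dict overrides)."""

    seed: int = 0
    params: dict = field(default_factory=dict)

    def block(self, name: str) -> dict:
        return dict(self.params.get(name, {}))


def _rotation_matrix(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    a = np.asarray(axis, float)
    a = a / np.linalg.norm(a)
    th = np.radians(angle_deg)
    K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)


def _protomer_template(with_sidechains: bool):
    names, resnames, resids, coords = [], [], [], []
    for _, lo, hi, (ox, oy) in _SEGMENTS:
        for k, res in enumerate(range(lo, hi + 1)):
            phase = np.radians(_HELIX_TWIST * k)
            x = ox + _HELIX_RADIUS * np.cos(phase)
            y = oy + _HELIX_RADIUS * np.sin(phase)
            z = _HELIX_RISE * k
            names.append("CA")
            resnames.append(_RESNAME_CYCLE[res % len(_RESNAME_CYCLE)])
            resids.append(res)
            coords.append((x, y, z))
            if with_sidechains:
                r_out = _HELIX_RADIUS + 1.5
                names.append("CB")
                resnames.append(resnames[-1])
                resids.append(res)
                coords.append((ox + r_out * np.cos(phase), oy + r_out * np.sin(phase), z))
    return names, resnames, resids, np.array(coords, float)


def _frame_from_parts(names, elements, resnames, resids, chains, coords, roles):
    radius = np.where(np.char.upper(np.asarray(elements)) == "O", 1.52, 1.70)
    return MolecularFrame(
        atom_name=np.asarray(names), element=np.asarray(elements),
        res_name=np.asarray(resnames), res_id=np.asarray(resids, int),
        chain_id=np.asarray(chains), coords=np.asarray(coords, float),
        role_tag=np.asarray(roles), radius=radius,
    )


def build_helix_dimer(splay_deg: float = 0.0, separation: float = 30.0,
                      with_sidechains: bool = True) -> MolecularFrame:
    """Two-protomer Cα-trace helix bundle at a requested TM5 splay angle.

    Protomer B is protomer A rotated by ``splay_deg`` about an axis
    perpendicular to A's TM5 axis vector (Cα 200 -> Cα 234) and displaced
    by ``separation`` Å, so the measured splay angle equals the request
    up to numerical precision.  Chains are labelled A and B.  Each residue
    carries a CA bead and (by default) one CB pseudo-sidechain bead.
    """
    if not 0.0 <= splay_deg <= 90.0:
        raise ValueError("splay angle must lie in [0, 90] degrees")
    names, resnames, resids, xyz = _protomer_template(with_sidechains)
    n = len(names)

    resids_arr = np.asarray(resids)
    names_arr = np.asarray(names)
    i200 = np.nonzero((resids_arr == 200) & (names_arr == "CA"))[0][0]
    i234 = np.nonzero((resids_arr == 234) & (names_arr == "CA"))[0][0]
    v = xyz[i234] - xyz[i200]
    perp = np.cross(v, [1.0, 0.0, 0.0])
    rot = _rotation_matrix(perp, splay_deg)
    center = xyz.mean(axis=0)
    xyz_b = (xyz - center) @ rot.T + center + np.array([separation, 0.0, 0.0])

    all_names = list(names) * 2
    all_resnames = list(resnames) * 2
    all_resids = list(resids) * 2
    chains = ["A"] * n + ["B"] * n
    coords = np.vstack([xyz, xyz_b])
    elements = ["C"] * (2 * n)
    roles = ["protein"] * (2 * n)
    return _frame_from_parts(all_names, elements, all_resnames, all_resids,
                             chains, coords, roles)


def build_micelle_system(protein: MolecularFrame, n_detergent: int = 150,
                         mode: str = "tails-in", seed: int = 0,
                         bead_spacing: float = 1.4, clearance: float = 1.0,
                         max_retries: int = 200) -> MolecularFrame:
    """Pack pseudo-detergents (C1-C12 tails + O5 head) around a protein.

    ``tails-in`` points the hydrocarbon tails at the protein with the
    headgroup outermost (the arrangement around a well-shielded monomer);
    ``vertical`` stacks the molecules parallel to the bundle axis with the
    head bead at the protein's mid-height, the lipid-like arrangement that
    exposes headgroups to mid-height interface residues.  Placement is
    randomised (seeded) with a steric retry budget.
    """
    if n_detergent < 1:
        raise ValueError("need at least one detergent")
    if mode not in ("tails-in", "vertical"):
        raise ValueError(f"unknown micelle mode {mode!r}")
    rng = np.random.default_rng(seed)
    center = protein.coords.mean(axis=0)
    rel = protein.coords - center
    r_surf = float(np.sqrt(rel[:, 0] ** 2 + rel[:, 1] ** 2).max()) + 2.0
    z_lo, z_hi = float(rel[:, 2].min()), float(rel[:, 2].max())
    z_mid = 0.5 * (z_lo + z_hi)

    placed: list = []
    det_coords, det_names = [], []
    for mol in range(n_detergent):
        for attempt in range(max_retries):
            phi = rng.uniform(0, 2 * np.pi)
            u = np.array([np.cos(phi), np.sin(phi), 0.0])
            if mode == "tails-in":
                z = rng.uniform(z_lo + 0.1 * (z_hi - z_lo), z_hi - 0.1 * (z_hi - z_lo))
                base = center + u * r_surf + np.array([0, 0, z])
                beads = [base + u * (bead_spacing * k) for k in range(12)]
                beads.append(base + u * (bead_spacing * 12 + 0.3))  # O5 outermost
            else:  # vertical: head anchored just outside a mid-height surface atom
                sign = 1.0 if rng.random() < 0.5 else -1.0
                mid_mask = np.abs(rel[:, 2] - z_mid) < 3.0
                anchors = rel[mid_mask] if mid_mask.any() else rel
                a = anchors[rng.integers(len(anchors))]
                radial = a[:2]
                norm = np.linalg.norm(radial)
                u2 = radial / norm if norm > 1e-6 else u[:2]
                head = center + a + np.concatenate([
                    u2 * (2.5 + 8.0 * rng.random() ** 2), [rng.normal(0, 2.0)]])
                beads = [head + np.array([0, 0, sign * bead_spacing * (12 - k)])
                         for k in range(12)]
                beads.append(head)
            beads = np.array(beads)
            if placed:
                prev = np.vstack(placed)
                d2 = ((beads[:, None, :] - prev[None, :, :]) ** 2).sum(-1)
                if d2.min() < clearance**2:
                    continue
            placed.append(beads)
            det_coords.append(beads)
            det_names.append([f"C{k + 1}" for k in range(12)] + ["O5"])
            break
        else:
            raise RuntimeError(
                f"could not place detergent {mol} within {max_retries} tries"
            )

    n_det_atoms = 13 * n_detergent
    names = list(protein.atom_name) + [nm for mol in det_names for nm in mol]
    elements = list(protein.element) + (["C"] * 12 + ["O"]) * n_detergent
    resnames = list(protein.res_name) + ["DDM"] * n_det_atoms
    res0 = int(protein.res_id.max()) + 1
    resids = list(protein.res_id) + [res0 + m for m in range(n_detergent) for _ in range(13)]
    chains = list(protein.chain_id) + ["D"] * n_det_atoms
    roles = list(protein.role_tag) + (["detergent_tail"] * 12 + ["detergent_head"]) * n_detergent
    coords = np.vstack([protein.coords] + det_coords)
    return _frame_from_parts(names, elements, resnames, resids, chains, coords, roles)


def jitter_trajectory(frame: MolecularFrame, n_frames: int, sigma: float,
                      seed: int = 0, time_step: float = 1.0,
                      t_start: float = 0.0) -> TrajectoryEnsemble:
    """Frame 0 is the input; later frames add i.i.d. Gaussian noise (Å)."""
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    rng = np.random.default_rng(seed)
    frames = [frame.with_coords(frame.coords.copy(), frame_time=t_start)]
    for i in range(1, n_frames):
        noise = rng.normal(0.0, sigma, size=frame.coords.shape) if sigma > 0 else 0.0
        frames.append(frame.with_coords(frame.coords + noise,
                                        frame_time=t_start + i * time_step))
    return TrajectoryEnsemble(frames=frames, time_step=time_step)


def simulate_dithionite_traces(n_traces: int = 1, f_min: float = 0.45,
                               t_half_fast: float = 16.8, t_half_slow: float = 170.0,
                               slow_fraction: float = 0.1, noise_sigma: float = 0.01,
                               baseline_s: float = 60.0, duration_s: float = 500.0,
                               sample_rate_hz: float = 1.0, f0_scale: float = 100.0,
                               seed: int = 0) -> list:
    """Dithionite bleach traces with fast/slow components and noise.

    The normalised model is F(t) = f_min + A_f 2^(-t/t_half_fast)
    + A_s 2^(-t/t_half_slow) with A_f + A_s = 1 - f_min and
    A_s = slow_fraction * (1 - f_min); a flat pre-addition baseline of 1
    covers ``baseline_s`` seconds.  Traces are scaled by ``f0_scale`` and
    carry Gaussian noise of ``noise_sigma`` (fraction of F_0).
    """
    if min(f_min, t_half_fast, t_half_slow, noise_sigma + 1e-12) < 0:
        raise ValueError("negative trace parameters")
    if t_half_fast >= t_half_slow:
        raise ValueError("fast half-time must be below the slow one")
    rng = np.random.default_rng(seed)
    dt = 1.0 / sample_rate_hz
    t = np.arange(0.0, baseline_s + duration_s, dt)
    post = t >= baseline_s
    tp = t[post] - baseline_s
    a_total = 1.0 - f_min
    a_slow = slow_fraction * a_total
    a_fast = a_total - a_slow
    model = np.ones_like(t)
    model[post] = (f_min + a_fast * np.exp(-np.log(2.0) * tp / t_half_fast)
                   + a_slow * np.exp(-np.log(2.0) * tp / t_half_slow))
    traces = []
    for _ in range(n_traces):
        noise = rng.normal(0.0, noise_sigma, size=t.size) if noise_sigma > 0 else 0.0
        traces.append(FluorescenceTrace(time=t.copy(),
                                        intensity=f0_scale * (model + noise),
                                        dithionite_time=baseline_s))
    return traces


def simulate_reconstitution_series(ppr_grid=(0.0, 0.03, 0.08, 0.15, 0.3, 1.0),
                                   mode: str = "dimer", n_vesicles: int = 200,
                                   occupancy_per_ppr: float = OCCUPANCY_PER_PPR,
                                   f_refractory: float = 0.45,
                                   residual_fluorescence: float = 0.0,
                                   seed: int = 0) -> pd.DataFrame:
    """Poisson-occupancy reconstitution series -> (PPR, F_min) samples.

    Monomer units land on vesicles as Poisson(c * PPR); in ``dimer`` mode
    the functional unit is an assembled dimer, so functional-unit
    occupancy is Poisson(c * PPR / 2).  A fraction of vesicles is
    refractory to reconstitution and always bleaches like protein-free
    liposomes (plateau 0.55); scrambling vesicles plateau at
    ``residual_fluorescence`` (0 by default).  F_min per PPR point is the
    ensemble mean over ``n_vesicles`` seeded draws.
    """
    if mode not in ("monomer", "dimer"):
        raise ValueError("mode must be 'monomer' or 'dimer'")
    if not 0.0 <= f_refractory < 1.0:
        raise ValueError("refractory fraction must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    rows = []
    for ppr in ppr_grid:
        if ppr < 0:
            raise ValueError("PPR must be nonnegative")
        lam = occupancy_per_ppr * ppr / (2.0 if mode == "dimer" else 1.0)
        occ = rng.poisson(lam, size=n_vesicles)
        p_active = float(np.mean(occ >= 1))
        f_min = (f_refractory * F_MIN_PROTEIN_FREE
                 + (1.0 - f_refractory)
                 * (p_active * residual_fluorescence
                    + (1.0 - p_active) * F_MIN_PROTEIN_FREE))
        rows.append((ppr, f_min, mode))
    return pd.DataFrame(rows, columns=["ppr", "f_min", "construct"])


def _gaussian(x, mu, sigma):
    return np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def simulate_spectra(fret_boost: float = 0.3, loss_factor: float = 0.8,
                     donor_quench: float = None, noise_sigma: float = 0.005,
                     buffer_scale: float = 1.5, seed: int = 0) -> SpectrumSet:
    """Synthetic donor/acceptor emission spectra for FRET_scaled.

    Donor band at 570 nm, acceptor at 670 nm (σ 15 nm), Rayleigh scatter
    peak at the excitation wavelength (σ 2 nm), flat-ish buffer
    background.  The treated donor-acceptor sample gains sensitized
    acceptor emission proportional to ``fret_boost`` (and loses the same
    fraction of donor emission unless ``donor_quench`` overrides), and is
    globally scaled by ``loss_factor`` to emulate protein loss; the mock
    pair has no boost or loss.  Direct-excitation (650 nm) spectra for the
    loss correction are included.  Noise is ``noise_sigma`` of the band
    peak.
    """
    if fret_boost < 0:
        raise ValueError("FRET boost must be nonnegative")
    if donor_quench is None:
        donor_quench = min(fret_boost, 0.9)
    rng = np.random.default_rng(seed)
    wl = np.arange(540.0, 751.0, 1.0)

    buffer_bg = 0.05 + 0.02 * _gaussian(wl, 620.0, 60.0)
    ray555 = 50.0 * _gaussian(wl, 555.0, 2.0)
    ray650 = 50.0 * _gaussian(wl, 650.0, 2.0)
    donor_band = _gaussian(wl, 570.0, 15.0)
    acceptor_band = _gaussian(wl, 670.0, 15.0)

    def spec(signal, excitation, rayleigh):
        noise = rng.normal(0.0, noise_sigma, size=wl.size)
        return EmissionSpectrum(wl, signal + buffer_scale * (buffer_bg + rayleigh) + noise,
                                excitation)

    a_base = 0.4 * acceptor_band           # direct acceptor excitation bleed at 555
    donor = donor_band
    buffer_555 = EmissionSpectrum(wl, buffer_bg + ray555, 555.0)
    buffer_650 = EmissionSpectrum(wl, buffer_bg + ray650, 650.0)

    return SpectrumSet(
        donor_acceptor=spec(loss_factor * ((1 - donor_quench) * donor
                                           + (1 + fret_boost) * a_base), 555.0, ray555),
        acceptor_only=spec(a_base, 555.0, ray555),
        buffer=buffer_555,
        da_direct=spec(loss_factor * acceptor_band, 650.0, ray650),
        a_direct=spec(acceptor_band, 650.0, ray650),
        buffer_direct=buffer_650,
        mock_donor_acceptor=spec(donor + a_base, 555.0, ray555),
        mock_acceptor_only=spec(a_base, 555.0, ray555),
        donor_only=spec(donor, 555.0, ray555),
    )


@dataclass
class SimulatedStepTrace:
    """Ground-truth photobleaching trace for detector validation."""

    time: np.ndarray
    intensity: np.ndarray
    true_step_indices: np.ndarray
    n_fluorophores: int


def simulate_step_traces(n_spots: int = 100, oligomer_size: int = 1,
                         labeling_p: float = 1.0, snr: float = 10.0,
                         duration_s: float = 30.0, sample_rate_hz: float = 20.0,
                         bleach_mean_s: float = 6.0, min_spacing: int = 20,
                         seed: int = 0) -> list:
    """Stepwise-bleaching intensity traces at 20 Hz.

    Per spot the fluorophore count is Binomial(oligomer_size, labeling_p)
    conditioned on >= 1; each fluorophore bleaches at an exponential time
    (mean ``bleach_mean_s``), all steps have unit size, and Gaussian noise
    of 1/snr is added.  Bleach times are redrawn until they are separated
    by ``min_spacing`` samples and sit away from the trace edges, keeping
    the ground truth resolvable.
    """
    if not 0.0 < labeling_p <= 1.0:
        raise ValueError("labeling probability must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    n_samples = int(round(duration_s * sample_rate_hz))
    t = np.arange(n_samples) / sample_rate_hz
    traces = []
    for _ in range(n_spots):
        m = 0
        while m == 0:
            m = int(rng.binomial(oligomer_size, labeling_p))
        for _attempt in range(1000):
            times = rng.exponential(bleach_mean_s, size=m)
            idx = np.sort(np.round(times * sample_rate_hz).astype(int))
            if idx[0] < min_spacing or idx[-1] > n_samples - min_spacing:
                continue
            if m > 1 and np.min(np.diff(idx)) < min_spacing:
                continue
            break
        else:
            raise RuntimeError("could not draw resolvable bleach times")
        signal = np.zeros(n_samples)
        level = float(m)
        pos = 0
        for k, i in enumerate(idx):
            signal[pos:i] = m - k
            pos = i
        signal[pos:] = 0.0
        noise = rng.normal(0.0, 1.0 / snr, size=n_samples)
        traces.append(SimulatedStepTrace(time=t.copy(), intensity=signal + noise,
                                         true_step_indices=idx,
                                         n_fluorophores=m))
    return traces
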