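"""Dimer-geometry and hydration statistics over trajectory frames.

Implements the quantities used to characterise the mutual arrangement of
two protomers in a helix-bundle dimer: the TM5 splay angle between the
protomers, Cα-Cα and minimum inter-residue distance series, residue-pair
contact-frequency maps, counts of water molecules in the protein interior,
and fixed-width histograms of any of these series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .structure_io import MolecularFrame, TrajectoryEnsemble, SelectionExpr, select_atoms

__all__ = [
    "BACKBONE_ATOMS",
    "SplaySeries",
    "ContactMap",
    "Histogram",
    "splay_angle",
    "splay_series",
    "ca_distance_series",
    "min_residue_distance",
    "min_residue_distance_series",
    "contact_frequency_map",
    "count_interior_waters",
    "interior_water_series",
    "build_histogram",
]

#: Backbone heavy-atom names; everything else heavy is "sidechain".
BACKBONE_ATOMS = ("N", "CA", "C", "O", "OXT")

#: Interior-hydration probe residues (TM6: 264/268/272, TM3: 127/131).
DEFAULT_WATER_PROBES = (264, 268, 272, 127, 131)


def _ca_coord(frame: MolecularFrame, chain: str, res: int) -> np.ndarray:
    idx = select_atoms(frame, SelectionExpr(chain_ids=[chain],
                                            residue_range=(res, res),
                                            atom_names=["CA"]))
    if len(idx) == 0:
        raise ValueError(f"no CA atom for residue {res} in chain {chain}")
    return frame.coords[idx[0]]


def splay_angle(frame: MolecularFrame, protomer_a: str, protomer_b: str,
                res_start: int = 200, res_end: int = 234) -> float:
    """Splay angle (degrees) between the TM5 axis vectors of two protomers.

    Each protomer's axis vector points from the Cα of ``res_start`` toward
    the Cα of ``res_end`` (by default residues 200 -> 234, i.e. along TM5
    from the extracellular to the intracellular end); the angle is the
    arccos of the dot product of the two unit vectors, in [0, 180].
    """
    va = _ca_coord(frame, protomer_a, res_end) - _ca_coord(frame, protomer_a, res_start)
    vb = _ca_coord(frame, protomer_b, res_end) - _ca_coord(frame, protomer_b, res_start)
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        raise ValueError("degenerate (zero-length) TM5 axis vector")
    cosang = float(np.dot(va, vb) / (na * nb))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


@dataclass
class SplaySeries:
    """Per-frame splay angles for one protomer pair."""

    angles: np.ndarray  # degrees, in [0, 180]
    times: np.ndarray
    protomers: tuple
    axis_residues: tuple = (200, 234)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "splay_deg": self.angles})


def splay_series(traj: TrajectoryEnsemble, protomer_a: str, protomer_b: str,
                 res_start: int = 200, res_end: int = 234) -> SplaySeries:
    angles = np.array([
        splay_angle(fr, protomer_a, protomer_b, res_start, res_end) for fr in traj
    ])
    return SplaySeries(angles=angles, times=traj.times,
                       protomers=(protomer_a, protomer_b),
                       axis_residues=(res_start, res_end))


def ca_distance_series(traj: TrajectoryEnsemble, resi: int, resj: int,
                       chains=None, combine: bool = False):
    """Per-frame Cα-Cα distance between two residues, per monomer.

    Returns a DataFrame (time, chain, distance_A); with ``combine=True``
    the per-chain series are concatenated into one flat array instead
    (the pooling used when histogramming over both monomers).
    """
    if chains is None:
        chains = sorted(set(traj[0].chain_id[traj[0].role_tag == "protein"]))
    records = []
    for fr in traj:
        for ch in chains:
            d = float(np.linalg.norm(_ca_coord(fr, ch, resi) - _ca_coord(fr, ch, resj)))
            records.append((fr.frame_time, ch, d))
    df = pd.DataFrame(records, columns=["time", "chain", "distance_A"])
    if combine:
        return df["distance_A"].to_numpy()
    return df


def _residue_atom_coords(frame: MolecularFrame, chain: str, res: int,
                         scope: str) -> np.ndarray:
    idx = select_atoms(frame, SelectionExpr(chain_ids=[chain], residue_range=(res, res)))
    if len(idx) == 0:
        raise ValueError(f"residue {res} not found in chain {chain}")
    heavy = idx[frame.element[idx] != "H"]
    if scope == "all-heavy":
        sel = heavy
    elif scope == "sidechain":
        sel = heavy[~np.isin(frame.atom_name[heavy], BACKBONE_ATOMS)]
        if len(sel) == 0:
            raise ValueError(
                f"residue {res} chain {chain} has no sidechain heavy atoms "
                "(e.g. GLY); use scope='all-heavy'"
            )
    else:
        raise ValueError(f"unknown atom scope {scope!r}")
    if len(sel) == 0:
        raise ValueError(f"residue {res} chain {chain}: empty atom scope")
    return frame.coords[sel]


def min_residue_distance(frame: MolecularFrame, res_a, res_b,
                         scope: str = "all-heavy") -> float:
    """Minimum distance (Å) between two residues' atoms within a scope.

    ``res_a``/``res_b`` are ``(residue_number, chain_id)`` pairs, so the
    two residues may sit on opposite protomers.
    """
    xa = _residue_atom_coords(frame, res_a[1], res_a[0], scope)
    xb = _residue_atom_coords(frame, res_b[1], res_b[0], scope)
    return float(cdist(xa, xb).min())


def min_residue_distance_series(traj: TrajectoryEnsemble, res_a, res_b,
                                scope: str = "all-heavy") -> np.ndarray:
    return np.array([min_residue_distance(fr, res_a, res_b, scope) for fr in traj])


@dataclass
class ContactMap:
    """Residue-pair contact frequencies over a trajectory.

    Keys are ``((res_id_a, chain_a), (res_id_b, chain_b))``; a pair counts
    as "in contact" in a frame iff the minimum heavy-atom distance between
    the residues is <= ``cutoff``.  Frequencies are fractions of frames.
    """

    frequencies: dict
    cutoff: float
    n_frames: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (ra[0], ra[1], rb[0], rb[1], f)
            for (ra, rb), f in sorted(self.frequencies.items())
        ]
        return pd.DataFrame(rows, columns=["res_a", "chain_a", "res_b", "chain_b", "frequency"])


def _residues_of(frame: MolecularFrame, idx: np.ndarray):
    """Group heavy-atom indices by (res_id, chain_id), insertion order."""
    idx = idx[frame.element[idx] != "H"]
    groups: dict = {}
    for i in idx:
        key = (int(frame.res_id[i]), str(frame.chain_id[i]))
        groups.setdefault(key, []).append(i)
    return {k: np.array(v) for k, v in groups.items()}


def contact_frequency_map(traj: TrajectoryEnsemble, sel_a, sel_b,
                          cutoff: float = 4.5) -> ContactMap:
    """Pairwise residue contact frequencies between two selections.

    The 4.5 Å default is a common all-atom heavy-atom contact criterion;
    it is a package choice, configurable via ``cutoff``.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if len(traj) == 0:
        raise ValueError("trajectory has no frames")
    top = traj[0]
    idx_a = sel_a if isinstance(sel_a, np.ndarray) else select_atoms(top, sel_a)
    idx_b = sel_b if isinstance(sel_b, np.ndarray) else select_atoms(top, sel_b)
    if len(idx_a) == 0 or len(idx_b) == 0:
        raise ValueError("empty selection")
    res_a = _residues_of(top, np.asarray(idx_a))
    res_b = _residues_of(top, np.asarray(idx_b))
    counts = {(ka, kb): 0 for ka in res_a for kb in res_b if ka != kb}
    for fr in traj:
        for ka, ia in res_a.items():
            xa = fr.coords[ia]
            for kb, ib in res_b.items():
                if ka == kb:
                    continue
                if cdist(xa, fr.coords[ib]).min() <= cutoff:
                    counts[(ka, kb)] += 1
    n = len(traj)
    freqs = {k: c / n for k, c in counts.items()}
    return ContactMap(frequencies=freqs, cutoff=cutoff, n_frames=n)


def count_interior_waters(frame: MolecularFrame, chain: str,
                          probe_residues=DEFAULT_WATER_PROBES,
                          cutoff: float = 7.0) -> int:
    """Water oxygens within ``cutoff`` of the probe residues' sidechains.

    A water counts once per monomer even when it is near several probe
    residues.  Probes default to the TM6/TM3 interior set (264, 268, 272,
    127, 131); distances are to sidechain heavy atoms.  A frame without
    waters returns 0.
    """
    w = np.nonzero((frame.role_tag == "water") & (frame.element == "O"))[0]
    if len(w) == 0:
        return 0
    probe_coords = []
    for res in probe_residues:
        probe_coords.append(_residue_atom_coords(frame, chain, res, "sidechain"))
    probes = np.vstack(probe_coords)
    d = cdist(frame.coords[w], probes)
    return int(np.sum(d.min(axis=1) <= cutoff))


def interior_water_series(traj: TrajectoryEnsemble, chains=None,
                          probe_residues=DEFAULT_WATER_PROBES,
                          cutoff: float = 7.0, combine: bool = False):
    """Per-frame interior-water counts per monomer (optionally pooled)."""
    if chains is None:
        chains = sorted(set(traj[0].chain_id[traj[0].role_tag == "protein"]))
    records = [
        (fr.frame_time, ch, count_interior_waters(fr, ch, probe_residues, cutoff))
        for fr in traj for ch in chains
    ]
    df = pd.DataFrame(records, columns=["time", "chain", "n_waters"])
    if combine:
        return df["n_waters"].to_numpy()
    return df


@dataclass
class Histogram:
    """Fixed-width histogram with bins anchored at zero (left-closed)."""

    edges: np.ndarray
    counts: np.ndarray
    bin_width: float
    normalized: bool = False

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def to_frame(self) -> pd.DataFrame:
        col = "probability" if self.normalized else "count"
        return pd.DataFrame({"bin_left": self.edges[:-1],
                             "bin_right": self.edges[1:],
                             col: self.counts})


def build_histogram(series, bin_width: float, normalize: bool = False) -> Histogram:
    """Histogram a series into left-closed bins of fixed width anchored at 0.

    Bin edges are integer multiples of ``bin_width`` (so e.g. a 1 Å bin
    width yields edges at ..., 14, 15, 16, ... Å).  ``normalize=True``
    converts counts to probabilities summing to 1.
    """
    x = np.asarray(series, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty series")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    lo = np.floor(x.min() / bin_width) * bin_width
    hi = (np.floor(x.max() / bin_width) + 1) * bin_width
    n_bins = int(round((hi - lo) / bin_width))
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(x, bins=edges)
    counts = counts.astype(float)
    if normalize:
        counts = counts / x.size
    return Histogram(edges=edges, counts=counts, bin_width=float(bin_width),
                     normalized=normalize)
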