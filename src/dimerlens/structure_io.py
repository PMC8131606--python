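"""Molecular structures, frame series and atom selections.

The in-memory containers are deliberately small: a :class:`MolecularFrame`
is a struct-of-arrays over atoms (names, residues, chains, coordinates,
role tags, radii) and a :class:`TrajectoryEnsemble` is an ordered list of
frames sharing one topology.  PDB reading/writing is delegated to biotite;
frame series use a minimal XYZ dialect (two header lines, element symbol
plus three floats per atom) with the topology supplied separately, so the
XYZ file carries coordinates only.

Role tags classify atoms by the part they play in the micelle analyses:
``protein``, ``detergent_head`` (the DDM O5-type headgroup oxygen),
``detergent_tail`` (hydrocarbon tail atoms C1-C12), ``water``, ``ion`` or
``other``.  Tags are assigned on read from residue/atom-name lookup tables
and may be overridden.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import biotite.structure as _struc
from biotite.structure.io.pdb import PDBFile as _PDBFile

__all__ = [
    "ROLE_TAGS",
    "BONDI_RADII",
    "MolecularFrame",
    "TrajectoryEnsemble",
    "SelectionExpr",
    "StructureParseError",
    "read_structure",
    "write_structure",
    "read_frames",
    "write_frames",
    "select_atoms",
    "bw_label",
    "bw_residue",
]


ROLE_TAGS = ("protein", "detergent_head", "detergent_tail", "water", "ion", "other")

#: Bondi van der Waals radii (Å) by element; used for SASA unless overridden.
BONDI_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
}
_DEFAULT_RADIUS = 1.70

_WATER_RESNAMES = {"HOH", "TIP3", "TIP", "WAT", "SOL", "SPC"}
_ION_RESNAMES = {"NA", "CL", "K", "POT", "CLA", "SOD", "MG", "CA", "ZN"}
_DETERGENT_RESNAMES = {"LMT", "DDM", "BDM", "DET"}
_TAIL_ATOM_NAMES = {f"C{i}" for i in range(1, 13)}


class StructureParseError(ValueError):
    """Raised when a structure file cannot be parsed."""


def _radius_for(element: str) -> float:
    return BONDI_RADII.get(element.upper(), _DEFAULT_RADIUS)


def _role_for(res_name: str, atom_name: str, hetero: bool) -> str:
    rn = res_name.strip().upper()
    if rn in _WATER_RESNAMES:
        return "water"
    if rn in _ION_RESNAMES:
        return "ion"
    if rn in _DETERGENT_RESNAMES:
        if atom_name.strip().upper() in _TAIL_ATOM_NAMES:
            return "detergent_tail"
        return "detergent_head"
    if not hetero:
        return "protein"
    return "other"


@dataclass
class MolecularFrame:
    """One set of atomic coordinates with per-atom metadata.

    All per-atom fields are numpy arrays of equal length; ``coords`` has
    shape ``(n_atoms, 3)`` in Å.  Atom order is significant and stable
    across the frames of one ensemble.
    """

    atom_name: np.ndarray
    element: np.ndarray
    res_name: np.ndarray
    res_id: np.ndarray
    chain_id: np.ndarray
    coords: np.ndarray
    role_tag: np.ndarray
    radius: np.ndarray
    frame_time: float = 0.0
    box: np.ndarray | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (n_atoms, 3)")
        n = self.coords.shape[0]
        for name in ("atom_name", "element", "res_name", "res_id",
                     "chain_id", "role_tag", "radius"):
            arr = np.asarray(getattr(self, name))
            if arr.shape[0] != n:
                raise ValueError(f"{name} length {arr.shape[0]} != n_atoms {n}")
            setattr(self, name, arr)
        self.res_id = self.res_id.astype(int)
        self.radius = self.radius.astype(float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def copy(self) -> "MolecularFrame":
        return MolecularFrame(
            atom_name=self.atom_name.copy(), element=self.element.copy(),
            res_name=self.res_name.copy(), res_id=self.res_id.copy(),
            chain_id=self.chain_id.copy(), coords=self.coords.copy(),
            role_tag=self.role_tag.copy(), radius=self.radius.copy(),
            frame_time=self.frame_time,
            box=None if self.box is None else np.asarray(self.box, float).copy(),
        )

    def with_coords(self, coords: np.ndarray, frame_time: float | None = None) -> "MolecularFrame":
        """New frame sharing this topology with replaced coordinates."""
        out = self.copy()
        coords = np.asarray(coords, dtype=float)
        if coords.shape != self.coords.shape:
            raise ValueError("coordinate shape mismatch")
        out.coords = coords
        if frame_time is not None:
            out.frame_time = frame_time
        return out

    def subset(self, indices: np.ndarray) -> "MolecularFrame":
        idx = np.asarray(indices, dtype=int)
        return MolecularFrame(
            atom_name=self.atom_name[idx], element=self.element[idx],
            res_name=self.res_name[idx], res_id=self.res_id[idx],
            chain_id=self.chain_id[idx], coords=self.coords[idx],
            role_tag=self.role_tag[idx], radius=self.radius[idx],
            frame_time=self.frame_time,
            box=None if self.box is None else self.box.copy(),
        )

    def same_topology(self, other: "MolecularFrame") -> bool:
        return (
            self.n_atoms == other.n_atoms
            and np.array_equal(self.atom_name, other.atom_name)
            and np.array_equal(self.res_id, other.res_id)
            and np.array_equal(self.res_name, other.res_name)
            and np.array_equal(self.chain_id, other.chain_id)
        )


@dataclass
class TrajectoryEnsemble:
    """Ordered frames over one topology."""

    frames: list
    replicate_id: str = ""
    time_step: float = 1.0

    def __post_init__(self):
        if not self.frames:
            raise ValueError("ensemble needs at least one frame")
        top = self.frames[0]
        for i, fr in enumerate(self.frames[1:], start=1):
            if not top.same_topology(fr):
                raise ValueError(f"frame {i} topology differs from frame 0")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i):
        return self.frames[i]

    @property
    def times(self) -> np.ndarray:
        return np.array([fr.frame_time for fr in self.frames], dtype=float)


@dataclass
class SelectionExpr:
    """Conjunctive atom selection; empty expression selects everything.

    ``residue_range`` is inclusive on both ends (author numbering).
    """

    chain_ids: Sequence[str] | None = None
    residue_range: tuple | None = None
    atom_names: Sequence[str] | None = None
    role_tags: Sequence[str] | None = None

    @classmethod
    def from_dict(cls, d: dict) -> "SelectionExpr":
        rr = d.get("residue_range")
        return cls(
            chain_ids=d.get("chain_ids"),
            residue_range=None if rr is None else (int(rr[0]), int(rr[1])),
            atom_names=d.get("atom_names"),
            role_tags=d.get("role_tags"),
        )


def select_atoms(frame: MolecularFrame, expr: SelectionExpr | dict | None = None) -> np.ndarray:
    """Indices (ascending) of atoms matching every supplied criterion."""
    if expr is None:
        expr = SelectionExpr()
    if isinstance(expr, dict):
        expr = SelectionExpr.from_dict(expr)
    mask = np.ones(frame.n_atoms, dtype=bool)
    if expr.chain_ids is not None:
        mask &= np.isin(frame.chain_id, list(expr.chain_ids))
    if expr.residue_range is not None:
        lo, hi = expr.residue_range
        mask &= (frame.res_id >= lo) & (frame.res_id <= hi)
    if expr.atom_names is not None:
        mask &= np.isin(frame.atom_name, list(expr.atom_names))
    if expr.role_tags is not None:
        mask &= np.isin(frame.role_tag, list(expr.role_tags))
    return np.nonzero(mask)[0]


# ---------------------------------------------------------------------------
# PDB input/output (biotite-backed)
# ---------------------------------------------------------------------------

def _validate_pdb_lines(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM  ", "HETATM")):
                try:
                    float(line[30:38]); float(line[38:46]); float(line[46:54])
                    int(line[22:26])
                except (ValueError, IndexError):
                    raise StructureParseError(
                        f"{path}: unparseable coordinate record at line {lineno}"
                    ) from None


def _frame_from_atom_array(arr, frame_time: float = 0.0) -> MolecularFrame:
    hetero = arr.hetero if "hetero" in arr.get_annotation_categories() else np.zeros(arr.array_length(), bool)
    elements = np.array([
        e if e else ("".join(c for c in a if c.isalpha())[:1] or "C")
        for e, a in zip(arr.element, arr.atom_name)
    ])
    roles = np.array([
        _role_for(rn, an, bool(h))
        for rn, an, h in zip(arr.res_name, arr.atom_name, hetero)
    ])
    radii = np.array([_radius_for(e) for e in elements], dtype=float)
    return MolecularFrame(
        atom_name=np.asarray(arr.atom_name), element=elements,
        res_name=np.asarray(arr.res_name), res_id=np.asarray(arr.res_id, int),
        chain_id=np.asarray(arr.chain_id), coords=np.asarray(arr.coord, float),
        role_tag=roles, radius=radii, frame_time=frame_time,
    )


def read_structure(path) -> MolecularFrame | TrajectoryEnsemble:
    """Read a PDB file; multi-MODEL files yield a :class:`TrajectoryEnsemble`.

    Author residue numbering is preserved.  HETATM records are role-tagged
    from residue-name lookup (HOH-type -> water, LMT/DDM -> detergent with
    C1-C12 as tail atoms, common ions -> ion).
    """
    path = Path(path)
    _validate_pdb_lines(path)
    pdb = _PDBFile.read(str(path))
    n_models = pdb.get_model_count()
    if n_models == 1:
        arr = pdb.get_structure(model=1)
        return _frame_from_atom_array(arr)
    try:
        stack = pdb.get_structure(model=None)
    except Exception as exc:  # inconsistent atom counts across models
        raise StructureParseError(
            f"{path}: inconsistent models ({exc})"
        ) from exc
    frames = [
        _frame_from_atom_array(stack[i], frame_time=float(i))
        for i in range(stack.stack_depth())
    ]
    return TrajectoryEnsemble(frames=frames)


def _atom_array_from_frame(frame: MolecularFrame):
    arr = _struc.AtomArray(frame.n_atoms)
    arr.coord = frame.coords.astype(np.float32)
    arr.atom_name = frame.atom_name.astype("U6")
    arr.res_name = frame.res_name.astype("U5")
    arr.res_id = frame.res_id
    arr.chain_id = frame.chain_id.astype("U4")
    arr.element = frame.element.astype("U2")
    arr.set_annotation("hetero", frame.role_tag != "protein")
    return arr


def write_structure(path, frames: MolecularFrame | TrajectoryEnsemble | Iterable[MolecularFrame]) -> None:
    """Write one frame (single model) or several (multi-MODEL PDB)."""
    if isinstance(frames, MolecularFrame):
        frames = [frames]
    elif isinstance(frames, TrajectoryEnsemble):
        frames = frames.frames
    else:
        frames = list(frames)
    pdb = _PDBFile()
    if len(frames) == 1:
        pdb.set_structure(_atom_array_from_frame(frames[0]))
    else:
        arrays = [_atom_array_from_frame(fr) for fr in frames]
        stack = _struc.stack(arrays)
        pdb.set_structure(stack)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# XYZ frame series (coordinates only; topology sidecar carries metadata)
# ---------------------------------------------------------------------------

def write_frames(path, ensemble: TrajectoryEnsemble | Iterable[MolecularFrame]) -> None:
    """Write frames as a concatenated XYZ series (element x y z)."""
    frames = ensemble.frames if isinstance(ensemble, TrajectoryEnsemble) else list(ensemble)
    with open(path, "w") as fh:
        for fr in frames:
            fh.write(f"{fr.n_atoms}\n")
            fh.write(f"t= {fr.frame_time:.6f}\n")
            for el, (x, y, z) in zip(fr.element, fr.coords):
                fh.write(f"{el:<2s} {x:14.6f} {y:14.6f} {z:14.6f}\n")


def read_frames(path, topology: MolecularFrame, time_step: float = 1.0,
                replicate_id: str = "") -> TrajectoryEnsemble:
    """Read an XYZ frame series onto a topology frame.

    Coordinates replace the topology's per frame; names, residues, chains,
    roles and radii come from the topology.  Atom counts must match.
    """
    frames = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    pos = 0
    frame_index = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            n = int(lines[pos].split()[0])
        except ValueError:
            raise StructureParseError(
                f"{path}: expected atom count at line {pos + 1}"
            ) from None
        if n != topology.n_atoms:
            raise StructureParseError(
                f"{path}: frame {frame_index} has {n} atoms, topology has {topology.n_atoms}"
            )
        comment = lines[pos + 1] if pos + 1 < len(lines) else ""
        t = frame_index * time_step
        if "t=" in comment:
            try:
                t = float(comment.split("t=")[1].split()[0])
            except (ValueError, IndexError):
                pass
        body = lines[pos + 2: pos + 2 + n]
        if len(body) < n:
            raise StructureParseError(f"{path}: truncated frame {frame_index}")
        coords = np.empty((n, 3), dtype=float)
        for i, line in enumerate(body):
            parts = line.split()
            if len(parts) < 4:
                raise StructureParseError(
                    f"{path}: bad atom line in frame {frame_index}: {line!r}"
                )
            coords[i] = [float(parts[1]), float(parts[2]), float(parts[3])]
        frames.append(topology.with_coords(coords, frame_time=t))
        pos += 2 + n
        frame_index += 1
    if not frames:
        raise StructureParseError(f"{path}: no frames found")
    return TrajectoryEnsemble(frames=frames, replicate_id=replicate_id, time_step=time_step)


# ---------------------------------------------------------------------------
# Ballesteros-Weinstein generic numbering (bovine rhodopsin)
# ---------------------------------------------------------------------------

# (helix, first_residue, last_residue, residue_at_x.50)
_BW_HELICES = (
    (1, 35, 64, 55),
    (2, 71, 100, 83),
    (3, 106, 139, 135),
    (4, 149, 173, 161),
    (5, 200, 236, 215),
    (6, 240, 279, 267),
    (7, 285, 309, 303),
)


def bw_label(residue_number: int) -> str:
    """Ballesteros-Weinstein label ``H.pos`` for a bovine-rhodopsin residue.

    >>> bw_label(220)
    '5.55'
    """
    n = int(residue_number)
    for helix, lo, hi, anchor in _BW_HELICES:
        if lo <= n <= hi:
            return f"{helix}.{50 + n - anchor}"
    raise KeyError(f"residue {n} is outside the packaged TM-helix table")


def bw_residue(label: str) -> int:
    """Inverse of :func:`bw_label`: ``'5.55' -> 220``."""
    try:
        helix_s, pos_s = str(label).split(".")
        helix, pos = int(helix_s), int(pos_s)
    except ValueError:
        raise KeyError(f"malformed Ballesteros-Weinstein label {label!r}") from None
    for h, lo, hi, anchor in _BW_HELICES:
        if h == helix:
            n = anchor + (pos - 50)
            if lo <= n <= hi:
                return n
            raise KeyError(f"label {label} falls outside helix {helix} range")
    raise KeyError(f"unknown helix in label {label!r}")
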