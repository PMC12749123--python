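"""Core in-memory containers: atoms, frames, trajectories, leaflet assignments.

Positions are stored in nanometres throughout the package; file readers
convert at the boundary (PDB ångströms are divided by 10 on input).
The bilayer normal is +z and the "upper" leaflet is the one at larger z.
Boxes are orthorhombic only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np

__all__ = ["AtomRecord", "Frame", "Trajectory", "LeafletAssignment"]


@dataclass(frozen=True)
class AtomRecord:
    """A single atom: identity plus a position in nm."""

    serial: int
    atom_name: str
    res_name: str
    res_id: int
    position: np.ndarray  # (3,) nm
    element: Optional[str] = None

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.serial}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)


class Frame:
    """One molecular snapshot: parallel per-atom arrays plus an orthorhombic box.

    Parameters
    ----------
    names, res_names : array-like of str
    res_ids, serials : array-like of int (serials default to 1..n)
    positions : (n, 3) float array, nm
    box : (Lx, Ly, Lz) in nm, all > 0
    elements : optional array of element symbols; inferred later if absent
    label : free-form tag (e.g. a time stamp or model number)
    """

    def __init__(self, names, res_names, res_ids, positions, box,
                 serials=None, elements=None, label: str = ""):
        self.names = np.asarray(names, dtype=object)
        self.res_names = np.asarray(res_names, dtype=object)
        self.res_ids = np.asarray(res_ids, dtype=int)
        self.positions = np.asarray(positions, dtype=float).reshape(-1, 3)
        n = len(self.names)
        if not (len(self.res_names) == len(self.res_ids) == self.positions.shape[0] == n):
            raise ValueError("per-atom arrays must have equal length")
        if serials is None:
            serials = np.arange(1, n + 1)
        self.serials = np.asarray(serials, dtype=int)
        if len(np.unique(self.serials)) != n:
            raise ValueError("atom serials must be unique within a frame")
        self.elements = None if elements is None else np.asarray(elements, dtype=object)
        box = np.asarray(box, dtype=float).reshape(3)
        if not np.all(np.isfinite(box)) or np.any(box <= 0):
            raise ValueError(f"box must have three positive components, got {box}")
        self.box = box
        self.label = label
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    def atom(self, i: int) -> AtomRecord:
        return AtomRecord(
            serial=int(self.serials[i]),
            atom_name=str(self.names[i]),
            res_name=str(self.res_names[i]),
            res_id=int(self.res_ids[i]),
            position=self.positions[i].copy(),
            element=None if self.elements is None else str(self.elements[i]),
        )

    def __iter__(self) -> Iterator[AtomRecord]:
        return (self.atom(i) for i in range(self.n_atoms))

    def __len__(self) -> int:
        return self.n_atoms

    def select(self, mask) -> "Frame":
        """Sub-frame of the atoms where ``mask`` is true (order preserved)."""
        mask = np.asarray(mask)
        return Frame(
            self.names[mask], self.res_names[mask], self.res_ids[mask],
            self.positions[mask], self.box, serials=self.serials[mask],
            elements=None if self.elements is None else self.elements[mask],
            label=self.label,
        )

    def copy(self) -> "Frame":
        return Frame(self.names.copy(), self.res_names.copy(), self.res_ids.copy(),
                     self.positions.copy(), self.box.copy(), serials=self.serials.copy(),
                     elements=None if self.elements is None else self.elements.copy(),
                     label=self.label)

    def residue_keys(self) -> np.ndarray:
        """(res_id, res_name) pair per atom, for grouping atoms into residues."""
        return np.array([f"{rid}:{rn}" for rid, rn in zip(self.res_ids, self.res_names)],
                        dtype=object)


@dataclass
class Trajectory:
    """An ordered sequence of frames with identical atom identity."""

    frames: list

    def __post_init__(self):
        if len(self.frames) == 0:
            raise ValueError("a trajectory needs at least one frame")
        ref = self.frames[0]
        for k, fr in enumerate(self.frames):
            if fr.n_atoms != ref.n_atoms:
                raise ValueError(
                    f"frame {k}: atom count {fr.n_atoms} differs from frame 0 ({ref.n_atoms})")
            if not (np.array_equal(fr.names, ref.names)
                    and np.array_equal(fr.res_ids, ref.res_ids)):
                raise ValueError(f"frame {k}: atom identity differs from frame 0")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i):
        return self.frames[i]


@dataclass
class LeafletAssignment:
    """Per-lipid-residue leaflet labels plus the bilayer midplane height.

    ``leaflet_of`` maps "res_id:res_name" keys to "upper" or "lower".
    """

    leaflet_of: dict
    midplane_z: float

    def residues(self, leaflet: str) -> set:
        return {k for k, v in self.leaflet_of.items() if v == leaflet}
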