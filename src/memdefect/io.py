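"""Coordinate file reading and writing (GRO and PDB) via MDAnalysis.

All positions cross this boundary in nanometres: PDB ångström coordinates
are divided by 10 on input and multiplied back on output.  Boxes must be
orthorhombic; triclinic boxes are rejected.  GRO files may contain several
concatenated frames; PDB files may contain several MODEL records.
"""

from __future__ import annotations

import io as _io
import os
import warnings

import numpy as np

from .models import Frame, Trajectory

__all__ = ["read_structure", "read_trajectory", "write_structure", "write_trajectory"]

_ANGLE_TOL = 1e-3


def _detect_format(path, fmt):
    if fmt is not None:
        f = fmt.lower().replace("-multiframe", "").replace("-multimodel", "")
        if f not in ("gro", "pdb"):
            raise ValueError(f"unsupported format {fmt!r}; expected 'gro' or 'pdb'")
        return f
    ext = os.path.splitext(str(path))[1].lower().lstrip(".")
    if ext in ("gro", "pdb"):
        return ext
    raise ValueError(f"cannot infer format from {path!r}; pass format='gro' or 'pdb'")


def _check_box(dimensions, path):
    if dimensions is None or not np.all(np.asarray(dimensions)[:3] > 0):
        raise ValueError(f"{path}: no box information (GRO box line / PDB CRYST1 required)")
    dims = np.asarray(dimensions, dtype=float)
    if np.any(np.abs(dims[3:] - 90.0) > _ANGLE_TOL):
        raise ValueError(f"{path}: triclinic box (angles {dims[3:]}) not supported")
    return dims[:3] / 10.0  # Angstrom -> nm


def _frame_from_universe(u, path, label="", fallback_dims=None):
    dims = u.dimensions if u.dimensions is not None else fallback_dims
    box = _check_box(dims, path)
    atoms = u.atoms
    elements = None
    if hasattr(atoms, "elements"):
        els = np.asarray(atoms.elements, dtype=object)
        if any(e for e in els):
            elements = np.array([e.capitalize() if e else "" for e in els], dtype=object)
    return Frame(
        names=np.asarray(atoms.names, dtype=object),
        res_names=np.asarray(atoms.resnames, dtype=object),
        res_ids=np.asarray(atoms.resids, dtype=int),
        positions=atoms.positions.astype(float) / 10.0,
        box=box,
        elements=elements,
        label=label,
    )


def _universe_from_text(text, suffix, path):
    import MDAnalysis as mda
    from MDAnalysis.lib.util import NamedStream

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stream = NamedStream(_io.StringIO(text), f"memdefect_block{suffix}")
        return mda.Universe(stream)


def _read_cryst1(path):
    with open(path) as fh:
        for line in fh:
            if line.startswith("CRYST1"):
                return np.array([float(line[6:15]), float(line[15:24]),
                                 float(line[24:33]), float(line[33:40]),
                                 float(line[40:47]), float(line[47:54])])
    return None


def _split_gro_blocks(path):
    """Split a (possibly concatenated) GRO file into per-frame text blocks."""
    with open(path) as fh:
        lines = fh.readlines()
    blocks, i = [], 0
    while i < len(lines):
        if not lines[i].strip() and i == len(lines) - 1:
            break
        if i + 1 >= len(lines):
            raise ValueError(f"{path}: truncated GRO frame starting at line {i + 1}")
        try:
            natoms = int(lines[i + 1].strip())
        except ValueError:
            raise ValueError(
                f"{path}: line {i + 2}: expected an atom count, got {lines[i + 1]!r}") from None
        end = i + 2 + natoms + 1
        if end > len(lines):
            raise ValueError(f"{path}: truncated GRO frame starting at line {i + 1}")
        blocks.append("".join(lines[i:end]))
        i = end
    if not blocks:
        raise ValueError(f"{path}: empty GRO file")
    return blocks


def read_trajectory(path, format=None) -> Trajectory:
    """Read a multi-frame GRO or multi-MODEL PDB file.

    Frames must share atom count and ordering; a mismatch raises an error
    naming the offending frame index.
    """
    fmt = _detect_format(path, format)
    frames = []
    if fmt == "gro":
        for k, block in enumerate(_split_gro_blocks(path)):
            try:
                u = _universe_from_text(block, ".gro", path)
            except Exception as exc:
                raise ValueError(f"{path}: frame {k}: GRO parse error: {exc}") from exc
            frames.append(_frame_from_universe(u, path, label=str(k)))
    else:
        import MDAnalysis as mda
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                u = mda.Universe(str(path))
            except Exception as exc:
                raise ValueError(f"{path}: PDB parse error: {exc}") from exc
            # a single CRYST1 record before MODEL 1 applies to every MODEL,
            # but MDAnalysis only exposes per-frame boxes; recover it here
            dims0 = _read_cryst1(path)
            for k, _ts in enumerate(u.trajectory):
                frames.append(_frame_from_universe(u, path, label=str(k),
                                                   fallback_dims=dims0))
    ref = frames[0]
    for k, fr in enumerate(frames):
        if fr.n_atoms != ref.n_atoms or not np.array_equal(fr.names, ref.names):
            raise ValueError(
                f"{path}: frame {k} does not match frame 0 "
                f"({fr.n_atoms} vs {ref.n_atoms} atoms)")
    return Trajectory(frames)


def read_structure(path, format=None) -> Frame:
    """Read a single frame (the first, for multi-frame files)."""
    return read_trajectory(path, format=format)[0]


def _universe_for_frame(frame: Frame):
    import MDAnalysis as mda

    # consecutive (res_id, res_name) runs -> residues
    keys = list(zip(frame.res_ids.tolist(), frame.res_names.tolist()))
    resindex = np.empty(frame.n_atoms, dtype=int)
    res_names, res_ids = [], []
    prev = None
    r = -1
    for i, key in enumerate(keys):
        if key != prev:
            r += 1
            res_ids.append(key[0])
            res_names.append(key[1])
            prev = key
        resindex[i] = r
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(frame.n_atoms, n_residues=r + 1,
                               atom_resindex=resindex,
                               residue_segindex=np.zeros(r + 1, dtype=int),
                               trajectory=True)
        u.add_TopologyAttr("names", [str(n) for n in frame.names])
        u.add_TopologyAttr("resnames", res_names)
        u.add_TopologyAttr("resids", res_ids)
        u.atoms.positions = frame.positions * 10.0
        u.dimensions = [*(frame.box * 10.0), 90.0, 90.0, 90.0]
    return u


def write_structure(frame: Frame, path, format=None):
    """Write one frame as GRO (positions to 3 decimals, nm) or PDB."""
    if frame.n_atoms == 0:
        raise ValueError("refusing to write an empty frame")
    fmt = _detect_format(path, format)
    u = _universe_for_frame(frame)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))
    return path


def write_trajectory(traj: Trajectory, path, format=None):
    """Write a trajectory as concatenated GRO frames or a multi-MODEL PDB."""
    fmt = _detect_format(path, format)
    if fmt == "gro":
        import tempfile
        chunks = []
        for fr in traj:
            with tempfile.NamedTemporaryFile(suffix=".gro", mode="r", delete=False) as tmp:
                tmpname = tmp.name
            try:
                write_structure(fr, tmpname, format="gro")
                with open(tmpname) as fh:
                    chunks.append(fh.read())
            finally:
                os.unlink(tmpname)
        with open(path, "w") as fh:
            fh.write("".join(chunks))
    else:
        import MDAnalysis as mda
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            with mda.Writer(str(path), multiframe=True,
                            n_atoms=traj[0].n_atoms) as w:
                for fr in traj:
                    w.write(_universe_for_frame(fr).atoms)
    return path
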