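"""Lipid topology/parameter configuration.

A :class:`LipidTopologySpec` tells the analysis which atoms of each lipid
residue are headgroup, glycerol-backbone, or tail atoms; what van der Waals
radius each element carries; and (for energy calculations) each atom's
partial charge and Lennard-Jones parameters.

Built-in defaults cover the common unsaturated phospholipids DOPC / DOPE /
DOPS (CHARMM-style atom names), cholesterol, and the coarse pseudo-lipids
produced by :mod:`memdefect.synth`.  A TOML config file can override or
extend any of these tables; see :func:`load_topology_spec` for the schema.

Radii default to Bondi values (nm): H 0.120, C 0.170, N 0.155, O 0.152,
P 0.180, S 0.180.  Sterols have no glycerol backbone; their ring-anchor
carbon (CHOL C3, pseudo SG1) plays the glycerol role so every lipid entry
has a non-empty glycerol set and sterols contribute sensibly to the
glycerol reference plane.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

__all__ = ["LipidEntry", "LipidTopologySpec", "load_topology_spec",
           "default_topology_spec", "load_params_tsv"]


@dataclass
class LipidEntry:
    headgroup_atoms: frozenset
    glycerol_atoms: frozenset
    tail_atoms: frozenset = frozenset()

    def validate(self, res_name: str):
        if not self.headgroup_atoms:
            raise ValueError(f"lipid {res_name}: headgroup atom set is empty")
        if not self.glycerol_atoms:
            raise ValueError(f"lipid {res_name}: glycerol atom set is empty")


_BONDI = {"H": 0.120, "C": 0.170, "N": 0.155, "O": 0.152, "P": 0.180, "S": 0.180}

# Pseudo-element radii used by the coarse-grained synthetic lipids (nm).
# EH: phospholipid headgroup bead; TG: upper-tail guard bead; GB: glycerol
# marker bead; TB: tail bead; SH: sterol hydroxyl-head bead; FQ: single-cell
# filler bead used by the defect-carving fixture machinery.
_PSEUDO_RADII = {"EH": 0.72, "TG": 0.85, "GB": 0.05, "TB": 0.17,
                 "SH": 0.05, "FQ": 0.05}

_GLYCEROL_PL = frozenset({"C1", "C2", "C3", "C21", "C31", "O21", "O22", "O31", "O32"})

_DEFAULT_LIPIDS = {
    "DOPC": LipidEntry(
        frozenset({"N", "C11", "C12", "C13", "C14", "C15",
                   "P", "O11", "O12", "O13", "O14"}), _GLYCEROL_PL),
    "DOPE": LipidEntry(
        frozenset({"N", "C11", "C12", "P", "O11", "O12", "O13", "O14"}), _GLYCEROL_PL),
    "DOPS": LipidEntry(
        frozenset({"N", "C11", "C12", "C13", "O13A", "O13B",
                   "P", "O11", "O12", "O13", "O14"}), _GLYCEROL_PL),
    "CHOL": LipidEntry(frozenset({"O3", "H3'"}), frozenset({"C3"})),
    # synthetic pseudo-lipids (see memdefect.synth)
    "PCX": LipidEntry(frozenset({"EH1", "OA1"}), frozenset({"GB1"}),
                      frozenset({"TG1", "TA1", "TA2"})),
    "PEX": LipidEntry(frozenset({"EH1", "OA1"}), frozenset({"GB1"}),
                      frozenset({"TG1", "TA1", "TA2"})),
    "PSX": LipidEntry(frozenset({"EH1", "OA1"}), frozenset({"GB1"}),
                      frozenset({"TG1", "TA1", "TA2"})),
    "CHX": LipidEntry(frozenset({"SH1"}), frozenset({"SG1"}),
                      frozenset({"SO1", "SB1", "SB2"})),
    "FIL": LipidEntry(frozenset({"FQ1"}), frozenset({"FG1"})),
}

_PSEUDO_ELEMENTS = {}
for _res in ("PCX", "PEX", "PSX"):
    _PSEUDO_ELEMENTS.update({
        (_res, "EH1"): "EH", (_res, "OA1"): "O", (_res, "GB1"): "GB",
        (_res, "TG1"): "TG", (_res, "TA1"): "TB", (_res, "TA2"): "TB",
    })
_PSEUDO_ELEMENTS.update({
    ("CHX", "SH1"): "SH", ("CHX", "SO1"): "O", ("CHX", "SG1"): "GB",
    ("CHX", "SB1"): "TB", ("CHX", "SB2"): "TB",
    ("FIL", "FQ1"): "FQ",
})

# (charge e, sigma nm, epsilon kJ/mol) for the synthetic beads; only the
# PS-like acceptor bead and the sterol hydroxyl carry net charge.
_PSEUDO_CHARGE_LJ = {}
for _res in ("PCX", "PEX", "PSX"):
    for _a in ("EH1", "GB1", "TG1", "TA1", "TA2"):
        _PSEUDO_CHARGE_LJ[(_res, _a)] = (0.0, 0.30, 0.10)
    _PSEUDO_CHARGE_LJ[(_res, "OA1")] = (0.0, 0.30, 0.50)
_PSEUDO_CHARGE_LJ[("PSX", "OA1")] = (-1.0, 0.30, 0.50)
for _a in ("SH1", "SG1", "SB1", "SB2"):
    _PSEUDO_CHARGE_LJ[("CHX", _a)] = (0.0, 0.30, 0.10)
_PSEUDO_CHARGE_LJ[("CHX", "SO1")] = (-0.2, 0.30, 0.50)
_PSEUDO_CHARGE_LJ[("FIL", "FQ1")] = (0.0, 0.30, 0.10)
# probe pseudo-protein: PRC residues carry +1e on the backbone nitrogen
for _res, _q in (("PRC", 1.0), ("PRN", 0.0)):
    _PSEUDO_CHARGE_LJ.update({
        (_res, "N"): (_q, 0.32, 0.50), (_res, "HN"): (0.0, 0.10, 0.05),
        (_res, "O"): (0.0, 0.30, 0.50), (_res, "CB"): (0.0, 0.35, 0.30),
    })


@dataclass
class LipidTopologySpec:
    """Role assignment plus radius / charge / LJ lookup tables."""

    lipids: Dict[str, LipidEntry] = field(default_factory=dict)
    radius_table: Dict[str, float] = field(default_factory=dict)
    charge_lj: Dict[Tuple[str, str], Tuple[float, float, float]] = field(default_factory=dict)
    element_overrides: Dict[Tuple[str, str], str] = field(default_factory=dict)

    def validate(self):
        for res, entry in self.lipids.items():
            entry.validate(res)
        for el, r in self.radius_table.items():
            if not (r > 0):
                raise ValueError(f"radius for element {el} must be positive, got {r}")
        for key, (_q, _s, eps) in self.charge_lj.items():
            if eps < 0:
                raise ValueError(f"epsilon for {key} must be >= 0")
        return self

    # -- lookups ---------------------------------------------------------
    def is_lipid(self, res_name: str) -> bool:
        return res_name in self.lipids

    def role_of(self, res_name: str, atom_name: str) -> Optional[str]:
        """'headgroup' | 'glycerol' | 'tail' for lipid atoms, else None.

        Lipid atoms not named in any role set are treated as tail atoms:
        the defect analysis only needs the head and glycerol sets to be
        exhaustive.
        """
        entry = self.lipids.get(res_name)
        if entry is None:
            return None
        if atom_name in entry.headgroup_atoms:
            return "headgroup"
        if atom_name in entry.glycerol_atoms:
            return "glycerol"
        return "tail"

    def element_of(self, res_name: str, atom_name: str) -> str:
        el = self.element_overrides.get((res_name, atom_name))
        if el is not None:
            return el
        return infer_element(atom_name)

    def radius_for(self, element: str, context: str = "") -> float:
        try:
            return self.radius_table[element]
        except KeyError:
            raise KeyError(
                f"no van der Waals radius for element {element!r}"
                + (f" (atom {context})" if context else "")) from None

    def charge_lj_for(self, res_name: str, atom_name: str) -> Tuple[float, float, float]:
        try:
            return self.charge_lj[(res_name, atom_name)]
        except KeyError:
            raise KeyError(
                f"no charge/LJ parameters for atom {atom_name!r} of residue "
                f"{res_name!r}") from None

    def resolve_elements(self, frame) -> np.ndarray:
        """Element symbol per atom: explicit > override table > name inference."""
        out = np.empty(frame.n_atoms, dtype=object)
        for i in range(frame.n_atoms):
            if frame.elements is not None and frame.elements[i]:
                out[i] = frame.elements[i]
            else:
                out[i] = self.element_of(str(frame.res_names[i]), str(frame.names[i]))
        return out

    # -- serialization ---------------------------------------------------
    def to_toml_str(self) -> str:
        lines = []
        for res in sorted(self.lipids):
            e = self.lipids[res]
            lines.append(f"[lipids.{res}]")
            lines.append("headgroup = [" + ", ".join(f'"{a}"' for a in sorted(e.headgroup_atoms)) + "]")
            lines.append("glycerol = [" + ", ".join(f'"{a}"' for a in sorted(e.glycerol_atoms)) + "]")
            lines.append("tails = [" + ", ".join(f'"{a}"' for a in sorted(e.tail_atoms)) + "]")
            lines.append("")
        lines.append("[radii]")
        for el in sorted(self.radius_table):
            lines.append(f'"{el}" = {self.radius_table[el]!r}')
        lines.append("")
        by_res = {}
        for (res, atom), el in self.element_overrides.items():
            by_res.setdefault(res, {})[atom] = el
        for res in sorted(by_res):
            lines.append(f"[elements.{res}]")
            for atom in sorted(by_res[res]):
                lines.append(f'"{atom}" = "{by_res[res][atom]}"')
            lines.append("")
        by_res = {}
        for (res, atom), v in self.charge_lj.items():
            by_res.setdefault(res, {})[atom] = v
        for res in sorted(by_res):
            lines.append(f"[charges.{res}]")
            for atom in sorted(by_res[res]):
                q, s, e = by_res[res][atom]
                lines.append(f'"{atom}" = [{q!r}, {s!r}, {e!r}]')
            lines.append("")
        return "\n".join(lines) + "\n"


_ELEMENT_EXCEPTIONS = {"CL": "Cl", "NA": "Na", "MG": "Mg", "K": "K"}


def infer_element(atom_name: str) -> str:
    """Guess an element from a (lipid-flavoured) atom name.

    GRO files carry no element field; lipid force-field names start with
    the element letter (C216, O22, P, N, H11A ...), so the leading
    alphabetic character is taken, after stripping any leading digits
    (PDB hydrogens like '1H5').
    """
    name = atom_name.strip().lstrip("0123456789'\"*")
    if not name:
        raise ValueError(f"cannot infer element from atom name {atom_name!r}")
    head = "".join(ch for ch in name if ch.isalpha())[:2].upper()
    if head in _ELEMENT_EXCEPTIONS:
        return _ELEMENT_EXCEPTIONS[head]
    return name[0].upper()


def default_topology_spec() -> LipidTopologySpec:
    """Built-in defaults: DOPC/DOPE/DOPS/CHOL plus the synthetic pseudo-lipids."""
    radii = dict(_BONDI)
    radii.update(_PSEUDO_RADII)
    return LipidTopologySpec(
        lipids=dict(_DEFAULT_LIPIDS),
        radius_table=radii,
        charge_lj=dict(_PSEUDO_CHARGE_LJ),
        element_overrides=dict(_PSEUDO_ELEMENTS),
    ).validate()


_ROLE_KEYS = {"headgroup", "glycerol", "tails"}
_TOP_KEYS = {"lipids", "radii", "elements", "charges"}


def load_topology_spec(path=None) -> LipidTopologySpec:
    """Load a TOML topology config, merged over the built-in defaults.

    Schema::

        [lipids.DOPC]
        headgroup = ["N", "P", ...]     # role keys: headgroup, glycerol, tails
        glycerol  = ["C1", ...]

        [radii]
        C = 0.17                        # element -> vdW radius, nm

        [elements.PCX]
        EH1 = "EH"                      # (residue, atom) -> element symbol

        [charges.PSX]
        OA1 = [-1.0, 0.30, 0.50]        # charge e, sigma nm, epsilon kJ/mol

    An empty or absent config returns the defaults unchanged.
    """
    spec = default_topology_spec()
    if path is None:
        return spec
    with open(path, "rb") as fh:
        data = tomllib.load(fh)

    unknown = set(data) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown topology config section(s): {sorted(unknown)}")

    for res, entry in data.get("lipids", {}).items():
        bad = set(entry) - _ROLE_KEYS
        if bad:
            raise ValueError(
                f"lipid {res}: unknown role keyword(s) {sorted(bad)}; "
                f"expected one of {sorted(_ROLE_KEYS)}")
        old = spec.lipids.get(res)
        head = frozenset(entry.get("headgroup", old.headgroup_atoms if old else ()))
        gly = frozenset(entry.get("glycerol", old.glycerol_atoms if old else ()))
        tails = frozenset(entry.get("tails", old.tail_atoms if old else ()))
        new = LipidEntry(head, gly, tails)
        new.validate(res)
        spec.lipids[res] = new

    for el, r in data.get("radii", {}).items():
        if not (isinstance(r, (int, float)) and r > 0):
            raise ValueError(f"radius for element {el} must be a positive number, got {r!r}")
        spec.radius_table[str(el)] = float(r)

    for res, table in data.get("elements", {}).items():
        for atom, el in table.items():
            spec.element_overrides[(str(res), str(atom))] = str(el)

    for res, table in data.get("charges", {}).items():
        for atom, v in table.items():
            if len(v) != 3:
                raise ValueError(f"charges.{res}.{atom}: expected [charge, sigma, epsilon]")
            q, s, e = (float(x) for x in v)
            if e < 0:
                raise ValueError(f"charges.{res}.{atom}: epsilon must be >= 0")
            spec.charge_lj[(str(res), str(atom))] = (q, s, e)

    return spec.validate()


def load_params_tsv(path, spec: Optional[LipidTopologySpec] = None) -> LipidTopologySpec:
    """Merge a charge/LJ parameter TSV into ``spec`` (or the defaults).

    Columns: res_name, atom_name, charge_e, sigma_nm, epsilon_kJmol; a
    header row is permitted and detected.
    """
    spec = spec if spec is not None else default_topology_spec()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[0] == "res_name":
                continue
            if len(parts) != 5:
                raise ValueError(f"{path}:{lineno}: expected 5 tab-separated fields")
            res, atom, q, s, e = parts
            eps = float(e)
            if eps < 0:
                raise ValueError(f"{path}:{lineno}: epsilon must be >= 0")
            spec.charge_lj[(res, atom)] = (float(q), float(s), eps)
    return spec.validate()
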