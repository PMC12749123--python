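"""Protein-membrane hydrogen bonds and cutoff non-bonded energetics.

Hydrogen bonds use the common geometric criterion: donor-acceptor distance
<= 0.35 nm and hydrogen-donor-acceptor angle <= 30 degrees, with donor and
acceptor on opposite sides of the protein/membrane boundary.  Hydrogens are
attached to their donor geometrically (nearest N/O/S heavy atom within
0.12 nm on the same side), since plain coordinate files carry no bonds.

Interaction energies are plain-cutoff sums over cross pairs under the
minimum-image convention:

    E_coul = sum f q_i q_j / r_ij,         f = 138.935485 kJ mol^-1 nm e^-2
    E_LJ   = sum 4 eps_ij [(sig_ij/r_ij)^12 - (sig_ij/r_ij)^6]

with Lorentz-Berthelot combining (arithmetic sigma, geometric epsilon) and
a 1.2 nm cutoff by default.  This is a cutoff scheme for relative and
ensemble comparisons; it makes no attempt at mesh-Ewald electrostatics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .models import Frame, Trajectory
from .topology import LipidTopologySpec

__all__ = [
    "HBondCriteria", "HBondRecord", "NonbondedParams", "EnergyBreakdown",
    "PerLipidEnergy", "select_protein_membrane", "find_hbonds",
    "hbond_timeseries", "pair_energy", "group_energy", "per_lipid_energy",
    "energy_timeseries", "ensemble_stats",
]

COULOMB_CONSTANT = 138.935485  # kJ mol^-1 nm e^-2

_SOLVENT = {"SOL", "TIP3", "TIP4", "WAT", "HOH", "NA", "CL", "K", "MG", "CA", "ION", "SOD", "CLA"}


@dataclass(frozen=True)
class HBondCriteria:
    d_max: float = 0.35       # nm, donor-acceptor
    angle_max: float = 30.0   # degrees, hydrogen-donor-acceptor
    bond_max: float = 0.12    # nm, H-to-donor attachment

    def __post_init__(self):
        if not (self.d_max > 0):
            raise ValueError("d_max must be positive")
        if not (0 < self.angle_max <= 90):
            raise ValueError("angle_max must lie in (0, 90] degrees")


@dataclass(frozen=True)
class HBondRecord:
    donor_serial: int
    hydrogen_serial: int
    acceptor_serial: int
    distance: float  # nm
    angle: float     # degrees
    frame_index: int = 0


@dataclass(frozen=True)
class NonbondedParams:
    cutoff: float = 1.2  # nm
    coulomb_constant: float = COULOMB_CONSTANT

    def __post_init__(self):
        if not (self.cutoff > 0):
            raise ValueError("cutoff must be positive")


@dataclass
class EnergyBreakdown:
    """Coulomb and Lennard-Jones energy, optionally decomposed into blocks.

    ``by_group`` maps (residue-group label, lipid species) to a
    (coulomb, lennard_jones) pair; blocks partition the cross pairs, so
    their sums reproduce the totals.
    """

    coulomb: float
    lennard_jones: float
    by_group: Optional[Dict[Tuple[str, str], Tuple[float, float]]] = None
    frame_index: int = 0

    @property
    def total(self) -> float:
        return self.coulomb + self.lennard_jones


@dataclass
class PerLipidEnergy:
    total: float
    n_contact_lipids: int
    per_lipid: Optional[float]  # None when no lipid is within the cutoff


# ---------------------------------------------------------------------------

def min_image_displacements(pa: np.ndarray, pb: np.ndarray, box: np.ndarray) -> np.ndarray:
    """(len(pa), len(pb), 3) displacement matrix under minimum image."""
    d = pa[:, None, :] - pb[None, :, :]
    d -= box * np.round(d / box)
    return d


def _sides(frame: Frame, spec: LipidTopologySpec):
    """'lipid' / 'protein' / 'solvent' label per atom."""
    out = np.empty(frame.n_atoms, dtype=object)
    for i, res in enumerate(frame.res_names):
        res = str(res)
        if spec.is_lipid(res):
            out[i] = "lipid"
        elif res.upper() in _SOLVENT:
            out[i] = "solvent"
        else:
            out[i] = "protein"
    return out


def select_protein_membrane(frame: Frame, spec: LipidTopologySpec):
    """Boolean (protein, membrane) atom masks; solvent and ions excluded."""
    sides = _sides(frame, spec)
    return sides == "protein", sides == "lipid"


# ---------------------------------------------------------------------------
# hydrogen bonds

def find_hbonds(frame: Frame, spec: LipidTopologySpec,
                donors: str = "both",
                criteria: HBondCriteria = HBondCriteria(),
                frame_index: int = 0) -> List[HBondRecord]:
    """All protein<->membrane hydrogen bonds of one frame.

    ``donors`` restricts which side donates: 'protein', 'lipid' or 'both'.
    Raises when the frame contains no hydrogens at all (an H-less structure
    cannot be hydrogen-bond analysed).
    """
    if donors not in ("protein", "lipid", "both"):
        raise ValueError("donors must be 'protein', 'lipid' or 'both'")
    elements = spec.resolve_elements(frame)
    sides = _sides(frame, spec)
    h_mask = elements == "H"
    if not h_mask.any():
        raise ValueError("frame contains no hydrogen atoms; structures without "
                         "hydrogens cannot be hydrogen-bond analysed")
    heavy_don = np.isin(elements, ("N", "O", "S"))
    box = frame.box
    records: List[HBondRecord] = []

    for side in ("protein", "lipid"):
        if donors != "both" and side != donors:
            continue
        other = "lipid" if side == "protein" else "protein"
        h_idx = np.where(h_mask & (sides == side))[0]
        d_idx = np.where(heavy_don & (sides == side))[0]
        a_idx = np.where(heavy_don & (sides == other))[0]
        if len(h_idx) == 0 or len(d_idx) == 0 or len(a_idx) == 0:
            continue
        # attach each H to its nearest heavy N/O/S within bond_max
        dh = min_image_displacements(frame.positions[h_idx], frame.positions[d_idx], box)
        dist_hd = np.sqrt((dh ** 2).sum(-1))
        nearest = dist_hd.argmin(axis=1)
        ok = dist_hd[np.arange(len(h_idx)), nearest] <= criteria.bond_max
        for k in np.where(ok)[0]:
            h = h_idx[k]
            d = d_idx[nearest[k]]
            v_da = frame.positions[np.newaxis, a_idx] - frame.positions[d]
            v_da = v_da[0] - box * np.round(v_da[0] / box)
            dist_da = np.sqrt((v_da ** 2).sum(-1))
            close = dist_da <= criteria.d_max
            if not close.any():
                continue
            v_dh = frame.positions[h] - frame.positions[d]
            v_dh -= box * np.round(v_dh / box)
            norm_dh = np.linalg.norm(v_dh)
            for m in np.where(close)[0]:
                cosang = float(np.dot(v_dh, v_da[m]) / (norm_dh * dist_da[m]))
                ang = math.degrees(math.acos(min(1.0, max(-1.0, cosang))))
                if ang <= criteria.angle_max:
                    records.append(HBondRecord(
                        donor_serial=int(frame.serials[d]),
                        hydrogen_serial=int(frame.serials[h]),
                        acceptor_serial=int(frame.serials[a_idx[m]]),
                        distance=float(dist_da[m]), angle=ang,
                        frame_index=frame_index))
    return records


def hbond_timeseries(traj: Trajectory, spec: LipidTopologySpec,
                     criteria: HBondCriteria = HBondCriteria(),
                     donors: str = "both"):
    """Per-frame protein-membrane H-bond counts plus mean +/- population SD."""
    counts = [len(find_hbonds(fr, spec, donors=donors, criteria=criteria, frame_index=k))
              for k, fr in enumerate(traj)]
    arr = np.array(counts, float)
    return {"counts": counts, "mean": float(arr.mean()), "sd": float(arr.std())}


def ensemble_stats(run_means: Sequence[float]):
    """Mean and population SD across independent run means."""
    arr = np.array(run_means, float)
    if arr.size == 0:
        raise ValueError("no runs")
    return {"mean": float(arr.mean()), "sd": float(arr.std()), "n_runs": int(arr.size)}


# ---------------------------------------------------------------------------
# energies

def _resolve_params(frame, spec, idx):
    q = np.empty(len(idx))
    sig = np.empty(len(idx))
    eps = np.empty(len(idx))
    for k, i in enumerate(idx):
        q[k], sig[k], eps[k] = spec.charge_lj_for(str(frame.res_names[i]), str(frame.names[i]))
    return q, sig, eps


def _as_indices(sel, n):
    sel = np.asarray(sel)
    if sel.dtype == bool:
        return np.where(sel)[0]
    return sel.astype(int)


def pair_energy(frame: Frame, spec: LipidTopologySpec, set_a, set_b,
                params: NonbondedParams = NonbondedParams(),
                frame_index: int = 0) -> EnergyBreakdown:
    """Cutoff Coulomb + LJ energy between two disjoint atom selections.

    Plain truncation at ``params.cutoff`` under minimum image; no shift,
    no reaction field, no reciprocal-space term.
    """
    ia = _as_indices(set_a, frame.n_atoms)
    ib = _as_indices(set_b, frame.n_atoms)
    if np.intersect1d(ia, ib).size:
        raise ValueError("atom selections overlap; cross-pair energy is undefined")
    if len(ia) == 0 or len(ib) == 0:
        return EnergyBreakdown(0.0, 0.0, frame_index=frame_index)
    qa, sa, ea = _resolve_params(frame, spec, ia)
    qb, sb, eb = _resolve_params(frame, spec, ib)
    d = min_image_displacements(frame.positions[ia], frame.positions[ib], frame.box)
    r = np.sqrt((d ** 2).sum(-1))
    within = r <= params.cutoff
    if not within.any():
        return EnergyBreakdown(0.0, 0.0, frame_index=frame_index)
    rin = r[within]
    qq = np.outer(qa, qb)[within]
    coul = params.coulomb_constant * float((qq / rin).sum())
    sij = (0.5 * (sa[:, None] + sb[None, :]))[within]
    eij = np.sqrt(np.outer(ea, eb))[within]
    sr6 = (sij / rin) ** 6
    lj = float((4.0 * eij * (sr6 ** 2 - sr6)).sum())
    return EnergyBreakdown(coulomb=coul, lennard_jones=lj, frame_index=frame_index)


def _decade_label(res_id: int) -> str:
    if 1 <= res_id <= 60:
        g = (res_id - 1) // 10
        return f"{10 * g + 1}-{10 * g + 10}"
    return "other"


def group_energy(frame: Frame, spec: LipidTopologySpec, protein_sel, membrane_sel,
                 params: NonbondedParams = NonbondedParams(),
                 frame_index: int = 0) -> EnergyBreakdown:
    """Energy decomposed into residue-decade x lipid-species blocks.

    Protein residues are expected to be numbered 1-60 (the N-terminal
    segment); residues outside that range fall into an 'other' group with
    a warning. Block sums reproduce the totals (same pairs, partitioned).
    """
    import warnings as _w
    ip = _as_indices(protein_sel, frame.n_atoms)
    im = _as_indices(membrane_sel, frame.n_atoms)
    total = pair_energy(frame, spec, ip, im, params, frame_index)
    decades = np.array([_decade_label(int(frame.res_ids[i])) for i in ip], dtype=object)
    if (decades == "other").any():
        _w.warn("protein residues outside 1-60 assigned to group 'other'", stacklevel=2)
    species = np.array([str(frame.res_names[i]) for i in im], dtype=object)
    blocks = {}
    for g in dict.fromkeys(decades):
        pg = ip[decades == g]
        for s in dict.fromkeys(species):
            ms = im[species == s]
            e = pair_energy(frame, spec, pg, ms, params, frame_index)
            blocks[(g, s)] = (e.coulomb, e.lennard_jones)
    total.by_group = blocks
    return total


def per_lipid_energy(frame: Frame, spec: LipidTopologySpec, protein_sel, membrane_sel,
                     params: NonbondedParams = NonbondedParams(),
                     breakdown: Optional[EnergyBreakdown] = None) -> PerLipidEnergy:
    """Total energy normalised by the number of contact lipids.

    A contact lipid has at least one atom within the cutoff of any protein
    atom. With zero contact lipids the per-lipid average is undefined
    (None), not zero.
    """
    ip = _as_indices(protein_sel, frame.n_atoms)
    im = _as_indices(membrane_sel, frame.n_atoms)
    if breakdown is None:
        breakdown = pair_energy(frame, spec, ip, im, params)
    n_contact = 0
    if len(ip) and len(im):
        d = min_image_displacements(frame.positions[im], frame.positions[ip], frame.box)
        mind = np.sqrt((d ** 2).sum(-1)).min(axis=1)
        keys = frame.residue_keys()[im]
        contact_res = {k for k, dist in zip(keys, mind) if dist <= params.cutoff}
        n_contact = len(contact_res)
    total = breakdown.total
    return PerLipidEnergy(total=total, n_contact_lipids=n_contact,
                          per_lipid=(total / n_contact) if n_contact else None)


def energy_timeseries(traj: Trajectory, spec: LipidTopologySpec,
                      params: NonbondedParams = NonbondedParams(),
                      protein_sel=None, membrane_sel=None):
    """Per-frame protein-membrane energies plus mean +/- population SD.

    Selections default to the protein/membrane split of the first frame
    (atom identity is constant along a trajectory).
    """
    if protein_sel is None or membrane_sel is None:
        protein_sel, membrane_sel = select_protein_membrane(traj[0], spec)
    frames = []
    for k, fr in enumerate(traj):
        frames.append(pair_energy(fr, spec, protein_sel, membrane_sel, params, frame_index=k))
    totals = np.array([e.total for e in frames])
    coul = np.array([e.coulomb for e in frames])
    lj = np.array([e.lennard_jones for e in frames])
    return {
        "frames": frames,
        "mean_total": float(totals.mean()), "sd_total": float(totals.std()),
        "mean_coulomb": float(coul.mean()), "sd_coulomb": float(coul.std()),
        "mean_lj": float(lj.mean()), "sd_lj": float(lj.std()),
        "n_frames": len(frames),
    }
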