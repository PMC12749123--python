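"""Deterministic synthetic bilayers with controllable packing defects.

The generator builds coarse bead-model planar bilayers on a jittered square
lattice: each phospholipid-like pseudo-lipid stacks a large headgroup bead
(radius 0.75 nm), a glycerol marker bead, an upper-tail "guard" bead just
above the deep plane (radius 0.85 nm) and two tail beads; sterol-like
lipids carry a small hydroxyl head bead (radius 0.35 nm) and a compact
body sunk below the deep plane.  The radii are chosen against the lattice
geometry (spacing 0.8 nm, jitter clipped to 0.1 nm) so that:

* a sterol-free leaflet covers every 0.1 nm grid cell — the defect
  pipeline reports zero defects on an uncarved membrane;
* sterol sites undercover their neighbourhood: isolated sterols leave
  small shallow rims (the neighbouring guard beads still cover the rim
  above the deep plane), while condensed sterol patches open large
  connected regions with nothing above the deep plane — deep defects.

That asymmetry is the generator's model of cholesterol condensation:
the ``condensation`` knob interpolates between uniformly random sterol
placement (0) and growth of a single connected sterol patch (1).

``carve_defect`` produces cell-exact ground truth: it removes the beads
covering a chosen contiguous set of grid cells and re-covers collateral
cells with single-cell filler beads, so the defect pipeline must recover
exactly the carved count, class and area.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .models import Frame
from .topology import LipidTopologySpec, default_topology_spec
from .leaflets import assign_leaflets
from .defects import (build_grid, compute_glycerol_plane, rasterize_coverage,
                      overlapping_atoms, GridSpec, DEFAULT_DEPTH_THRESHOLD)

__all__ = [
    "SyntheticMembraneSpec", "PRESETS", "largest_remainder_counts",
    "generate_bilayer", "carve_defect", "sample_defect_areas",
    "generate_probe_protein", "combine_frames",
]

# canonical species order (used for deterministic rounding tie-breaks)
SPECIES = ("PS", "PE", "PC", "sterol")
RES_OF = {"PS": "PSX", "PE": "PEX", "PC": "PCX", "sterol": "CHX"}

# membrane compositions matching the studied systems (molar fractions)
PRESETS = {
    "chol0": {"PS": 0.12, "PE": 0.20, "PC": 0.68, "sterol": 0.0},
    "chol10": {"PS": 0.12, "PE": 0.20, "PC": 0.58, "sterol": 0.10},
    "chol40": {"PS": 0.12, "PE": 0.20, "PC": 0.28, "sterol": 0.40},
}

_LEAFLET_OFFSET = 1.0  # nm, glycerol plane distance from the bilayer midplane

# per-species bead stacks: (atom_name, dz toward the water phase)
_PHOSPHOLIPID_BEADS = (
    ("EH1", 0.30), ("OA1", 0.30), ("GB1", 0.0),
    ("TG1", -0.05), ("TA1", -0.40), ("TA2", -0.75),
)
_STEROL_BEADS = (
    ("SH1", 0.25), ("SG1", 0.0), ("SO1", -0.25), ("SB1", -0.45), ("SB2", -0.80),
)


@dataclass
class SyntheticMembraneSpec:
    """Parameters of a synthetic bilayer; a pure function of spec + seed."""

    n_lipids_per_leaflet: int = 64
    lattice_spacing: float = 0.8  # nm
    jitter_sd: float = 0.05       # nm, xy jitter (clipped at min(2 sd, 0.1))
    composition: Dict[str, float] = field(
        default_factory=lambda: dict(PRESETS["chol0"]))
    condensation: float = 0.0     # 0 = random sterols, 1 = one connected patch
    carved_defects: List[Tuple[int, str]] = field(default_factory=list)
    box_z: float = 6.0            # nm
    seed: int = 0

    def validate(self):
        if self.n_lipids_per_leaflet < 4:
            raise ValueError("need at least 4 lipids per leaflet")
        n_side = math.isqrt(self.n_lipids_per_leaflet)
        if n_side * n_side != self.n_lipids_per_leaflet:
            raise ValueError("n_lipids_per_leaflet must be a perfect square "
                             "(lipids sit on a square lattice)")
        total = sum(self.composition.get(s, 0.0) for s in SPECIES)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"composition fractions must sum to 1, got {total}")
        if not (0.0 <= self.condensation <= 1.0):
            raise ValueError("condensation must lie in [0, 1]")
        return self


def largest_remainder_counts(fractions: Dict[str, float], n: int) -> Dict[str, int]:
    """Integer species counts by largest-remainder rounding of fractions."""
    quotas = {s: fractions.get(s, 0.0) * n for s in SPECIES}
    counts = {s: math.floor(q) for s, q in quotas.items()}
    remaining = n - sum(counts.values())
    order = sorted(SPECIES, key=lambda s: (-(quotas[s] - counts[s]), SPECIES.index(s)))
    for s in order[:remaining]:
        counts[s] += 1
    return counts


def _place_sterols(n_side: int, k: int, kappa: float, rng) -> set:
    """Choose k sterol sites on an n_side x n_side periodic lattice.

    A random seed site is drawn first; each subsequent sterol goes, with
    probability ``kappa``, to the free site nearest the seed (periodic
    metric) — growing one compact patch — and otherwise to a uniform
    random free site. kappa=1 therefore yields a single connected disk,
    kappa=0 a uniform random placement.
    """
    total = n_side * n_side
    if k == 0:
        return set()
    if k > total:
        raise ValueError("more sterols than lattice sites")
    seed_site = int(rng.integers(total))
    si, sj = divmod(seed_site, n_side)

    def dist2(site):
        i, j = divmod(site, n_side)
        di = min((i - si) % n_side, (si - i) % n_side)
        dj = min((j - sj) % n_side, (sj - j) % n_side)
        return di * di + dj * dj

    by_distance = sorted(range(total), key=lambda s: (dist2(s), s))
    chosen = {seed_site}
    while len(chosen) < k:
        if rng.random() < kappa:
            site = next(s for s in by_distance if s not in chosen)
        else:
            pool = [s for s in range(total) if s not in chosen]
            site = pool[int(rng.integers(len(pool)))]
        chosen.add(site)
    return chosen


def generate_bilayer(spec: SyntheticMembraneSpec,
                     topology: Optional[LipidTopologySpec] = None
                     ) -> Tuple[Frame, LipidTopologySpec]:
    """Build a two-leaflet synthetic bilayer frame plus its topology spec.

    Leaflets are mirrored about z = box_z/2; lipids sit on a jittered
    square lattice; sterols are placed by the condensation knob. Output is
    deterministic for a fixed spec + seed. Any ``carved_defects`` are
    applied to the upper leaflet.
    """
    spec.validate()
    topo = topology if topology is not None else default_topology_spec()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_lipids_per_leaflet
    n_side = math.isqrt(n)
    a = spec.lattice_spacing
    box = np.array([n_side * a, n_side * a, spec.box_z])
    counts = largest_remainder_counts(spec.composition, n)
    clip = min(2.0 * spec.jitter_sd, 0.1)

    names, res_names, res_ids, positions = [], [], [], []
    res_counter = 0
    for sign in (+1, -1):  # upper leaflet first
        z_gly = spec.box_z / 2.0 + sign * _LEAFLET_OFFSET
        sterol_sites = _place_sterols(n_side, counts["sterol"], spec.condensation, rng)
        others = [s for s in range(n) if s not in sterol_sites]
        perm = rng.permutation(len(others))
        species_of = {}
        pos = 0
        for s_name in ("PS", "PE", "PC"):
            for t in range(counts[s_name]):
                species_of[others[perm[pos]]] = s_name
                pos += 1
        jit = np.clip(rng.normal(0.0, spec.jitter_sd, size=(n, 2)), -clip, clip)
        for site in range(n):
            i, j = divmod(site, n_side)
            x = (i + 0.5) * a + jit[site, 0]
            y = (j + 0.5) * a + jit[site, 1]
            sp = "sterol" if site in sterol_sites else species_of[site]
            res_counter += 1
            beads = _STEROL_BEADS if sp == "sterol" else _PHOSPHOLIPID_BEADS
            for atom_name, dz in beads:
                names.append(atom_name)
                res_names.append(RES_OF[sp])
                res_ids.append(res_counter)
                positions.append((x % box[0], y % box[1], z_gly + sign * dz))

    frame = Frame(names=names, res_names=res_names, res_ids=res_ids,
                  positions=np.array(positions), box=box, label="synthetic")
    for k, (n_cells, depth_class) in enumerate(spec.carved_defects):
        frame = carve_defect(frame, topo, "upper", n_cells, depth_class,
                             seed=int(rng.integers(2 ** 31)))
    return frame, topo


# ---------------------------------------------------------------------------

def carve_defect(frame: Frame, topo: LipidTopologySpec, leaflet: str,
                 n_cells: int, depth_class: str, grid: Optional[GridSpec] = None,
                 seed: int = 0, depth_threshold: float = DEFAULT_DEPTH_THRESHOLD,
                 clearance: float = 0.6, return_cells: bool = False):
    """Carve an exact n-cell defect of the given class into one leaflet.

    Picks a contiguous set of ``n_cells`` currently covered grid cells
    (at least ``clearance`` nm away from any existing uncovered cell, so
    the carved defect never merges with a pre-existing one), deletes every
    headgroup bead overlapping them (for 'deep', every bead above the deep
    plane), and restores coverage of collateral cells with single-cell
    filler beads placed exactly at cell centres.  The defect pipeline then
    reports exactly one defect of ``n_cells`` cells with the given class.
    """
    if depth_class not in ("deep", "shallow"):
        raise ValueError("depth_class must be 'deep' or 'shallow'")
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    assignment = assign_leaflets(frame, topo)
    grid = grid if grid is not None else build_grid(frame)
    orient = +1 if leaflet == "upper" else -1
    gly_z = compute_glycerol_plane(frame, topo, leaflet, assignment)

    keys = frame.residue_keys()
    members = assignment.residues(leaflet)
    in_leaf = np.array([k in members for k in keys])
    roles = np.array([topo.role_of(str(r), str(nm)) or ""
                      for r, nm in zip(frame.res_names, frame.names)], dtype=object)
    lipid_leaf = in_leaf & (roles != "")
    elements = topo.resolve_elements(frame)
    radii = np.zeros(frame.n_atoms)
    for i in np.where(lipid_leaf)[0]:
        radii[i] = topo.radius_for(str(elements[i]),
                                   context=f"{frame.res_names[i]}:{frame.names[i]}")
    head = lipid_leaf & (roles == "headgroup")
    core_head = head & (frame.res_names != "FIL")

    xy = frame.positions[:, :2]
    cov_core = rasterize_coverage(grid, xy[core_head], radii[core_head])
    cov_all = rasterize_coverage(grid, xy[head], radii[head])

    # keep clear of existing uncovered cells (and filler-only patches)
    forbidden = ~cov_core
    if forbidden.any():
        base = forbidden.copy()
        kx = int(clearance / grid.cell_x) + 1
        ky = int(clearance / grid.cell_y) + 1
        for di in range(-kx, kx + 1):
            for dj in range(-ky, ky + 1):
                if (di * grid.cell_x) ** 2 + (dj * grid.cell_y) ** 2 <= clearance ** 2:
                    forbidden |= np.roll(base, (di, dj), axis=(0, 1))
    candidates = cov_core & ~forbidden
    cand = np.argwhere(candidates)
    if len(cand) == 0:
        raise ValueError("no covered cells available for carving")

    rng = np.random.default_rng(seed)
    target: Optional[set] = None
    for _attempt in range(50):
        start = tuple(int(v) for v in cand[int(rng.integers(len(cand)))])
        S = {start}
        while len(S) < n_cells:
            frontier = sorted({
                ((i + di) % grid.nx, (j + dj) % grid.ny)
                for (i, j) in S
                for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1))
            } - S)
            frontier = [c for c in frontier if candidates[c]]
            if not frontier:
                break
            S.add(frontier[int(rng.integers(len(frontier)))])
        if len(S) == n_cells:
            target = S
            break
    if target is None:
        raise ValueError(f"cannot place a contiguous {n_cells}-cell defect: "
                         "requested size exceeds the available free area")
    cells = sorted(target)

    # delete beads: headgroup coverage always; everything above the deep
    # plane for a deep defect
    delete = np.zeros(frame.n_atoms, dtype=bool)
    head_idx = np.where(head)[0]
    hit = overlapping_atoms(grid, xy[head_idx], radii[head_idx], cells)
    delete[head_idx[hit]] = True
    if depth_class == "deep":
        above = lipid_leaf & (orient * (frame.positions[:, 2] - gly_z) > -depth_threshold)
        ai = np.where(above)[0]
        hit = overlapping_atoms(grid, xy[ai], radii[ai], cells)
        delete[ai[hit]] = True

    kept = frame.select(~delete)
    k_roles = np.array([topo.role_of(str(r), str(nm)) or ""
                        for r, nm in zip(kept.res_names, kept.names)], dtype=object)
    k_keys = kept.residue_keys()
    k_in_leaf = np.array([k in members for k in k_keys])
    k_head = k_in_leaf & (k_roles == "headgroup")
    k_radii = np.array([topo.radius_for(str(topo.element_of(str(r), str(nm))))
                        for r, nm in zip(kept.res_names[k_head], kept.names[k_head])]
                       ) if k_head.any() else np.array([])
    cov_after = rasterize_coverage(grid, kept.positions[k_head][:, :2], k_radii)

    s_mask = np.zeros((grid.nx, grid.ny), dtype=bool)
    for c in cells:
        s_mask[c] = True
    fill = cov_all & ~cov_after & ~s_mask
    fill_cells = np.argwhere(fill)

    z_fill = float(frame.positions[core_head, 2].mean())
    add_names, add_res, add_rid, add_pos = [], [], [], []
    next_rid = int(frame.res_ids.max()) + 1
    for (i, j) in fill_cells:
        cxy = grid.center(int(i), int(j))
        add_names.append("FQ1")
        add_res.append("FIL")
        add_rid.append(next_rid)
        next_rid += 1
        add_pos.append((cxy[0], cxy[1], z_fill))

    n_new = kept.n_atoms + len(add_names)
    out = Frame(
        names=np.concatenate([kept.names, np.array(add_names, dtype=object)]),
        res_names=np.concatenate([kept.res_names, np.array(add_res, dtype=object)]),
        res_ids=np.concatenate([kept.res_ids, np.array(add_rid, dtype=int)]) if add_rid
                else kept.res_ids,
        positions=np.vstack([kept.positions, np.array(add_pos).reshape(-1, 3)]) if add_pos
                  else kept.positions,
        box=frame.box,
        serials=np.arange(1, n_new + 1),
        label=frame.label,
    )
    if return_cells:
        return out, cells
    return out


# ---------------------------------------------------------------------------

def sample_defect_areas(A0: float, n: int, fit_min: float = 5.0, seed: int = 0) -> np.ndarray:
    """i.i.d. defect areas: fit_min + Exponential(mean A0), in A^2."""
    if not (A0 > 0):
        raise ValueError("A0 must be positive")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return fit_min + rng.exponential(A0, size=n)


def generate_probe_protein(n_residues: int = 60, placement: float = 5.0,
                           charges: str = "uniform", seed: int = 0,
                           membrane: Optional[Frame] = None,
                           box=None) -> Tuple[Frame, LipidTopologySpec]:
    """Bead-chain pseudo-protein with donors/hydrogens/acceptors and charges.

    Each residue carries a backbone N (donor), an HN hydrogen pointing
    toward the membrane, a carbonyl-like O acceptor and a CB body bead.
    ``charges``: 'uniform' (+1e on every residue's N), 'first_decade'
    (residues 1-10 only), 'none', or a boolean sequence per residue.
    The chain is laid out serpentine at ``placement`` nm above the membrane
    surface (or at z = placement when no membrane frame is given).
    """
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    if membrane is not None:
        box = np.asarray(membrane.box, float)
        z0 = float(membrane.positions[:, 2].max()) + placement
    else:
        box = np.asarray(box if box is not None else (10.0, 10.0, 12.0), float)
        z0 = placement
    if isinstance(charges, str):
        if charges == "uniform":
            charged = [True] * n_residues
        elif charges == "first_decade":
            charged = [r <= 10 for r in range(1, n_residues + 1)]
        elif charges == "none":
            charged = [False] * n_residues
        else:
            raise ValueError(f"unknown charge pattern {charges!r}")
    else:
        charged = [bool(c) for c in charges]
        if len(charged) != n_residues:
            raise ValueError("charge pattern length must equal n_residues")

    spacing, row_gap, margin = 0.35, 0.45, 0.5
    per_row = max(1, int((box[0] - 2 * margin) / spacing))
    names, res_names, res_ids, positions = [], [], [], []
    for r in range(1, n_residues + 1):
        k = r - 1
        x = margin + (k % per_row) * spacing
        y = margin + (k // per_row) * row_gap
        res = "PRC" if charged[k] else "PRN"
        for nm, dx, dz in (("N", 0.0, 0.0), ("HN", 0.0, -0.10),
                           ("O", 0.12, 0.0), ("CB", 0.0, 0.15)):
            names.append(nm)
            res_names.append(res)
            res_ids.append(r)
            positions.append((x + dx, y, z0 + dz))
    frame = Frame(names=names, res_names=res_names, res_ids=res_ids,
                  positions=np.array(positions), box=box, label="probe")
    return frame, default_topology_spec()


def combine_frames(a: Frame, b: Frame) -> Frame:
    """Concatenate two frames sharing a box (e.g. membrane + probe protein)."""
    if not np.allclose(a.box, b.box):
        raise ValueError("frames have different boxes")
    n = a.n_atoms + b.n_atoms
    return Frame(
        names=np.concatenate([a.names, b.names]),
        res_names=np.concatenate([a.res_names, b.res_names]),
        res_ids=np.concatenate([a.res_ids, b.res_ids]),
        positions=np.vstack([a.positions, b.positions]),
        box=a.box, serials=np.arange(1, n + 1), label=a.label,
    )
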