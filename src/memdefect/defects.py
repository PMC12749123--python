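"""Grid-based lipid packing-defect detection and the defect size constant.

The interfacial surface of each leaflet is discretised into a square grid
(0.1 nm cells by default).  A cell is *covered* when the xy-projection of
some headgroup atom lies within that atom's van der Waals radius of the
cell centre; uncovered cells are packing defects, each carrying the cell
area (0.01 nm^2 at the default grid).  Defect cells whose centres lie
within 0.3 nm of each other (periodic in xy) belong to the same defect.

Defects are *deep* when no lipid atom above a plane 1 A below the leaflet's
glycerol region overlaps the cell — the acyl chains are exposed — and
*shallow* otherwise.  The probability distribution of defect areas decays
roughly exponentially, P(x) ~ A exp(-x/A0); the decay constant A0 (in A^2,
the *defect size constant*) summarises how heavy the large-defect tail is
independently of any single threshold choice.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .models import Frame, LeafletAssignment
from .topology import LipidTopologySpec
from .leaflets import assign_leaflets

__all__ = [
    "GridSpec", "DefectCellMap", "Defect", "ClassStats", "DefectFrameStats",
    "AggregateStats", "DefectSizeDistribution", "SizeConstantFit",
    "build_grid", "compute_glycerol_plane", "project_and_classify_cells",
    "detect_defect_cells", "merge_cells_to_defects", "frame_defect_stats",
    "aggregate_trajectory_stats", "defect_area_histogram", "fit_size_constant",
    "analyze_frame_defects",
]

DEFAULT_CELL_SIZE = 0.1      # nm
DEFAULT_MERGE_DISTANCE = 0.3  # nm
DEFAULT_DEPTH_THRESHOLD = 0.1  # nm (1 A below the glycerol plane)

CELL_NONE, CELL_SHALLOW, CELL_DEEP = 0, 1, 2


@dataclass(frozen=True)
class GridSpec:
    """A 2D analysis grid tiling the xy box exactly."""

    nx: int
    ny: int
    cell_x: float  # nm, recomputed so nx*cell_x == Lx
    cell_y: float
    lx: float
    ly: float
    periodic: Tuple[bool, bool] = (True, True)

    @property
    def cell_area(self) -> float:
        return self.cell_x * self.cell_y

    def centers_x(self) -> np.ndarray:
        return (np.arange(self.nx) + 0.5) * self.cell_x

    def centers_y(self) -> np.ndarray:
        return (np.arange(self.ny) + 0.5) * self.cell_y

    def center(self, i: int, j: int) -> Tuple[float, float]:
        return ((i + 0.5) * self.cell_x, (j + 0.5) * self.cell_y)


def build_grid(frame: Frame, cell_size: float = DEFAULT_CELL_SIZE,
               periodic: Tuple[bool, bool] = (True, True)) -> GridSpec:
    """Grid with nx = round(Lx/cell_size) cells per axis, tiling exactly.

    The actual cell size is recomputed as Lx/nx (and Ly/ny) so the grid
    tiles the box; with commensurate boxes it equals ``cell_size``.
    """
    if not (cell_size > 0):
        raise ValueError(f"cell_size must be positive, got {cell_size}")
    lx, ly = float(frame.box[0]), float(frame.box[1])
    nx, ny = round(lx / cell_size), round(ly / cell_size)
    if nx < 1 or ny < 1:
        raise ValueError(f"box ({lx} x {ly} nm) smaller than one grid cell ({cell_size} nm)")
    return GridSpec(nx=nx, ny=ny, cell_x=lx / nx, cell_y=ly / ny, lx=lx, ly=ly,
                    periodic=periodic)


@dataclass
class DefectCellMap:
    """Per-cell coverage state for one leaflet of one frame.

    ``orientation`` is +1 for the upper leaflet (water side at larger z)
    and -1 for the lower; elevations are measured toward the water phase,
    so the deep-plane test is orientation-independent.
    """

    leaflet: str
    grid: GridSpec
    covered_by_headgroup: np.ndarray     # (nx, ny) bool
    covered_above_deep_plane: np.ndarray  # (nx, ny) bool
    max_exposed_elev: np.ndarray         # (nx, ny) nm relative to glycerol plane; -inf if none
    glycerol_z: float
    deep_plane_z: float
    orientation: int


@dataclass(frozen=True)
class Defect:
    """A merged set of defect cells."""

    leaflet: str
    member_cells: frozenset
    area: float  # nm^2
    depth_class: str  # 'deep' | 'shallow'
    frame_index: int = 0


# ---------------------------------------------------------------------------
# rasterisation helpers (shared with the synthetic generator)

def _axis_window(coord, r, cell, n, length, periodic):
    """Cell indices whose centres may fall within r of coord along one axis.

    Returns (wrapped unique indices, centre-to-coord signed distances).
    """
    i0 = math.floor((coord - r) / cell)
    i1 = math.floor((coord + r) / cell)
    if periodic and (i1 - i0 + 1) >= n:
        idx = np.arange(n)
        d = (idx + 0.5) * cell - coord
        d -= length * np.round(d / length)
        return idx, d
    idx = np.arange(i0, i1 + 1)
    d = (idx + 0.5) * cell - coord
    if periodic:
        return idx % n, d
    keep = (idx >= 0) & (idx < n)
    return idx[keep], d[keep]


def rasterize_coverage(grid: GridSpec, xy: np.ndarray, radii: np.ndarray) -> np.ndarray:
    """Boolean map of cells whose centre lies within an atom's radius (2D, periodic)."""
    cov = np.zeros((grid.nx, grid.ny), dtype=bool)
    for (x, y), r in zip(np.asarray(xy, float), np.asarray(radii, float)):
        ii, dx = _axis_window(x, r, grid.cell_x, grid.nx, grid.lx, grid.periodic[0])
        jj, dy = _axis_window(y, r, grid.cell_y, grid.ny, grid.ly, grid.periodic[1])
        if len(ii) == 0 or len(jj) == 0:
            continue
        m = dx[:, None] ** 2 + dy[None, :] ** 2 <= r * r + 1e-15
        cov[np.ix_(ii, jj)] |= m
    return cov


def overlapping_atoms(grid: GridSpec, xy: np.ndarray, radii: np.ndarray,
                      cells: Sequence[Tuple[int, int]]) -> np.ndarray:
    """Indices of atoms whose coverage disk contains any of the given cell centres."""
    if len(cells) == 0:
        return np.array([], dtype=int)
    centers = np.array([grid.center(i, j) for i, j in cells])  # (m, 2)
    xy = np.asarray(xy, float)
    d = centers[None, :, :] - xy[:, None, :]
    box = np.array([grid.lx, grid.ly])
    for k in range(2):
        if grid.periodic[k]:
            d[:, :, k] -= box[k] * np.round(d[:, :, k] / box[k])
    dist2 = (d ** 2).sum(axis=2)
    r2 = np.asarray(radii, float)[:, None] ** 2
    return np.where((dist2 <= r2 + 1e-15).any(axis=1))[0]


# ---------------------------------------------------------------------------

def _leaflet_lipid_masks(frame, spec, leaflet, assignment):
    keys = frame.residue_keys()
    members = assignment.residues(leaflet)
    in_leaf = np.array([k in members for k in keys])
    roles = np.array([spec.role_of(str(r), str(n)) or ""
                      for r, n in zip(frame.res_names, frame.names)], dtype=object)
    lipid = roles != ""
    return in_leaf & lipid, roles


def compute_glycerol_plane(frame: Frame, spec: LipidTopologySpec, leaflet: str,
                           assignment: Optional[LeafletAssignment] = None) -> float:
    """Mean z (nm) of the glycerol-role atoms of one leaflet's lipids."""
    assignment = assignment or assign_leaflets(frame, spec)
    leaf_mask, roles = _leaflet_lipid_masks(frame, spec, leaflet, assignment)
    gly = leaf_mask & (roles == "glycerol")
    if not gly.any():
        raise ValueError(f"{leaflet} leaflet has no glycerol-role atoms; "
                         "cannot place the depth reference plane")
    return float(frame.positions[gly, 2].mean())


def project_and_classify_cells(frame: Frame, spec: LipidTopologySpec, grid: GridSpec,
                               leaflet: str,
                               assignment: Optional[LeafletAssignment] = None,
                               glycerol_z: Optional[float] = None,
                               depth_threshold: float = DEFAULT_DEPTH_THRESHOLD,
                               ) -> DefectCellMap:
    """Project one leaflet's lipid atoms onto the grid and record coverage.

    A cell is covered by the headgroup layer when some headgroup atom's
    xy-projection lies within that atom's vdW radius of the cell centre
    (periodic in xy). Coverage above the deep plane considers every lipid
    atom whose elevation toward the water phase exceeds -depth_threshold
    relative to the glycerol plane. Protein atoms never cover cells.
    """
    assignment = assignment or assign_leaflets(frame, spec)
    orientation = +1 if leaflet == "upper" else -1
    if glycerol_z is None:
        glycerol_z = compute_glycerol_plane(frame, spec, leaflet, assignment)
    leaf_mask, roles = _leaflet_lipid_masks(frame, spec, leaflet, assignment)
    idx = np.where(leaf_mask)[0]
    elements = spec.resolve_elements(frame)
    radii = np.array([spec.radius_for(str(elements[i]),
                                      context=f"{frame.res_names[i]}:{frame.names[i]}")
                      for i in idx])
    if len(idx) and 2 * radii.max() >= min(grid.lx, grid.ly):
        raise ValueError("an atom's coverage disk spans the whole box; box too small")
    xy = frame.positions[idx, :2]
    elev = orientation * (frame.positions[idx, 2] - glycerol_z)

    head = roles[idx] == "headgroup"
    covered_head = rasterize_coverage(grid, xy[head], radii[head])

    above = elev > -depth_threshold
    covered_above = rasterize_coverage(grid, xy[above], radii[above])

    max_elev = np.full((grid.nx, grid.ny), -np.inf)
    for (x, y), r, e in zip(xy, radii, elev):
        ii, dx = _axis_window(x, r, grid.cell_x, grid.nx, grid.lx, grid.periodic[0])
        jj, dy = _axis_window(y, r, grid.cell_y, grid.ny, grid.ly, grid.periodic[1])
        if len(ii) == 0 or len(jj) == 0:
            continue
        m = dx[:, None] ** 2 + dy[None, :] ** 2 <= r * r + 1e-15
        sub = max_elev[np.ix_(ii, jj)]
        max_elev[np.ix_(ii, jj)] = np.maximum(sub, np.where(m, e, -np.inf))

    return DefectCellMap(
        leaflet=leaflet, grid=grid,
        covered_by_headgroup=covered_head,
        covered_above_deep_plane=covered_above,
        max_exposed_elev=max_elev,
        glycerol_z=glycerol_z,
        deep_plane_z=glycerol_z - orientation * depth_threshold,
        orientation=orientation,
    )


def detect_defect_cells(cmap: DefectCellMap) -> np.ndarray:
    """Classify cells: 0 covered, 1 shallow defect, 2 deep defect.

    A cell is a defect iff no headgroup atom covers it; a defect is deep
    iff no lipid atom above the deep plane overlaps it (cells with no atom
    beneath at all are deep — a fully exposed solvent channel).
    """
    out = np.zeros(cmap.covered_by_headgroup.shape, dtype=np.int8)
    defect = ~cmap.covered_by_headgroup
    out[defect & cmap.covered_above_deep_plane] = CELL_SHALLOW
    out[defect & ~cmap.covered_above_deep_plane] = CELL_DEEP
    return out


class _UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, a):
        p = self.parent
        while p[a] != a:
            p[a] = p[p[a]]
            a = p[a]
        return a

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def _merge_offsets(grid: GridSpec, merge_distance: float):
    kx = int(merge_distance / grid.cell_x) + 1
    ky = int(merge_distance / grid.cell_y) + 1
    offsets = []
    for di in range(-kx, kx + 1):
        for dj in range(-ky, ky + 1):
            if (di, dj) <= (0, 0):
                continue  # each unordered pair visited once
            if (di * grid.cell_x) ** 2 + (dj * grid.cell_y) ** 2 <= merge_distance ** 2 + 1e-15:
                offsets.append((di, dj))
    return offsets


def _components(cells: List[Tuple[int, int]], grid: GridSpec, merge_distance: float):
    cells = sorted(cells)
    index = {c: k for k, c in enumerate(cells)}
    uf = _UnionFind(len(cells))
    offsets = _merge_offsets(grid, merge_distance)
    for (i, j) in cells:
        a = index[(i, j)]
        for di, dj in offsets:
            ni, nj = i + di, j + dj
            if grid.periodic[0]:
                ni %= grid.nx
            elif not (0 <= ni < grid.nx):
                continue
            if grid.periodic[1]:
                nj %= grid.ny
            elif not (0 <= nj < grid.ny):
                continue
            b = index.get((ni, nj))
            if b is not None:
                uf.union(a, b)
    groups: Dict[int, list] = {}
    for c, k in index.items():
        groups.setdefault(uf.find(k), []).append(c)
    return sorted((sorted(g) for g in groups.values()), key=lambda g: g[0])


def merge_cells_to_defects(class_map: np.ndarray, grid: GridSpec,
                           merge_distance: float = DEFAULT_MERGE_DISTANCE,
                           mode: str = "per_class", leaflet: str = "upper",
                           frame_index: int = 0) -> List[Defect]:
    """Merge defect cells into defects (centre distance <= merge_distance, periodic).

    ``per_class`` merges deep and shallow cells separately (per-class size
    distributions); ``all`` merges every defect cell and labels the result
    deep when at least one member cell is deep.
    """
    if merge_distance < min(grid.cell_x, grid.cell_y):
        warnings.warn("merge_distance below the cell size: every defect cell "
                      "becomes its own defect", stacklevel=2)
    defects: List[Defect] = []

    def emit(cells, depth_of):
        for comp in _components(cells, grid, merge_distance):
            classes = {depth_of[c] for c in comp}
            depth = "deep" if "deep" in classes else "shallow"
            defects.append(Defect(leaflet=leaflet, member_cells=frozenset(comp),
                                  area=len(comp) * grid.cell_area,
                                  depth_class=depth, frame_index=frame_index))

    ii, jj = np.where(class_map != CELL_NONE)
    depth_of = {(int(i), int(j)): ("deep" if class_map[i, j] == CELL_DEEP else "shallow")
                for i, j in zip(ii, jj)}
    if mode == "all":
        emit(list(depth_of), depth_of)
    elif mode == "per_class":
        emit([c for c, d in depth_of.items() if d == "deep"], depth_of)
        emit([c for c, d in depth_of.items() if d == "shallow"], depth_of)
    else:
        raise ValueError(f"unknown merge mode {mode!r}; expected 'per_class' or 'all'")
    defects.sort(key=lambda d: min(d.member_cells))
    return defects


# ---------------------------------------------------------------------------
# statistics

@dataclass(frozen=True)
class ClassStats:
    n_defects: int
    total_area: float          # nm^2
    mean_area: Optional[float]  # nm^2; None when there are no defects
    area_fraction: float


@dataclass
class DefectFrameStats:
    """Defect statistics of one frame+leaflet, per class and combined."""

    classes: Dict[str, ClassStats]
    leaflet: str = "upper"
    frame_index: int = 0


def frame_defect_stats(defects: Sequence[Defect], grid: GridSpec,
                       leaflet_area: Optional[float] = None,
                       leaflet: str = "upper", frame_index: int = 0) -> DefectFrameStats:
    """Counts, total/mean areas and area fractions for deep, shallow and total."""
    if leaflet_area is None:
        leaflet_area = grid.lx * grid.ly
    out = {}
    for cls in ("deep", "shallow", "total"):
        sel = [d for d in defects if cls == "total" or d.depth_class == cls]
        n = len(sel)
        total = float(sum(d.area for d in sel))
        out[cls] = ClassStats(
            n_defects=n, total_area=total,
            mean_area=(total / n) if n else None,
            area_fraction=total / leaflet_area)
    return DefectFrameStats(classes=out, leaflet=leaflet, frame_index=frame_index)


@dataclass
class AggregateStats:
    """Across-frame mean +/- population SD of each per-class quantity."""

    table: Dict[str, Dict[str, Tuple[Optional[float], Optional[float]]]]
    n_frames: int
    ratio_to_reference: Optional[Dict[str, float]] = None


def aggregate_trajectory_stats(stats_list: Sequence[DefectFrameStats],
                               reference: Optional[AggregateStats] = None) -> AggregateStats:
    """Aggregate per-frame stats; optionally report defect-count ratios.

    The ratio (per class) is this aggregate's mean defect count divided by
    the reference aggregate's mean count — the presentation used when
    comparing membranes against a cholesterol-free baseline.
    """
    if len(stats_list) == 0:
        raise ValueError("cannot aggregate an empty list of frame statistics")
    table = {}
    for cls in ("deep", "shallow", "total"):
        row = {}
        for q in ("n_defects", "total_area", "mean_area", "area_fraction"):
            vals = [getattr(s.classes[cls], q) for s in stats_list]
            vals = [v for v in vals if v is not None]
            if vals:
                arr = np.array(vals, float)
                row[q] = (float(arr.mean()), float(arr.std()))  # population SD
            else:
                row[q] = (None, None)
        table[cls] = row
    ratios = None
    if reference is not None:
        ratios = {}
        for cls in ("deep", "shallow", "total"):
            ref_mean = reference.table[cls]["n_defects"][0]
            if not ref_mean:
                raise ValueError(f"reference mean defect count for class {cls!r} is zero")
            ratios[cls] = table[cls]["n_defects"][0] / ref_mean
    return AggregateStats(table=table, n_frames=len(stats_list), ratio_to_reference=ratios)


# ---------------------------------------------------------------------------
# size distribution and the defect size constant

@dataclass
class DefectSizeDistribution:
    """Normalised probability distribution of defect areas (A^2)."""

    bin_width: float
    edges: np.ndarray
    centers: np.ndarray
    counts: np.ndarray
    probabilities: np.ndarray
    n_total: int


def defect_area_histogram(defects, bin_width: float = 1.0) -> DefectSizeDistribution:
    """Histogram of defect areas in A^2 (1 nm^2 = 100 A^2), normalised to sum 1."""
    areas = np.array([d.area * 100.0 if isinstance(d, Defect) else float(d)
                      for d in defects], dtype=float)
    if len(areas) == 0:
        raise ValueError("no defects to histogram")
    if not (bin_width > 0):
        raise ValueError("bin_width must be positive")
    n_bins = max(1, math.ceil((areas.max() + 1e-12) / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(areas, bins=edges)
    probs = counts / counts.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    return DefectSizeDistribution(bin_width=bin_width, edges=edges, centers=centers,
                                  counts=counts, probabilities=probs,
                                  n_total=int(counts.sum()))


@dataclass(frozen=True)
class SizeConstantFit:
    """Exponential fit P(x) = A exp(-x/A0) to the small-defect regime."""

    A: float
    A0: float       # A^2
    fit_min: float  # A^2
    fit_max: float  # A^2
    r_squared: float
    n_samples: int


def fit_size_constant(dist: DefectSizeDistribution, fit_min: float = 5.0,
                      fit_max: Optional[float] = None, n_min: int = 50,
                      min_count_for_max: int = 5) -> SizeConstantFit:
    """Weighted least-squares fit of ln P(x) = ln A - x/A0 over [fit_min, fit_max].

    ``fit_max`` defaults to the largest bin still holding at least
    ``min_count_for_max`` defects, restricting the fit to the well-sampled
    small-defect regime. Bins are weighted by sqrt(count) (the approximate
    inverse SD of a log Poisson count). Raises rather than extrapolating
    when fewer than 3 occupied bins or ``n_min`` samples fall in range.
    """
    if fit_max is None:
        rich = dist.counts >= min_count_for_max
        if not rich.any():
            raise ValueError(f"no bin holds >= {min_count_for_max} defects; "
                             "cannot choose a fit range")
        fit_max = float(dist.centers[rich][-1])
    if not (fit_min < fit_max):
        raise ValueError(f"degenerate fit range [{fit_min}, {fit_max}]")
    sel = (dist.centers >= fit_min) & (dist.centers <= fit_max) & (dist.counts > 0)
    n_samples = int(dist.counts[sel].sum())
    if sel.sum() < 3:
        raise ValueError(f"only {int(sel.sum())} occupied bins in the fit range; need >= 3")
    if n_samples < n_min:
        raise ValueError(f"only {n_samples} defects in the fit range; need >= {n_min}")
    x = dist.centers[sel]
    y = np.log(dist.probabilities[sel])
    w = np.sqrt(dist.counts[sel])
    slope, intercept = np.polyfit(x, y, 1, w=w)
    if slope >= 0:
        raise ValueError("defect size distribution shows no exponential decay "
                         f"(slope {slope:.3g} >= 0)")
    yhat = slope * x + intercept
    ss_res = float(((y - yhat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return SizeConstantFit(A=float(np.exp(intercept)), A0=float(-1.0 / slope),
                           fit_min=float(fit_min), fit_max=float(fit_max),
                           r_squared=r2, n_samples=n_samples)


# ---------------------------------------------------------------------------

def analyze_frame_defects(frame: Frame, spec: LipidTopologySpec, leaflet: str = "upper",
                          assignment: Optional[LeafletAssignment] = None,
                          cell_size: float = DEFAULT_CELL_SIZE,
                          merge_distance: float = DEFAULT_MERGE_DISTANCE,
                          depth_threshold: float = DEFAULT_DEPTH_THRESHOLD,
                          mode: str = "per_class", frame_index: int = 0):
    """Full single-frame pipeline: grid -> coverage -> classes -> defects -> stats.

    Returns a dict with keys ``grid``, ``cell_map``, ``class_map``,
    ``defects`` and ``stats``.
    """
    assignment = assignment or assign_leaflets(frame, spec)
    grid = build_grid(frame, cell_size)
    cmap = project_and_classify_cells(frame, spec, grid, leaflet, assignment,
                                      depth_threshold=depth_threshold)
    class_map = detect_defect_cells(cmap)
    defects = merge_cells_to_defects(class_map, grid, merge_distance, mode=mode,
                                     leaflet=leaflet, frame_index=frame_index)
    stats = frame_defect_stats(defects, grid, leaflet=leaflet, frame_index=frame_index)
    return {"grid": grid, "cell_map": cmap, "class_map": class_map,
            "defects": defects, "stats": stats}
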