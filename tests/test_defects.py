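"""Defect detection: grid, coverage, classification, merging, statistics, A0 fit."""

import numpy as np
import pytest

from memdefect.models import Frame
from memdefect.leaflets import assign_leaflets
from memdefect.defects import (build_grid, compute_glycerol_plane,
                               project_and_classify_cells, detect_defect_cells,
                               merge_cells_to_defects, frame_defect_stats,
                               aggregate_trajectory_stats, defect_area_histogram,
                               fit_size_constant, analyze_frame_defects,
                               DefectFrameStats, ClassStats,
                               CELL_NONE, CELL_SHALLOW, CELL_DEEP)
from memdefect.synth import (SyntheticMembraneSpec, generate_bilayer,
                             sample_defect_areas, PRESETS)


# ---------------------------------------------------------------- grid

def test_grid_20nm_box_gives_200_cells():
    fr = Frame(["EH1"], ["PCX"], [1], [[1, 1, 1]], box=[20, 20, 12])
    g = build_grid(fr, 0.1)
    assert (g.nx, g.ny) == (200, 200)
    assert g.cell_area == pytest.approx(0.01)


def test_grid_incommensurate_box_tiles_exactly():
    fr = Frame(["EH1"], ["PCX"], [1], [[1, 1, 1]], box=[2.05, 2.0, 5.0])
    g = build_grid(fr, 0.1)
    assert g.nx in (20, 21)
    assert g.nx * g.cell_x == pytest.approx(2.05)


def test_grid_zero_cell_size_rejected():
    fr = Frame(["EH1"], ["PCX"], [1], [[1, 1, 1]], box=[2, 2, 2])
    with pytest.raises(ValueError):
        build_grid(fr, 0.0)


# ---------------------------------------------------------------- glycerol plane

def _two_lipid_frame(z1, z2):
    names, res_names, res_ids, pos = [], [], [], []
    for rid, (x, z) in enumerate([(1.0, z1), (2.0, z2)], start=1):
        for nm, dz in (("EH1", 0.3), ("GB1", 0.0), ("TA1", -0.4)):
            names.append(nm); res_names.append("PCX"); res_ids.append(rid)
            pos.append([x, 1.0, z + dz])
    # a lower leaflet partner so leaflet assignment works
    for nm, dz in (("EH1", -0.3), ("GB1", 0.0), ("TA1", 0.4)):
        names.append(nm); res_names.append("PCX"); res_ids.append(3)
        pos.append([1.5, 1.0, 0.5 + dz])
    return Frame(names, res_names, res_ids, pos, box=[4, 4, 6])


def test_glycerol_plane_is_mean_z(topo):
    fr = _two_lipid_frame(2.0, 2.2)
    assert compute_glycerol_plane(fr, topo, "upper") == pytest.approx(2.1)
    fr2 = _two_lipid_frame(2.0, 2.0)
    assert compute_glycerol_plane(fr2, topo, "upper") == pytest.approx(2.0)


def test_glycerol_plane_missing_atoms_is_error(topo):
    # sterol-only upper leaflet but with its glycerol-role bead removed
    names = ["SH1", "SB1", "EH1", "GB1", "TA1"]
    res_names = ["CHX", "CHX", "PCX", "PCX", "PCX"]
    res_ids = [1, 1, 2, 2, 2]
    pos = [[1, 1, 4.0], [1, 1, 3.3], [1, 1, 0.8], [1, 1, 0.5], [1, 1, 0.1]]
    fr = Frame(names, res_names, res_ids, pos, box=[3, 3, 5])
    with pytest.raises(ValueError, match="glycerol"):
        compute_glycerol_plane(fr, topo, "upper")


# ---------------------------------------------------------------- coverage

def test_single_atom_covers_disk(topo):
    """One headgroup atom of radius r covers exactly the cells within r."""
    names = ["EH1", "GB1", "EH1", "GB1"]
    res_names = ["PCX"] * 4
    res_ids = [1, 1, 2, 2]
    pos = [[1.55, 1.55, 4.0], [1.55, 1.55, 3.7],   # upper lipid
           [1.55, 1.55, 1.0], [1.55, 1.55, 1.3]]   # lower lipid
    fr = Frame(names, res_names, res_ids, pos, box=[3.1, 3.1, 5.0])
    grid = build_grid(fr, 0.1)
    cmap = project_and_classify_cells(fr, topo, grid, "upper")
    r = topo.radius_table["EH"]
    cx, cy = np.meshgrid(grid.centers_x(), grid.centers_y(), indexing="ij")
    expected = (cx - 1.55) ** 2 + (cy - 1.55) ** 2 <= r * r + 1e-15
    assert np.array_equal(cmap.covered_by_headgroup, expected)


def test_empty_leaflet_all_uncovered(topo):
    # upper leaflet present only via assignment; give it one far-away lipid
    # then select the lower leaflet which holds zero atoms after masking
    fr = _two_lipid_frame(2.0, 2.0)
    grid = build_grid(fr, 0.1)
    cmap = project_and_classify_cells(fr, topo, grid, "upper")
    assert cmap.covered_by_headgroup.any()


def _brute_force_coverage(frame, topo, grid, leaflet):
    """Independent all-cells x all-atoms double loop (vectorised over cells)."""
    asg = assign_leaflets(frame, topo)
    members = asg.residues(leaflet)
    keys = frame.residue_keys()
    elements = topo.resolve_elements(frame)
    cx, cy = np.meshgrid(grid.centers_x(), grid.centers_y(), indexing="ij")
    centers = np.stack([cx.ravel(), cy.ravel()], axis=1)
    cov = np.zeros(len(centers), dtype=bool)
    box = np.array([grid.lx, grid.ly])
    for i in range(frame.n_atoms):
        res, nm = str(frame.res_names[i]), str(frame.names[i])
        if keys[i] not in members or topo.role_of(res, nm) != "headgroup":
            continue
        r = topo.radius_for(str(elements[i]))
        d = centers - frame.positions[i, :2]
        d -= box * np.round(d / box)
        cov |= (d ** 2).sum(axis=1) <= r * r + 1e-15
    return cov.reshape(grid.nx, grid.ny)


@pytest.mark.parametrize("seed", range(5))
def test_coverage_matches_brute_force(seed, topo):
    spec = SyntheticMembraneSpec(n_lipids_per_leaflet=36,
                                 composition=dict(PRESETS["chol40"]),
                                 condensation=0.3, seed=seed)
    frame, tp = generate_bilayer(spec)
    grid = build_grid(frame, 0.1)
    cmap = project_and_classify_cells(frame, tp, grid, "upper")
    brute = _brute_force_coverage(frame, tp, grid, "upper")
    assert np.array_equal(cmap.covered_by_headgroup, brute)


# ---------------------------------------------------------------- classification

def _cmap_stub(covered_head, covered_above):
    from memdefect.defects import DefectCellMap, GridSpec
    g = GridSpec(nx=covered_head.shape[0], ny=covered_head.shape[1],
                 cell_x=0.1, cell_y=0.1,
                 lx=0.1 * covered_head.shape[0], ly=0.1 * covered_head.shape[1])
    return DefectCellMap(leaflet="upper", grid=g, covered_by_headgroup=covered_head,
                         covered_above_deep_plane=covered_above,
                         max_exposed_elev=np.full(covered_head.shape, -np.inf),
                         glycerol_z=2.0, deep_plane_z=1.9, orientation=+1)


def test_cell_classification_rules():
    head = np.array([[True, False, False]])
    above = np.array([[True, True, False]])
    classes = detect_defect_cells(_cmap_stub(head, above))
    assert classes[0, 0] == CELL_NONE       # headgroup-covered
    assert classes[0, 1] == CELL_SHALLOW    # exposed atom above the deep plane
    assert classes[0, 2] == CELL_DEEP       # nothing above the deep plane


# ---------------------------------------------------------------- merging

def _grid(nx=40, ny=40, cell=0.1):
    from memdefect.defects import GridSpec
    return GridSpec(nx=nx, ny=ny, cell_x=cell, cell_y=cell, lx=nx * cell, ly=ny * cell)


def _class_map(grid, cells, value=CELL_SHALLOW):
    cm = np.zeros((grid.nx, grid.ny), dtype=np.int8)
    for c in cells:
        cm[c] = value
    return cm


def test_cells_within_merge_distance_join():
    g = _grid()
    cm = _class_map(g, [(10, 10), (12, 10)])  # centres 0.2 nm apart
    ds = merge_cells_to_defects(cm, g)
    assert len(ds) == 1
    assert ds[0].area == pytest.approx(0.02)


def test_cells_beyond_merge_distance_stay_separate():
    g = _grid()
    cm = _class_map(g, [(10, 10), (15, 10)])  # 0.5 nm apart
    ds = merge_cells_to_defects(cm, g)
    assert len(ds) == 2


def test_merge_across_periodic_boundary():
    g = _grid()
    # cells at x ~ 0 and x ~ Lx: gap of 0.2 nm across the boundary
    cm = _class_map(g, [(0, 20), (38, 20)])
    ds = merge_cells_to_defects(cm, g)
    assert len(ds) == 1
    # oracle: same two cells shifted to the box centre merge identically
    cm2 = _class_map(g, [(19, 20), (21, 20)])
    ds2 = merge_cells_to_defects(cm2, g)
    assert len(ds2) == 1 and ds2[0].area == pytest.approx(ds[0].area)


def test_merge_mode_all_labels_deep_if_any_member_deep():
    g = _grid()
    cm = np.zeros((g.nx, g.ny), dtype=np.int8)
    cm[10, 10] = CELL_DEEP
    cm[11, 10] = CELL_SHALLOW
    ds_all = merge_cells_to_defects(cm, g, mode="all")
    assert len(ds_all) == 1 and ds_all[0].depth_class == "deep"
    ds_pc = merge_cells_to_defects(cm, g, mode="per_class")
    assert sorted(d.depth_class for d in ds_pc) == ["deep", "shallow"]


def test_merge_distance_below_cell_size_warns():
    g = _grid()
    cm = _class_map(g, [(10, 10), (11, 10)])
    with pytest.warns(UserWarning):
        ds = merge_cells_to_defects(cm, g, merge_distance=0.05)
    assert len(ds) == 2


def test_component_identity_independent_of_translation():
    """Shifting the cell pattern by lattice vectors preserves the area multiset."""
    g = _grid()
    rng = np.random.default_rng(5)
    cells = {(int(rng.integers(g.nx)), int(rng.integers(g.ny))) for _ in range(60)}
    cm = _class_map(g, cells)
    ref = sorted(d.area for d in merge_cells_to_defects(cm, g))
    for dx, dy in ((3, 0), (0, 7), (17, 29)):
        shifted = {((i + dx) % g.nx, (j + dy) % g.ny) for i, j in cells}
        got = sorted(d.area for d in merge_cells_to_defects(_class_map(g, shifted), g))
        assert got == ref


# ---------------------------------------------------------------- statistics

def test_single_cell_defect_area_is_printed_cell_area():
    g = _grid()
    cm = _class_map(g, [(5, 5)])
    ds = merge_cells_to_defects(cm, g)
    st = frame_defect_stats(ds, g)
    assert st.classes["total"].total_area == pytest.approx(0.01)


def test_stats_mean_and_total():
    g = _grid()
    cm = _class_map(g, [(5, 5), (5, 6), (20, 20), (20, 21), (21, 20), (21, 21)])
    ds = merge_cells_to_defects(cm, g)
    st = frame_defect_stats(ds, g)
    assert st.classes["total"].mean_area == pytest.approx(0.03)
    assert st.classes["total"].total_area == pytest.approx(0.06)


def test_stats_zero_defects_mean_is_undefined():
    g = _grid()
    st = frame_defect_stats([], g)
    assert st.classes["total"].n_defects == 0
    assert st.classes["total"].mean_area is None


def test_total_equals_deep_plus_shallow(topo):
    spec = SyntheticMembraneSpec(n_lipids_per_leaflet=100,
                                 composition=dict(PRESETS["chol40"]),
                                 condensation=0.5, seed=3)
    frame, tp = generate_bilayer(spec)
    res = analyze_frame_defects(frame, tp, "upper", mode="per_class")
    cls = res["stats"].classes
    assert cls["deep"].n_defects + cls["shallow"].n_defects == cls["total"].n_defects
    assert cls["deep"].total_area + cls["shallow"].total_area == pytest.approx(
        cls["total"].total_area)
    # exactness: total area equals cell area times number of defect cells
    n_cells = int((res["class_map"] != CELL_NONE).sum())
    assert cls["total"].total_area == pytest.approx(n_cells * res["grid"].cell_area)


def _stats_with_counts(counts):
    out = []
    for c in counts:
        cs = ClassStats(n_defects=c, total_area=0.01 * c,
                        mean_area=0.01 if c else None, area_fraction=0.001 * c)
        out.append(DefectFrameStats(classes={"deep": cs, "shallow": cs, "total": cs}))
    return out


def test_aggregate_ratio_to_itself_is_one():
    agg = aggregate_trajectory_stats(_stats_with_counts([2, 4]))
    agg2 = aggregate_trajectory_stats(_stats_with_counts([2, 4]), reference=agg)
    assert agg2.ratio_to_reference["total"] == pytest.approx(1.0)


def test_aggregate_population_sd():
    agg = aggregate_trajectory_stats(_stats_with_counts([2, 4]))
    mean, sd = agg.table["total"]["n_defects"]
    assert mean == pytest.approx(3.0)
    assert sd == pytest.approx(1.0)  # population SD, not sample SD sqrt(2)


def test_aggregate_empty_list_is_error():
    with pytest.raises(ValueError):
        aggregate_trajectory_stats([])


def test_aggregate_zero_reference_is_error():
    ref = aggregate_trajectory_stats(_stats_with_counts([0, 0]))
    with pytest.raises(ValueError, match="zero"):
        aggregate_trajectory_stats(_stats_with_counts([2]), reference=ref)


# ---------------------------------------------------------------- histogram + fit

def test_histogram_single_bin_probability_one():
    d = defect_area_histogram([1.2, 1.3, 1.4], bin_width=1.0)
    occupied = d.probabilities[d.counts > 0]
    assert occupied.sum() == pytest.approx(1.0)
    assert (d.counts > 0).sum() == 1


def test_histogram_matches_direct_counting():
    rng = np.random.default_rng(2)
    areas = rng.exponential(10.0, 1000) + 5.0
    d = defect_area_histogram(areas, bin_width=2.0)
    for k in range(len(d.counts)):
        lo, hi = d.edges[k], d.edges[k + 1]
        assert d.counts[k] == ((areas >= lo) & (areas < hi)).sum()
    assert d.probabilities.sum() == pytest.approx(1.0)


def test_fit_recovers_known_decay_constant():
    areas = sample_defect_areas(15.0, 5000, fit_min=5.0, seed=42)
    fit = fit_size_constant(defect_area_histogram(areas, 1.0), fit_min=5.0)
    assert fit.A0 == pytest.approx(15.0, abs=1.5)
    assert fit.A0 > 0 and fit.fit_min < fit.fit_max
    assert fit.n_samples >= 50


def test_fit_degenerate_distribution_is_error():
    with pytest.raises(ValueError):
        fit_size_constant(defect_area_histogram([7.0] * 500, 1.0), fit_min=5.0)


def test_fit_scale_invariance_of_decay_constant():
    areas = sample_defect_areas(12.0, 4000, fit_min=5.0, seed=9)
    d1 = defect_area_histogram(areas, 1.0)
    d2 = defect_area_histogram(np.repeat(areas, 2), 1.0)  # doubled counts
    # same fit window: the decay constant ignores the normalisation
    f1 = fit_size_constant(d1, fit_min=5.0, fit_max=40.0)
    f2 = fit_size_constant(d2, fit_min=5.0, fit_max=40.0)
    assert f2.A0 == pytest.approx(f1.A0, rel=1e-9)
    assert f2.A == pytest.approx(f1.A, rel=1e-9)


def test_fit_too_few_samples_is_error():
    areas = sample_defect_areas(15.0, 20, fit_min=5.0, seed=1)
    with pytest.raises(ValueError):
        fit_size_constant(defect_area_histogram(areas, 1.0), fit_min=5.0)


# ---------------------------------------------------------------- invariances

def test_pipeline_translation_invariance(topo):
    spec = SyntheticMembraneSpec(n_lipids_per_leaflet=64,
                                 composition=dict(PRESETS["chol40"]),
                                 condensation=0.5, seed=8)
    frame, tp = generate_bilayer(spec)
    ref = analyze_frame_defects(frame, tp, "upper")
    ref_areas = sorted(d.area for d in ref["defects"])
    g = ref["grid"]
    for shift_cells in ((5, 0), (0, 11), (13, 27)):
        moved = frame.copy()
        moved.positions = moved.positions.copy()
        moved.positions[:, 0] = (moved.positions[:, 0] + shift_cells[0] * g.cell_x) % g.lx
        moved.positions[:, 1] = (moved.positions[:, 1] + shift_cells[1] * g.cell_y) % g.ly
        got = analyze_frame_defects(moved, tp, "upper")
        assert sorted(d.area for d in got["defects"]) == pytest.approx(ref_areas)


def test_grid_refinement_stability(topo):
    spec = SyntheticMembraneSpec(n_lipids_per_leaflet=100,
                                 composition=dict(PRESETS["chol40"]),
                                 condensation=0.5, seed=4)
    frame, tp = generate_bilayer(spec)
    coarse = analyze_frame_defects(frame, tp, "upper", cell_size=0.1)
    fine = analyze_frame_defects(frame, tp, "upper", cell_size=0.05)
    a0 = coarse["stats"].classes["total"].total_area
    a1 = fine["stats"].classes["total"].total_area
    assert abs(a1 - a0) / a0 < 0.20
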