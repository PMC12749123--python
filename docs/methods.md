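# Methods

## Defect detection model

A planar bilayer frame (orthorhombic box, bilayer normal +z) is split into
leaflets by the sign of each lipid residue's mean headgroup height relative
to the bilayer midplane (mean z of lipid phosphorus atoms; mean headgroup z
for phosphorus-free coarse models). All lengths are nm internally; PDB
ångströms are converted at the file boundary.

Each leaflet surface is discretised into a grid of square cells,
`nx = round(Lx/cell_size)` per axis with the cell size recomputed as
`Lx/nx` so the grid tiles the box exactly; at the default 0.1 nm cell the
cell area is 0.01 nm². The overlap criterion is concrete: a cell is
*covered* when the 2D distance (periodic in xy) between its centre and the
xy-projection of some headgroup atom is at most that atom's van der Waals
radius. Radii are element-based Bondi values (H 0.120, C 0.170, N 0.155,
O 0.152, P 0.180 nm), overridable per config; using element radii rather
than force-field atom types keeps the analysis reproducible from plain
coordinate files. Protein atoms never cover cells — defects are a property
of the lipid surface, computed identically with and without a bound
protein.

Cells not covered by any headgroup atom are defect cells. The depth
reference is the *glycerol plane*, the mean z of the leaflet's
glycerol-role atoms; sterols contribute through a ring-anchor atom
(cholesterol C3) placed in the glycerol role so the topology invariant
(every lipid has headgroup and glycerol sets) holds without letting
sterols distort the plane. A defect cell is **deep** when no lipid atom of
any role with elevation above −0.1 nm (1 Å) relative to the glycerol plane
overlaps it, and **shallow** otherwise; elevations are measured toward the
water phase so both leaflets use the same rule. Cells with no atom beneath
at all are deep — a fully exposed solvent channel is the deepest possible
defect.

Defect cells merge into defects when their centre-to-centre distance is at
most 0.3 nm (periodic in xy); at the default grid this links up to
third-nearest neighbours. Components are built with deterministic
union-find and emitted sorted by their lexicographically smallest member
cell, so output is independent of enumeration order. `per_class` mode
merges deep and shallow cells separately (used for per-class size
distributions); `all` mode merges every defect cell and labels the result
deep when any member cell is deep — one deep access point makes the whole
defect insertion-competent.

Per-frame statistics (counts, total and mean area, area fraction of the
leaflet) are reported for deep, shallow and total. Across frames the
package reports mean ± population SD; across independent runs, the SD of
run means. Count ratios against a reference aggregate (e.g. a sterol-free
membrane) are the reference-relative presentation of defect abundance.

## Defect size constant

Defect areas (converted to Å², 1 nm² = 100 Å²) are histogrammed in 1 Å²
bins and normalised to a probability distribution. The small-defect regime
is fitted with ln P(x) = ln A − x/A₀ by weighted least squares, weights
√count per bin (the approximate inverse SD of the log of a Poisson count).
The fit window runs from `fit_min` (default 5 Å²) to the largest bin still
holding ≥ 5 defects — restricting the fit to the well-sampled regime
rather than the noisy tail. The fit refuses (never extrapolates) with
fewer than 3 occupied bins or 50 samples in range, or when the slope is
non-negative. On synthetic exponential samples (A₀ = 15 Å², n = 5000) the
estimator recovers A₀ within a few percent per seed and the error shrinks
with sample size; the tests pin this.

The histogram-over-defect-areas reading of a threshold-free defect measure
is one of two possible interpretations of "varying the defect threshold";
the alternative (scanning the depth threshold itself) is available via the
`--depth-threshold` option but is not the default.

## Interactions

Hydrogen bonds use the standard geometric criterion — donor–acceptor
distance ≤ 0.35 nm and H–donor–acceptor angle ≤ 30° — restricted to pairs
crossing the protein/membrane boundary, under minimum image. Coordinate
files carry no bonds, so hydrogens are attached geometrically to the
nearest N/O/S heavy atom within 0.12 nm on the same side. Both cutoffs are
exposed as options.

Energies are plain-truncation sums over cross pairs within 1.2 nm
(minimum image, all three axes): Coulomb with f = 138.935485
kJ·mol⁻¹·nm·e⁻², Lennard-Jones with Lorentz–Berthelot combining
(arithmetic σ, geometric ε). There is no shift, reaction field or
reciprocal-space term: absolute agreement with mesh-Ewald MD energies is
out of scope by design; the outputs are for relative, decomposition and
ensemble comparisons. The residue-decade × lipid-species decomposition
partitions the same pair set, so block sums reproduce totals to rounding.
Per-lipid normalisation divides by the number of *contact lipids* (≥ 1
atom within the cutoff of any protein atom); with no contact lipid the
average is undefined (None), never zero. Pairwise distances are computed
in float64 NumPy directly so the double-loop oracle equality holds to
1e-9 relative.

## Synthetic membrane generator

The generator emulates the studied systems at desk scale: planar bilayers
on a jittered square lattice (spacing 0.8 nm, Gaussian xy jitter of
SD 0.05 nm clipped at 0.1 nm), two leaflets mirrored about z = box_z/2,
glycerol planes 1 nm from the midplane, compositions from the studied
presets (12/20/68 PS/PE/PC with 0, 10 or 40% sterol replacing PC,
largest-remainder rounding so species counts are exactly testable), and a
60-residue probe chain placed a configurable distance above the surface
(the studied initial separation is ~5 nm). Lipid counts per leaflet must
be perfect squares; the test fixtures use 16–256 lipids per leaflet rather
than the 2048-lipid production scale, which keeps every test and the
acceptance script within seconds while exercising identical code paths.

Pseudo-lipids are coarse bead stacks, not all-atom lipids; the pipeline is
role- and radius-driven, so bead models exercise all of its logic. The
bead geometry is derived from the coverage inequality, not tuned: a disk
of radius r covers every point of a periodic square lattice of spacing a
when r ≥ a/√2, so with jitter ≤ 0.1 nm per component the worst-case
centre-to-head distance is 0.8/√2 + 0.1·√2 ≈ 0.707 nm, and the headgroup
bead radius of 0.72 nm guarantees a sterol-free leaflet covers every grid
cell — an uncarved membrane yields exactly zero defects. Each
phospholipid also carries a glycerol marker bead, an upper-tail "guard"
bead just above the deep plane (radius 0.85 nm), and two deep tail beads.
Sterols carry a deliberately tiny hydroxyl head bead (0.05 nm — an -OH
barely shields the interface) and a body sunk below the deep plane.
Consequently an isolated sterol opens a small defect that neighbouring
phospholipid guards keep shallow, while a condensed sterol patch opens a
large connected region with nothing above the deep plane: a deep defect.
The `condensation` knob κ places sterols uniformly at random (κ = 0) or,
with probability κ per sterol, grows a single compact patch around a
random seed site (κ = 1 gives one connected disk). This reproduces the
condensation phenomenology — rising κ at 40% sterol suppresses the
shallow-defect count and inflates the deep-defect mean area — as an
emergent property of the geometry, verified by sign tests across seeds.

`carve_defect` creates cell-exact ground truth: it picks a contiguous set
of covered cells at least 0.6 nm from any existing uncovered cell, deletes
every headgroup bead overlapping them (for deep defects, every bead above
the deep plane), and restores collateral coverage with single-cell filler
beads of radius 0.05 nm placed exactly at cell centres (the next cell
centre is 0.1 nm away, so a filler covers precisely its own cell). The
pipeline must then report exactly one defect of the requested cell count
and class — the basis of the depth-partition and single-cell-area tests.

What the generator does *not* emulate: thermal disorder of real
interfaces (defects from conformational fluctuations rather than carved
vacancies), atomistic headgroup chemistry, membrane undulations, or
energy-minimised packing. Passing tests therefore demonstrate the
correctness of the detection/merging/classification/fit machinery and the
qualitative condensation mechanism, not quantitative agreement with
all-atom MD ensembles — whose figure-level results are presented only
graphically and are not desk-reproducible.

## Numerical choices and degenerate inputs

- Overlap and merge comparisons use ≤ with a 1e-15 absolute slack so
  exact-tie geometries are stable across platforms.
- Leaflet ties (headgroup exactly at the midplane) go to the upper leaflet.
- An empty defect list yields mean area None (undefined), never 0; ratio
  computation against a zero-count reference raises.
- Boxes are orthorhombic only; triclinic inputs are rejected at parse time.
- Frames slices (start:stop:stride) select which frames enter averages;
  no equilibration discard is assumed on the user's behalf.
- All generator outputs are pure functions of (spec, seed) via
  `numpy.random.default_rng`.

## Known limitations

- Cutoff electrostatics differ from mesh-Ewald values by construction;
  only relative/ensemble comparisons are meaningful.
- Geometric H-bond attachment can mis-assign hydrogens in exotic
  geometries (< 0.12 nm to two heavy atoms); real force-field connectivity
  is not read.
- Defect statistics are per leaflet; combining leaflets is the caller's
  choice (`--leaflet both` reports each separately).
- The built-in DOPC/DOPE/DOPS/CHOL role sets use CHARMM-style atom names;
  other force fields need a topology TOML override.
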