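# Methods

This package reconstructs, as testable computation, the quantitative
workflow of a comparison between two vertically-aligned carbon nanotube
(VACNT) electrode geometries for dissociated retinal neuron/glia
co-cultures: an 'open' fractal H-tree whose SiO2 gaps form one
interconnected network, and a 'closed' grid whose gaps are isolated
square chambers.  The biology itself is not reproducible from a paper —
it lived in specific cultures — so the package pairs the deterministic
geometry with a synthetic-image generator that carries exact ground
truth, and validates the measurement pipeline against that truth.

## Electrode geometry

**H-tree construction.** One repeating level contributes a horizontal
and a vertical segment generation, so `m` levels give `K = 2m`
generations and `2^K - 1` branches.  Generation `k` holds `2^(k-1)`
segments of length `L1 * r^(k-1)` with `r = 2^(-1/D)`; children are
perpendicular to their parent and centred on its tips, and every
centreline is drawn as a rectangle of width `W_CNT`.  The seed length
`L1` is calibrated so that the overall width (horizontal centreline
extent plus one branch width from the two outermost vertical
rectangles) equals `W`:

    W = W_CNT + L1 * (1 - r^(2m)) / (1 - r^2)

For the published design (D=2, m=5, W_CNT=20 um, W=6260 um) this gives
`L1 = (W - W_CNT) * 16/31 = 3220.65 um`, which is also the maximum
electrode separation (`W_Si-max`, centre-to-centre spacing of the two
second-generation branches); the edge-to-edge value `L1 - W_CNT` is
reported alongside.

**Exact measurement.** Union area and perimeter are computed by a
coordinate-compression sweep over the rectilinear arrangement (every
elementary cell is fully covered or fully empty), which is exact up to
floating-point rounding.  For H-trees the result is cross-checked
against the junction-overlap closed forms: each of the `2^K - 2`
parent-child junctions overlaps by a `W_CNT x W_CNT/2` rectangle, so

    A_CNT = W_CNT * L_total - (W_CNT^2 / 2) * (2^K - 2)
    E     = 2 * L_total + 2 * W_CNT * (2^K - 1) - 3 * W_CNT * (2^K - 2)

with `L_total = L1 * ((2r)^K - 1)/(2r - 1)`.  Disagreement between the
sweep and the closed form signals sibling overlaps, i.e. a design whose
branches are too wide for its terminal gaps; such layouts are rejected.

**Bounding convention.** `A_bounding` uses the idealized boxes: `W^2`
for the grid (whose outer walls close the square exactly) and
`W^2/sqrt(2)` for the H-tree, whose tight box is ~0.3% shorter in y.
`A_Si = A_bounding - A_CNT` by definition, so the partition identity
holds to machine precision.  The tight-box area is reported too.

**Known inconsistencies in the nominal design table.** Two printed
cells contradict the others: the grid material area (printed 5.36e6,
but `W^2 - A_Si = 5.40e6`, and the printed area ratio 1.28 matches the
latter) and the fractal area ratio (printed 5.88, but the printed
areas give 2.31e7/4.62e6 = 5.0).  Both are treated as typographical and
flagged `excluded` in the design-table report.  The printed fractal
`W_Si-min = 60 um` could not be derived from the stated construction
(the narrowest measured corridor is wider); the measured minimum is
reported instead of forcing the nominal value.

**Gap topology.** The gap is the in-box complement of the electrode,
rasterized by a pixel-centre test with a half-open tie rule.  Because
the substrate physically extends beyond the pattern, the box is padded
by a 3-px gap ring before labelling; components that exist only in the
pad (the ring around the grid's outer walls) are not counted.  This
yields one component for the fractal and `n^2 = 1849` for the grid.
Gap *proximity* is summarized as the mean Euclidean distance of gap
pixels to the nearest electrode pixel; gap *connectedness* as the area
fraction of the largest component.  Corridor widths are twice the
clearance sampled on the gap medial axis after pruning axis spurs
shorter than `W_CNT`; in square chambers the corner diagonals survive
partially, so the reported minimum sits below the face-to-face chamber
width — a property of the corridor definition, not a bug.

## Tiling and surface masks

Fields of view are 2048 px (662.65 um) squares tiled with 10% nominal
border overlap.  The stride is snapped to a whole number of pixels
(1843 px at defaults) so that all tiles share one pixel lattice and the
overlap strips of neighbours carry bit-identical content.  A pixel is
electrode iff its centre lies in the rectangle union (lower-left
inclusive, upper-right exclusive — no double counting at seams); gap
iff in-domain and not electrode.  For aggregation each physical point
is owned by exactly one tile (the covering tile whose origin is
nearest, so overlap strips belong to the upper/right neighbour), and
ownership regions partition the covered area exactly.  Mask offsets
(dilation/erosion of the electrode by up to 10 px) mirror the manual
corrections used when registering nominal masks to fabricated widths.

## Synthetic cultures

The generator builds a *vector* scene first and renders images from it,
so the ground truth (polyline lengths, blob areas) is analytic and
independent of any rasterization choice.

* **Somas** follow surface-specific Poisson processes; a configurable
  fraction aggregates into clusters.  Defaults (40 /mm^2 on the gaps,
  120 /mm^2 on the electrode tops) encode the observed preference of
  neurons for the textured VACNT surface, at an areal density loosely
  consistent with a 3.7e6 cells/mL seeding after adhesion losses.
* **Neurites** grow as persistent random walks (step = one pixel;
  heading noise sigma = (1 - tortuosity)/2 rad per step, giving a
  persistence length of ~130 um at the default tortuosity 0.9).  Within
  `d_edge = 3 um` of an electrode boundary a step follows the boundary
  tangent with probability `p_edge_follow = 0.6` (with a small lateral
  wiggle, and a gentle push-off below 0.8 um so surface attribution
  stays unambiguous), emulating the observed edge-guided growth.
  Walks steer around soma disks — neurites navigate around cell bodies
  rather than under them, which also keeps every planted centreline
  optically observable — and terminate at the open scene border.
  With probability `p_bundle = 0.15` a new neurite duplicates an
  existing path at a sub-pixel offset (a bundle).
* **Glia** are radially-perturbed ellipses (lognormal size scatter,
  elongated 3:1 along the local branch axis on electrode tops, nearly
  isotropic on the gaps), added — and clipped to their surface — until
  the target coverage is met; the final approach uses single,
  deficit-sized blobs so the realized coverage lands within a fraction
  of a percentage point of the target.
* **Rendering**: neurite paths are splatted bilinearly (~1.5 px
  ribbons), somas and nuclei are disks, glia are filled polygons; each
  channel is blurred with a Gaussian PSF (sigma 0.5 um), offset by a
  background (200 counts) and given signal-dependent Gaussian noise
  (variance proportional to intensity — a shot-noise approximation),
  then quantized to 16 bits.  All randomness derives from one integer
  seed; per-tile noise streams are keyed by (seed, channel, row, col),
  so scenes are bit-reproducible and tile content in overlap strips is
  consistent.

**Merged truth.** The measurement-comparable truth collapses co-located
routes: processing paths in order, any point within the collapse radius
of an earlier path is dropped, and surviving runs form the merged
centreline set.  The default radius of 2.0 um is the resolution limit
of the rendering/detection chain — planted parallel pairs merge into a
single detected ribbon up to ~2 um centre separation and resolve above
~2.5 um — so exact bundles vanish entirely and partial co-travel is
collapsed only over the shared stretch.  Raw truth sums every planted
centreline regardless.

What the generator does *not* model: defocus between the two imaging
planes (surfaces are separated by masks, not focus), uneven
illumination, real neurite branching trees, glial process texture, and
cell debris.  Passing recovery tests therefore certify the measurement
pipeline against idealized-but-noisy imaging, not against every
pathology of real micrographs.

## Quantification

Per FOV and per surface (matching how the imaging data were analyzed;
stitching is provided for visualization and cross-checks):

1. background subtraction (smooth Gaussian estimate, radius 15 um, or
   an exact rolling ball);
2. one automatic threshold per FOV over in-domain pixels — the lowest
   three-class Otsu cut for the tri-modal neuron channel (background /
   neurite ridges / bright somas), plain Otsu for the bimodal glia
   channel — accepted only if it separates the classes by at least
   ~6 robust standard deviations of the background, else the channel is
   declared empty; a fixed threshold reproduces the semi-automated
   manual path;
3. soma/cluster removal: bodies are found as distance-transform cores
   deeper than 0.7 * r_soma (r_soma = 5 um) and grown back to their
   boundary plus a 2 px PSF margin, so neurite ribbons are cut flush
   with the soma edge;
4. cleanup: sub-resolution holes (< 4 um^2) are filled (otherwise the
   skeleton loops around threshold speckle between near-parallel
   ribbons), objects smaller than 1 um^2 and components nowhere thicker
   than ~2 px (boundary spill-over slivers) are dropped;
5. skeletonization by Lee's thinning — the classic two-subiteration
   scheme can erase uniform diagonal ribbons entirely — followed by
   junction-aware spur pruning (branches that reach a junction within
   l_min = 2 um are deleted; genuine free ends are kept whole);
6. length = (0.948 * orthogonal + 1.340 * diagonal steps) * pixel size
   (Vossepoel-Smeulders weights; the naive 1/sqrt(2) weighting is
   available but overestimates tilted lines by up to 8%), plus a
   2.5 px/endpoint credit for the thinning erosion of free ends.

Glial area is the thresholded, debris-filtered (>= 20 um^2) pixel count
times the pixel area.  Totals over included FOVs are de-duplicated by
tile ownership and normalized by the design's surface areas into
`N_Si = N_LSi/A_Si`, `N_CNT = N_LCNT/A_CNT` (um^-1) and
`G_Si = G_ASi/A_Si`, `G_CNT = G_ACNT/A_CNT` (dimensionless).

**Validation.** Over 20 seeded default scenes (a reduced 9x9-chamber
grid covering a 2x2 plan of full 2048 px tiles — sized so the study
runs in minutes), the median absolute recovery error of the merged
process length is ~2% (gap) and ~3% (electrode) and of the glial
coverage < 0.5%; planted bundle pairs are measured once.  Bidirectional
failure modes remain at the percent level: co-located independent paths
just above the collapse radius merge in the detector (undercount), and
chain-code quantization moves single-line lengths by ~1% with sub-pixel
placement.

## Statistics

Nonparametric throughout, mirroring the experimental analysis:
Shapiro-Wilk screening (scipy reference implementation), Kruskal-Wallis
with pooled mid-ranks and tie correction (p from the chi-square
approximation, or exact permutation for small samples), asymmetric IQR
outlier fences (`Q1 - 1.5*IQR` below, `Q3 + 3*IQR` above — the
asymmetry is deliberate), and through-origin least squares with a
*centred*-SST R^2 (which may be negative; undefined for constant y).
Quartiles default to linear interpolation of order statistics (the
original tool's convention is unknown; the convention is switchable).
The battery runs within-design surface comparisons, across-design
metric comparisons, the four scatter fits, success counts for
`G_Si > G_CNT` and `N_CNT > N_Si`, and per-metric outlier flags.
The published p-values and R^2 are data-dependent properties of the
original cultures and are not reproduction targets; the battery is
validated on planted effects instead.

## Numerical and design choices

* Half-open pixel-centre rasterization everywhere (no seam double
  counting); integer-pixel tile stride (exact overlap consistency).
* Degenerate inputs: empty surfaces measure zero (not an error);
  all-identical samples give H = 0, p = 1; constant samples are
  rejected by Shapiro-Wilk; zero-area denominators raise.
* Replicate seeds derive as `seed*1000 + arm*100 + replicate`
  (mod 2^31), keeping arms and replicates on disjoint streams.
* The grid design derives the chamber side from `(W, n, W_CNT)`
  (c = 61.16 um for the published design, printed nominally as 60);
  this is the only closed set of parameters that reproduces the
  printed edge length, gap area and area ratio simultaneously.

## Limitations

Geometry is strictly 2-D: the ~25 um VACNT height matters biologically
(it walls the glia in) but enters only through the gap-topology
abstraction.  The synthetic generator's distributions (process length,
cluster sizes, glial morphology) are plausible placeholders, not fits
to data.  Real-data mask registration (fitting the design to the DAPI
channel) is out of scope; masks here are exact by construction.
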