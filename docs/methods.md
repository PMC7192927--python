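# Methods

## The physical model

A droplet interface bilayer (DIB) forms when two lipid-monolayer-coated
aqueous droplets in oil touch: the two monolayers zip into a bilayer and the
droplets flatten against each other. At equilibrium the contact angle θ_DIB
between the spherical droplet surfaces and the flat bilayer satisfies the
Young balance γ_b = 2 γ_m cos θ, so the work of adhesion per unit bilayer
area is ΔF = 2 γ_m (1 − cos θ): larger angles mean stickier, more deformed
pairs. For a measured pair the angle follows from circle–circle
intersection geometry,

    2 θ_DIB = arccos((L² − R₁² − R₂²) / (2 R₁ R₂)),

which for equal radii reduces to θ = arccos(L / 2R). A droplet adhering to
a substrate obeys θ_surface = arcsin(R_b / R_a).

Composition controls the tensions and hence the angle. Over the
experimentally relevant range the dependence is linear in both the silicone
oil volume fraction φ_SIL and the POPC mole fraction x_POPC; the package
ships the published plane θ = (0.930 φ + 0.368 x − 0.238)/0.009 as a frozen
constant and refits planes by ordinary least squares (vertical residuals in
θ). The printed coefficients are rounded at three decimals, so evaluating
them reproduces in-text angles only to about ±1.5°; the constant stores
them verbatim rather than attempting to reverse-engineer the unrounded fit.
Predictions outside [0°, 90°) are returned unclamped but flagged with a
warning, because silently clamping would hide extrapolation misuse.

When a pair equilibrates, each droplet deforms from a sphere of radius R₀
into a truncated sphere of radius R(θ) at centre distance L(θ) = 2R(θ)cos θ.
R(θ) is fixed by volume conservation: the sphere-minus-cap volume at cap
height R(1 − cos θ) must equal (4/3)πR₀³. This is solved by bracketed root
finding on R ∈ [R₀, 2R₀] (Brent, relative tolerance 1e-12; the truncated
sphere always loses volume so the bracket is guaranteed). The model assumes
equal volumes and a flat bilayer; unequal pairs are handled only through
the measurement formula above.

The geometric anchor of the whole study is the critical angle. Four
droplets with centres on a regular tetrahedron trap a pocket of oil; the
pocket closes exactly when the pair contact angle reaches half the
tetrahedron's dihedral angle, i.e. cos 2θ_c = 1/3, θ_c = 35.264…°. Printed
networks pack best when θ_DIB ≈ θ_c: far below it droplets barely adhere
(loose, unpacked networks with large oil inclusions), far above it the
centre-to-centre shrinkage L(θ) drags droplets off their printed positions
(dense amorphous packing).

## Packing classification

Droplet centroids are meshed by Delaunay triangulation (scipy/Qhull); each
triangle is a triplet of mutual neighbours because its circumcircle
contains no other centroid. Three dimensionless metrics classify each
triplet:

* θ_max — largest interior angle (law of cosines),
* Â — triangle area / mean droplet area,
* P̂ — triangle perimeter / mean droplet radius.

Classes: hexagonal 60° ≤ θ_max < 67°, amorphous 67° ≤ θ_max < 83°, square
83° ≤ θ_max < 97°, each additionally requiring 0.25 < Â < 0.75 and
P̂ < 3.73 + 0.0545 θ_max; everything else, including degenerate (collinear)
triplets, is no-packing. The P̂ constraint removes "sliver" triangles — two
touching droplets plus one distant droplet — which the θ_max/Â rules alone
would admit. All bounds are implemented exactly as stated, with strict
inequalities where written; per-network summaries weight classes by
triangle area, since packing is reported as area fractions.

The mean droplet radius entering P̂ uses equivalent-circle radii
√(area/π) averaged over the droplet regions. Under this convention a
perfect touching hexagonal lattice gives P̂ = 6 and a square one
P̂ = (2+√2)√π ≈ 6.05 from segmented regions (or 4+2√2 ≈ 6.83 with disc
areas), all comfortably inside the sliver bound (7.00 at 60°, 8.64 at 90°),
so classification outcomes are insensitive to the convention. A
hexagon-circumradius convention would rescale P̂ values but not the
classifications; the threshold line is used exactly as printed rather than
re-derived from either convention.

Cocircular degeneracies (four points on one circle, as in a perfect square
lattice) are resolved by Qhull's deterministic tie-break; both diagonal
choices give right-isosceles triangles, so the class is invariant and tests
assert the class, not the diagonal.

## Segmentation

Membrane-fluorescence images show bright interconnected bilayers/monolayers
around dark droplet interiors. Segmentation proceeds: Hessian-eigenvalue
(Sato) bright-ridge enhancement at a configurable scale (default 2 px),
normalised to [0, 1]; Otsu threshold; speck-sized holes (≤ 2 px) in the
ridge band filled; skeletonisation; morphological closing of skeleton gaps
up to `gap_close_px` (default 3 px); connected-component labelling of the
enclosed regions. Components reaching the image corners are background.
Regions under 5 px² are dropped. Border-touching regions are kept but
flagged, since whole first layers — edges included — are analysed.

Regions are droplets iff 0.4·median ≤ area ≤ 10·median and
area/convex-hull-area ≥ 0.9 (the median over *all* regions, before any
classification); the rest are oil inclusions. Droplet excess is
100(N − N_t)/N_t with N_t a design input (the 7×8×4 reference print's first
layer settles to 8×9 = 72, shipped as `N_T_FIRST_LAYER`); droplet size CV
uses the sample SD (n−1). Interactive cleanup steps in the original
workflow are replaced by the automated equivalents above, for
reproducibility.

## Synthetic data

The generator renders the fully packed first layer as the Voronoi partition
of the droplet centres clipped to equal discs: touching droplets share
straight bright edges (bilayers), isolated droplets show bright circular
rims (monolayers). This idealisation matches the polygonal cross-sections
that close-packed droplets actually adopt and, crucially, has analytic
ground truth — every rendered region, centroid and area is known exactly,
which is what downstream recovery tests measure against. Ridges of width
3 px are blurred (Gaussian, σ = 1 px) and corrupted with additive Gaussian
noise. Additive noise only: the classifier consumes geometry, not
intensities, so shot-noise realism buys nothing here. No quantitative
PSF/noise calibration of the original confocal imagery exists, so these
defaults are plausible rather than calibrated — passing tests demonstrate
correctness of the analysis chain on images whose degradations are mild and
known, not robustness to every real-world artefact (uneven illumination,
z-blur, debris, touching-layer bleed-through).

Lattices: hexagonal (triangular lattice, row pitch √3/2·spacing), square,
amorphous (hexagonal + iid Gaussian jitter), sparse (spacing inflated to
≥ 2.2 diameters so nothing touches), mixed (perfect core, jittered rim of
depth 2 sites — the synthetic analogue of edge disorder in real prints).
Default droplet radius is 25 px with 45 px spacing; all classifier
thresholds are dimensionless, so the scale only sets image size and test
speed. Oil inclusions are injected by deleting interior droplets — chosen
in adjacent pairs so the merged vacancies are concave (convexity < 0.9) and
hence morphologically recognisable — re-rendering, and counting the vacated
area; deletion stops when the inclusion area fraction is within ±20% of the
target (monotone in the deletion count, so a doubling-then-bisection search
on the fixed deletion order suffices; unreachable targets return
best-effort with a flag). Only sites at least one lattice pitch clear of
the convex hull are deleted, so vacancies stay enclosed. Excess droplets
("fallen from the upper layers") are appended at vacant sites one lattice
step from existing droplets, expanding the image frame as needed.

Every generator is deterministic in (arguments, seed); per-operation random
streams are derived from the user seed by hashing the operation name, so
adding one generator call does not shift another's randomness.

## Registration and heatmaps

Replicate prints are registered to a reference by iterative closest point
over droplet centroids, restricted to rotation + translation (Kabsch with
the reflection guard; no scaling, so network geometry is preserved).
Because lattices have rotational symmetries, ICP runs from a set of initial
rotations (principal-axis alignment plus a 30° scan) and, among equally
good fits, the smallest rotation wins — a deterministic tie-break that
makes round-trip recovery exact (< 1e-6 px) for noise-free rigid copies
well beyond ±30°. A user-supplied transform can replace the automatic one.

Each classified triangle's pixel footprint (after transform) marks its
class's binary map; maps are summed across prints and binned onto the
idealised design: regular hexagons of circumradius spacing/√3 centred on
the design's droplet positions, which tessellate exactly. Pixels go to the
nearest bin centre, kept only inside that centre's hexagon. Per bin, class
counts are normalised to proportions (Σ over classes = 1); bins with no
counts are emitted as NaN rather than 0 so plots can distinguish "no data"
from "none of this class". Triangle footprints — the classified unit — are
what is rasterised, rather than whole-droplet footprints.

## Pipeline defaults and degenerate inputs

All angles cross the API in degrees. Classifier thresholds are exposed in
the run configuration but default-locked to the standard rule set; any
override marks the summary JSON `non_standard_thresholds`. Blank images
yield empty segmentations with a warning, not an exception; fewer than
three droplet regions is a triangulation error; stage failures in the
pipeline abort, remove partial outputs, and name the stage and input. Pair
images are measured by splitting the filled silhouette in two (watershed on
the distance transform), masking the abutment zone around the bilayer
chord, and fitting one circle per free rim arc (Kåsa algebraic fit refined
by geometric least squares, intensity-weighted); the centre distance is
clipped at tangency before the angle formula.

## Problem sizes

The study sizes used throughout tests, analysis scripts and the acceptance
script are 10×10 first layers (12×12 for inclusion injection, 8×9 = 72
sites for droplet-excess experiments, 6×6 sparse), 20 seeds per jitter
level, and 5 replicate prints for heatmaps. These sizes give interior-
dominated lattices (edge triplets are a < 5% area minority) while keeping a
full run of everything in well under a minute.

## Known limitations

* The segmentation is tuned to bright-ridge membrane images with modest
  noise; it has no illumination correction or gap-bridging beyond the
  morphological closing.
* The plane fit minimises vertical θ residuals; if composition values carry
  comparable error a total-least-squares fit would differ slightly.
* Pair-deformation geometry assumes equal volumes and a flat bilayer.
* The heatmap registration needs a reasonable fraction of droplets common
  to all prints; it is point-based and ignores image intensities.
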