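# Methods

## The geometric model

The protein is reduced to its heavy atoms with van der Waals radii; the
smallest convex domain enclosing them is partitioned into tetrahedral
cells by a plain (unweighted) Delaunay triangulation with atoms at the
vertices. Two adjacent cells communicate through their shared triangular
face, which acts as a door. The ligand is reduced, at each door, to the
circular cross-section of its cylindrical model: a disc of diameter CV,
the ligand's critical thickness. A door is open iff a disc of that
diameter fits inside the closed triangle clear of the three vertex
spheres, i.e. iff

    CVmax = 2 · max(0, max_{c ∈ triangle} min_i (‖c − p_i‖ − r_i)) ≥ CV.

Two deliberate consequences of this definition:

* the disc centre is constrained to the closed triangle — a passage
  point outside the triangle belongs to a neighbouring door;
* only the three vertex atoms obstruct their own door. Occlusion by
  nearby atoms is represented by the adjacent doors those atoms form,
  which the ligand must also pass. This keeps the test local and exact,
  at the price that a single door can be slightly optimistic about
  what a full cylinder with tilt could do; no orientation optimisation
  of the cylinder is attempted.

The max–min clearance problem is solved exactly by candidate
enumeration in the triangle's plane: the weighted-equidistant
(Apollonius) point of the three spheres when it lies inside the
triangle, the two-sphere equalisation points restricted to each edge
(roots of a quadratic), and the vertices. A brute-force oracle
(`cvmax_oracle`) maximises the clearance field on a coarse-to-fine
barycentric grid; because the field is 1-Lipschitz, pruning cells more
than 2.5 pitches below the running best is sound, and the result is
within O(step) of the optimum. The test suite keeps solver and oracle
within 2·step of each other on randomised doors.

## Channels, CVlim, paths

The facial graph has one node per cell, one edge per door carrying its
CVmax, and a single EXTERIOR super-node attached through every hull
face (a ligand may enter wherever a surface door is wide enough). It is
a multigraph: a cell with several hull faces keeps several independent
exterior doors, which matters when paths are removed edge by edge. The
target cells are all cells incident to the target atom — the heme iron
is itself a tessellation vertex, so its "location" is its star of
cells — or the single cell containing a literal target point.

At thickness CV the graph keeps the edges with CVmax ≥ CV; a connected
component of cells linking EXTERIOR to a target cell is an access
channel. CVlim is the bottleneck (widest-path) value over all
exterior→target routes. It is computed by binary search over the sorted
distinct CVmax values using connectivity tests, and cross-checked by a
max–min variant of Dijkstra; the two must agree exactly.

Minimal cost paths price each door at CV/CVmax ∈ (0, 1] — wide doors
are cheap — and are found by Dijkstra from the EXTERIOR to the nearest
target cell (the multiple target cells act as a zero-cost virtual
sink). Ties are broken by fewer doors, then by the lexicographically
smallest cell sequence, making extraction deterministic and independent
of node ordering. Successive paths are obtained by removing all edges
(not nodes) of the current path and re-running; the edge set strictly
decreases, so the process terminates with pairwise edge-disjoint MCPs.

MCPs are clustered into trajectories by single-linkage agglomeration on
the Jaccard index of their cell sets, threshold 0.3 by default (a
config knob). The metric and threshold are this package's choice: they
are scale-free, deterministic, and merge paths that share a common
corridor while keeping paths through unrelated openings apart.

## Measures, classification, lining

A region (channel, MCP, trajectory) has volume Σ|det|/6 over its cells
and a bounding surface equal to the total area of its closed incident
faces (CVmax < CV). Open faces are openings even on the rim of the
region — an MCP threading wide doors can legitimately have zero
bounding surface. A closed internal face shared by two cells of the
region is one wall and is counted once.

The void of a channel is partitioned volume-weighted into *surface
pocket* (cells with a hull face, extended through connected cells that
keep at least one vertex atom on the convex hull), *active site*
(non-surface cells with a vertex atom in the cofactor residue) and
*transit* (the remainder). The published observations this mirrors are
qualitative ("most of the void is surface pockets"), and the exact
notion of a surface pocket is acknowledged to be unsettled; the rule
above is therefore a declared reconstruction, and the fractions it
reports should be read with that in mind.

Lining atoms are the union of vertex atoms of a region's cells; lining
residues are their unique residues, amino acids and cofactor listed
separately. Egress annotation takes the hull-adjacent (mouth) cells of
a trajectory and reports the HELIX/SHEET elements containing their
lining residues, with contiguous unmatched residues merged into loop
segments. Channel naming in the field's 2a/2f/2e/S scheme is curation,
not computation: the package reports anonymous channels plus egress
elements, and an annotation mapping can supply canonical labels.

## Ligand thickness

CV of a ligand is the diameter of the thinnest infinite cylinder
enclosing its atom spheres: minimised over axis direction (Fibonacci
hemisphere of ≥500 directions, then Nelder–Mead refinement of the best
direction) with, per direction, the smallest enclosing circle of the
projected centres with radii added (Frank–Wolfe iteration polished by a
simplex search; the objective is convex). A centre-only variant
(ignoring radii) sits behind a flag, default off. Because the cylinder
convention of the original measurement is not fully published, every
entry point of the pipeline accepts an explicit numeric CV, so nothing
downstream depends on this module.

## Structure input

PDB files are read with gemmi. Hydrogens are dropped; alternate
locations resolve to the highest-occupancy conformer (ties → altLoc
'A') for a deterministic single-conformer input. ATOM records are
protein; HETATM heme variants are cofactor, waters are water,
everything else is ligand. The tessellated set defaults to protein +
cofactor: waters are displaceable and co-crystallised ligands are
exactly what the channels are computed *for*, so their sites must be
empty. One chain is analysed at a time (default: the first). The
packaged radii table is Bondi-style (C 1.70, N 1.55, O 1.52, S 1.80 Å,
…); Bondi gives no iron value, so Fe uses 2.00 Å, and unknown elements
fall back to a configurable default (2.0 Å) with a warning. Published
channel measurements never state the radius set used, which is one
reason all comparisons against them carry tolerances (±0.25 Å on
CV-type values, ±15 % on volumes/surfaces).

## Numerical choices

* Exactly coplanar input is a hard error; cospherical (or otherwise
  Qhull-degenerate) input gets a deterministic Gaussian jitter of
  1e-6 Å with a fixed recorded seed, applied only on backend failure.
* Face identity is the sorted vertex triple; face ids follow the
  sorted-triple order, cell ids the backend simplex order — all outputs
  (channel ordering by volume desc then smallest cell id, MCP ranks,
  trajectory ordering) are deterministic given the input.
* Costs are compared as floats; exact ties fall through to the
  discrete tie-breaks above.

## The synthetic fixtures and what they show

`make_shell_pore` builds a quasi-uniform Fibonacci shell (default 800
atoms on a 10 Å sphere, spacing ≈ 1.25 Å, Gaussian jitter 0.1 Å, seeded)
of carbon-like atoms with a buried FE/HEM target at the centre. A pore
is a polar cap cut out of the shell and "doored" by three marker atoms
on a circle of diameter `aperture_width`; the convex hull then caps the
hole with the marker triangle, whose clear-disc diameter is exactly
`aperture − 2·atom_radius`. The cap is cut one atom spacing beyond the
marker circle so the surrounding sliver doors stay narrower (≈ 87 % of
the marker door). This makes the fixture's ground truth analytic:
CVlim must recover the effective aperture (observed error well under
0.5 Å across seeds), a closed shell must have no channel, and the
three marker atoms — annotated as a labelled mouth helix — must come
back as the egress element.

`make_two_pore` adds a second, narrower pore at the opposite pole and
an equatorial wall of atom rings hugging the target sphere, sealing
the two half-cavities from each other while leaving each with
wide-doored cells on the iron's star. Ground truth: the first access
channel appears at ≈ aperture1 − 2r, a second cell-disjoint one at
≈ aperture2 − 2r, and at a CV between the wide pore's sliver doors and
the narrow pore's door each pore carries exactly one minimal cost
path, so iterative extraction yields two edge-disjoint MCPs clustering
into two trajectories. The default apertures (8.0 and 7.5 Å) are close
together precisely to keep that window open.

What the fixtures do *not* emulate: real packing density gradients,
side-chain texture, multiple nested cavities, long winding channels
whose MCPs share most of their cells, or crystallographic artefacts.
Passing the fixture tests shows the machinery (tessellation, door
widths, bottleneck logic, path extraction, clustering, annotation) is
correct on known geometry — not that any biological claim holds; for
that the package exposes regression anchors against published CYP3A4
measurements, which require the 1TQN/2V0M structures and carry the
tolerances discussed above.

## Problem sizes

The shipped verification study (test suite and
`scripts/acceptance.py`) runs on 100 random doors for the geometry
oracle, 50–60 random graphs of ≤ 12 nodes for the path/bottleneck
oracles, 120–150-point clouds for volume conservation, and the default
800-atom fixtures (≈ 4000–6500 cells) for end-to-end runs — sizes
chosen so the whole study completes in a couple of minutes on one CPU
while exercising every code path at full fidelity. A full CYP3A4 chain
(≈ 3800 heavy atoms, ≈ 25 000 cells) runs through the same pipeline in
well under ten minutes.

## Known limitations

* The door test is per-triangle; a long tilted cylinder could in
  principle be rejected or admitted differently by a sweeping test.
* Plain Delaunay ignores radius differences in the *topology* (a
  weighted/regular triangulation could shift cell boundaries); radii
  enter only through door widths.
* The surface-pocket rule and the clustering threshold are declared
  reconstructions of under-specified published procedure; both are
  config knobs.
* Pores (exterior↔exterior components avoiding the target) are
  detected as components but not further analysed.
* No conformational flexibility: one crystal structure, one answer.
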