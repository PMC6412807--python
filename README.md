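# channeltess

Geometric detection of ligand access channels in proteins with buried
active sites — cytochrome P450s being the archetype, where every
substrate must travel from the protein surface to the heminic site deep
inside the fold.

Instead of rolling a spherical probe, `channeltess` models the ligand by
its *critical thickness* CV (the diameter of the thinnest cylinder
enclosing its atom spheres) and asks a purely combinatorial question of
the protein's shape:

1. The convex hull of the heavy atoms (protein + cofactor; waters and
   co-crystallised ligands excluded) is partitioned into tetrahedral
   cells by Delaunay triangulation, with atoms at the vertices.
2. Each triangular face between two cells is a **door**. Its width
   CVmax is the diameter of the largest disc that fits in the closed
   triangle clear of the three vertex atoms' van der Waals spheres; a
   door is open for a ligand iff CVmax ≥ CV.
3. The **facial graph** has cells as nodes, open doors as edges, plus a
   single EXTERIOR node attached through every hull face. A connected
   component linking the EXTERIOR to the target cells (the star of the
   heme iron, by default) is an access **channel**; the largest CV at
   which one exists is the limiting thickness
   **CVlim = max over exterior→target paths of (min CVmax on the path)**,
   a bottleneck/widest-path quantity computed exactly.
4. Within the open graph at a given CV, **minimal cost paths** (MCPs)
   minimise Σ CV/CVmax over their doors (Dijkstra); further paths are
   extracted by deleting the previous path's edges and re-running, and
   the resulting edge-disjoint MCPs are clustered (single linkage,
   Jaccard overlap of cell sets) into **trajectories** — one trajectory
   per named channel in the P450 channel nomenclature.

Every region (channel, MCP, trajectory) gets a volume (sum of cell
volumes), a bounding surface (areas of its closed faces), lining atoms
and residues, egress secondary-structure annotation, and two PDB-format
visualizations (pseudo-atoms at cell barycenters bonded through open
doors, or boundary-face edges drawn as pseudo-bonds between real atoms).

## Worked example

The package ships a generator of synthetic "toy proteins": an atom
shell with a pore of known width and a buried FE/HEM target at the
centre. A pore of aperture 8 Å pierced in a shell of carbon-sized atoms
(r = 1.7 Å) should admit ligands up to 8 − 2·1.7 = 4.6 Å:

```sh
$ channeltess fixtures shell-pore --seed 1 -o shell.pdb
$ channeltess cvlim shell.pdb
structure       cvlim_A
shell   4.5809
```

CVlim recovers the analytic aperture to within the jitter of the atom
placement. Thinner ligands see one channel through the pore:

```sh
$ channeltess profile shell.pdb --grid 5:2:0.5
cv      n_channels      new_channels    volumes_A3
5.00    0       0       -
4.50    1       1       3976.2
4.00    1       0       3976.2
3.50    1       0       3977.6
3.00    1       0       3978.1
2.50    1       0       3978.1
```

The first access channel appears between CV 5.0 and 4.5 (i.e. at
CVlim ≈ 4.58) with a volume of ~3976 Å³ — the pore mouth plus the
hollow interior. At CV = 3 Å the pore admits several edge-disjoint
minimal cost paths:

```sh
$ channeltess mcps shell.pdb --cv 3.0
rank    total_cost      n_cells volume_A3       boundary_surface_A2
1       0.6549  1       62.7    0.0
2       1.6107  2       37.5    11.7
...
```

The cheapest path crosses a single cell (the tetrahedron under the
pore door, which already touches the iron) at cost CV/CVmax = 0.65, and
its bounding surface is 0: an MCP is bounded only where its doors are
closed. `channeltess analyze shell.pdb --cv 3 -o out/` writes the full
JSON report, TSV tables and both visualization PDBs;
`channeltess thickness <file> --ligand <resname>` computes a ligand's
CV under the cylindrical model, which `analyze --ligand` uses directly.

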