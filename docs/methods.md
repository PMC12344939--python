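# Methods

## Overview

`foldmap` turns 3D protein structures into standardized 2D diagrams.
The pipeline is deliberately lossy: it keeps the topology and relative
placement of secondary-structure elements and discards loop curvature,
side chains and depth cues, trading fine-grained detail for instant
visual comparability across a family. Four stages compose:

1. **Orientation** — a rigid frame placing the molecule in a canonical
   view (family alignment, a user matrix, or the inertia frame).
2. **Projection** — orthographic projection onto the canvas plane; the
   discarded view-axis coordinate is retained as per-element depth.
3. **Abstraction** — per-residue secondary structure coalesced into
   segments, one glyph per segment.
4. **Serialization** — deterministic SVG (or rasterized PNG for large
   overlays).

## Orientation

### Inertia frame

The default view is the principal-axis frame of the atomic coordinate
distribution: rows of the rotation are the covariance eigenvectors
sorted by descending eigenvalue, so the projected x axis carries the
largest variance, y the second, and the view axis z the least — the
same convention as the `orient` command of common molecular viewers.
Input to the covariance is **all non-hydrogen atoms** (configurable;
rendering itself only ever uses Cα). Eigenvector signs are inherently
arbitrary, so they are pinned deterministically: each of the first two
axes is flipped so the point projecting farthest along it lands on the
non-negative side; an exactly symmetric cloud falls back to making the
axis's dominant component positive; the third axis is the cross product
of the first two, forcing right-handedness. Degenerate clouds (single
point, collinear, coplanar) get the missing axes completed from the
coordinate axes by Gram–Schmidt, with a warning. Eigenvalue ties keep
solver order and then apply the same sign rule — arbitrary but
deterministic.

Every frame, from any source, is validated at construction:
orthonormality and det = +1 within 1e-6. A frame applies as
`p' = R (p + t)`; for the inertia frame `t = −centroid`, so the view is
centered.

### User matrices

Plain-text matrix files carry 3 rows (rotation) or 4 rows (rotation +
translation) of 3 whitespace-separated numbers; `#` starts a comment.
Any malformed, non-orthonormal or reflecting matrix is rejected with a
warning and the inertia frame is used instead — an invalid matrix never
aborts a projection.

### Family alignment

To draw all members of a family identically, a query is matched against
a family database: a directory of representative structures plus a TOML
manifest storing, per family, the representative file and its reference
frame (the representative's own inertia frame, 12 numbers). The hit's
superposition transform (query → representative coordinates) is
composed with that stored reference frame, so the query lands in the
family's canonical view, reproducible from the database alone.

Two search backends share one result type:

* **foldseek** — subprocess wrapper around the external structure
  search binary with a pinned tab-separated column set
  (`query, target, prob, alntmscore, u, t, qstart, tstart, cigar`);
  `u`/`t` map query onto target coordinates, and CIGAR `M` advances
  both sequences, `I` the query, `D` the target. Used when the binary
  is on PATH; its output dialect is unit-tested on golden tables so the
  parser does not need the binary.
* **builtin** — exact-backbone search: Cα pairs matched by residue
  index, Kabsch superposition, TM-score (normalized by query length,
  `d0` clamped at 0.5 Å for short chains) as the probability-like
  similarity. It is deterministic, fully offline, and appropriate for
  small custom databases of near-identical folds; it is *not* a
  remote-homology detector and makes no claim at low sequence/structure
  identity.

The similarity threshold defaults to 0.5; the best hit below it yields
no frame, a warning, and an inertia fallback. Both frame paths — tool
matrix and Kabsch on matched pairs — must agree within 1e-3 on
fixtures, which is asserted in the tests.

Kabsch superposition is the standard SVD construction with the
reflection corrected by flipping the smallest singular direction, so
the result is always a proper rotation; collinear point sets are
rejected as degenerate. Family representatives are chosen as the member
with the highest mean pairwise TM-score (self excluded), ties broken to
the lexicographically smallest identifier.

## Secondary structure

Assignments come from, in order of preference: categories embedded in
the source mmCIF (`struct_conf` → helix, `struct_sheet_range` → strand,
a residue claimed by both becomes helix with a warning), or a DSSP
output file (classic fixed-column and mmCIF dialects both accepted;
unlisted residues default to coil). The package never computes
secondary structure from geometry — DSSP is an external dependency by
design.

DSSP codes map H/G/I → helix, E → strand, everything else (including
isolated bridges B, turns T, bends S) → coil, because single-residue
bridges render as noise at this abstraction level. Maximal runs are
merged; helix runs shorter than 3 and strand runs shorter than 2
residues are demoted to coil (too short to draw meaningfully). The
resulting segments always partition the chain: lengths sum to the
residue count, no overlaps, no adjacent segments of equal type.

Disulfides are detected geometrically: every unordered CYS pair with
SG–SG distance ≤ 2.5 Å (covalent ~2.05 Å plus model noise); CYS without
an SG atom are skipped.

## Glyphs and scenes

Glyphs are anchored only at the projected Cα of a segment's first and
last residue; internal curvature is intentionally dropped.

* **Helix** — zigzag polyline with `k = max(2, round(n_res/2))`
  interior vertices alternating ±amplitude (default 4 canvas units)
  perpendicular to the start→end axis, evenly spaced. A fully
  foreshortened helix degenerates to a disc of radius = amplitude.
* **Strand** — filled isoceles triangle, base (default 6 units)
  centered at the segment start, apex at the end, so the arrow points
  toward the C-terminus.
* **Coil** — straight line; zero-length connectors are elided.

Consecutive glyphs are joined by connector lines, giving a
C0-continuous trace. Each element carries the mean projected depth of
its residues; drawing order is ascending depth (+z toward the viewer,
so back-to-front), ties broken by sequence order, with labels,
annotations and disulfide lines always on top. Annotations (points,
lines, residue-range areas) and styles come from TOML files; unknown
style keys warn and are ignored, invalid values (negative widths, bad
colors) are errors naming the key.

The canvas transform is isotropic — `s = min((W−2p)/extent_x,
(H−2p)/extent_y)` — content centered, default canvas 1000×1000 px with
40 px padding. Internally y points up; the single y-flip to SVG's
y-down convention happens at serialization. The SVG writer emits one
shape node per element with a CSS class per kind, at fixed numeric
precision, so identical inputs give byte-identical documents.

## Overlays

An overlay projects every member in one shared frame (family alignment
when a database is given — members failing the threshold are dropped
with a warning rather than mixed in with inertia frames, which would
corrupt the consensus reading — otherwise each member's own inertia
frame) and applies one global transform from the union bounding box, so
conserved elements overlap pixel-wise. Per-member opacity is
`min(0.8, max(0.05, 1/N))`: conserved regions accumulate darkness,
variable regions stay faint; the clamps keep N = 1 visible and large
families unsaturated. PNG export draws the same scenes at 2× canvas
resolution with per-member alpha compositing, for families where SVG
output would grow large.

Optional pre-clustering reduces redundancy before overlaying. The
built-in clusterer is greedy and longest-first (CD-HIT style): a
structure joins the first representative it matches on mutual length
coverage ≥ 0.9, global sequence identity ≥ 0.5 (edit-distance based),
and Cα TM-score ≥ 0.5, else it seeds a new cluster. It is deterministic
and adequate at toy scale; the external search tool's clustering mode
is used instead when the binary is available.

## Domain splits

A region string like `A:1-30,A:40-60` (ASCII hyphen or en-dash,
1-based inclusive author numbering) cuts a chain into sub-structures;
regions must not overlap and must select at least one residue each.
Each segment is oriented independently (family search with inertia
fallback), drawn, and laid out left-to-right in sequence order at a
common scale — so relative domain sizes survive — with a gap of 10% of
the summed segment widths, each segment labelled with its region and
matched family (or "inertia"). A single whole-chain region reproduces
the plain projection up to translation.

## Synthetic structures

The fixture generator builds Cα-only traces from textbook geometry:
α-helices with 1.5 Å rise, 100°/residue twist, 2.3 Å radius
(consecutive Cα–Cα ≈ 3.8 Å); strands as 3.4 Å/residue extended chains
with a ±0.5 Å alternating pleat; coils as self-avoiding 3.8 Å-step
random walks. Blocks are concatenated with seeded rigid placements,
rejecting any placement that brings non-consecutive Cα within 2 Å
(1000 tries, then an error). Ground-truth per-residue codes are emitted
alongside, and CYS pairs with SG atoms placed 2.04 Å apart can be
requested for disulfide tests. Everything is bit-reproducible given the
spec and seed.

These traces make the orientation and glyph arithmetic analytically
checkable; they are *not* realistic backbones — no Ramachandran
statistics, no side chains, no hydrogen-bond geometry, and polyalanine
sequences. Consequently, passing tests demonstrate the correctness of
the geometry, layering, formats and consensus encoding, not the
biological quality of alignments on real remote homologs, which depends
on the external search tool.

## Numerical choices

- Rotation validation tolerance 1e-6 (orthonormality and determinant).
- Kabsch degeneracy: second singular value < 1e-10 × the largest is
  rejected as collinear.
- Zero-length glyph threshold 1e-9 canvas units.
- SVG coordinates serialized at 3 decimals (sub-pixel at default canvas
  size) for byte-stable output; "-0.000" is normalized to "0.000".
- TM-score `d0 = max(0.5, 1.24·(L−15)^{1/3} − 1.8)` with L the query
  length.
- Altloc resolution: highest occupancy, ties to altloc 'A'; model 1
  only; waters and Cα-less hetero groups excluded, MSE and similar
  in-chain hetero residues kept.

## Problem sizes in the checks

The test suite and the acceptance script run entirely on generated
inputs: property sweeps use 50–100 seeded repetitions, structures range
from 5 to 100 residues, databases hold 1–2 toy families, overlays stack
up to 5 members, and the clustering demonstration uses 5 structures in
2 folds. The screening-table tally runs on a 20,420-row synthetic
record table. Checks against the published kallikrein family set (437
predicted structures) require that separately downloaded dataset under
`data/KLK/` and report its clustering and length statistics only when
it is present.

## Known limitations

- The builtin search backend matches residues by index; it cannot align
  structures with shifted numbering or indels (use the external tool
  there).
- Strand connectivity within sheets is not encoded; repeated strand
  positions only become visible through consistent placement.
- No NMR multi-model handling, no per-residue color gradients, no
  interactive output.
- PNG text labels use the raster library's default font and are not
  size-matched to the SVG output.
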