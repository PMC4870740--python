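# Methods

## Model

A halogen bond is the attractive contact C–X···A between a carbon-bonded
halogen X ∈ {Cl, Br, I} and an electron donor A ∈ {O, N, S}. The positive
σ-hole sits on the distal end of the C–X axis, so the interaction strength
decays both with the X···A distance and with the deviation of the C–X···A
angle Θ from linearity. `xbsf` scores each candidate pair with

E = W · Φ(Θ) · D(r, Θ),

an empirical product of a per-halogen weight, an angle factor and a
distance factor, and sums the terms over all (halogen site, acceptor) pairs
of a complex. The model assumes rigid heavy-atom geometry (hydrogens are
parsed but ignored), treats every O/N/S acceptor equally, and does not
model π-system acceptors or cooperative effects between interactions.

### Angle factor

The halogen's effective surface charge at the contact point is modelled as
Z(Θ) = A·cos(να) + B with α = 180° − Θ. Φ normalises this by its value at
the ideal linear geometry and clamps at the electroneutral angle Θ₀ where
the surface charge changes sign:

Φ = Z(Θ)/Z(180°) for Θ₀ ≤ Θ ≤ 180°, else 0.

Θ₀ is 146° (Cl), 126° (Br), 122° (I): the heavier, more polarisable
halogen keeps a positive cap over a wider angular range. The shipped
charge model uses ν = 1, A = 1 and derives B = −cos(α₀) so that Z(Θ₀) = 0
exactly, which makes Φ a closed-form cosine ramp that is 0 at Θ₀, 1 at
180°, continuous and monotone in between. Users holding independently
fitted per-halogen (A, B, ν) coefficients can override them in the YAML
config; note that if B is set such that Z(Θ₀) ≠ 0, Φ acquires a step at
Θ₀ (the implementation clips Φ to [0, 1] regardless).

### Distance factor and polar flattening

With van der Waals radii r_Cl = 1.8, r_Br = 2.02, r_I = 2.2, r_O = 1.7,
r_N = 1.8 Å, the signed overlap is d = r(X···A) − (r_X + r_A). D ramps
linearly from 0 at d = 0 to 1 at d = −δ. Because the halogen is flattened
along the σ-hole axis, the saturation depth δ grows as Θ approaches 180°;
it is tabulated per halogen over 15° bins:

| halogen | 165°–180° | 150°–165° | 135°–150° |
|---------|-----------|-----------|-----------|
| Cl      | 0.25 Å    | 0.15 Å    | —         |
| Br      | 0.45 Å    | 0.35 Å    | 0.25 Å    |
| I       | 0.55 Å    | 0.45 Å    | 0.35 Å    |

Numerical choices:

* Bins are half-open, [165°, 180°] closed at the top, so every angle maps
  to exactly one row. D therefore steps by one table increment when Θ
  crosses a bin edge at fixed distance; the table is applied literally,
  with no smoothing across edges.
* Between Θ₀ and the lowest tabulated row (e.g. iodine on [122°, 135°))
  the table has no entry. The default extends the lowest δ downward
  (`below_table: extend`), since Φ is already near zero there and zeroing
  D would contradict the nonzero angle factor; `below_table: zero` is
  available for users who prefer a hard cutoff.
* A sulfur acceptor radius is not part of the original table; the package
  defaults to the conventional 2.0 Å, configurable.
* Overlaps smaller than 1e-9 Å are treated as the d = 0 boundary so that
  contacts at exactly the radii sum score 0 despite float representation.
* Φ and D are kept at full precision internally; display rounds to three
  decimals. At the reference iodine geometry (3.354 Å, 177.8°) the
  full-precision values are Φ = 0.99843 and D = 0.99273, so Φ·D = 0.99117;
  sources that round the factors to three digits before multiplying quote
  0.998 × 0.992 = 0.99014 for the same contact — the differences are below
  2 × 10⁻³ and purely presentational.

### Interaction enumeration

Halogen sites are inferred geometrically (prepared PDBQT files carry no
connectivity): a Cl/Br/I atom is a donor if a carbon lies within 2.1, 2.2
or 2.4 Å respectively (typical C–X bond lengths 1.79/1.94/2.13 Å plus
slack); the nearest such carbon is the bonded partner, ties broken by
lowest serial. Fluorine and free halide ions are never donors. Acceptors
are all O/N/S atoms of the receptor; water oxygens are excluded by default
(receptor preparation normally strips them) and HETATM cofactor atoms are
included by default, both switchable. Alternate locations other than blank
or 'A' are dropped for deterministic geometry. No cutoff radius is needed
for scoring: D is identically zero once the radii no longer overlap, and
only nonzero-energy pairs are reported.

## Supporting computations

* **Mining.** `mine_contacts` enumerates C–X···A geometries across
  (protein, ligand) pairs — or single mixed structures partitioned into
  ATOM receptor and HETATM ligand atoms — within a window of 4.5 Å and
  ≥ 120° by default, wide enough to cover the whole region where the δ
  trend is visible; entries with a known resolution worse than an optional
  cutoff are skipped. `bin_contacts` tallies one element pair into the
  three 15° angle bins against half-open distance bins (default width
  0.1 Å; the exact width used in the original survey is not recorded, and
  the histogram is exact for any width). Shifting distance peaks across
  angle bins are the crystallographic signature of polar flattening.
* **Grid box.** size per axis = coordinate extent + 15 Å total padding;
  center = extent midpoint, optionally shifted per axis by an independent
  draw from {−2.5, 0, +2.5} Å under a user seed (the original protocol
  does not state whether shifts could be negative; the symmetric choice is
  the default and the magnitude is configurable). The same seed always
  yields the identical box.
* **Pose RMSD.** Docking convention: heavy atoms, in place (no
  superposition), no symmetry correction, atoms matched by name order with
  a hard error on any mismatch. An optional minimum-cost assignment within
  each element (`match="element"`) serves renumbered poses; it is a lower
  bound on the name-matched value.

## Synthetic fixtures

`fixtures.make_complex` builds a minimal complex realising any requested
(halogen, acceptor, distance, Θ) exactly: the halogen at the origin, its
carbon along −x at the typical C–X bond length, the acceptor placed
analytically, and optional decoy carbons ≥ 6 Å from the contact triple so
they cannot change any score. `make_pose_set` adds rigid perturbations
(translation of magnitude ~uniform[0.75, 1.25]·p plus ≤ 0.1 rad rotation
about the centroid) for pose-rescoring tests. Generated geometry is exact
to machine precision in memory and to ~1e-3 Å / ~0.02° after PDB
coordinate rounding (three decimals).

These fixtures emulate only the geometry of a halogen-bonded complex: two
to a dozen atoms, no chemistry, no crystallographic noise, no alternate
conformers, no symmetry-related contacts. Tests passing on them establish
that detection, measurement and scoring are correct functions of geometry;
they say nothing about performance on real crystal structures, ligand
strain, or the interplay with the other terms of a docking score.

## Problem sizes and determinism

The test suite and the acceptance script run on synthetic complexes of a
few dozen atoms: property sweeps use 10⁵-point parameter grids, 50 random
fixtures for the pair-sum oracle, 200 synthetic contacts for histogram
checks, and ~100 poses for displacement statistics. All randomness flows
through explicit `numpy.random.default_rng` seeds; hypothesis-based
property tests are derandomised.

## Known limitations

* The scoring term is reported standalone; combining it with (or replacing
  a repulsion term inside) a full docking score is left to the caller.
* The δ-table step discontinuity at bin edges is intentional but means the
  energy is not smooth in Θ — unsuitable as-is for gradient-based
  optimisation.
* Halogen-site inference is purely distance-based and may mispair atoms in
  pathological geometries (e.g. a carbon closer to the halogen than its
  true bonded partner).
* PDBQT parsing covers the Vina multi-MODEL output dialect (ROOT/BRANCH
  and TORSDOF records are ignored); exotic AutoDock atom types fall back
  to name-based element resolution.
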