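# xbsf — halogen-bond rescoring for protein–ligand complexes

Most docking scoring functions treat a halogen as an isotropically charged
sphere, so a close C–X···A contact (X = Cl, Br, I; A = O, N, S) is penalised
as steric repulsion even when it is actually a favourable halogen bond made
through the halogen's σ-hole — the patch of positive electrostatic potential
on the distal end of the C–X bond. `xbsf` is a standalone library and CLI
for chemists and modellers who want to detect these interactions in
protein–ligand structures (PDB, or the PDBQT pose files written by docking
engines) and score them with an empirical, geometry-based energy term —
e.g. to rescore and re-rank docked pose sets.

## The scoring function

Each carbon-bonded halogen X paired with an acceptor A is scored as

```
E = W · Φ(Θ) · D(r, Θ)
```

* **W** — per-halogen energy-well weight: W(Cl) = −0.265, W(Br) = −0.32,
  W(I) = −0.4. Acceptors are equally weighted.
* **Φ(Θ)** — angle factor. With α = 180° − Θ the effective σ-hole charge is
  Z(Θ) = A·cos(να) + B; Φ = Z(Θ)/Z(180°) for Θ₀ ≤ Θ ≤ 180° and 0 otherwise,
  where Θ₀ is the electroneutral angle at which the halogen surface charge
  changes sign (146°/126°/122° for Cl/Br/I). The default charge model fixes
  B so that Z(Θ₀) = 0, giving the closed form
  Φ(Θ) = (cos α − cos α₀)/(1 − cos α₀).
* **D(r, Θ)** — distance factor. With signed van der Waals overlap
  d = r(X···A) − (r_X + r_A), D = 1 for d ≤ −δ, D = 0 for d ≥ 0, linear in
  between. The overlap depth δ depends on both the halogen and the angle
  (polar flattening: the halogen is "squashed" along the σ-hole axis), read
  from a table binned in 15° ranges — e.g. δ(I) = 0.55/0.45/0.35 Å for
  Θ in 165°–180°/150°–165°/135°–150°.

Both factors lie in [0, 1], so every interaction contributes between W and
0, and a ligand without Cl/Br/I scores exactly zero.

The package also ships the surrounding workflow pieces: a miner that
surveys C–X···A contact geometries and histograms them in the same 15°
angle bins (the analysis that motivates the δ table), a grid-box builder
(extent + 15 Å total padding per axis, optional seeded ±2.5 Å center
shift), in-place heavy-atom pose RMSD, and a synthetic-complex generator
that places a C–X fragment and an acceptor at any exact distance/angle.

## Worked example

The classic test case is a kinase inhibitor whose aryl iodine contacts a
backbone carbonyl oxygen at 3.354 Å with a C–I···O angle of 177.8°:

```python
from xbsf import GeometrySpec, make_complex, score_complex

protein, ligand = make_complex(GeometrySpec(
    halogen="I", acceptor="O", distance_XA=3.354, theta=177.8))
result = score_complex(protein, ligand)
s = result.interactions[0]
print(f"Phi={s.phi:.3f} D={s.dfac:.3f} pre-weight={s.pre_weight:.5f} "
      f"E={s.energy:.4f}")
```

prints

```
Phi=0.998 D=0.993 pre-weight=0.99117 E=-0.3965
```

Φ ≈ 0.998 because the contact is nearly collinear with the C–I bond, right
on top of the σ-hole; the 0.546 Å radii overlap is just short of the
δ = 0.55 Å saturation depth for iodine in the 165°–180° bin, so D ≈ 0.993;
and the iodine weight −0.4 scales the product into the final energy. The
same numbers are available from the shell:

```
xbsf fixture --halogen I --acceptor O --distance 3.354 --theta 177.8 --out-dir fx/
xbsf score --receptor fx/protein.pdb --ligand fx/ligand.pdbqt
```

Other subcommands: `xbsf rescore` (pose-set CSV with XB energies and RMSD
to a native pose), `xbsf gridbox` (Vina-style config.txt), `xbsf mine`
(contact CSV + angle/distance histogram), `xbsf rmsd`.

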