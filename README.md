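# coilflex

Bending flexibility of two-chain coiled-coil proteins — tropomyosin being
the motivating case — estimated from conformational ensembles such as MD
trajectory snapshots.

Semi-rigid coiled coils like tropomyosin work as mechanical elements: the
stiffness of the strand along the actin filament controls how
cooperatively regulatory signals propagate. `coilflex` measures that
stiffness from an ensemble of conformations and locates where along the
molecule the flexibility concentrates, alongside the backbone
hydrogen-bond occupancy and inter-helix distances that rationalise it.

## Method

The coiled-coil axis is approximated per snapshot *j* by a polygonal line:
Cα atoms of consecutive, endpoint-sharing 11-residue segments (terminal
residues weighted 0.5, so each segment covers ~3 helical turns) are
averaged into per-chain centroids, and the midpoints between the two
chains' centroids are the polygon vertices. Unit vectors **t**<sub>ij</sub>
between consecutive vertices are the local tangents.

For a worm-like chain, tangents decorrelate exponentially with contour
distance *s*. For an *intrinsically curved* filament the straight-rod
correlation ⟨(**t**(s), **t**(0))⟩ conflates built-in shape with thermal
flexibility, so each tangent is instead correlated with its own
time-average direction:

> c(s) = ⟨(**t**(s), ⟨**t**(s)⟩)⟩ = exp(−s / L<sub>p</sub>),
> ⟨**t**(s)⟩ = Σ<sub>j</sub> **t**<sub>ij</sub> / |Σ<sub>j</sub> **t**<sub>ij</sub>|

ln c(s) is fitted against *s* either by ordinary least squares over all
positions or by the secant through the first and last points; the
persistence length is L<sub>p</sub> = −1/slope, and the bending stiffness
k = L<sub>p</sub> k<sub>B</sub> T. Uncertainties come from block
averaging (contiguous trajectory blocks), since consecutive snapshots are
autocorrelated. The local slope of ln c(s) maps flexibility back to
residue intervals; its steepest point marks the most flexible region.

Backbone N–H···O=C hydrogen bonds are detected geometrically
(donor–acceptor ≤ 0.35 nm, H–N···O ≤ 30° when hydrogens are present) and
aggregated over user-defined residue regions, both chains summed.

A discrete Kratky–Porod generator (exact inverse-CDF sampling of the
joint-angle density, no small-angle approximation) produces worm-like
chains of known persistence length — optionally with intrinsic curvature
or a softened joint — and a pseudo-atomic builder wraps a two-chain
coiled-coil backbone around each sampled centerline so that every stage of
the pipeline can be validated against ground truth.

## Worked example

```sh
python examples/persistence_recovery.py
```

```
ln c(s) profile (s in nm):
  s =   0.0   c = 1.0000
  s =   1.5   c = 0.9849
  ...
  s =  13.5   c = 0.8733
least-squares Lp = 100.0 ± 0.2 nm (true 100.0 nm)
secant        Lp = 99.7 nm
bending stiffness k = Lp kB T = 4.144e-19 J nm
```

The correlation decays by a factor e over L<sub>p</sub> = 100 nm of
contour length; both estimators recover the stiffness the generator was
given, and the stiffness conversion uses the simulation temperature
(300 K here).

Comparing two simulated conditions end to end
(`python examples/condition_comparison.py`):

```
reference : Lp = 98.7 ± 1.1 (100.6) nm; most flexible region residues 181-211
stiff     : Lp = 140.6 ± 1.2 (143.4) nm; most flexible region residues 121-151

condition   T_K  Lp_lsq_nm  Lp_secant_nm   Lp_ratio
reference 300.0  98.685889    100.575917 1.00(1.00)
    stiff 300.0 140.641449    143.375205 1.43(1.43)
t-test stiff vs reference: p = 1.3e-08
```

The ratio column reports the least-squares ratio with the secant ratio in
brackets; the p-value is a two-tailed Student's t-test on block-wise
L<sub>p</sub> estimates. The other examples cover the curved-rod
estimator (`curved_rod_estimators.py`) and regional hydrogen-bond
occupancy (`hbond_occupancy.py`).

A thin CLI mirrors the library: `coilflex simulate` writes synthetic
ensembles (multi-model PDB or a TSV coordinate table), `coilflex analyze`
runs the single-condition pipeline, and `coilflex compare` builds the
cross-condition table from its JSON artifacts.

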