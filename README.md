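# paveshape

Outline morphometrics of leaf epidermal pavement cells, for comparative
(multi-species) surveys: traditional shape descriptors, elliptic Fourier
analysis, species/leaf-side aggregation, leaf–cell shape correlations, and
phylogenetic-signal testing — plus a synthetic-data generator that emulates a
full survey so the entire pipeline is testable without microscopy data.

## Who this is for

Plant biologists quantifying pavement-cell shape from segmented micrographs
(binary masks or traced outline CSVs) across many species, and anyone needing
reference implementations of convex-hull solidity, principal-axis aspect
ratio, Kuhl–Giardina elliptic Fourier descriptors, or local Moran's I
phylogenetic hotspot tests on tip traits.

## The quantities at the core

For a closed cell outline with area $A$, perimeter $P$, convex-hull area
$A_h$, and principal-axis extents $L \ge W$:

- **solidity** $S = A / A_h \in (0,1]$ — margin undulation (1 = convex);
- **aspect ratio** $AR = W / L \in (0,1]$ — base-shape anisotropy;
- **circularity** $C = P^2 / (4\pi A) \ge 1$ — mixes both;
- **EFA**: harmonic coefficients $(a_n, b_n, c_n, d_n)$ of the boundary
  traversal, normalized to the first-harmonic ellipse (20 harmonics default).

Phylogenetic signal of a species-mean trait $x$ on a tree uses local Moran's
I with inverse-patristic, row-normalized weights $w_{ij}$:

$$I_i = \frac{z_i}{m_2} \sum_j w_{ij} z_j, \qquad z_i = x_i - \bar x,\quad
m_2 = \tfrac1n \sum z_i^2,$$

with conditional-permutation p-values (tip $i$ held fixed, others shuffled)
and a one-sided hotspot call at $p < 0.05,\ I_i > 0$.

## Worked example

```python
import paveshape as ps
from paveshape import stats, physig

# a lobed cell: 2:1 ellipse with eight lobes of 20% amplitude
cell = ps.make_lobed_cell(ps.LobedCellParams(a=40, b=20, k=8, amp=0.2))
m = ps.measure(cell)
print(f"S={m.solidity:.3f}  AR={m.aspect_ratio:.3f}  C={m.circularity:.3f}")
# S=0.777  AR=0.500  C=2.538

# a full synthetic survey: 3 clades x 30 species x 2 sides x 30 cells
ds = ps.make_dataset(seed=1)
cells = ps.measure_cells(ds.cells)
summ = stats.summarize_species(cells, ds.leaves, ds.meta)
sd = stats.side_difference(summ)
print(f"abaxial more undulate in {sd.n_positive}/{sd.n_both_sides} species")
# abaxial more undulate in 90/90 species

r = stats.leaf_cell_correlation(summ, ["fern", "monocot"])
print(f"leaf AR ~ cell AR: rho={r.rho:.2f}, p={r.p_value:.2g}, n={r.n}")
# leaf AR ~ cell AR: rho=0.84, p=5e-17, n=60

tree = ps.make_clade_tree(ds.meta, seed=2)
res = physig.local_moran(dict(zip(summ.species, summ.mean_solidity)),
                         physig.proximity_matrix(tree), seed=3)
print(f"global I={res.global_I:.2f} (E={res.expected_I:.3f}), "
      f"hotspots={int(res.hotspot.sum())}/90")
# global I=0.33 (E=-0.011), hotspots=57/90
```

The solidity of 0.78 says the margins are moderately undulate; AR 0.50
recovers the 2:1 base ellipse. In the survey, the generator's +0.06 abaxial
lobe-amplitude offset is detected in every species; leaf and cell anisotropy
correlate strongly in the clades where the generator couples them; and the
clade-structured solidity trait produces widespread positive local Moran's I
hotspots on the clade-mapped phylogeny.

## Command-line pipeline

```sh
paveshape simulate  --outdir run --seed 1       # synthetic survey + tree
paveshape extract   --outdir run --masks-dir masks/   # or: trace real masks
paveshape measure   --outdir run                # descriptors per cell
paveshape efa       --outdir run                # normalized EFA coefficients
paveshape summarize --outdir run --seed 1       # species/side aggregation
paveshape pca       --outdir run                # descriptor-space PCA
paveshape correlate --outdir run                # side differences, leaf~cell
paveshape physignal --outdir run --seed 1       # local Moran's I hotspots
```

Every stage reads/writes tidy CSV (plus Newick for trees), accepts a flat
TOML config (`--config run.toml`, any key overridable by flag), and writes a
JSON manifest with the config echo and output content hashes; reruns with
the same seed are byte-identical.

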