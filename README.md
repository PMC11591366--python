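# chondrometry

Articular-cartilage thickness mapping from paired 3D surface scans of the
same bone — once with cartilage, once after cartilage removal — registered
through spherical fiducial markers.

## The measurement problem

Cartilage thickness on the distal femur can be measured with high accuracy
from surface scans: scan the articular surface, remove the cartilage, scan
the exposed bone, and take the point-wise distance between the two models.
Two error sources dominate:

* **Random error.** Each scan has a precision σ (RMS surface deviation
  between repeated scans). Thickness is the difference of two independent
  scans, so its precision is

  σ_t = √(σ² + σ²) = √2 · σ

  e.g. σ = 0.087 mm gives σ_t ≈ 0.123 mm — about 6% of a typical 2 mm
  cartilage layer.

* **Systematic error (bias).** If the removal process alters the bone
  surface, every thickness value shifts. Bias is assessed by comparing bone
  models before and after removal via point-to-surface RMSD and average
  deviation (AD), judged against the repeatability floor obtained from
  repeated models of the same scan (n models → n(n−1)/2 pairwise
  comparisons).

To compare the two scans point-wise without shape-matching (which would
itself bias the distances), rigid spherical fiducial markers are attached to
the bone. Each marker's scanned surface is reduced to a least-squares sphere
center; corresponding centers across scans give the rigid transform
(Kabsch/SVD), which carries the cartilage-bearing model into the bone-only
frame. Thickness at each cartilage-surface point is then its closest-point
(minimum Euclidean) distance to the bone surface.

Measurements are reported over anatomically standardized subregions: the
bone is expressed in a frame built from the posterior femoral condyles
(medial–lateral axis through their fitted sphere centers) and the medial
tibial plateau plane; on each condyle a distal weight-bearing subregion
(0° flexion) and a posterior subregion (90° flexion) are constructed from
the 60% / central-⅓ / 15%-of-width rules on the cartilage extent landmarks.

Because real paired specimen scans cannot be shipped, the package includes a
phantom generator: a bicondylar surface with a known thickness field, offset
cartilage surface, fiducial markers, anatomical patches, and seeded sensor
noise — so every stage of the pipeline is testable against ground truth.

## Worked example

```python
import chondrometry as cm

# a synthetic specimen: uniform 2.0 mm cartilage over a bicondylar surface
ph = cm.add_markers(cm.make_bicondylar_phantom(thickness_base=2.0))
pair = cm.simulate_two_scans(ph, sigma=0.087, seed=1)

# register the bone-only scan back into the cartilage scan's frame
set_with = cm.fit_marker_set(pair.markers_with, "with")
set_without = cm.fit_marker_set(pair.markers_without, "without")
reg = cm.register_marker_sets(set_without, set_with)
bone = pair.without_mesh.transformed(reg.transform)
print(f"FRE = {reg.fre_rms:.4f} mm")

# subregions and thickness
ext, regions = cm.extract_all_subregions(pair.with_mesh, ph.patches["trochlea"])
for (condyle, flexion), sr in regions.items():
    tmap = cm.compute_thickness_map(pair.with_mesh, bone, sr)
    mean, sd = cm.subregion_stats(tmap)
    print(f"{condyle:>7s} {flexion:>2d} deg: {mean:.1f} ({sd:.1f}) mm over {tmap.n_valid} points")
```

Output:

```
FRE = 0.0157 mm
 medial  0 deg: 2.0 (0.1) mm over 117 points
 medial 90 deg: 2.0 (0.1) mm over 117 points
lateral  0 deg: 2.0 (0.1) mm over 117 points
lateral 90 deg: 2.0 (0.1) mm over 117 points
```

The FRE (fiducial registration error) is the RMS residual between
corresponding marker centers after alignment — a few microns here, because
each center is averaged over 400 marker-surface points. Each subregion mean
recovers the 2.0 mm truth; the 0.1 mm SD reflects the √2 · σ per-point noise
of the simulated scans.

The same workflow is available from the shell:

```bash
chondrometry phantom --kind bicondylar --seed 42 --out ph/ --sigma 0.087
chondrometry fit-markers --in ph/markers_with --out with.csv
chondrometry fit-markers --in ph/markers_without --out without.csv
chondrometry register --source without.csv --target with.csv --out reg.json
chondrometry summarize --in study.csv --out summary.json
```

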