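# vtsubstrate

Structural substrate analysis for scar-related ventricular tachycardia (VT)
from late-gadolinium-enhancement (LGE) style cardiac imaging, validated on
synthetic left-ventricular phantoms with analytic ground truth.

After a myocardial infarction, the reentrant circuits of VT run through
surviving myocardium inside and around the scar. This package implements
the image-analysis chain used to characterize that tissue and to relate it
to electroanatomic mapping (EAM) recordings:

1. **Tissue classification** — within a given myocardial segmentation,
   voxels ≥ 60% of the maximum signal intensity are dense scar and voxels
   in 40–60% are heterogeneous tissue (HT, the border zone); the rest is
   normal myocardium.
2. **Wall thickness and transmurality** — the Laplace equation ∇²u = 0 is
   solved across the wall with Dirichlet conditions u = 0 on the
   endocardium and u = 1 on the epicardium; wall thickness at an
   endocardial node is the arc length of the streamline of ∇u traced to
   the epicardium, and scar/HT transmurality is the proportion of samples
   along that path in each tissue class. Combined scar/HT transmurality
   below 95% is "non-transmural".
3. **Surface metrics** — the endocardial thickness field is interpolated
   with a thin-plate-spline radial basis function; its tangential gradient
   magnitude identifies steep-gradient regions, and per-vertex Euclidean
   distances to HT and to the steep set are computed.
4. **Co-registration** — EAM point clouds recorded in a displaced frame
   are aligned by landmark (apex + ostial fiducials) Kabsch fitting
   followed by trimmed point-to-surface ICP, then mapped to mesh nodes
   within a 1 mm radius.
5. **Conduction block** — adjacent activation points separated by
   > 15 ms mark block-crossing pairs; block lines are the polylines through
   the crossing-edge midpoints, with total length and region count.
   Diastolic activation times are classified into early/mid/late tertiles
   of the diastolic window (from QRS end).
6. **Statistics** — Shapiro–Wilk, Mann–Whitney U (exact by enumeration
   for small samples), Kruskal–Wallis with Dunn–Bonferroni follow-up,
   paired t with 95% CI, Pearson correlation; medians with IQRs
   throughout.

Because no real imaging/EAM dataset ships with the package, a first-class
phantom generator (`vtsubstrate.phantom`) produces label/intensity volumes
(slab, spherical shell, truncated ellipsoid; 1.2 mm isotropic), scar
patches of controlled transmural fraction with an HT rim and wall
thinning, EAM exports in a known displaced frame, and activation maps with
constructed lines of block — every downstream quantity has an analytic
ground-truth counterpart.

## Worked example

```python
from vtsubstrate import PipelineConfig, run_pipeline

result = run_pipeline(PipelineConfig(seed=1))
for key in ("median_thickness_diastolic_mm", "median_thickness_normal_mm",
            "median_dist_ht_diastolic_mm", "median_dist_ht_normal_mm",
            "non_transmural_fraction_pct"):
    print(key, round(result.summary[key], 2))
```

prints

```
median_thickness_diastolic_mm 8.4
median_thickness_normal_mm 8.68
median_dist_ht_diastolic_mm 1.7
median_dist_ht_normal_mm 24.26
non_transmural_fraction_pct 73.91
```

i.e. on the default phantom — an 8.4 mm shell wall thinning to 5 mm inside
a 30° infarct patch, with diastolic points seeded around the scar border
and normal points in remote wall — sites with diastolic activation lie in
thinner wall, an order of magnitude closer to heterogeneous tissue than
normally-activated sites, and mostly within non-transmural scar/HT. The
accompanying Mann–Whitney tests are in `result.tests`.

The numbered scripts under `analysis/` run the same chain step by step
(phantom → segmentation → thickness → surface metrics → registration →
conduction block → group statistics), each printing what it found and
writing its tables under `results/`. A thin CLI (`vtsub phantom | segment |
thickness | register | stats-report | run`) wraps the same functions.

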