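# sccmorph

Three-dimensional morphometry of the semicircular canals (SCC) of the inner
ear, and bilateral group statistics for case–control studies of canal
asymmetry — for example in adolescent idiopathic scoliosis (AIS), where a
more horizontally oriented left lateral canal has been linked to the
condition.

The package covers the whole chain from a T2-weighted-like volume of the
labyrinth to a statistical report:

1. **Phantoms** (`sccmorph.phantom`) — synthetic labyrinths (three planar
   circular canal arcs meeting a spherical vestibule and a common-crus
   junction) voxelized with analytic partial volume, plus a two-group
   bilateral cohort simulator with a controllable group-by-side effect.
   Every downstream stage is validated against these known-truth objects.
2. **Preprocessing** (`sccmorph.preprocess`) — B-spline resampling to an
   isotropic working grid (default 0.28 mm), rigid AC–PC reorientation
   (midline = plane x = 0, axial plane = z = const), optional
   gradient-diffusion edge-preserving smoothing.
3. **Segmentation** (`sccmorph.segment`) — per-side ROI crop, two-pass
   GrowCut (a competitive region-growing cellular automaton; the first
   segmentation re-seeds the second), and surface extraction at the
   half-intensity iso-level.
4. **Morphometry** (`sccmorph.morphometry`) — cross-sectional divisions
   every 0.25 mm perpendicular to a refined centroid spline, canal
   separation at the vestibule/common-crus junctions, and the nine canal
   shape parameters per side:
   three inter-canal plane angles `theta = arccos(n1 . n2)`, the signed
   lateral-canal inclination versus the axial plane, midline distances of
   the lateral and posterior canals, and each canal's minimum
   cross-sectional area. Canal planes minimize the weighted total least
   squares objective `f = sum_i |w_i n . (x_i - c)|^2` over the canal's
   volumetric point cloud with `w_i = 1 / A_i^2` (inverse squared area of
   the nearest division), approximating the functional maximal-response
   plane.
5. **Statistics** (`sccmorph.stats`) — per parameter, a linear mixed model
   `value ~ group + side + group:side` with a common unstructured 2x2
   right/left covariance (REML; for complete data this equals the pooled
   two-sample t-test on per-subject R−L differences), and the
   **Benjamini–Liu step-down FDR** across the nine interaction p-values,
   plus group-by-side, curve-type and Cobb-angle summary tables.
6. **CLI** (`sccmorph` command) — `phantom`, `preprocess`, `segment`,
   `measure`, `stats` and `run` (a YAML-configured end-to-end pipeline).

## Worked example

Simulate a bilateral two-group cohort (20 AIS vs 19 controls) whose only
systematic asymmetry is a 4.1° group-by-side interaction on the lateral
canal inclination, then run the full statistical analysis:

```python
from sccmorph.phantom import CohortSimSpec, generate_measurement_table
from sccmorph import stats as st

spec = CohortSimSpec(n_per_group=(20, 19), interaction_delta=4.1, seed=7)
table = generate_measurement_table(spec)

results, fdr = st.run_all_parameters(table)
r = results["lateral_inclination"]
print(f"interaction estimate: {r.interaction:.1f} deg "
      f"(95% CI {r.interaction_ci[0]:.1f} to {r.interaction_ci[1]:.1f}), "
      f"p = {r.p_value:.4f}")
print(fdr.to_frame().round(4).to_string(index=False))
```

Output:

```
interaction estimate: 2.9 deg (95% CI 1.2 to 4.7), p = 0.0018
                 parameter  p_value  fdr_adjusted_p  significant
    angle_lateral_superior   0.9211          0.5942        False
  angle_superior_posterior   0.3092          0.5942        False
   angle_lateral_posterior   0.1501          0.5287        False
       lateral_inclination   0.0018          0.0162         True
  midline_distance_lateral   0.0576          0.3361        False
midline_distance_posterior   0.7536          0.5942        False
           min_csa_lateral   0.6861          0.5942        False
          min_csa_superior   0.5065          0.5942        False
         min_csa_posterior   0.9512          0.5942        False
```

The interaction estimate is the AIS minus control difference of the mean
right-minus-left inclination; at this sample size a 4.1° effect is
estimated with a CI half-width of about 1.7°, and only the lateral
inclination survives the step-down FDR at q = 0.05.

The same analysis runs end-to-end from synthetic images — each subject's
labyrinths generated as an intensity volume, GrowCut-segmented and
measured — via `sccmorph.pipeline.simulate_phantom_cohort`, or from the
command line:

```bash
sccmorph run study.yaml     # see sccmorph.config.PipelineConfig
sccmorph phantom -o out --spacing 0.28 --tilt 4.1
sccmorph stats cohort.csv -o report --curves-csv curves.csv
```

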