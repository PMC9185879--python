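# rootmorph

Quantitative 3D morphometry and diagnostics for single-rooted teeth.
Given a closed triangle mesh of a tooth with six anatomical landmarks, the
package measures root length (RL), root surface area (RSA), root volume (RV)
and the normalised indices RSA/RL and RV/RL; given a 2D periapical-style root
silhouette it computes the root-width parameter PRW; and a statistics layer
provides ROC/AUC analysis, Youden-optimal cut-offs, 2×2 accuracy metrics,
test–retest ICC and two-group sample-size calculation for discriminating
conical from normal roots. A shape-atlas layer registers teeth rigidly
(landmark Procrustes, optional ICP refinement), builds per-group mean models
and renders signed surface-distance colour maps (blue–green–red, clamped at
±1.145 mm).

Because clinical CBCT segmentations cannot be redistributed, the
`rootmorph.synthetic` module generates parametric tooth meshes (surfaces of
revolution with elliptical cross-sections; convex "normal" vs straight
"conical" taper), 2D silhouettes and scalar cohorts with configurable group
means/SDs — each with analytic or quadrature ground truth so every pipeline
stage is testable offline.

## Layout

| module | contents |
| --- | --- |
| `rootmorph.meshes` | mesh container, STL/PLY I/O, area/volume, closest-point queries |
| `rootmorph.morphometry` | CEJ-plane fit, plane splitting with caps, RL/RSA/RV pipeline |
| `rootmorph.radiograph` | PRW construction from a 2D outline |
| `rootmorph.synthetic` | tooth/cohort/silhouette generators with ground truth |
| `rootmorph.diagnostics` | ROC/AUC, Youden cut-offs, 2×2 metrics, ICC, sample size |
| `rootmorph.reports` | cohort-level comparison / ROC / accuracy tables |
| `rootmorph.atlas` | rigid registration, mean models, distance colour maps |
| `rootmorph.cli` | `rootmorph` command-line pipeline |

## CLI

```sh
rootmorph generate --out-dir generated --n-nrt 54 --n-crt 41 --seed 7 --meshes 2
rootmorph measure generated/nrt_000.stl --out metrics.csv
rootmorph prw outline.csv landmarks.json
rootmorph diagnose generated/cohort.csv --out-dir reports
rootmorph reproduce-tables generated/cohort.csv --out-dir tables
rootmorph atlas --out-dir atlas_out --n-per-group 4 --seed 0
```

Every CSV artifact embeds the seed and a config hash in a `#` comment header;
identical flags reproduce outputs byte for byte.

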