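# octamorph

Microvascular morphometry of OCTA en-face angiograms.

Retinal vein occlusion (RVO) remodels the macular capillary bed: capillary
dropout lowers perfusion, and altered transmural pressure changes vessel
shape. `octamorph` is for researchers quantifying that remodeling from
optical coherence tomography angiography (OCTA): it turns a grayscale
en-face angiogram of one capillary layer (superficial or deep plexus) into
a skeleton-graph of vessel branches and reports, per region,

* **branch number** — count of skeleton branches,
* **ΣBL, ΣEL** — sums of branch lengths and of Euclidean (chord) lengths
  between branch nodes, in mm,
* **mean BL, mean EL** — per-branch arithmetic means, in µm,
* **vessel tortuosity** — VT = ΣBL / ΣEL (≥ 1; 1 = perfectly straight),
* **vessel density** — VD = vessel pixels / total pixels.

Regions follow the clinical convention for branch RVO: the central 3×3 mm
crop is split into superior and inferior halves, labeled *affected* /
*nonaffected* by the occluded hemifield (mirrored onto fellow eyes). A
statistics stage reproduces the usual cohort analyses: group contrasts
against controls, paired occluded-vs-fellow tests, and age- and
sex-adjusted linear regressions of visual acuity (logMAR) on each rescaled
metric.

Because clinical OCTA cohorts are rarely redistributable, the package
includes a synthetic capillary-plexus generator with exact ground truth
(branch paths, lengths, tortuosity, density) plus lesion models for
capillary dropout (uniform, short-branch-preferential, hemifield-restricted)
and cohort simulation with planted acuity–metric relationships. All
randomness flows from explicit seeds; reruns are byte-identical.

## Worked example

```python
import octamorph as om

# a DCP-style synthetic plexus: 3 mm crop, 445 planted branches
image, mask, truth = om.generate_plexus(om.dcp_params(), seed=1)

graph = om.build_graph(om.skeletonize(mask))
rec = om.summarize_region(mask, graph, eye_id="demo", half="full")
print(truth.metrics("full"))
print(rec)
```

prints (abbreviated)

```
{'branch_number': 445, 'mean_bl_um': 106.99, 'vt': 1.2140, 'vd': 0.0412, ...}
MorphometricRecord(eye_id='demo', layer='DCP', region='full',
                   branch_number=446, sum_bl_mm=46.58, sum_el_mm=38.61,
                   mean_bl_um=104.45, mean_el_um=86.58,
                   vt=1.2064, vd=0.0412)
```

The measurement recovers the planted branch count within 1 branch, VT
within 0.008, and VD exactly (density depends only on the mask). Applying
a 30 % short-branch-preferential dropout to the superior half and
re-measuring that half:

```python
m2, _ = om.apply_lesion(
    truth, om.LesionParams(0.3, "short_branch_preferential", "superior"),
    seed=2)
rec2 = om.summarize_region(m2, om.build_graph(om.skeletonize(m2)),
                           eye_id="demo", half="superior")
print(rec2.branch_number, rec2.mean_bl_um, rec2.vt)
```

```
161 107.26 1.2047
```

— branch number and density collapse, mean branch length *rises* (the
short branches died first), and tortuosity barely moves: the dropout
signature that distinguishes hemifield nonperfusion from diffuse loss.

A command line covers the same stages:

```sh
octamorph simulate --out sim --seed 1 --layer DCP
octamorph segment --in sim/angiogram.tif --out mask.tif --method otsu --scan-width-mm 3
octamorph metrics --in mask.tif --out demo
octamorph run --images images.csv --clinical clinical.csv --out results
```

See `docs/methods.md` for the model, conventions, parameter defaults and
their calibration, and known limitations.

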