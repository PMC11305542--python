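# vmseg

Automatic segmentation of retinal **non-perfusion** (capillary dropout) on
widefield OCT-angiography en-face images, and estimation of the
**non-perfusion index (NPI)**.

In diabetic retinopathy, capillary occlusion produces retinal areas with no
detectable flow. On an OCT-A en-face slab these appear as regions that are
simultaneously *dark* (low decorrelation signal) and *homogeneous* (no vessel
texture). A single global intensity threshold cannot find them on widefield
photomontages (~24 × 24 mm, 1900 × 1900 px) because brightness falls off from
the macula to the periphery. VMseg instead binarizes a **local spatial
variance map**, which is insensitive to that gradient.

The package is aimed at readers and researchers quantifying retinal ischemia:
it provides the segmentation pipeline, the evaluation metrics used to validate
it (Dice, NPI, Spearman, Bland–Altman), the grid-search protocol that tunes
its parameters on a development set, and a synthetic phantom generator so the
whole chain is testable without clinical images.

## The algorithm

For an image $I$, elimination mask $E$ (manually cropped-out low-quality
areas, encoded as white paint), and parameters
$(K, t_i, t_v, n_{\mathrm{morph}})$:

1. min–max normalize $I$ to $[0,255]$; bilateral filter (9 px window, both
   sigmas 40);
2. local variance map $V_k(x) = \mathrm{Var}\{I(y) : y \in W_k(x)\}$ for each
   window size $k \in K \subseteq \{3,5,7\}$, averaged over $K$;
3. rescale to $[0,255]$ (homogeneous areas → low values) and set pixels with
   normalized intensity $\ge t_i$ to 255 — the *vessel override*: bright
   pixels are flow, never dropout;
4. second bilateral pass, then grayscale closing and opening with a 5-px
   cross kernel, $n_{\mathrm{morph}}$ iterations;
5. binarize: candidate non-perfusion where the map value $< t_v$;
6. fill interior holes of each 8-connected component and drop components
   smaller than 250 px;
7. remove eliminated pixels; report
   $\mathrm{NPI} = \dfrac{\mathrm{Area}_{\mathrm{nonperfusion}}}{\mathrm{Area}_{\mathrm{total}} - \mathrm{Area}_{\mathrm{eliminated}}}$.

Defaults are the optimum found on the original development set:
$K = \{3,5\}$, $t_v = 17$, $t_i = 75$, $n_{\mathrm{morph}} = 1$.

## Worked example

```python
from vmseg import PhantomConfig, VMsegParams, generate_phantom, evaluate_pair, segment

sample = generate_phantom(PhantomConfig(seed=1))      # 512 px synthetic OCT-A
mask = segment(sample.image, sample.elim, VMsegParams())
rec = evaluate_pair("phantom-1", mask, sample.truth, sample.elim)
print(f"Dice          : {rec.dice:.3f}")
print(f"estimated NPI : {rec.npi_estimated:.4f}")
print(f"true NPI      : {rec.npi_ground_truth:.4f}")
```

prints

```
Dice          : 0.979
estimated NPI : 0.0644
true NPI      : 0.0669
```

i.e. the pipeline recovers the phantom's known dropout patches with a Dice
overlap of 0.979, and the estimated non-perfusion index (6.4% of the
analyzable area) is close to the ground-truth 6.7%.

The same operations are available from the shell:

```bash
vmseg simulate --n 20 --seed 0 --out suite/        # phantom suite + manifest
vmseg segment suite/phantom_000.png --elim-dir suite/ --out out/
vmseg evaluate --pred-dir out/ --truth-dir suite/ --elim-dir suite/ --out eval.csv
vmseg optimize --image-dir suite/ --truth-dir suite/ --out opt/
vmseg robustness --image-dir suite/ --truth-dir suite/ --n-repeats 10 --out rob.csv
```

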