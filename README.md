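# fluoroquant

Quantitative analysis of multi-channel 2-D fluorescence microscopy images,
built around three questions that come up when studying drug localization
and mitochondrial adaptation in stressed cells:

1. **Where does a fluorescent compound accumulate?** Two-channel
   colocalization between a compound's intrinsic fluorescence (e.g.
   doxorubicin) and an organelle marker (LysoTracker, MitoTracker, a DNA
   stain), quantified by Pearson correlation, Manders coefficients and the
   intensity correlation quotient.
2. **How is mitochondrial membrane potential distributed in space?**
   JC-1 is a ratiometric dye — green monomer at low ΔΨm, red aggregates at
   high ΔΨm — so the red/green intensity ratio profiled along each
   mitochondrion maps the potential along it and reveals "mosaic"
   distributions within single organelles.
3. **How long and how elongated are mitochondria?** Morphometry of tubular
   mitochondria from a Frangi-tubeness enhancement, with one Otsu threshold
   shared by every image of every experimental condition so that genuine
   inter-condition intensity differences are not normalized away.

A synthetic-field generator with exact ground truth (tube centerline
lengths, designed colocalized fractions, designed axial potential patterns)
makes every stage testable without microscope data.

## The statistics and the models

For paired channel intensities $a_i, b_i$:

- **PCC**: $r = \sum (a_i-\bar a)(b_i-\bar b) \,/\, \sqrt{\sum(a_i-\bar a)^2 \sum(b_i-\bar b)^2} \in [-1,1]$,
  computed pixel-wise inside the union of the per-channel Otsu masks and
  again along an optimized scan line (the image chord through the
  union-mask centroid whose orientation maximizes the summed joint
  intensity).
- **Manders**: $M_1 = \sum_{i \in A \cap B} a_i / \sum_{i \in A} a_i \in [0,1]$
  (and $M_2$ symmetrically), with $A, B$ the per-channel Otsu masks.
- **ICQ**: fraction of mask pixels with $(a_i-\bar a)(b_i-\bar b) > 0$ among
  those with a nonzero product, minus 0.5; in $[-0.5, 0.5]$.
- **Frangi tubeness** at scale $\sigma$: from Hessian eigenvalues
  $|\lambda_1| \le |\lambda_2|$,
  $V = e^{-R_B^2/2\beta^2}\,(1 - e^{-S^2/2\gamma^2})$ for bright ridges
  ($\lambda_2 < 0$), $R_B = \lambda_1/\lambda_2$,
  $S = \sqrt{\lambda_1^2+\lambda_2^2}$; maximum over $\sigma \in \{1,2,3,4\}$.
- **Skeleton length**: topological thinning, spur pruning, then a weighted
  chain-code step sum (Kulpa weights 0.948 / 1.343) scaled by the pixel
  size; objects are kept when the length falls in the closed interval
  1–20 µm (shorter = noise, longer = fused networks, counted separately).
- **JC-1 axial profiles**: per object, the leading PCA axis of the
  intensity-weighted pixel coordinates; both channels sampled along it by
  bilinear interpolation, each normalized to its own maximum; the red/green
  ratio profile plus the within-object pixel-wise red–green PCC ("pix PCC",
  negative for mosaic potential distributions).

## Worked example

Simulate a batch of tube fields with known centerline lengths, then run
morphometry:

```sh
fluoroquant simulate tubes --seed 42 --n-images 4 --n-objects 10 --out demo
fluoroquant morpho --manifest demo/manifest.csv \
    --out demo/objects.csv --summary demo/summary.csv
```

prints

```
40 objects retained (0 below 1.0 um, 0 above 20.0 um); global threshold 0.2787
```

and `demo/summary.csv` reports a mean skeleton length of **8.017 µm**
(median 8.212, SD 3.57, mean aspect ratio 8.46, n = 40) against a ground-truth
mean of 8.115 µm recorded in `demo/truth.json` — a 1.2 % recovery error.

Colocalization on a two-channel spot field with a designed 70 %
colocalized fraction:

```sh
fluoroquant simulate coloc --seed 42 --n-images 1 --n-objects 200 \
    --overlap-fraction 0.7 --out demo_c
fluoroquant coloc --manifest demo_c/manifest.csv --out demo_c/res.csv
```

yields `m1=0.735, m2=0.710` (close to the designed 0.7; the residual is
mask bleed at spot edges), `pcc_line=0.884` along the optimized scan line,
and a low pixel-wise `pcc_pixel=0.220`/`icq=0.221` — as expected when only
part of the punctate field co-occurs. Each run also writes a
`*.provenance.json` with every threshold and parameter used.

The library API mirrors the CLI (`colocalize`, `morphometry_pipeline`,
`jc1_pipeline`, `make_tube_field`, ...); see the module docstrings.

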