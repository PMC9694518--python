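# Methods

## The segmentation model

`fasgaseg` assumes a FASGA-stained grass internode cross section scanned
in RGB brightfield at a known pixel size (reference: 5.17 µm/px). The
stain maps chemistry to color — safranin reds mark lignified walls,
alcian blues poorly lignified ones — and the anatomy maps color to
geometry: a dark, sclerenchyma-rich rind surrounds a lighter rind band
and a large medullary pith; vascular bundles are dense in the rind and
scattered in the pith. The workflow exploits both facts: per-pixel
saturation/value thresholds capture the stain response, and the spatial
density of one particular threshold selection reconstructs the anatomy.

All thresholds and morphology constants are global: nothing is tuned per
image. This is the property that makes per-tissue areas comparable
across genotypes, treatments and species.

### Preprocessing

Scanner acquisitions are dim, so every channel is doubled and clipped at
255, then smoothed with three passes of a radius-2 circular mean filter
(the 21-pixel footprint x²+y² ≤ 5, replicate-edge padding). Three
iterated box passes closely approximate a Gaussian (σ ≈ 2.2 px); a
single Gaussian of matched variance is available as an option
(`enhance(..., use_gaussian=True)`). Doubling precedes smoothing.

The enhanced image is decomposed with the standard hexcone transform:
V = max/255, S = (max−min)/max (0 when max = 0), H the fraction of the
color circle, with H ≡ 0 for achromatic pixels. All three planes live on
[0, 1]; every threshold below is expressed on that scale.

### Pixel classes

Three saturation ranges — [0.05, 0.26), [0.26, 0.78), [0.78, 1] — and
three value ranges — [0.42, 0.65), [0.66, 0.93), [0.95, 1] — define 15
pixel classes: ids 1–3 (S range only, V in a gap), 4–6 (V range only),
and 7–15 (the 3×3 combinations, id = 6 + 3(i−1) + j). Ranges within one
dimension are half-open except the last (closed), so a value on a shared
boundary belongs to the upper range and the printed gaps (e.g.
V ∈ [0.65, 0.66)) are real gaps. Pixels in no S and no V range form
class 0; the V-range-3-only class (S below every range, V ≥ 0.95) is the
near-white slide background and is treated as non-section alongside
class 0 when the section mask is built. Hue plays no role at this stage.

### Region masks

The low-saturation selection (S range 1) is spatially structured: dense
inside the dark rind band and inside bundles, sparse elsewhere. The
derivation, with all constants as named `RegionParams` defaults:

1. **Section**: non-background classes, closed (radius 2), largest
   connected component; holes < 500 px are filled, larger holes are
   biological (hollow stems) and stay open.
2. **Density**: mean filter (disk radius 15 px ≈ 78 µm) of the low-S
   indicator inside the section; "dense" = density ≥ 0.5.
3. **Dark rind**: dense components touching the outer boundary band
   (width 10 px, computed on the hole-filled section so hole rims never
   count as outer boundary), plus non-dense shell components confined
   near the boundary (component depth ≤ 2× band width — the epidermis
   layers). The depth guard matters: without it, any local breach of the
   dense ring would connect the interior to the boundary and flood the
   whole section into the rind. The union is closed and small holes
   (≤ max bundle area) filled, which absorbs rind-embedded bundles.
4. **Bundles**: each remaining dense blob seeds its full connected
   component of the (closed) low-S selection, which is then hole-filled —
   the density window only fits inside the central part of a bundle, so
   the grown component, not the raw dense blob, is the bundle's extent,
   and interior high-saturation sclerenchyma islands are filled in.
   Components fused to the dark rind are absorbed into it; components
   outside [50, 20000] px (≈ 1.3·10³–5.3·10⁵ µm²) return to the pith
   pathway.
5. **Light rind / pith**: the remainder minus a 10-px band inward of the
   dark rind; the largest component of what is left is the pith, the
   rest (band included) is light rind.

Raising the density threshold never grows the dark rind while the dense
ring stays closed; if the ring disintegrates entirely the dark rind is
reported empty with a warning and all non-bundle tissue follows the
pith/light-rind pathway.

### Tissue taxonomy

Pixel class × region gives 36 tissue types: 2 ET + 9 DRT inside the
dark-rind mask, 5 BT inside bundles, and 10 LRT / 10 MT that share class
definitions and differ only by mask (light rind vs pith). Four medullary
types are then sub-split by hue — MT1/MT4 (lignified): H ∈ [0.005, 0.09]
→ "a", else "b"; MT2/MT5 (poorly lignified): H ∈ [0.51, 0.91] → "a",
else "b"; both intervals closed — for the final 40. The upper blue bound
is configurable (an alternative convention uses 0.94).

The default class→tissue mapping orders names by lignification signal
(MT1/MT4 the saturated red classes, MT2/MT5 the blue ones, BT1/BT4 the
sclerenchyma-pole classes, BT2 bundle parenchyma, BT5 phloem; ET the
darkest saturated classes; DRT8/DRT9 the bright saturated classes that
are rind-bundle sclerenchyma) and reserves one catch-all entry per
region (DRT7, LRT10, BT3, MT10) for the six single-dimension classes.
One non-obvious constraint shaped it: the region derivation *requires*
the dark-rind ground mass and bundle interiors to sit in the low-S
classes (7–9), so those classes carry the anatomical signal while the
red/blue distinction lives on the non-low-S classes (11–15). Class-0
pixels swallowed into the section by closing map to the same tissue as
class 1 (the catch-all), so every section pixel gets a label. The whole
mapping is an editable CSV (columns tissue_name, region, class_ids,
color_hex); censuses (2/9/10/5/14 with exactly the four a/b pairs) are
enforced on load.

### Quantification

Per tissue: pixel count, area = count × pixel_size², and percent of the
quantification region — %MT over all medullary tissue, %BT over bundle
tissue, %RT over epidermis + dark rind + light rind combined. The area
table always enumerates all 40 tissues in catalogue order, zeros
included. Two groupings are provided: `regions5` (the five families) and
`legland4` (rind / bundles / lignified medulla = MT1a/b ∪ MT4a/b /
low-lignified medulla = the rest; MT3 and MT6–MT10 join the
low-lignified group by default, switchable, since only MT1/MT4 carry the
lignified designation).

## The synthetic phantom

`generate_phantom` renders a concentric cross section — epidermis ring
(ET1), dark rind (DRT1) with embedded sclerenchyma blobs (DRT8), light
rind (LRT3), blue pith band (MT2a), red pith core (MT1a), elliptical
pith bundles (BT5 bodies with inset BT1 sclerenchyma caps behind a thin
parenchyma rim), optional central hole — and records ground-truth tissue
and region maps before any noise. Per-pixel HSV values are drawn from
narrow normals centered inside each tissue's class cell and clipped with
margin for 8-bit quantization. The image is written at half intensity:
the contrast-doubling step of the pipeline restores the intended values,
exactly as it compensates dim scanner output on real data.

Default geometry (1024² grid): section radius 480 px, epidermis 6 px,
dark rind 40 px, light rind 10 px, blue band 60 px, 12 rind bundles of
radius 7 px, 8 pith bundles with semi-major axes 25–40 px (0.26–0.41 mm
at 5.17 µm/px, the scale of maize pith bundles — and comfortably wider
than the 15-px density window, below which a bundle is undetectable by
construction). Bundle placement keeps 24 px clearance from other
bundles, the light rind and the hole so density blobs never merge.
Random draws use three decoupled streams (rind bundles, pith bundles,
colors) spawned from one seed; `pith_bundle_seed` overrides the middle
stream so two phantoms can differ *only* in bundle placement.
Reduced-scale phantoms for fast tests come from `scaled_spec` /
`scaled_region_params`, which scale lengths linearly and areas
quadratically with floors that keep every structure wider than its
detection window.

What the phantom does **not** emulate: cell-level texture, staining
gradients within a tissue, uneven illumination, section tears and folds,
and the gradual red→blue transition of real parenchyma (phantom
interfaces are step edges). Passing recovery tests therefore shows the
pipeline's logic is correct and stable, not that the thresholds are
optimal for any particular scanner.

## Numerical behavior and limitations

- The pipeline is fully deterministic: repeated runs are bit-identical,
  and processing order cannot affect any output.
- Noise-free full-scale phantoms are recovered at ≈ 99.5% pixel
  agreement outside 3-px boundary bands, with exact bundle counts;
  agreement degrades monotonically with additive acquisition noise.
- The three mean-filter passes mix colors over ≈ 6 px at tissue
  interfaces. A mixed red/blue pixel loses the high saturation that
  defines the lignified classes (20% contamination already drops S below
  0.78), so interface ribbons vote one-sidedly for low-lignification
  classes. On the default phantom this transfers ≈ 3% of the medullary
  area between the legland groups when whole maps are compared; outside
  3-px boundary bands the planted areas are recovered to well under 1%.
  Real sections have gradual transitions, where the same ribbon pixels
  are genuinely intermediate tissue.
- Quantization: images are 8-bit; the phantom's clip margins (≥ 0.01 per
  channel) absorb the worst-case half-intensity rounding error.
- Degenerate inputs: an all-white (or empty) image raises a
  "no section detected" error naming the image; a section with no
  interior low-S structure yields an empty bundle mask and quantification
  proceeds; an empty dark rind triggers a warning and the fallback
  pathway. Batch runs record per-image failures and continue.

## Problem sizes used by the test suite

The suite exercises full-scale (1024², the study condition) phantoms for
recovery and noise-monotonicity checks and reduced-scale (384²–512²)
phantoms for partition, conservation, locality and batch-determinism
checks; the acceptance script uses one full-scale phantom plus a
half-scale determinism pair. These sizes were chosen so the complete
suite runs in well under a minute of compute per full-scale image while
keeping every morphological structure larger than its detection window.
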