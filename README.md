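# cxrline

Anatomically guided postprocessing and evaluation for catheter segmentation
in chest radiographs.

A right internal jugular line (RIJL) is the most common central venous
catheter; after every insertion its placement is checked on a portable AP
chest X-ray, and the clinically decisive quantity is the location of the
catheter **tip**. CNN segmentations of these thin, low-contrast lines come
out fragmented and are easily confused with other tubes, which wrecks
tip localization (the tip is defined as the most inferior point of the
mask, so a single distractor blob below the catheter moves it by
centimetres). `cxrline` implements the deterministic reasoning stages that
wrap such a CNN:

* **Trachea-guided cropping** — reduce the trachea landmark mask to its
  largest component, and place a 300 mm × 150 mm search box to the
  patient's right of its centroid; crop for the segmenter and restore
  predictions to original coordinates exactly via a saved crop footprint.
* **Bidirectional Connect** — anchor on the largest connected component of
  the prediction, skeletonize it, and from its superior and inferior
  endpoints march along the local tangent sweeping a forward half-disk
  (radius 10 mm, step 5 mm, per-endpoint budget 40 mm); absorb every
  fragment hit, bridge gaps with digital straight segments, and dilate the
  result back to a consistent stroke width — one continuous curve out.
* **Evaluation** — average symmetric surface distance

  `ASSD(B1,B2) = [Σ_{x∈B1} d(x,B2) + Σ_{y∈B2} d(y,B1)] / (|B1|+|B2|)`

  over boundary point sets in mm, tip distance (spacing-adjusted Euclidean
  distance between most-inferior points), and Dice; summaries as
  mean ± SD with normal 95% CIs.
* **Phantoms** — a seeded generator of mask-level synthetic radiographs
  (trachea blob, descending catheter with known tip, fragmentation gaps,
  contralateral distractor tubes) so the whole pipeline is testable with
  no clinical data.

The CNN itself is an external interface: any program mapping a cropped
image to a binary mask of the same shape. See `docs/methods.md` for the
full algorithm and design rationale.

## Worked example

Compare the three postprocessing variants on a 50-phantom set (defaults:
512×512 px at 1 mm spacing, 2 gaps of 5–20 px, one distractor ≥ 60 mm off
the catheter trajectory):

```python
from cxrline import run_compare

report = run_compare(n=50, seed=0)
for method in ("none", "largest_cc", "bd_connect"):
    s = report["summary"][method]
    print(f"{method:12s} ASSD {s['assd_mm']['mean']:6.2f} ± {s['assd_mm']['sd']:.2f} mm"
          f"   tip {s['tip_distance_mm']['mean']:6.2f} mm"
          f"   DSC {s['dsc']['mean']:.3f}")
```

```
none         ASSD   8.15 ± 1.01 mm   tip  85.54 mm   DSC 0.860
largest_cc   ASSD  25.53 ± 13.68 mm   tip  91.24 mm   DSC 0.660
bd_connect   ASSD   0.21 ± 0.04 mm   tip   0.00 mm   DSC 0.930
```

Reading: the raw fragmented prediction scores ASSD 8.15 mm, dominated by
the distractor's boundary, and its most-inferior-point tip lands on the
distractor (85.5 mm error). Keeping only the largest component discards the
distractor *and* two thirds of the catheter, which is why this common
default makes ASSD worse, not better. Bidirectional Connect reabsorbs the
catheter fragments while the distractor stays outside its 50 mm search
envelope: ASSD drops to 0.21 mm and the tip is recovered exactly on all 50
phantoms.

The same comparison is available from the shell, along with the individual
stages:

```sh
cxrline simulate --n 5 --seed 0 --out phantoms/
cxrline connect --pred phantoms/phantom_0000_pred.png --spacing 1 1 --out connected.png
cxrline tip --mask connected.png --spacing 1 1 --out tip.json
cxrline compare --n 50 --seed 0 --out-dir report/
```

Exit codes: 0 success, 2 geometry/landmark failure, 3 empty prediction,
4 I/O error.

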