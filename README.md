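# ptcscreen

Fast screening of cytological whole-slide images (WSIs) for papillary
thyroid carcinoma (PTC).

Cytopathologists diagnose PTC by visually scanning papanicolaou-stained
fine-needle-aspiration (FNA) smears and ThinPrep (TP) slides — gigapixel
images once digitized. `ptcscreen` implements an automated screening
pipeline for such slides: each WSI is decomposed into a grid of 512-px
tiles, background-only tiles are discarded by a cheap thumbnail-level
tissue filter, the remaining tiles are segmented by a fully convolutional
network, and the per-tile class maps are stitched back into a whole-slide
PTC mask. The package also ships the evaluation machinery (five pixel
metrics plus Fisher's LSD post-hoc comparison) and a deterministic
synthetic-slide generator so that every stage is testable without
clinical data.

## The model

The segmenter is an FCN-32s-style adaptation of VGG16. An input tile
`512 × 512 × 3` is zero-padded by 100 px per side (→ 712), passed through
the five VGG16 convolution blocks — the first convolution is *valid*
(712 → 710), all other 3×3 convolutions preserve size, and the 2×2
max-poolings use ceiling division (710 → 355 → 178 → 89 → 45 → 23) — then
through the fc-converted layers `conv6` (7×7, valid, 23 → 17) and `conv7`
(1×1), a 1×1 scoring layer with `K = 3` classes, and a single transposed
convolution with kernel 64 and stride 32 (17 → 576) whose output is
cropped back to 512. The class map is the per-pixel argmax of the three
score planes (0 = background, 1 = non-PTC material, 2 = PTC).

Training minimizes the per-image *summed* pixel-wise softmax
cross-entropy with SGD (learning rate 1×10⁻¹⁰, dropout 0.5, weight decay
5×10⁻⁴ — the published recipe; the tiny rate is paired with the
unnormalized loss). All layers, the loss, and backpropagation are
implemented in numpy; a `width_multiplier` scales every channel width so
the identical topology trains and runs on a CPU in seconds.

## Worked example

```python
import ptcscreen as p
from ptcscreen.nn.reference import make_color_rule_model

# a synthetic papanicolaou-like slide: 3 clusters, two of them PTC
spec = p.FixtureSpec(width_px=1536, height_px=1536, n_clusters=3,
                     ptc_fraction=2/3, cluster_radius_px=(150, 260), seed=7)
_, truth, _ = p.generate_slide(spec, out_dir="scratch", slide_id="demo")

model = make_color_rule_model(512)           # hand-weighted reference net
with p.open_slide("scratch/demo.tiff") as slide:
    mask, report = p.screen_slide(slide, model)

print(report.total_tiles, report.kept_tiles, report.ptc_pixel_count)
pred, ref = mask.labels == 2, truth == 2
print(round((pred & ref).sum() / (pred | ref).sum(), 3))
```

prints

```
9 4 368804
0.786
```

— the 1536-px slide tiles into a 3×3 grid, the background filter discards
the five tiles with no stained material (only 4 of 9 are ever scored),
and the predicted PTC mask overlaps the generator's ground truth at
IoU 0.79 (block-level decisions dilate cluster boundaries, which bounds
the IoU of the untrained reference model; see `docs/methods.md`).

The same flow is available from the shell:

```bash
ptcscreen simulate --out scratch/demo
ptcscreen train --out scratch/model.npz
ptcscreen screen --slide scratch/demo/synthetic_slide.tiff \
    --model scratch/model.npz --out scratch/mask.tiff --report scratch/report.csv
ptcscreen evaluate --pred scratch/pred --truth scratch/truth --out scratch/results
```

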