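# pollenvia

Automated pollen-viability scoring from acetocarmine-stained micrographs.

Counting stained pollen under the microscope is the standard way to measure
pollen viability — the trait `PolVia = 100 · n_viable / (n_viable +
n_nonviable)` — in plant stress phenotyping. Viable grains take up the
acetocarmine dye and appear red; non-viable grains stay transparent. Manual
counting is slow and observer-biased. `pollenvia` replaces it with a classical
computer-vision pipeline:

1. **Segmentation** — grayscale conversion, optional Sobel gradient
   highlighting, Canny edge detection + morphological closing + hole filling,
   and marker-based watershed on the interior distance transform to split
   touching grains. Extracted contours are kept only when circularity
   `4πA/P² > 0.5` and area `A > 100` px (strict).
2. **Features** — each grain becomes a 19-value descriptor: 10 geometric
   (area, perimeter, circularity, equivalent diameter, major/minor axis,
   aspect ratio, eccentricity, solidity, extent), 2 texture (within-region
   grayscale SD and 8-bin Shannon entropy), 7 color (mean R/G/B, mean H/S/V,
   red-dominant pixel fraction).
3. **Classification** — a soft-margin linear SVM (`w·x + b`, viable iff
   margin > 0) trained with a seeded stratified 70/30 train/validation split,
   feature standardization fitted on the training portion only, and a
   500-iteration solver cap. Validation accuracy is stored with the model.

Because real annotated slide corpora are rarely published, the package ships a
seeded **synthetic slide generator** that renders ground-truth scenes in the
same visual idiom (red viable blobs, rim-only transparent non-viable blobs,
touching pairs, debris specks, noise, illumination gradient), so the whole
pipeline is trainable and verifiable with zero external data.

## Worked example

```python
import pollenvia as pv

# train on ~800 synthetic grains (400 per class)
data = pv.synthetic_training_set(n_per_class=400, seed=42)
model = pv.train_svm(data, seed=42)
print(model.validation_accuracy_)        # 1.0

# score a fresh synthetic slide with known truth (20 viable, 5 non-viable)
scene = pv.generate_scene(pv.SceneParams(n_viable=20, n_nonviable=5, seed=11))
report = pv.process_image(scene.image, model)
print(report.n_viable, report.n_nonviable, report.pol_via_pct)
# 20 5 80.0
```

The model reaches perfect validation accuracy because stained and unstained
synthetic grains are linearly separable in color (mean R − mean B); the scene
counts are recovered exactly and PolVia is 80.0 %.

The same workflow is available from the shell:

```sh
pollenvia synth --n-scenes 6 --seed 100 --out-dir data/
pollenvia train --images data/ --seed 42 --model-out model.json
pollenvia count --model model.json --images data/scene_0000.png \
    --report-out report.csv --overlay-dir overlays/
pollenvia eval  --report report.csv --truth data/counts.csv --out-dir eval/
```

`count` writes a per-image CSV (counts, PolVia %, a no-grains flag instead of
a fabricated 0 %); `--overlay-dir` saves annotated PNGs (yellow boxes = viable,
blue = non-viable); `eval` prints the per-class Pearson correlation between
automated and true counts and saves scatter plots.

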