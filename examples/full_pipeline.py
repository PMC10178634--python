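"""End-to-end run: simulate -> enhance -> extract -> fuse -> select -> evaluate.

Everything is seeded, so re-running this script prints identical numbers.
The synthetic images are tiny and the toy backbone replaces a trained CNN,
so the absolute accuracies mean nothing clinically — the point is that
every stage hands a valid, reproducible artifact to the next.
"""

from mammocad import (
    FPcRFConfig,
    FeatureMatrix,
    ImageFixtureSpec,
    compute_metrics,
    enhance,
    extract_features,
    fpcrf_select,
    kfold_evaluate,
    make_images,
    threshold_fuse,
    toy_backbone,
)

SEED = 7
items = make_images(ImageFixtureSpec(n_per_class=10, seed=SEED))
labels = [it.label for it in items]
originals = [it.image for it in items]
enhanced = [enhance(img) for img in originals]
print(f"simulated {len(items)} images, 3 classes")

backbone = toy_backbone(seed=SEED, d=32)
f_orig = extract_features(originals, labels, backbone, source_id="original")
f_enh = extract_features(enhanced, labels, backbone, source_id="enhanced")

fused = threshold_fuse(f_orig, f_enh)
print(f"fused {f_orig.n_features}+{f_enh.n_features} -> kept "
      f"{fused.matrix.n_features} (Fnc={fused.threshold:.4f})")

sel = fpcrf_select(fused.matrix, FPcRFConfig(n_pollens=10, max_iter=10, folds=5, seed=SEED))
print(f"selected {sel.selected_indices.size}/{fused.matrix.n_features} features, "
      f"wrapper CV error {sel.final_fitness:.3f}")

subset = FeatureMatrix(fused.matrix.values[:, sel.mask], fused.matrix.labels)
for name in ("fknn", "lsvm"):
    cm, _ = kfold_evaluate(subset, name, k=5, seed=SEED)
    rep = compute_metrics(cm)
    print(f"{name}: accuracy {rep.accuracy:.1f}%  kappa {rep.kappa:.1f}%  "
          f"MCC {rep.mcc:.1f}%")
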