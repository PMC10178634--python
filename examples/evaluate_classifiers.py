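"""Score classifiers with 10-fold CV and the full metric suite.

Evaluates the fine-KNN (1-nearest-neighbor) and cubic-SVM presets on a
planted feature matrix, printing the seven confusion-matrix metrics, and
finishes with a margin-of-error analysis of the kappa values at 95%
confidence (half-width = 1.960 * s / sqrt(n)).
"""

from mammocad import (
    FeatureFixtureSpec,
    compute_metrics,
    kfold_evaluate,
    make_features,
    margin_of_error,
)

X, _ = make_features(FeatureFixtureSpec(n_per_class=100, d_informative=4,
                                        d_noise=6, effect_size=1.5, seed=3))

kappas = []
for name in ("fknn", "csvm"):
    cm, elapsed = kfold_evaluate(X, name, k=10, seed=0)
    rep = compute_metrics(cm, time_s=elapsed)
    kappas.append(rep.kappa)
    print(f"{name:5s} accuracy {rep.accuracy:5.1f}%  precision {rep.precision:5.1f}%  "
          f"sensitivity {rep.sensitivity:5.1f}%  F1 {rep.f1:5.1f}%  "
          f"FPR {rep.fpr:.3f}  kappa {rep.kappa:5.1f}%  MCC {rep.mcc:5.1f}%  "
          f"({elapsed:.2f}s)")

center, half, pct = margin_of_error(kappas, confidence=0.95)
print(f"kappa margin of error (95%): {center:.2f} +/- {half:.3f} (+/-{pct:.2f}%)")
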