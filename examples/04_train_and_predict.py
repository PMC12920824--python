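"""Train the residual-network + SVM classifier and predict new phantoms.

Fits on a small labeled cohort, then classifies held-out phantoms,
printing the one-vs-rest decision values (the predicted class is the
largest).
"""

import numpy as np

from thermoclass import CLASS_LABELS, generate_labeled_set
from thermoclass.network import TrainConfig
from thermoclass.pipeline import PipelineConfig, fit_classifier, predict, prepare_inputs

train_imgs, train_labels = generate_labeled_set(10, height=64, width=64, seed=0)
test_imgs, test_labels = generate_labeled_set(3, height=64, width=64, seed=99)

cfg = PipelineConfig(train=TrainConfig(epochs=40))
X = prepare_inputs(train_imgs, cfg)
y = np.array([CLASS_LABELS.index(l) for l in train_labels])
clf = fit_classifier(X, y, cfg, seed=0)
print(f"trained on {len(train_imgs)} phantoms; "
      f"final hinge loss {clf.training_losses[-1]:.4f}")

correct = 0
for img, true in zip(test_imgs, test_labels):
    label, dec = predict(img, clf)
    correct += label == true
    print(f"true {true:15s} -> predicted {label:15s} "
          f"decisions {np.round(dec, 2)}")
print(f"held-out accuracy: {correct}/{len(test_imgs)}")
# positive decision values mean the one-vs-rest machine votes for that class
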