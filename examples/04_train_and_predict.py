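"""Train the tiny preset on a phantom cohort and run coarse-to-fine inference.

This is a miniature of the full recovery exercise (fewer cases and epochs so
it finishes in a couple of minutes); expect rougher localization than the
full protocol in cephalo3d.experiments.run_recovery.
"""

import numpy as np

from cephalo3d import PhantomConfig, PredictionConfig
from cephalo3d.catalog import catalog_names, phantom_catalog
from cephalo3d.experiments import RecoveryConfig, train_models
from cephalo3d.metrics import radial_error
from cephalo3d.phantom import generate_batch
from cephalo3d.predictor import predict_landmarks

cfg = RecoveryConfig(n_train=6, n_val=2, n_test=2, epochs_3d=15, epochs_2d=6)
names = catalog_names(phantom_catalog())
cohort = generate_batch(cfg.phantom, 10, base_seed=7000)
train_ph, val_ph, test_ph = cohort[:6], cohort[6:8], cohort[8:]

print("training coarse 3D network and three 2D branches (a few minutes)...")
models = train_models(train_ph, val_ph, cfg, seed=7)

for ph in test_ph:
    pred = predict_landmarks(ph.volume, models, names, PredictionConfig(tau=0.35))
    errs = [radial_error(pred[n].coord, ph.truth[n].coord)
            for n in names if ph.truth[n].present and pred[n].present]
    print(f"{ph.scenario.name:8s} mean radial error {np.mean(errs):.2f} mm "
          f"over {len(errs)} predicted-present landmarks")
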