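"""Step 2: isocontours, features, pairing, and saliency classification.

Closed isocontours of the probability map are gated by perimeter
(0.6-6 um), described by 7 features, paired across adjacent planes
within 0.4 um, and classified by a second random forest.
"""

import numpy as np

from mitoseg import PhantomParams, PipelineConfig, generate_phantom, train_pipeline
from mitoseg.pipeline import detect_and_featurize
from mitoseg.patches import predict_probability_map
from mitoseg.contours import enumerate_pairs

cfg = PipelineConfig(n_pos_patches=400, n_neg_patches=500, seed=0)
volume, labels = generate_phantom(PhantomParams(shape=(14, 200, 200), n_organelles=4, seed=42))

tp = train_pipeline(volume, labels, cfg, select_T=False)
prob = predict_probability_map(tp.patch_model, volume)
by_plane = detect_and_featurize(volume, prob, cfg)
n_contours = sum(len(v) for v in by_plane.values())
pairs = enumerate_pairs(by_plane, cfg.pair_gate_D_um)
probs = tp.contour_model.predict_prob(np.stack([p.feature_vector for p in pairs]))
kept = (probs >= cfg.pair_threshold_T).sum()
print(f"{n_contours} perimeter-gated contours on {volume.shape[0]} planes")
print(f"{len(pairs)} adjacent-plane pairs inside the {cfg.pair_gate_D_um} um gate")
print(f"{kept} pairs at or above the saliency threshold T={cfg.pair_threshold_T}")
# pairs surviving T mark their member contours salient; everything else —
# membrane and vesicle contours included — is discarded
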