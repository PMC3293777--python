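"""Full pipeline: train on half a phantom, segment the other half.

Prints the voxel metrics of the final segmentation — the quantity the
whole three-step design optimizes.
"""

from mitoseg import (
    IntensityVolume,
    LabelVolume,
    PhantomParams,
    PipelineConfig,
    confusion,
    generate_phantom,
    metrics,
    segment,
    train_pipeline,
)

volume, labels = generate_phantom(
    PhantomParams(
        shape=(16, 220, 220), n_organelles=7,
        organelle_axes_um=(0.15, 0.35), organelle_z_axes_um=(0.1, 0.22), seed=42,
    )
)
half = volume.shape[0] // 2
train_v = IntensityVolume(volume.data[:half], volume.spacing)
train_l = LabelVolume(labels.data[:half], labels.spacing)
test_v = IntensityVolume(volume.data[half:], volume.spacing)
test_l = LabelVolume(labels.data[half:], labels.spacing)

cfg = PipelineConfig(n_pos_patches=500, n_neg_patches=650, seed=0)
tp = train_pipeline(train_v, train_l, cfg, select_T=False)
res = segment(test_v, tp)

tpr, fpr, acc = metrics(confusion(res.labels, test_l))
print(f"contours: {len(res.contours)} detected, {len(res.salient_contours)} salient")
print(f"held-out voxel metrics: TPR {tpr:.3f}, FPR {fpr:.4f}, accuracy {acc:.4f}")
# accuracy is (TP+TN)/(TP+FP+FN+TN) over voxels; on the full-size study
# phantom the same protocol reaches ~0.97-0.99
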