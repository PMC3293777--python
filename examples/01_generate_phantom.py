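"""Generate a synthetic EM phantom and inspect its ground truth.

The phantom mimics serial block-face SEM neuropil: dark striped
ellipsoids (the organelles to segment) among membrane curves and
vesicles, at 10 nm XY pixels and 50 nm Z steps.
"""

from mitoseg import PhantomParams, generate_phantom

params = PhantomParams(shape=(12, 200, 200), n_organelles=4,
    organelle_axes_um=(0.15, 0.35), organelle_z_axes_um=(0.1, 0.22), seed=42)
volume, labels = generate_phantom(params)

frac = labels.data.mean()
inside = volume.data[labels.data == 1].mean()
outside = volume.data[labels.data == 0].mean()
print(f"volume shape (z, y, x): {volume.shape}, spacing {volume.spacing} nm")
print(f"labeled organelle fraction: {frac:.3f}")
print(f"mean gray inside organelles: {inside:.1f}, background: {outside:.1f}")
# the labeled fraction is the voxel prior a segmenter must beat; organelles
# are darker than background but overlap it heavily once noise is added
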