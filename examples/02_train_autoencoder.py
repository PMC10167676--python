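"""Train the 3D convolutional autoencoder and measure reconstruction quality.

Trains the undercomplete encoder/decoder on a small synthetic cohort and
prints the compression ratio, the held-out mean squared reconstruction
error, and a voxel-distribution comparison between an original and its
reconstruction. Lower held-out MSE means the 32-channel latent grid retains
nearly all the information in the smoothed Jacobian map.
"""

import numpy as np

from dbmorph.autoencoder import (compression_fraction, decode, encode,
                                 train_autoencoder)
from dbmorph.classifier import stratified_split
from dbmorph.synthetic import generate_cohort

cohort = generate_cohort(n_cases=24, n_controls=24, dims=(24, 28, 24), seed=1)
split = stratified_split(cohort, test_ratio=0.2, seed=1)

print(f"latent size fraction: "
      f"{100 * compression_fraction((24, 28, 24)):.1f}% of the input "
      f"(full-resolution equivalent: "
      f"{100 * compression_fraction((121, 145, 121)):.1f}%)")

ae, trace = train_autoencoder(cohort.volume_array(), split, steps=600, seed=1)
print(f"held-out MSE after {trace.steps[-1]} steps: {trace.test_loss[-1]:.2e}")

x = cohort.volumes[split.test_ids[0]]
x_hat = decode(ae, encode(ae, x))
inm = cohort.mask.voxels
print("voxel quantiles (original vs reconstruction):")
for q in (0.25, 0.5, 0.75):
    print(f"  q{int(q * 100)}: {np.quantile(x.voxels[inm], q):.3f} "
          f"vs {np.quantile(x_hat.voxels[inm], q):.3f}")
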