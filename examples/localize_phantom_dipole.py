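"""Localize a simulated dipole on a folded-cortex phantom at several SNRs.

Builds the four-layer evaluation phantom (skin/skull/CSF shells and a
folded cortical boundary), assembles the gain matrix reciprocally, picks a
tangentially oriented sulcal-wall dipole, simulates its sensor signal with
the independent direct forward path, and localizes it with the depth-
weighted minimum-norm inverse — noiseless first, then with correlated
cortical noise mixed in at decreasing SNR.  Distances are from the true
dipole to the peak and to the centroid of the 75 % activation region.

Runs in a few minutes (coarser meshes than the validation suite would use).
"""

import numpy as np

from recimeg import (apply_inverse, build_evaluation_phantom, build_helmet_array,
                     build_noise_model, depth_weights, direct_column, localize,
                     make_inverse_operator, mix_to_snr, sample_noise,
                     select_lambda2, face_mean_curvature)
from recimeg.bem import ChargeOperator
from recimeg.leadfield import assemble_leadfield

head, sources = build_evaluation_phantom(cortex_subdivisions=3, seed=0)
sensors = build_helmet_array(24, 0.13, coverage=0.45, kinds=("magnetometer",))
op = ChargeOperator(head)
lf = assemble_leadfield(head, sensors, sources, method="reciprocal")

_, R = depth_weights(lf)
inv = make_inverse_operator(lf, R, np.eye(len(sensors)), select_lambda2(3.0),
                            normalize_gain_trace=True)

# probe: a sulcal-wall source with tangential orientation under the helmet
pos = sources.positions
rhat = pos / np.linalg.norm(pos, axis=1)[:, None]
radialness = np.abs(np.einsum("ij,ij->i", sources.normals, rhat))
H = face_mean_curvature(head.layer("cortex").mesh)
cand = np.nonzero((radialness < 0.6) & (H < 0) & (pos[:, 2] > 0.04))[0]
j = int(cand[len(cand) // 2])

b = direct_column(head, pos[j], 1e-8 * sources.normals[j], sensors, operator=op)
b /= np.linalg.norm(b)
loc = localize(apply_inverse(inv, b).strengths, sources, pos[j], threshold=0.75)
print(f"noiseless: centroid error {1e3 * loc.centroid_distance:.1f} mm, "
      f"peak error {1e3 * loc.peak_distance:.1f} mm")

noise = build_noise_model(head, sensors, sources, K=48, seed=1, operator=op)
rng = np.random.default_rng(2)
print("SNR sweep (mean +- std of centroid error over 50 noise draws):")
for snr in (81, 9, 1.5):
    d = []
    for _ in range(50):
        eps = sample_noise(noise, 0, rng=rng)
        sig = mix_to_snr(b, eps, snr)
        d.append(1e3 * localize(apply_inverse(inv, sig.signal).strengths,
                                sources, pos[j], 0.75).centroid_distance)
    print(f"  SNR {snr:>4}: {np.mean(d):5.1f} +- {np.std(d):.2f} mm")
print("The mean error stays near the noiseless value at high SNR while the "
      "scatter (std) grows as the noise share increases.")
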