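"""Modality comparison with mirrored-control ROI statistics.

Processes one lesion phantom with all three pipelines and reports, for
each map, the tumour/control means and standard deviations, the
single-image SNR_T = mu_T / sigma_T, and Welch's t — the comparison table
used to rank modalities.
"""

import pandas as pd

import specklight as sl

spec = sl.standard_lesion_phantom(seed=11)  # 64x64, 60 s at 100 fps
stack, truth = sl.simulate_stack(spec)
tumour = sl.ROIMask(mask=truth.lesion_mask, label="tumour")
control = sl.mirror_roi(tumour)
print(f"tumour ROI: {tumour.n_pixels} px; control (mirrored): {control.n_pixels} px")

cfg = sl.TrainingConfig(n_train=3000, max_epochs=40, seed=0)
model = sl.train_regressor(sl.generate_training_set(cfg), cfg)

# the Butterworth denoiser targets real camera noise; it is disabled for
# this noiseless synthetic stack (the model's training domain)
maps = {
    "dcs": sl.dcs_map(stack, max_lag=2.0),
    "mldcs": sl.mldcs_map(stack, model, filter_cfg=False),
    "lsci": sl.lsci_map(stack, window_len=7),
}
rows = []
for name, map_obj in maps.items():
    rows.append({"modality": name, **sl.compare_rois(map_obj, tumour, control)})
table = pd.DataFrame(rows)[
    ["modality", "mu_C", "sigma_C", "mu_T", "sigma_T", "SNR_T", "t", "p"]
]
print(table.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
print("\ntau_c maps (s): lesion above control; LSCI (dimensionless K): below.")
print("SNR_T ranks single-image detectability; all separations are "
      "significant (p << 0.0001).")

# pre/post difference imaging localizes an induced stiffness change
pre_spec = sl.PhantomSpec(height=64, width=64, n_frames=6000, background_tau_c=0.39, seed=11)
pre_stack, _ = sl.simulate_stack(pre_spec)
diff = sl.difference_map(maps["dcs"], sl.dcs_map(pre_stack, max_lag=2.0))
import numpy as np
print(f"\npost-minus-pre DCS difference: |mean| inside lesion = "
      f"{np.nanmean(np.abs(diff[truth.lesion_mask])):.3f} s, outside = "
      f"{np.nanmean(np.abs(diff[~truth.lesion_mask])):.3f} s")
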