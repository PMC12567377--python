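"""Generate a small synthetic multimodal dataset and verify its key
analytic property: a variance multiplier m on a (band, region) signature
shifts the differential entropy of the targeted entries by ln(m)/2 nats."""

import numpy as np

from mmha import SynthConfig, extract_de_features, synth_dataset
from mmha.topomap import default_layout, region_channels

config = SynthConfig(n_subjects=2, clips_per_emotion=2, clip_duration=10.0,
                     subject_gain_sd=0.0, seed=42)
ds = synth_dataset(config, face_size=64)
print(f"dataset: {len(ds.eeg_recordings)} EEG clips, "
      f"{len(ds.face_frames)} face frames, {len(ds.manifest)} windows")
print(ds.manifest.groupby('emotion').size().to_string())

# the 'fear' signature multiplies gamma-band variance over occipital sites by 4
layout = default_layout()
occipital = region_channels(layout, "occipital")
gamma = 4  # band order: delta, theta, alpha, beta, gamma
sig, bg = [], []
for rec in ds.eeg_recordings:
    de = extract_de_features(rec).values[:, occipital, gamma]
    (sig if rec.emotion == "fear" else bg).append(de)
shift = np.concatenate(sig).mean() - np.concatenate(bg).mean()
print(f"\nmeasured gamma/occipital DE shift for 'fear': {shift:.3f} nats")
print(f"analytic expectation ln(4)/2:                  {0.5 * np.log(4):.3f} nats")
print("-> the generator's class signal is exactly the amount predicted by "
      "the Gaussian entropy formula, so downstream stages can be tested "
      "against known ground truth.")
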