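"""Time-resolved cross-decoding of stimulus categories from simulated MEG.

Simulates a small MEG experiment (4 subjects, 8 exemplars per category),
reduces channels with PCA, and cross-decodes each category pair with a
leave-one-exemplar-out LDA classifier at three latencies.  Accuracies are
percent correct vs a 50% chance level; because train and test never share
exemplars, above-chance accuracy reflects category structure, not memorized
images.  Expect the illusory-vs-matched comparison to peak near 160 ms and
fall away by 260 ms, while human-vs-object decoding stays high.
"""

import numpy as np

import pareidolia as p
from pareidolia.preprocess import pca_reduce

cfg = p.SyntheticMEGConfig(
    n_subjects=4, n_channels=64, n_exemplars_per_category=8,
    n_runs=2, repeats_per_run=6, sample_rate_hz=100.0,
    epoch_ms=(-100.0, 390.0), seed=0,
)
epochs = [pca_reduce(ep) for ep in p.generate_meg_dataset(cfg)]
stimuli = p.make_stimulus_set(cfg.n_exemplars_per_category)
times = np.array([-50.0, 130.0, 160.0, 260.0])

print(f"{'comparison':<35}" + "".join(f"{t:>9.0f}ms" for t in times))
for pair in [("human_face", "matched_object"),
             ("human_face", "illusory_face"),
             ("illusory_face", "matched_object")]:
    res = p.decode_timecourse(epochs, stimuli, pair,
                              scheme="paired_exemplar", times_ms=times)
    label = f"{pair[0]} vs {pair[1]}"
    print(f"{label:<35}" + "".join(f"{a:>10.1f}" for a in res.group_mean))

print("\nValues are group-mean accuracies (%); 50 = chance. The pre-onset")
print("column should hover at chance; the illusory/matched column should be")
print("clearly above chance at 160 ms and much weaker at 260 ms.")
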