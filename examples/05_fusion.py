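"""fMRI-MEG fusion: when does the FFA-like representation appear in time?

Correlates each region's group fMRI RDM with every MEG subject's RDM at
every timepoint (Kendall tau-a, human faces removed), then marks
significant latencies with TFCE sign-flip permutation inference.  Only the
region profiles that separate illusory faces from matched objects (FFA,
OFA) should correlate with the MEG timecourse — briefly, around the
160 ms representational peak.
"""

import numpy as np

import pareidolia as p
from pareidolia.core import PatternMatrix, mean_rdm
from pareidolia.preprocess import pca_reduce
from pareidolia.rsa import compute_rdm, fusion_timecourse, rdm_timecourse
from pareidolia.stats import significant_windows, tfce_signperm_inference

cfg = p.SyntheticMEGConfig(
    n_subjects=8, n_channels=64, n_exemplars_per_category=8,
    n_runs=6, repeats_per_run=4, sample_rate_hz=100.0,
    epoch_ms=(-100.0, 390.0), yoke_offset_corr=0.0, seed=0,
)
meg = [pca_reduce(ep) for ep in p.generate_meg_dataset(cfg)]
meg_rdms = rdm_timecourse(meg)

fmri, stimuli = p.generate_fmri_dataset(
    n_subjects=16, n_runs=5, n_exemplars_per_category=8,
    yoke_offset_corr=0.0, seed=100,
)
fmri_rdms = {
    roi: mean_rdm([
        compute_rdm(PatternMatrix(d[roi].run_average(), d[roi].stimulus_ids))
        for d in fmri
    ])
    for roi in fmri[0]
}

fusion = fusion_timecourse(fmri_rdms, meg_rdms, stimuli)
for roi, mc in fusion.items():
    inf = tfce_signperm_inference(mc.tau, n_perm=500, seed=7)
    wins = significant_windows(inf.significant, mc.times_ms)
    peak = int(np.argmax(mc.group_mean))
    print(f"{roi:<5} peak tau-a {mc.group_mean[peak]:+.3f} at "
          f"{mc.times_ms[peak]:>5.0f} ms   significant windows: "
          f"{wins if wins else 'none'}")
print("\nFFA/OFA should show transient significant timepoints inside the")
print("injected signal epoch (~130-260 ms); LO/PPA, whose profiles carry no")
print("illusory/matched separation, should show none there. Isolated single-")
print("timepoint detections elsewhere occur at the designed 5% familywise rate.")
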