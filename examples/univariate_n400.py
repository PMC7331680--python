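"""Classic univariate N400 analysis on one simulated subject.

Averages the 9-channel centro-parietal ROI, runs pointwise t-tests from
150 ms with the autocorrelation-matched minimum-cluster-length correction,
and integrates the difference waveform over 300-800 ms.
"""

from n400kit import EffectSpec, Montage, RoiSpec, baseline_correct, simulate_subject, univariate_n400

montage = Montage.standard_64()
roi = RoiSpec()
channels = roi.channels + ("Fz", "Pz", "F3", "F4")

epochs, _ = simulate_subject(
    94,
    montage=montage,
    channels=channels,
    srate=128.0,
    seed=11,
    effect=EffectSpec(amplitude=-4.0, peak_latency=400.0, topography_center="Cz"),
)
epochs = baseline_correct(epochs)

out = univariate_n400(epochs, roi, n_sim=1000, seed=2)

print(f"difference-waveform lag-1 autocorrelation: {out['autocorr']:.3f}")
print(f"minimum significant cluster length: {out['min_cluster_len']} samples "
      f"({1000 * out['min_cluster_len'] / epochs.srate:.0f} ms)")
for start, end, length in out["clusters"].clusters:
    print(f"  cluster: {start:.0f}-{end:.0f} ms ({length} samples)")
print(f"significant N400 effect: {out['clusters'].significant}")
print(f"N400 area (congruent - incongruent, 300-800 ms): "
      f"{out['area_uVms']:.0f} uV.ms")
# A positive area means the incongruent condition was more negative over
# the N400 window, the expected direction for a semantic violation.
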