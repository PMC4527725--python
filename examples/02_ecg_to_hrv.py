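"""The full measurement chain: ECG -> R peaks -> ectopy screening -> HRV.

A noisy 1000 Hz single-lead ECG is synthesized from a tachogram with known
beat times, 5% of beats are replaced by ectopic couplets, and the chain
detects the R peaks, flags and repairs the ectopic intervals, and reports
time- and frequency-domain HRV on the cleaned window.
"""

import numpy as np

import shockhrv as sh

rri = sh.generate_rri_series(sh.RRIGenParams(
    mean_rr=800, lf_amp=20, hf_amp=10, noise_sd=10, duration=300, seed=42))
dirty = sh.inject_ectopy(rri, rate=0.05, magnitude=0.5, seed=42)
ecg = sh.generate_ecg(dirty, sh.ECGGenParams(
    sampling_rate=1000, baseline_noise_sd=0.1, seed=42))
print(f"ECG: {len(ecg.samples)} samples at {ecg.sampling_rate:.0f} Hz, "
      f"{len(ecg.true_beat_times)} true beats")

beats = sh.detect_r_peaks(ecg)
errs = np.abs(ecg.true_beat_times[:, None] - beats[None, :]).min(axis=1)
print(f"detected {len(beats)} beats; "
      f"sensitivity {100 * np.mean(errs <= 0.05):.1f}%, "
      f"max timing error {1000 * errs[errs <= 0.05].max():.1f} ms")

detected = sh.beats_to_rri(beats)
clean, report = sh.screen_ectopy(detected)
print(f"ectopy screen: {len(report.flagged_indices)} of {report.n_intervals} "
      f"intervals flagged ({100 * report.edit_fraction:.1f}%) and repaired")

res = sh.analyze_window(clean)
print(f"time domain: sdnn={res.time.sdnn:.1f} ms  rmssd={res.time.rmssd:.1f} ms")
print(f"frequency domain: lf={res.freq.lf_abs:.0f} ms²  hf={res.freq.hf_abs:.0f} ms²  "
      f"lf/hf={res.freq.lf_hf:.2f}")
print("Ectopy repair recovers the LF oscillation (injected: 200 ms²); the 10 ms "
      "white beat-to-beat noise adds broadband power that lands mostly in the "
      "wide HF band, on top of the injected 50 ms².")
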