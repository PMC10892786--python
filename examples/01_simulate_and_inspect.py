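"""Simulate one night of synthetic single-channel EEG and inspect it.

Builds a Markov-chain hypnogram with sticky stages, renders stage-dependent
EEG (α/β1 wake, θ N1, σ spindles + K-complexes in N2, large δ in SWS,
θ/β2 REM) and prints the per-stage δ/α/σ power profile. The printed powers
should mirror the stage physiology: δ dominant in SWS, α dominant in wake.
"""

import numpy as np

from somnoboost import simulate_subject
from somnoboost.features_spectral import band_power, welch_psd
from somnoboost.preprocess import DEFAULT_BANDS, bandpass, normalise, segment

rec, hyp = simulate_subject(n_epochs=120, preset="easy", seed=42, rec_id="DEMO")
print(f"subject {rec.id}: age {rec.age:.0f}, sex {rec.sex}, "
      f"{len(rec.samples)} samples at {rec.rate:.0f} Hz")

counts = {s: hyp.stages.count(s) for s in ("W", "N1", "N2", "SWS", "REM")}
print("stage counts over 120 epochs:", counts)

epochs = normalise(segment(bandpass(rec)))
bands = {b.name: b for b in DEFAULT_BANDS}
print("\nmean band power (normalised units) per stage:")
print(f"{'stage':>6} {'delta':>8} {'alpha':>8} {'sigma':>8}")
for stage in ("W", "N1", "N2", "SWS", "REM"):
    rows = [
        [band_power(welch_psd(ep), bands[k]) for k in ("delta", "alpha", "sigma")]
        for ep, s in zip(epochs, hyp.stages)
        if s == stage
    ]
    d, a, sg = np.mean(rows, axis=0)
    print(f"{stage:>6} {d:8.3f} {a:8.3f} {sg:8.3f}")

print("\nδ power should peak in SWS, α in wake, σ in N2 (spindles).")
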