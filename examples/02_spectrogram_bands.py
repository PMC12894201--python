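"""Lomb-Scargle spectrogram of a synthetic night and its band features.

Builds the 180 s / 175 s-overlap spectrogram of the cleaned R-R series and
compares the low-frequency band mass (0-0.04 Hz, the cyclical-variation
signature) between event-labeled and quiet windows.
"""

import sdbscreen as sdb
from sdbscreen.pipeline import extract_windows

record, truth = sdb.simulate_subject(
    sdb.SubjectParams(duration=3600.0, target_ahi=45.0, seed=7), subject_id="demo"
)

rr = sdb.clean_rr(
    sdb.build_rr(sdb.BeatSeries(record.beat_times, record.beat_times * 0 > 1))
)
spect = sdb.build_spectrogram(rr, record_duration=3600.0)
print(f"windows          : {spect.n_windows} ({int(spect.valid.sum())} valid)")
print(f"grid resolution  : {spect.grid.resolution:.5f} Hz "
      f"(reported as ~{spect.grid.resolution_rounded})")

table = extract_windows(record)
valid = table[table["valid"]]
low = valid["b01"] + valid["b02"]
print(f"0-0.04 Hz mass   : event windows {low[valid['label'] == 1].mean():.3f}  "
      f"vs quiet windows {low[valid['label'] == 0].mean():.3f}")

# Each valid window's spectrum is normalized to sum to 1 over the grid, so
# band masses are relative-power fractions.  The event-locked bradycardia/
# tachycardia cycle at ~0.02 Hz concentrates mass in the two lowest bands,
# which is exactly what the window classifier exploits.
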