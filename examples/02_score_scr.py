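"""Render one continuous skin-conductance recording and score it.

Shows the full signal path: biexponential response waveforms + noise +
50 Hz mains -> zero-phase low-pass + notch filtering -> trough-to-peak
amplitudes -> log + range-corrected values.
"""

from dataclasses import replace

from fearcond import SimulationConfig, generate_cohort, score_recording, transform_amplitudes

cfg = replace(SimulationConfig(), n=1)
cohort = generate_cohort(cfg, seed=2, ratings=False)
recording = cohort.render_recording(0)
print(f"recording: {recording.duration:.0f} s at {recording.sampling_rate:.0f} Hz")

table = score_recording(recording, cohort.schedule)  # filters, then scores TTP
table = transform_amplitudes(table)
print(table.head(8).to_string(index=False))
print(f"\nnon-responses (scored 0): {(~table['response']).sum()} of {len(table)}")
print("raw column is in microsiemens; transformed is log10(1+x) divided by "
      "the participant's maximum, so the largest response is exactly 1.")
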