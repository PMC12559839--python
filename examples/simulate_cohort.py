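"""Simulate one participant's bilateral LFP recordings and export them.

Generates a session per hemisphere on a 1/f background with task-graded
band effects (theta increase during speech, beta decrease before sentence
onset), then writes EDF signals plus CSV and TextGrid annotations.
"""

from pathlib import Path

from speechlfp import (
    SynthConfig,
    generate_session,
    write_edf,
    write_events_csv,
    write_textgrid,
)

out = Path("example_output")
out.mkdir(exist_ok=True)

config = SynthConfig(n_participants=1, trials_per_task=30, seed=42)
for hemisphere in ("left", "right"):
    session, events, truth = generate_session(config, "P01", hemisphere,
                                              seed=1 if hemisphere == "left" else 2)
    write_edf(session, out / f"P01_{hemisphere}.edf")
    write_events_csv(events, out / f"P01_{hemisphere}_events.csv")
    write_textgrid(events, out / f"P01_{hemisphere}_events.TextGrid")
    print(f"{hemisphere:5s}: {session.n_samples} samples at "
          f"{session.sampling_rate_hz:.0f} Hz on {len(session.channels)} contacts, "
          f"{len(events)} trials over {session.duration_s:.0f} s")
    print("      injected effects (dB):")
    print(truth.effects.to_string(index=False))

# The effects table is the ground truth the downstream pipeline should
# recover: positive theta dB during speech graded by task complexity,
# negative beta dB before sentence onset.
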