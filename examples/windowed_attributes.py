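"""Windowed attribute profile of a synthetic transcript.

Attributes are computed on 30-word moving windows with a 15-word step and
averaged, so subjects who talk more are not scored as more diverse merely
for producing a bigger graph.
"""

import wordgraphs as wg

params = wg.GeneratorParams(theta_new=0.4, theta_persev=0.15,
                            theta_return=0.15, length=150, seed=3)
transcript = wg.Transcript("demo", wg.generate_transcript(params),
                           wg.Group.CONTROL, age_years=25.0,
                           education_years=12.0)

profile = wg.windowed_profile(transcript)
print(f"{profile.n_windows} windows of {profile.window_length} words, "
      f"step {profile.step}")
print(f"{'window':>6} {'N':>4} {'RE':>4} {'LSC':>4} {'ASP':>7}")
for i, a in enumerate(profile.per_window):
    print(f"{i:>6} {a.N:>4} {a.RE:>4} {a.LSC:>4} {a.ASP:>7.3f}")
m = profile.mean_attributes
print(f"{'mean':>6} {m.N:>4.1f} {m.RE:>4.1f} {m.LSC:>4.1f} {m.ASP:>7.3f}")
print()
print("The means are the subject-level summary used by every downstream "
      "correlation and fit.")
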