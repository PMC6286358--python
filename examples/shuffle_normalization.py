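"""Distance from random word order via shuffle normalization.

Each 30-word window is shuffled 100 times (same words, new order); the
observed attribute divided by the shuffled average measures how far the
discourse structure is from what random ordering of the same words would
give. Two transcripts are compared that differ only in how often the
speaker loops back to earlier words (the long-range return dial); the
normalized largest-strongly-connected-component separates them, while
normalized N is exactly 1 for both because shuffling never changes which
words a window contains.
"""

import wordgraphs as wg


def make(subject_id, theta_return, seed):
    params = wg.GeneratorParams(theta_new=0.3, theta_persev=0.2,
                                theta_return=theta_return, length=150,
                                seed=seed)
    return wg.Transcript(subject_id, wg.generate_transcript(params),
                         wg.Group.CONTROL, age_years=30.0,
                         education_years=12.0)


linear = make("linear", theta_return=0.02, seed=5)
looping = make("looping", theta_return=0.35, seed=6)

for t in (linear, looping):
    na = wg.shuffle_normalize(t, n_shuffles=100, seed=11)
    print(f"{t.subject_id:>8}: norm_N = {na.norm_N:.3f}  "
          f"norm_RE = {na.norm_RE:.3f}  norm_LSC = {na.norm_LSC:.3f}  "
          f"norm_ASP = {na.norm_ASP:.3f}  ({na.n_windows} windows)")

print()
print("The looping speaker's norm_LSC sits clearly above the linear "
      "speaker's: returning to earlier words builds more mutual "
      "reachability than random order produces, which is the structural "
      "signature of connected discourse.")
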