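"""Path choice at a Y-junction under chemotactic bias.

Drives a cell down a loading stem into a junction with two 10-um arms and
scores the whole-cell entry rule (every membrane bead at least 5 um past
the arm mouth).  Repeats over a few seeds and reports the choice split.
At the default calibration and these short horizons cells typically reach
the junction and straddle the splitter without completing an entry, so
expect censored runs (see the limitations section of docs/methods.md).
"""

from mtcrosstalk import analysis as an
from mtcrosstalk.experiments import channel_run, y_junction_env

env = y_junction_env(w_left=10.0, w_right=10.0)
entries = []
for seed in range(4):
    entry, t_entry, track = channel_run(env, lmt=9.3, Nmt=100, seed=seed,
                                        t_max=2500.0)
    status = f"entered '{entry}' at t = {t_entry:.0f} s" if entry \
        else "did not commit to an arm"
    print(f"seed {seed}: {status}")
    entries.append((entry, t_entry))

print()
print(an.channel_choice_stats(entries).to_string(index=False))
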