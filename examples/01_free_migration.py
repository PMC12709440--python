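"""Free 2D migration of a single cell.

Runs the whole-cell model in open space with regular microtubules
(mean length 9.3 um, 100 filaments), then summarizes the trajectory:
net displacement, MSD scaling exponent, and the polarity angle between
the migration direction and the nucleus-to-centrosome axis (theta < 90
degrees means the centrosome leads).
"""

import numpy as np

from mtcrosstalk import Params, simulate
from mtcrosstalk import analysis as an

params = Params(lmt_target=9.3, Nmt=100, seed=1, t_total=900.0)
track, state = simulate(params)

xy = track[["x", "y"]].to_numpy()
disp = float(np.hypot(*(xy[-1] - xy[0])))
alpha, _ = an.fit_msd_exponent(an.msd(track), tau_range=(15.0, 200.0))
theta = an.polarity_angle(track)
lp, lower_bound = an.persistence_length(track)

print(f"simulated {track['t'].iloc[-1]:.0f} s, {len(track)} frames")
print(f"net centroid displacement: {disp:.1f} um")
print(f"MSD exponent alpha = {alpha:.2f}  (2 = ballistic, 1 = diffusive)")
print(f"fraction of frames with the centrosome leading (theta < 90 deg): "
      f"{np.mean(theta < 90):.2f}")
note = " (lower bound)" if lower_bound else ""
print(f"persistence length Lp = {lp:.1f} um{note}")
print(f"final area ratio A/A0 = "
      f"{track['area'].iloc[-1] / (np.pi * params.Rcell ** 2):.2f}, "
      f"aspect ratio = {track['aspect_ratio'].iloc[-1]:.2f}")
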