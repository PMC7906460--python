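"""Map alignment on a single frame of a milling school.

Builds one synthetic milling frame, constructs the spatial-proximity and
velocity-profile distance matrices, turns each into a diffusion basis, and
prints the map alignment statistic in both directions together with the
analytic null the statistic is standardized against.
"""

import numpy as np

from mapalign import (
    MetricConfig,
    RegimeSpec,
    gknn_kernel,
    make_regime,
    map_alignment_statistic,
    normalize_to_markov,
    null_model,
    spectral_decompose,
)
from mapalign.metrics import (
    TrajectoryWindow,
    position_distance_matrix,
    velocity_profile_distance_matrix,
)

rng = np.random.default_rng(0)
seg = make_regime(RegimeSpec(regime="milling", n=120, duration=80), rng)

frame = 79
cfg = MetricConfig(window=10, tau=5.0)
window = TrajectoryWindow(
    frame=frame,
    positions=seg.positions[frame - 9 : frame + 1][::-1],
    velocities=seg.velocities[frame - 9 : frame + 1][::-1],
)

d_space = position_distance_matrix(seg.positions[frame])
d_vel = velocity_profile_distance_matrix(window, cfg)

bases = [
    spectral_decompose(normalize_to_markov(gknn_kernel(d, k_nn=7)))
    for d in (d_space, d_vel)
]

k = 15
forward = map_alignment_statistic(bases[0], bases[1], k)
reverse = map_alignment_statistic(bases[1], bases[0], k)
nm = null_model(forward.n, k)

print(f"milling frame with n = {forward.n} fish, subspace size k = {k}")
print(f"Z(position, velocity) = {forward.z:.2f}")
print(f"Z(velocity, position) = {reverse.z:.2f}")
print(f"null per-mode squared projection: mean {nm.mean:.4f}, sd {nm.variance**0.5:.4f}")
print(
    "Each Z sums k standardized projections that are centered with unit\n"
    "variance when the two geometries are unrelated, so values this far\n"
    "above ~0 mean the spatial arrangement and the recent velocity profiles\n"
    "of the fish organize the school along the same macro-scale lines —\n"
    "exactly what circling motion produces."
)
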