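"""Choosing the subspace size k from the decay of diffusion spectra.

The head of a diffusion spectrum carries macro-scale structure; the bulk
decays like a power law. This script collects spectra from several frames
of a polarized school segment and applies the tail-fit heuristic, printing
the suggested k and its diagnostics.
"""

import numpy as np

from mapalign import (
    MetricConfig,
    RegimeSpec,
    gknn_kernel,
    make_regime,
    normalize_to_markov,
    spectral_decompose,
    suggest_k,
)
from mapalign.metrics import TrajectoryWindow, velocity_profile_distance_matrix

rng = np.random.default_rng(5)
seg = make_regime(RegimeSpec(regime="polarized-single", n=150, duration=120), rng)

cfg = MetricConfig(window=10, tau=5.0)
spectra = []
for frame in range(20, 120, 20):
    window = TrajectoryWindow(
        frame=frame,
        positions=seg.positions[frame - 9 : frame + 1][::-1],
        velocities=seg.velocities[frame - 9 : frame + 1][::-1],
    )
    d = velocity_profile_distance_matrix(window, cfg)
    basis = spectral_decompose(normalize_to_markov(gknn_kernel(d, k_nn=7)))
    spectra.append(basis.eigenvalues[:40])

suggestion = suggest_k(spectra)
print(f"suggested subspace size k = {suggestion.k} "
      f"(converged: {suggestion.converged})")
print(f"fitted tail power law: {suggestion.coefficient:.3f} * j^-{suggestion.exponent:.2f}")
stable = suggestion.stable_fraction_modes
print(f"modes with frame-stable variance fractions: {int(stable.sum())} of {stable.size}")
print(
    "Modes past the suggested cut follow the fitted power law and explain a\n"
    "stable fraction of the spectrum across frames — the signature of noise\n"
    "rather than macro-scale organization. Overshooting k is harmless: the\n"
    "extra summands of the alignment statistic are near-independent of the\n"
    "leading modes, so Z_k stabilizes."
)
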