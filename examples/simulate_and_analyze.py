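"""Simulate two fiber fields and measure their alignment.

Renders a strongly aligned (κ=100) and an isotropic (κ=0) synthetic
trichrome-like image, runs the full CIELAB → enhancement → Fourier chain,
and compares the image-domain coefficient with the ground-truth circular
resultant of the sampled fiber angles.
"""

import numpy as np

from fibralign import FiberFieldParams, analyze_image, generate_fiber_image, true_alignment

for name, kappa in [("aligned (κ=100)", 100.0), ("isotropic (κ=0)", 0.0)]:
    params = FiberFieldParams(image_size=512, n_fibers=250,
                              mean_orientation=np.pi / 3,
                              concentration=kappa, noise_sd=3.0, seed=7)
    image, truth = generate_fiber_image(params)
    res = analyze_image(image)
    oracle = true_alignment(truth.orientations)
    print(f"{name:18s} coefficient={res.coefficient:.3f} "
          f"(ground truth {oracle:.3f})  "
          f"orientation={np.degrees(res.dominant_orientation):6.1f}°  "
          f"density={res.density:.3f}")

print("\nThe coefficient is the energy-weighted circular resultant on doubled")
print("angles: ~1 for parallel fibers, ~0 for random ones. The dominant")
print("orientation should sit near the simulated mean axis (60°) for the")
print("aligned field; density is the fraction of enhanced non-zero pixels.")
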