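"""Coarse grid search selecting the `synthetic` hyperparameter preset.

The published scanner presets are tuned to that scanner's forward-operator
scaling; the bundled simulator has its own, so the default weights for
synthetic runs are chosen here once, on a tuning scenario (shell phantom,
sparse 45-view acquisition, fabricated half-size+blur prior, seed 7) that is
disjoint from the seeds used anywhere else.  Only the overall weight ratios
matter (K u = r is scale invariant), so mu is fixed at 1 and lam, alpha,
gamma are searched.  Run from the repository root:

    python scripts/tune_defaults.py
"""

import itertools
import time

import numpy as np

from picdl.geometry import parallel_geometry, fbp_reconstruct
from picdl.l2piccs import Hyperparameters, reconstruct_l2piccs
from picdl.metrics import psnr
from picdl.polysim import (
    PriorSpec,
    SamplingScheme,
    attenuation_image,
    fabricate_prior,
    make_phantom,
    project_monochromatic,
    subsample_projections,
    toy_spectrum,
)

N = 128
SEED = 7

ph = make_phantom("shell_skull", N, 0.5, seed=SEED)
spec1 = toy_spectrum(1)
target = attenuation_image(ph, spec1, 0)
geom_full = parallel_geometry(N, 0.5)
sino_full = project_monochromatic(ph, geom_full, 0, spec1)
sino = subsample_projections(
    sino_full, SamplingScheme("LNP", count_range=(45, 45), seed=SEED)
)
geom = geom_full.with_angles(sino.angles)
prior = fabricate_prior(target, PriorSpec(blur_sigma=1.0, seed=SEED))
fbp_img = fbp_reconstruct(sino, geom)
print(f"FBP PSNR {psnr(fbp_img, target):.2f} dB, prior PSNR {psnr(prior, target):.2f} dB")

best = None
for lam, alpha, gamma in itertools.product(
    [2.0, 5.0, 10.0, 20.0, 50.0], [0.3, 0.5, 0.9], [0.5, 1.0, 2.0]
):
    hp = Hyperparameters(mu=1.0, lam=lam, alpha=alpha, gamma=gamma, n_outer=30)
    t0 = time.time()
    rec, _ = reconstruct_l2piccs(sino, geom, prior, hp)
    p = psnr(rec, target)
    print(f"lam={lam:5g} alpha={alpha} gamma={gamma}: {p:6.2f} dB ({time.time()-t0:.1f}s)")
    if best is None or p > best[0]:
        best = (p, lam, alpha, gamma)

print(f"\nbest: lam={best[1]}, alpha={best[2]}, gamma={best[3]} -> {best[0]:.2f} dB")
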