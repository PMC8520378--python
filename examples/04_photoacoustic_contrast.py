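"""The three-arm contrast-enhancement experiment on synthetic A-lines.

Simulates pre/post-irradiation photoacoustic A-lines for a targeted
phase-change contrast agent (AP_GNP, echo amplitude x3 after the laser
pulse), blank nanoparticles (NP, no enhancement) and a water control
(no absorbers), then compares mean signal energies.
"""

import numpy as np

from pacsense import PhantomConfig, simulate_contrast_experiment

cfg = PhantomConfig()  # 3 absorbers at 9/15/22.5 mm, noise sigma 0.02
print(f"{'group':<8} {'pre energy':>12} {'post energy':>12} {'post/pre':>9}")
for group in ("AP_GNP", "NP", "water"):
    pre_e, post_e = [], []
    for seed in range(50):
        exp = simulate_contrast_experiment(cfg, group,
                                           enhancement_factor=3.0, seed=seed)
        pre_e.append(np.mean(exp.pre.samples ** 2))
        post_e.append(np.mean(exp.post.samples ** 2))
    pre_m, post_m = np.mean(pre_e), np.mean(post_e)
    print(f"{group:<8} {pre_m:>12.5f} {post_m:>12.5f} {post_m / pre_m:>9.2f}")
print()
print("Only the targeted agent shows the post-irradiation energy jump")
print("(~9x for a 3x amplitude enhancement); blanks are unchanged and the")
print("water arm carries nothing but acquisition noise.")
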