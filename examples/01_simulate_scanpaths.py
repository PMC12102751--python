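"""Simulate scan paths for one individual and summarise their microstructure.

Builds a 32-trial session (5-s two-picture trials) in the
strong-target-differentiation regime (lam1 = 1.4 > lam2 = lam3 = 1.1),
then prints the fixation-duration and transition statistics the model
produces. The target advantage in looking proportion and the longer
target fixation durations (via the activation-modulated gamma timing)
are the model's two signature effects.
"""

import numpy as np

from lookdyn import AOI_LABELS, ModelParams, simulate_individual, summarize

params = ModelParams()  # lam=(1.4, 1.1, 1.1), mu_t=200 ms, gamma=0.5, ...
session = simulate_individual(params, n_trials=32, seed=11)

first = session.scan_paths[0]
print(f"trial 1: {len(first)} fixations")
for f in first.fixations[:5]:
    print(f"  {AOI_LABELS[f.aoi]}  onset {f.onset_ms:7.1f} ms  "
          f"duration {f.duration_ms:6.1f} ms")
print("  ...")

s = summarize(session.scan_paths)
print(f"\nfixations in session:        {s.n_fixations}")
print(f"mean fixation duration:      {s.mean_fixdur_all:.1f} ms")
print("mean duration by AOI (T/D/M):",
      " / ".join(f"{d:.1f}" for d in s.mean_fixdur_by_aoi), "ms")
print(f"proportion target looking:   {s.prop_target_looking:.3f}")
print(f"refixation rate:             {s.refixation_rate:.3f}")
print("transition matrix (rows = from T/D/M):")
with np.printoptions(precision=3, suppress=True):
    print(s.transition_matrix)

print("\nTarget fixations last longest because each target fixation "
      "multiplies the target's activation by lam1=1.4, and the gamma "
      "timing mean grows with activation (gamma=0.5).")
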