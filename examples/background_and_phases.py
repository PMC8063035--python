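"""Background estimation and phase assignment on simulated counts.

Draws counts from the two-phase model (cell-specific zero-inflated Poisson
background, lognormal-Poisson active phase), then recovers the per-cell
background parameters and the latent phase of every observation. Printed
errors show how close the estimates come to the generative truth.
"""

import numpy as np

import sc2pnorm as sp

truth = sp.simulate(sp.SimConfig(
    n_genes=5_000, n_cells=30,
    bg_p0_range=(0.2, 0.4), bg_lam_range=(0.7, 1.5), seed=8,
))

bg = sp.estimate_background(truth.cm)
print("per-cell ZIP background (first 5 cells):")
print("  p0_hat :", np.round(bg.p0[:5], 3), " truth:", np.round(truth.p0[:5], 3))
print("  lam_hat:", np.round(bg.lam[:5], 3), " truth:", np.round(truth.lam[:5], 3))

fit = sp.em_fit(truth.cm, bg)
est = fit.estimable
rmse = np.sqrt(np.nanmean((fit.mu[est] - truth.mu[est]) ** 2))
calls = sp.phase_call(fit, 0.5)
acc = (calls == (truth.Z == 1)).mean()
print(f"EM converged in {fit.n_iter} iterations "
      f"(log-likelihood strictly non-decreasing: "
      f"{bool(np.all(np.diff(fit.loglik_trace) >= -1e-6))})")
print(f"mu recovery RMSE: {rmse:.3f} (log scale)")
print(f"phase-call accuracy vs truth: {acc:.4f}")
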