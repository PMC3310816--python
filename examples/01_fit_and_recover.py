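"""Fit the multiple-site model to a simulated SPOT array and recover the truth.

Simulates one domain's array (1,000 peptides of 13-14 residues, a hidden
6-residue energy table, 0.1 RT noise), fits the MS model, and compares the
fitted J table with the generating one.
"""

import numpy as np

from msbind import FitConfig, SimConfig, fit_ms, simulate

dataset = simulate(SimConfig(seed=7))
print(f"simulated {len(dataset.records)} spots; "
      f"first: {dataset.records[0].peptide.sequence} "
      f"E={dataset.records[0].pseudo_energy:+.3f} RT")

fit = fit_ms(dataset.records, S=6, config=FitConfig(n_restarts=3, seed=0))
recovered = fit.model.reparameterized(dataset.truth.params.profile)
r = np.corrcoef(dataset.truth.params.J.ravel(),
                recovered.params.J.ravel())[0, 1]

print(f"SSE {fit.sse:.2f} over {len(fit.record_ids)} records "
      f"(winning restart {fit.restart_index})")
print(f"alpha fitted {recovered.alpha:.2f} vs true {dataset.truth.alpha:.2f} "
      f"(expressed against the truth's reference profile)")
print(f"Pearson r(true J, fitted J) = {r:.3f}")
# SSE near n * noise_sd^2 (~10) and r > 0.99 mean the 114-term energy table
# is recovered almost exactly from 1,000 noisy spot intensities.
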