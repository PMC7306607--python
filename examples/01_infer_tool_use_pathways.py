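"""Infer tool-use acquisition orderings from the packaged catalogue.

Builds convergent transition observations from the packaged 22-mode trait
matrix, runs a short pseudo-marginal MCMC chain, and prints each mode's
posterior mean acquisition step with its early/late class (1 = earliest
quartile, 4 = latest) and bimodality flag.  Desk-scale settings: a real
analysis would raise the iteration and path counts.
"""

import numpy as np

import hypertraps as ht

matrix = ht.load_packaged_matrix()
print(f"{len(matrix.taxa)} taxa x {matrix.n_modes} modes "
      f"(first mode: {matrix.modes[0]})")

obs = ht.transitions_convergent(ht.binarize(matrix))
cfg = ht.ChainConfig(n_iterations=3000, burn_in=1500, thin=10,
                     n_paths=50, proposal_scale=0.02, seed=1)
posterior = ht.run_chain(obs, cfg)
print(f"chain acceptance rate: {posterior.acceptance_rate:.2f}")

om = ht.ordering_matrix(posterior, 20, np.random.default_rng(2),
                        mode_names=matrix.modes)
classes = ht.classify_modes(om).sort_values("mean_step")
print("\nmode            mean step  class  bimodal")
for mode, row in classes.iterrows():
    print(f"{mode:<15s} {row.mean_step:9.2f} {int(row['class']):6d}  "
          f"{'*' if row.bimodal else ''}")
print("\nlow mean step = typically acquired early on an evolutionary "
      "lineage; '*' marks modes whose ordering is bimodal (two distinct "
      "pathway types).")
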