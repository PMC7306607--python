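"""Recover two competing evolutionary pathways from synthetic data.

Simulates taxa whose trait patterns come from two mutually suppressing
pathway regimes, re-infers the dynamics with MCMC, and checks that the
posterior reproduces the generator: bimodal ordering rows, a pathway graph
that splits into branch components pure in pathway membership, and a mean
acquisition order matching the generating paths.  This is a scaled-down
version of the package's full recovery benchmark
(hypertraps.experiments.two_pathway_recovery).
"""

from hypertraps import experiments

result = experiments.two_pathway_recovery(seed=1, n_iterations=10_000)
print(f"bimodal ordering rows: {result['bimodal_modes']}/{result['n_modes']}")
print(f"pathway-graph branch components (empty/full states removed): "
      f"{result['branch_components']}, pure in pathway membership: "
      f"{result['branches_pure']}")
print(f"observed states from both taxon groups on branches: "
      f"{result['both_groups_observed']}")
print(f"Spearman(posterior mean order, generating mean order) = "
      f"{result['spearman_vs_truth']:.3f}")
print("\nvalues near 1 mean the chain recovered the generating dynamics; "
      "bimodality is the signature of coexisting pathways.")
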