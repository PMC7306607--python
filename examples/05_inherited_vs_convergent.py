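"""Compare the two limiting treatments of traits shared across clades.

Simulates trait evolution along a random taxonomy (genuine inheritance),
then infers acquisition orderings twice: once attributing shared traits to
reconstructed common ancestors (one transition per tree edge) and once
treating every taxon as an independent convergent acquisition from the
toolless state.  Agreement between the two posteriors means downstream
conclusions do not hinge on the unknown true inheritance pattern.
"""

from hypertraps import experiments

result = experiments.limiting_case_consistency(seed=1, n_iterations=8000)
print(f"convergent observations: {result['n_convergent_obs']} (one per taxon)")
print(f"inherited observations:  {result['n_inherited_obs']} (one per tree edge)")
print(f"Spearman between ordering matrices: {result['spearman']:.3f}")
print(f"mean total-variation distance per mode: "
      f"{result['mean_total_variation']:.3f}")
print("\na Spearman near 1 shows the inferred acquisition order is stable "
      "across the two extreme inheritance assumptions.")
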