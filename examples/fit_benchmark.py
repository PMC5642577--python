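"""Fit the bilinear model on the bundled 90-peptide HLA-A*0201 training set.

Starts the alternating solver from equal fragment weights (B = 1) and
prints the convergence trace endpoints: the correlation R between fitted
and experimental pIC50 rises from ~0.41 on the first property step to
~0.89 at convergence, while the RMS residual Q falls to ~0.37 log units.
"""

import tlpca

bench = tlpca.builtin_benchmark()
tensor = tlpca.encode_peptides(bench.training, bench.property_table)
model, trace = tlpca.fit(tensor)

print(f"samples: {tensor.n_samples}, fragments: {len(tensor.fragment_labels)}, "
      f"properties: {len(tensor.property_names)}")
print(f"converged: {model.converged} after {model.n_iterations} iterations")
print(f"first property-step R = {trace.r_a[0]:.4f}")
print(f"final training     R = {trace.r_b[-1]:.4f}, Q = {trace.q_b[-1]:.4f}")
print("\nproperty coefficients a_k:")
for name, a in zip(model.property_names, model.A):
    print(f"  {name:8s} {a:+.5f}")
print("position coefficients b_l:")
for label, b in zip(model.fragment_labels, model.B):
    print(f"  {label:10s} {b:+.5f}")
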