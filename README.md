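# tlpca — two-level PCA for fragment-based bioactivity modelling

`tlpca` fits a bilinear *fragment × property* model of molecular
bioactivity. A molecule is split into L structural fragments (for a
nonamer peptide: the nine side chains), each fragment is described by K
physicochemical properties, and the bioactivity of sample *i* is

```
w_i = Σ_l b_l · ( Σ_k a_k · x_{i,l,k} )
```

with one coefficient per property (`a_k`, shared across fragments) and one
per fragment position (`b_l`, shared across properties). The coefficients
are fitted by alternating least squares: with B fixed, the N×L×K descriptor
tensor X collapses to a property matrix **F** = X·B and A solves the normal
system (FᵗF)A = FᵗW; with A fixed it collapses to a fragment matrix
**H** = X·A and B solves (HᵗH)B = HᵗW. Each normal system is inverted
through a symmetric eigendecomposition with small eigenvalues truncated.
At convergence, eigen-decomposing V = FᵗF and U = HᵗH yields normalized
eigenvalue shares and eigenvalue-weighted squared loadings — the
contribution γ of each property and λ of each fragment position to the
modelled activity — plus per-sample projections and contributions.

The package is aimed at QSAR / peptide-drug-design work where both *which
chemistry* and *which position* matter. It ships the published benchmark of
nonamer epitope peptides binding the human MHC class I allele HLA-A\*0201:
an 8-property × 20-amino-acid scale table, 90 training and 40 independent
test peptides with experimental pIC50, and the published converged
coefficient vectors as a reference model.

## Worked example

```python
import tlpca

bench = tlpca.builtin_benchmark()
tensor = tlpca.encode_peptides(bench.training, bench.property_table)
model, trace = tlpca.fit(tensor)
print(f"R first step {trace.r_a[0]:.4f} -> converged {trace.r_b[-1]:.4f}")

test = tlpca.encode_peptides(bench.testing, bench.property_table)
print(f"independent test r = {tlpca.pearson_r(tlpca.predict(model, test), test.W):.4f}")

result = tlpca.analyze_model(model, tensor)
print(f"leading property eigen share = {result.property_report.eigenvalues_normalized[0]:.5f}")
print(result.per_property.round(5).to_string())
```

prints

```
R first step 0.4117 -> converged 0.8859
independent test r = 0.8671
leading property eigen share = 0.99165
Lip        0.00003
Hyd        0.00000
S_L        0.20203
S_H        0.00096
P_alpha    0.00003
P_beta     0.00005
P_c        0.00001
Vol        0.78853
```

Training correlation rises from 0.41 (equal fragment weights) to 0.89 at
convergence; the model generalises to the 40 held-out peptides at r = 0.87.
The property-side spectrum is dominated by one component, and side-chain
volume (γ ≈ 0.79) plus lipophilic surface area (γ ≈ 0.20) carry nearly all
of the modelled activity, while the nine sequence positions contribute
almost equally (λ ≈ 0.10–0.12 each). The `examples/` scripts walk through
fitting, prediction, contribution analysis and synthetic-data recovery one
capability at a time.

## Command line

```
tlpca train   --dataset peptides.csv --out run/
tlpca predict --model run/model.json --dataset new_peptides.fasta --out pred.csv
tlpca analyze --model run/model.json --dataset peptides.csv --out analysis/
tlpca simulate --n 200 --seed 1 --out sim/
tlpca export-fixtures --out fixtures/
```

Peptide datasets are `id,sequence[,activity]` CSV or FASTA; non-peptide
molecules enter as long-format descriptor tensors
(`sample_id,fragment,property,value[,activity]`). Exit codes: 0 success,
2 input/validation error, 3 numerical failure.

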