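{
 "schema_version": 1,
 "property_names": [
  "Lip",
  "Hyd",
  "S_L",
  "S_H",
  "P_alpha",
  "P_beta",
  "P_c",
  "Vol"
 ],
 "fragment_labels": [
  "Residue-1",
  "Residue-2",
  "Residue-3",
  "Residue-4",
  "Residue-5",
  "Residue-6",
  "Residue-7",
  "Residue-8",
  "Residue-9"
 ],
 "A": [
  -0.02445,
  0.19258,
  -0.00212,
  0.00348,
  0.15367,
  0.07823,
  0.19764,
  0.00366
 ],
 "B": [
  2.53268,
  8.36712,
  3.06856,
  -4.89559,
  3.12686,
  2.45367,
  1.24669,
  -3.50416,
  -3.79249
 ],
 "n_iterations": null,
 "converged": true,
 "provenance": "published converged coefficients for the HLA-A*0201 benchmark"
}
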