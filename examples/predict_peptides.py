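"""Predict binding affinities of new nonamer peptides.

Encodes sequences with the bundled 8-property amino-acid table and
evaluates the published coefficient vectors. Output is predicted pIC50
(-log10 IC50): higher means stronger predicted binding to HLA-A*0201.
"""

import tlpca

bench = tlpca.builtin_benchmark()
peptides = [
    tlpca.PeptideRecord("strong-binder", "ILWQVPFSV"),   # measured pIC50 8.770
    tlpca.PeptideRecord("weak-binder", "VALVGLFVL"),     # measured pIC50 5.148
    tlpca.PeptideRecord("novel", "KLMEYGWSV"),
]
tensor = tlpca.encode_peptides(peptides, bench.property_table)
for rec, value in zip(peptides, tlpca.predict(bench.reference_model, tensor)):
    print(f"{rec.id:15s} {rec.sequence}  predicted pIC50 = {value:.3f}")
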