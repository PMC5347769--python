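"""Quantify knockdown efficiency from qPCR Ct values (Pfaffl method).

Relative expression = E_target^dCt_target / E_ref^dCt_ref with
dCt = Ct(control) - Ct(knockdown), normalized to the HPRT1 reference
gene. Control expression is 1 by construction; the planted knockdown
leaves 34% residual mRNA.
"""

import bilineage as bl

table = bl.generate_qpcr_table({"ERN1": 0.34}, n_samples=6,
                               noise_sd=0.15, seed=3)
print(table.head(4).to_string(index=False))

result = bl.pfaffl_from_table(table, "ERN1", reference_gene="HPRT1")
print(f"\nrelative ERN1 expression after knockdown: "
      f"{result.ratio:.3f} +/- {result.sem:.3f} "
      f"(n = {result.n_knockdown} knockdown replicates)")
print(f"single measurement, perfect efficiency, 1 cycle later: "
      f"{bl.pfaffl_ratio(24.0, 25.0, 20.0, 20.0):.2f}")
# 0.34 means 66% of the target mRNA was depleted relative to the
# HPRT1-normalized control; the +/- is the delta-method SEM from the
# replicate Ct spread.
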