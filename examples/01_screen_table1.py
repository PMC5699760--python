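"""Screen the packaged dimorphic-DMET table at two fold-change thresholds.

The package ships a 77-gene table of sex-dimorphic drug-metabolizing enzyme
and transporter (DMET) genes (gene symbol, t-test P-value, linear fold
change, biased sex). This script loads it, applies the strict screening rule
(P < p_max AND FC > fc_min) at the two conventional thresholds, and prints
the ranked results.
"""

from hepatodimorph import load_table1_fixture, screen

records = load_table1_fixture()
print(f"fixture: {len(records)} dimorphic DMET genes\n")

strong = screen(records, p_max=0.05, fc_min=1.5)
print(f"P < 0.05 and FC > 1.5 -> {len(strong)} genes:")
for rank, r in enumerate(strong, start=1):
    print(f"  {rank:2d}. {r.gene_id:8s} FC {r.fold_change:4.2f} "
          f"({r.bias}-biased, P = {r.p_value:.2e})")

broad = screen(records, p_max=0.05, fc_min=1.1)
n_f = sum(r.bias == "F" for r in broad)
n_m = sum(r.bias == "M" for r in broad)
print(f"\nP < 0.05 and FC > 1.1 -> {len(broad)} genes "
      f"({n_f} female-biased, {n_m} male-biased)")
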