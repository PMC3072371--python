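"""Mixed-model genome scan on a synthetic inbred panel.

Simulates the default panel (100 strains, 9 replicates each, a causal
coding SNP explaining 15% of strain-mean variance), runs the REML
mixed-model scan with leave-one-chromosome-out kinship, and prints the
top associations next to the planted truth.
"""

import logging

from strainmap import mixedmodel as mm, synth

logging.basicConfig(level=logging.INFO, format="%(message)s")

ds = synth.simulate_scenario(synth.ScenarioConfig(n_snps=2000), seed=0)
print(f"panel: {ds.panel.n_strains} strains x {ds.panel.n_snps} SNPs; "
      f"planted causal SNP {ds.truth.causal_snp_id} in {ds.truth.causal_gene}")

res = mm.genome_scan(ds.phenotypes, ds.panel, None, "bmd", mode="exact",
                     loco=True)
top = res.table.nlargest(5, "neglog10P")[
    ["snp_id", "chrom", "pos", "maf", "F", "neglog10P"]]
print("\ntop 5 associations (-log10 P; genome-wide threshold is 5.39):")
print(top.to_string(index=False))
print("\nThe planted SNP (or a close LD partner) should top the scan and "
      "exceed the threshold; its -log10 P reflects a 15%-variance effect "
      "mapped in ~100 strains.")
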