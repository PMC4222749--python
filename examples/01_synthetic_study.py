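"""Generate a synthetic pooled-resequencing study and filter it.

Builds the emulated design — six Pennsylvania spring/fall pools over three
years plus five clinal pools — with 2% of SNPs oscillating 20 percentage
points between seasons, then applies the common-SNP filters.
"""

from seasonscan import AnalysisConfig, filter_snps
from seasonscan.synth import TruthConfig, simulate_study, simulate_truth

cfg = TruthConfig(n_snps=5000, frac_seasonal=0.02, frac_clinal=0.05, seed=7)
truth = simulate_truth(cfg)
table, metas = simulate_study(truth, cfg)

print(f"simulated {len(table)} SNPs x {len(metas)} pooled samples")
print(truth["class"].value_counts().to_string())

kept, removed = filter_snps(table, AnalysisConfig())
print(f"\nafter MAF >= 0.15 and depth in [10, 400] filters: "
      f"{len(kept)} SNPs kept, removed {removed}")
# removed['maf'] counts SNPs whose across-sample mean minor allele
# frequency fell below 15%; removed['depth'] counts SNPs with any sample
# outside the depth window.
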