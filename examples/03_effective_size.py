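"""Effective population size from pedigree rates and genomic LD.

An idealized random-mating population of census size 50 is simulated for
10 generations; every estimator should recover roughly Ne = 50. The LD
method uses inter-chromosomal r² of the final generation's genotypes.
"""

import pandas as pd

import flockdiv as fd

N, GENS = 50, 10
ped = fd.simulate_wright_fisher_pedigree(N // 2, N // 2, GENS, seed=3)
F = fd.inbreeding_ml(ped)
m = fd.generation_metrics(ped)
t = m["equivalent_complete_generations"]
years = pd.Series(ped.birth_year, index=ped.ids)
last = [a for a, y in zip(ped.ids, ped.birth_year) if y == 2000 + GENS]

print(f"true census size N = {N}, {GENS} generations")
print(f"F on generations:    {fd.ne_regression_on_generations(F, t).estimate:.1f}")
print(f"individual deltaF:   {fd.ne_individual_deltaF(F, t, last).estimate:.1f}")
print(f"birth-year slope:    {fd.ne_birthyear_regression(F, years, 1.0).estimate:.1f}")
print(f"log(1-F) slope:      {fd.ne_log_regression(F, t.round()).estimate:.1f}")
print(f"pair coancestry:     {fd.ne_coancestry(ped, last, t=t).estimate:.1f}")

gd, _ = fd.simulate_genotypes(ped, fd.GenomeConfig(
    n_chromosomes=10, snps_per_chrom=200, chrom_length_bp=20_000_000, seed=3))
sub = gd.subset(sample_mask=(gd.samples["birth_year"] == 2000 + GENS).to_numpy())
ld = fd.ne_ld(sub)
print(f"LD method:           {ld.estimate:.1f} "
      f"(jackknife CI {ld.ci_low:.0f}-{ld.ci_high:.0f})")
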