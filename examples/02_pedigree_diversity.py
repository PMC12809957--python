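"""Pedigree-based diversity: F, AR, founders/ancestors, generation interval.

Numbers printed: mean inbreeding and average relatedness (percent), the
effective numbers of founders (f_e) and ancestors (f_a) of the youngest
cohort — their ratio flags bottlenecks — and the four-path generation
interval L in years.
"""

import flockdiv as fd

ped = fd.simulate_pedigree(fd.SimConfig(
    n_founder_sires=12, n_founder_dams=80, n_generations=6,
    n_flocks=4, seed=2))

F = fd.inbreeding_ml(ped)
AR = fd.average_relatedness(ped, F)
print(f"mean F:  {100 * F.mean():.2f}%   mean AR: {100 * AR.mean():.2f}%")

recent = fd.subgroup_birth_years(ped, int(ped.birth_year.max()) - 3,
                                 int(ped.birth_year.max()))
fe = fd.founder_contributions(ped, sorted(recent)).f_e
anc = fd.marginal_ancestors(ped, sorted(recent))
print(f"f_e = {fe:.1f}, f_a = {anc.f_a:.1f}, ratio = {fe / anc.f_a:.2f} "
      f"(ratio > 1 means a bottleneck narrowed the gene pool)")
print(f"ancestors explaining 50% of genes: {anc.n_50:.0f}")

gi = fd.generation_intervals(ped)
print(f"generation interval L = {gi.L:.2f} +/- {gi.L_se:.2f} years "
      f"(weighted over the four parent-offspring paths)")
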