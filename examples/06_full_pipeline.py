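"""One-call orchestration: pedigree -> subgroups -> Ne -> QC -> genomics.

Writes every report table (diversity summary, top ancestors, Ne by
method, heterozygosity by flock, QC log, estimator correlations) to an
output directory and prints a few headline numbers.
"""

import tempfile
from pathlib import Path

import flockdiv as fd
from flockdiv.pipeline import RunConfig, run_pipeline

tmp = Path(tempfile.mkdtemp())
ped = fd.simulate_pedigree(fd.SimConfig(
    n_founder_sires=10, n_founder_dams=60, n_generations=6, n_flocks=4,
    birth_year_start=2003, seed=6))
gd, _ = fd.simulate_genotypes(ped, fd.GenomeConfig(
    n_chromosomes=6, snps_per_chrom=150, chrom_length_bp=25_000_000, seed=6))
ped.write_csv(tmp / "ped.csv")
recent = ped.birth_year >= ped.birth_year.max() - 6
gd.subset(sample_mask=recent).write_ped_map(tmp / "geno")

report = run_pipeline(RunConfig(
    pedigree_csv=str(tmp / "ped.csv"), plink_prefix=str(tmp / "geno"),
    out_dir=str(tmp / "out"), sg1_years=(2015, 2024), sg2_min_complete=3,
    fst_n_boot=50, pca_replicates=2, seed=6))

full = next(r for r in report["table1"] if r["subgroup"] == "full")
print(f"pedigree: {full['N']} animals, mean F {full['F_pct']:.2f}%, "
      f"f_e {full['f_e']:.0f}, f_a {full['f_a']:.0f}")
print(f"generation interval {report['generation_interval']['L']:.2f} y, "
      f"deltaF {100 * report['delta_f']['mean']:.2f}%/generation")
print("Ne by method:")
for row in report["table3"]:
    est = "undefined" if row["Ne"] is None else f"{row['Ne']:.0f}"
    print(f"  {row['method']:28s} {est}")
print(f"genomic: F_ROH {report['genomic']['mean_F_ROH_pct']:.2f}%, "
      f"F_HBD {report['genomic']['mean_F_HBD_pct']:.2f}%, "
      f"flock FST {report['genomic']['mean_flock_fst']:.3f}")
print(f"report files in {tmp / 'out'}")
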