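"""End-to-end orchestration: pedigree -> subgroups -> diversity -> Ne ->
genotype QC -> genomic inbreeding -> population structure.

:func:`run_pipeline` takes a :class:`RunConfig` (constructed directly or
from a YAML file), runs every stage that its inputs allow, writes TSV/JSON
outputs, and returns a nested report dict whose keys trace each number to
the module operation that produced it. Genomic sections are marked
``skipped`` when no genotypes are supplied. Reruns with the same config
and seed are byte-identical.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import genomic, inbreeding, ne, pedigree, qc, structure
from .errors import FlockdivError
from .genotypes import GenotypeDataset


@dataclass
class RunConfig:
    pedigree_csv: str
    plink_prefix: str | None = None          # PED/MAP prefix (optional)
    out_dir: str = "flockdiv_out"
    sg1_years: tuple[int, int] = (2021, 2023)
    sg2_min_complete: int = 4
    genotyped_ids_file: str | None = None    # defines SG3; defaults to all genotyped
    pci_depth: int = 5
    roh: genomic.RohParams = field(default_factory=genomic.RohParams)
    hbd: genomic.HbdModelParams = field(default_factory=genomic.HbdModelParams)
    qc: qc.QcParams = field(default_factory=qc.QcParams)
    fst_n_boot: int = 100
    pca_max_per_flock: int = 30
    pca_replicates: int = 5
    ne_ld_max_jackknife: int | None = 100
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key, typ in (("roh", genomic.RohParams),
                         ("hbd", genomic.HbdModelParams),
                         ("qc", qc.QcParams)):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = typ(**raw[key])
        if "sg1_years" in raw:
            raw["sg1_years"] = tuple(raw["sg1_years"])
        return cls(**raw)


class StageError(FlockdivError, RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""


def _stage(name):
    def deco(fn):
        def wrapper(*a, **kw):
            try:
                return fn(*a, **kw)
            except Exception as exc:          # noqa: BLE001 - re-raise tagged
                raise StageError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


def run_pipeline(cfg: RunConfig) -> dict:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": {"seed": cfg.seed,
                               "sg1_years": list(cfg.sg1_years),
                               "pedigree_csv": str(cfg.pedigree_csv),
                               "plink_prefix": cfg.plink_prefix},
                    "log": []}

    def log(msg):
        report["log"].append(msg)

    try:
        ped = _stage("read_pedigree")(pedigree.read_pedigree)(cfg.pedigree_csv)
        log(f"pedigree: {ped.n_animals} animals")

        gd = None
        if cfg.plink_prefix is not None:
            gd = _stage("read_genotypes")(GenotypeDataset.read_ped_map)(
                cfg.plink_prefix)
            # attach pedigree metadata (birth years) to genotyped samples
            meta = ped.df.set_index("id")
            gd.samples["birth_year"] = [
                meta["birth_year"].get(a, np.nan) for a in gd.samples["id"]]
            log(f"genotypes: {gd.n_samples} samples x {gd.n_markers} markers")

        metrics = _stage("generation_metrics")(pedigree.generation_metrics)(ped)
        pci_s = _stage("pci")(pedigree.pci)(ped, cfg.pci_depth)
        gi = _stage("generation_intervals")(pedigree.generation_intervals)(ped)
        F = _stage("inbreeding")(inbreeding.inbreeding_ml)(ped)
        AR = _stage("average_relatedness")(inbreeding.average_relatedness)(ped, F)
        C, slots = inbreeding.founder_contribution_matrix(ped)
        gci_s = _stage("gci")(inbreeding.gci)(ped, C)

        # QC first so SG3 can default to the animals passing it
        qc_result = None
        if gd is not None:
            qc_result = _stage("qc")(qc.qc_pipeline)(gd, ped, cfg.qc)
            report["qc"] = qc_result.report.to_dict()

        # subgroups
        sg1 = pedigree.subgroup_birth_years(ped, *cfg.sg1_years)
        sg2 = pedigree.subgroup_min_complete(ped, sg1, cfg.sg2_min_complete,
                                             metrics)
        if cfg.genotyped_ids_file:
            sg3 = pedigree.subgroup_id_list(
                ped, Path(cfg.genotyped_ids_file).read_text().split())
        elif qc_result is not None:
            sg3 = pedigree.subgroup_id_list(
                ped, qc_result.full.samples["id"])
        else:
            sg3 = set()
        sg4 = pedigree.subgroup_sires_of(ped, sg1)
        groups = {"full": set(ped.ids), "SG1": sg1, "SG2": sg2,
                  "SG3": sg3, "SG4": sg4}

        # Table-1 analog: per-subgroup diversity summary
        tab1_rows = []
        ancestors_full = None
        for name, ids in groups.items():
            if not ids:
                log(f"subgroup {name} empty; skipped")
                continue
            idx = sorted(ids)
            fr = inbreeding.founder_contributions(ped, idx, C, slots)
            anc = inbreeding.marginal_ancestors(ped, idx)
            if name == "full":
                ancestors_full = anc
            flocks_here = {ped.df["flock"][ped.index_of(a)] for a in idx}
            tab1_rows.append({
                "subgroup": name, "N": len(idx),
                "flocks": len({f for f in flocks_here if f is not None}),
                "F_pct": 100 * float(F.loc[idx].mean()),
                "AR_pct": 100 * float(AR.loc[idx].mean()),
                "mean_max_generations": float(
                    metrics.loc[idx, "max_generations"].mean()),
                "mean_complete_generations": float(
                    metrics.loc[idx, "complete_generations"].mean()),
                "mean_equivalent_generations": float(
                    metrics.loc[idx, "equivalent_complete_generations"].mean()),
                "PCI_pct": 100 * float(pci_s.loc[idx].mean()),
                "f_e": fr.f_e, "f_a": anc.f_a,
                "fe_over_fa": fr.f_e / anc.f_a if anc.f_a else math.nan,
                "GCI": float(gci_s.loc[idx].mean()),
                "n_ancestors_50pct": anc.n_50,
            })
        table1 = pd.DataFrame(tab1_rows).set_index("subgroup")
        table1.to_csv(out / "table1_diversity.tsv", sep="\t")
        report["table1"] = table1.reset_index().to_dict(orient="records")

        # Table-2 analog: top marginal contributors (full pedigree)
        if ancestors_full is not None:
            top = ancestors_full.table.head(10).copy()
            meta = ped.df.set_index("id")
            top["flock"] = [meta["flock"].get(a) for a in top["id"]]
            top["birth_year"] = [meta["birth_year"].get(a) for a in top["id"]]
            prog = pd.Series(0, index=ped.ids)
            for arr in (ped.sire_idx, ped.dam_idx):
                for i in arr[arr >= 0]:
                    prog.iloc[i] += 1
            top["progeny"] = [int(prog.get(a, 0)) for a in top["id"]]
            top.to_csv(out / "table2_top_ancestors.tsv", sep="\t", index=False)
            report["table2"] = top.to_dict(orient="records")

        # ΔF trend and Table-3 analog: Ne estimates
        dft = _stage("delta_f_trend")(inbreeding.delta_f_trend)(
            F, pd.Series(ped.birth_year, index=ped.ids),
            gi.L if math.isfinite(gi.L) else 1.0)
        report["generation_interval"] = {
            "L": gi.L, "L_se": gi.L_se, "path_means": gi.path_means,
            "path_counts": gi.path_counts, "flag": gi.flag}
        report["delta_f"] = {"mean": dft.mean_delta_f, "slope": dft.slope,
                             "p_value": dft.p_value, "flag": dft.flag}

        t = metrics["equivalent_complete_generations"]
        ne_rows = {}
        ne_rows["F_on_max_generations"] = ne.ne_regression_on_generations(
            F, metrics["max_generations"])
        ne_rows["F_on_complete_generations"] = ne.ne_regression_on_generations(
            F, metrics["complete_generations"])
        ne_rows["F_on_equivalent_generations"] = ne.ne_regression_on_generations(
            F, t)
        ne_rows["individual_deltaF"] = ne.ne_individual_deltaF(F, t)
        ne_rows["birth_year_regression"] = ne.ne_birthyear_regression(
            F, pd.Series(ped.birth_year, index=ped.ids),
            gi.L if math.isfinite(gi.L) else 1.0)
        ne_rows["log_regression"] = ne.ne_log_regression(
            F, metrics["equivalent_complete_generations"].round())
        coanc_ref = sorted(sg1) if sg1 else ped.ids
        ne_rows["pairwise_coancestry"] = _stage("ne_coancestry")(
            ne.ne_coancestry)(ped, coanc_ref, t=t, seed=cfg.seed)
        if qc_result is not None:
            ne_rows["ld_method"] = _stage("ne_ld")(ne.ne_ld)(
                qc_result.reduced, max_jackknife=cfg.ne_ld_max_jackknife,
                seed=cfg.seed)
        table3 = pd.DataFrame(
            [{"method": k, "Ne": r.estimate, "flag": r.flag,
              "ci_low": r.ci_low, "ci_high": r.ci_high}
             for k, r in ne_rows.items()]).set_index("method")
        table3.to_csv(out / "table3_ne.tsv", sep="\t")
        report["table3"] = table3.reset_index().to_dict(orient="records")

        # pedigree-based flock structure
        try:
            fdiff = inbreeding.pedigree_fst_nei(ped)
            report["pedigree_structure"] = {
                "fst": fdiff.fst,
                "mean_nei_distance": float(
                    fdiff.nei_distance.to_numpy()[np.triu_indices(
                        len(fdiff.nei_distance), k=1)].mean())
                if len(fdiff.nei_distance) > 1 else 0.0}
        except FlockdivError as exc:
            log(f"pedigree structure skipped: {exc}")

        # genomic sections
        if qc_result is None:
            report["genomic"] = "skipped"
        else:
            full, reduced, ldds = (qc_result.full, qc_result.reduced,
                                   qc_result.ld)
            spect = genomic.maf_spectrum(full)
            spect.to_csv(out / "maf_spectrum.tsv", sep="\t", index=False)
            het = _stage("heterozygosity")(genomic.heterozygosity)(
                reduced, reduced.samples["flock"])
            segs = _stage("roh")(genomic.detect_roh)(full, cfg.roh)
            segs.to_csv(out / "roh_segments.tsv", sep="\t", index=False)
            froh = genomic.f_roh(segs, full)
            hbd = _stage("hbd")(genomic.hbd_posterior)(full, cfg.hbd)
            G, fgrm = _stage("grm")(genomic.grm_vanraden1)(reduced)
            ldres = _stage("ld_decay")(genomic.ld_decay)(ldds)

            fped = F.reindex(full.samples["id"])
            tbl = pd.DataFrame({
                "F_PED": fped.to_numpy(),
                "F_IND": het.f_ind.reindex(full.samples["id"]).to_numpy(),
                "F_ROH": froh["F_ROH"].to_numpy(),
                "F_ROH_1-6Mb": froh["F_ROH_1-6Mb"].to_numpy(),
                "F_ROH_6-12Mb": froh["F_ROH_6-12Mb"].to_numpy(),
                "F_ROH_12-24Mb": froh["F_ROH_12-24Mb"].to_numpy(),
                "F_ROH_>24Mb": froh["F_ROH_>24Mb"].to_numpy(),
                "F_GRM": fgrm.reindex(full.samples["id"]).to_numpy(),
                "F_HBD": hbd.f_hbd.reindex(full.samples["id"]).to_numpy(),
            }, index=full.samples["id"])
            tbl.to_csv(out / "inbreeding_table.tsv", sep="\t")
            corr = genomic.inbreeding_correlations(tbl)
            corr.matrix.to_csv(out / "inbreeding_correlations.tsv", sep="\t")

            fst = _stage("fst")(structure.pairwise_fst)(
                reduced, n_boot=cfg.fst_n_boot, seed=cfg.seed)
            fst.point.to_csv(out / "fst_matrix.tsv", sep="\t")
            pca = _stage("pca")(structure.pca_with_subsampling)(
                reduced, max_per_flock=cfg.pca_max_per_flock,
                n_replicates=cfg.pca_replicates, seed=cfg.seed)
            for r, rep in enumerate(pca.replicates, 1):
                rep.scores.to_csv(out / f"pca_scores_rep{r}.tsv",
                                  sep="\t", index=False)

            # Table-4 analog: per-flock heterozygosity summary
            if het.by_group is not None:
                het.by_group.to_csv(out / "table4_heterozygosity.tsv", sep="\t")
            report["genomic"] = {
                "maf_first_bin_pct": 100 * float(spect["proportion"].iloc[0]),
                "H_E": het.h_e, "H_O": het.h_o, "Hnb": het.hnb,
                "F_IS": het.f_is,
                "mean_F_IND_pct": 100 * het.mean_f_ind,
                "mean_F_ROH_pct": 100 * float(froh["F_ROH"].mean()),
                "mean_F_GRM_pct": 100 * float(fgrm.mean()),
                "mean_F_HBD_pct": 100 * float(hbd.f_hbd.mean()),
                "mean_roh_per_animal": float(froh["n_segments"].mean()),
                "adjacent_snp_mean_r2": ldres.adjacent_mean_r2,
                "adjacent_snp_mean_dist_bp": ldres.adjacent_mean_dist_bp,
                "mean_flock_fst": fst.overall_mean,
                "pca_pct_variance_rep1":
                    [float(v) for v in pca.replicates[0].pct_variance],
                "inbreeding_correlations":
                    corr.matrix.round(6).to_dict(),
            }
    finally:
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=_json_default)
    return report


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, float) and math.isnan(o):
        return None
    return str(o)
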