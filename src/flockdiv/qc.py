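"""Genotype quality control and construction of analysis dataset variants.

Three variants of a QC'd dataset are produced, mirroring common practice
for medium-density array studies:

* ``full``    -- autosomal SNPs passing call-rate filters, LD-pruned at
                 r² > 0.5 (fixed/rare alleles retained; used for MAF
                 spectra, ROH and HBD where fixed alleles are integral);
* ``reduced`` -- the full dataset minus MAF < 0.01 markers (used for
                 heterozygosity, GRM, FST, PCA, LD-method Ne);
* ``ld``      -- the call-rate-filtered markers minus MAF < 0.01, with
                 **no** LD pruning (used for LD-decay analyses).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import QcStageError
from .genotypes import GenotypeDataset
from .pedigree import PedigreeTable


@dataclass
class QcParams:
    sample_call_rate_min: float = 0.90
    marker_call_rate_min: float = 0.90
    ld_r2_threshold: float = 0.5
    ld_window_snps: int = 50
    ld_window_step: int = 5
    maf_min: float = 0.01
    autosomes: tuple[int, int] = (1, 26)
    require_known_parents: bool = True


@dataclass
class QcReport:
    """Bookkeeping for every QC stage; removed + retained always equals
    the stage input."""
    input_samples: int = 0
    input_markers: int = 0
    removed_samples: dict = field(default_factory=dict)
    removed_markers: dict = field(default_factory=dict)
    retained: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "input_samples": self.input_samples,
            "input_markers": self.input_markers,
            "removed_samples": dict(self.removed_samples),
            "removed_markers": dict(self.removed_markers),
            "retained": dict(self.retained),
        }


def _r2_matrix(X: np.ndarray) -> np.ndarray:
    """Squared Pearson correlations between marker columns (missing
    mean-imputed); zero-variance columns give r² = 0."""
    X = X.astype(float)
    miss = X < 0
    if miss.any():
        col_mean = np.nanmean(np.where(miss, np.nan, X), axis=0)
        X = np.where(miss, col_mean[None, :], X)
    Xc = X - X.mean(axis=0)
    norms = np.sqrt((Xc ** 2).sum(axis=0))
    safe = np.where(norms > 0, norms, 1.0)
    Xs = Xc / safe
    r = Xs.T @ Xs
    r[norms == 0, :] = 0.0
    r[:, norms == 0] = 0.0
    return r ** 2


def ld_prune(gd: GenotypeDataset, r2_threshold: float = 0.5,
             window_snps: int = 50, step: int = 5) -> GenotypeDataset:
    """Sliding-window pairwise LD pruning.

    Within each window the most-correlated pair above the threshold is
    resolved by removing the lower-MAF member (tie: the later position).
    Windows advance by ``step`` over the surviving markers and passes
    repeat until no window contains a pair above the threshold.
    """
    maf = gd.maf()
    chrom = gd.markers["chrom"].to_numpy()
    keep = np.ones(gd.n_markers, dtype=bool)

    changed = True
    while changed:
        changed = False
        for c in np.unique(chrom):
            cidx = np.flatnonzero((chrom == c) & keep)
            start = 0
            while start < len(cidx):
                # windows are defined over currently surviving markers
                cidx = np.flatnonzero((chrom == c) & keep)
                if start >= len(cidx):
                    break
                win = cidx[start:start + window_snps]
                if len(win) >= 2:
                    while True:
                        live = win[keep[win]]
                        if len(live) < 2:
                            break
                        r2 = _r2_matrix(gd.geno[:, live])
                        np.fill_diagonal(r2, 0.0)
                        i, j = np.unravel_index(np.argmax(r2), r2.shape)
                        if r2[i, j] <= r2_threshold:
                            break
                        a, b = live[i], live[j]
                        if maf[a] < maf[b] or (maf[a] == maf[b] and a > b):
                            keep[a] = False
                        else:
                            keep[b] = False
                        changed = True
                start += step
    return gd.subset(marker_mask=keep)


@dataclass
class QcResult:
    full: GenotypeDataset
    reduced: GenotypeDataset
    ld: GenotypeDataset
    report: QcReport


def qc_pipeline(gd: GenotypeDataset, ped: PedigreeTable | None = None,
                params: QcParams | None = None) -> QcResult:
    """Run the staged QC pipeline and build the three dataset variants.

    Order: (1) drop animals with unknown parentage (when a pedigree is
    supplied), (2) drop animals with call rate below threshold, (3) keep
    autosomal markers above the marker call-rate threshold, (4) LD-prune
    -> ``full``; (5) full minus low-MAF -> ``reduced``; (6) unpruned
    step-3 markers minus low-MAF -> ``ld``.
    """
    p = params or QcParams()
    report = QcReport(input_samples=gd.n_samples, input_markers=gd.n_markers)

    # (1) parentage
    if ped is not None and p.require_known_parents:
        known = []
        for a in gd.samples["id"]:
            if a in ped._index:
                i = ped.index_of(a)
                known.append(ped.sire_idx[i] >= 0 and ped.dam_idx[i] >= 0)
            else:
                known.append(False)
        known = np.array(known, dtype=bool)
        report.removed_samples["unknown_parentage"] = int((~known).sum())
        gd = gd.subset(sample_mask=known)
    else:
        report.removed_samples["unknown_parentage"] = 0
    if gd.n_samples == 0:
        raise QcStageError("no samples left after parentage filter")

    # (2) sample call rate
    cr = gd.sample_call_rate()
    keep_s = cr >= p.sample_call_rate_min
    report.removed_samples["low_call_rate"] = int((~keep_s).sum())
    gd = gd.subset(sample_mask=keep_s)
    if gd.n_samples == 0:
        raise QcStageError("no samples left after call-rate filter")

    # (3) autosomal markers by call rate
    chrom = gd.markers["chrom"].to_numpy()
    auto = (chrom >= p.autosomes[0]) & (chrom <= p.autosomes[1])
    report.removed_markers["non_autosomal"] = int((~auto).sum())
    mcr = gd.marker_call_rate()
    good = mcr > p.marker_call_rate_min
    report.removed_markers["low_call_rate"] = int((auto & ~good).sum())
    base = gd.subset(marker_mask=auto & good)
    if base.n_markers == 0:
        raise QcStageError("no markers left after call-rate filter")

    # (4) LD pruning -> full
    full = ld_prune(base, p.ld_r2_threshold, p.ld_window_snps, p.ld_window_step)
    report.removed_markers["ld_pruned"] = base.n_markers - full.n_markers
    if full.n_markers == 0:
        raise QcStageError("no markers left after LD pruning")

    # (5) full minus MAF < threshold -> reduced
    maf_full = full.maf()
    keep_maf = maf_full >= p.maf_min
    report.removed_markers["low_maf_from_full"] = int((~keep_maf).sum())
    reduced = full.subset(marker_mask=keep_maf)
    if reduced.n_markers == 0:
        raise QcStageError("no markers left after MAF filter (reduced)")

    # (6) unpruned base minus MAF < threshold -> ld
    maf_base = base.maf()
    keep_ld = maf_base >= p.maf_min
    report.removed_markers["low_maf_from_unpruned"] = int((~keep_ld).sum())
    ld = base.subset(marker_mask=keep_ld)
    if ld.n_markers == 0:
        raise QcStageError("no markers left after MAF filter (ld)")

    report.retained = {
        "samples": gd.n_samples,
        "markers_callrate": base.n_markers,
        "full": full.n_markers,
        "reduced": reduced.n_markers,
        "ld": ld.n_markers,
    }
    return QcResult(full=full, reduced=reduced, ld=ld, report=report)
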