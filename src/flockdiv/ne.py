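"""Effective population size (Ne) estimators.

Seven pedigree-based estimators (regressions of F on three generation
metrics, the individual rate of inbreeding, regression of F on birth
year, log-regression of 1−F on generation, and the pairwise rate of
coancestry) plus the genomic linkage-disequilibrium method with
delete-one jackknife confidence intervals.

Every estimator returns a :class:`NeResult`; an estimator whose inputs
imply no inbreeding accumulation (non-positive slope, zero rates) returns
``flag='undefined'`` rather than a spurious number.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisError
from .genotypes import GenotypeDataset
from .inbreeding import a_times_x, inbreeding_ml, _dvec
from .pedigree import PedigreeTable

UNDEFINED = "undefined"


@dataclass
class NeResult:
    estimate: float
    flag: str | None = None
    ci_low: float = math.nan
    ci_high: float = math.nan
    details: dict | None = None

    @property
    def defined(self) -> bool:
        return self.flag is None


def _ne_from_slope(b: float, extras: dict) -> NeResult:
    if not np.isfinite(b) or b <= 0:
        return NeResult(math.nan, UNDEFINED, details=extras)
    return NeResult(1.0 / (2.0 * b), None, details=extras)


def ne_regression_on_generations(F: pd.Series, metric: pd.Series) -> NeResult:
    """Ne = 1/(2b) with b the OLS slope of F on a generation metric
    (maximum, complete, or equivalent complete generations)."""
    x = metric.to_numpy(dtype=float)
    y = F.reindex(metric.index).to_numpy(dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 2 or len(np.unique(x[ok])) < 2:
        return NeResult(math.nan, UNDEFINED, details={"reason": "degenerate"})
    res = stats.linregress(x[ok], y[ok])
    return _ne_from_slope(float(res.slope), {"slope": float(res.slope)})


def ne_individual_deltaF(F: pd.Series, t: pd.Series,
                         reference_ids=None) -> NeResult:
    """Individual rate of inbreeding: ΔF_i = 1 − (1 − F_i)^(1/(t_i − 1))
    with t the equivalent complete generations; Ne = 1/(2 mean ΔF)."""
    if reference_ids is not None:
        idx = [a for a in reference_ids]
        F = F.reindex(idx)
        t = t.reindex(idx)
    tv = t.to_numpy(dtype=float)
    fv = F.to_numpy(dtype=float)
    ok = np.isfinite(tv) & np.isfinite(fv) & (tv > 1.0)
    if not ok.any():
        return NeResult(math.nan, UNDEFINED, details={"reason": "all t <= 1"})
    dfi = 1.0 - (1.0 - fv[ok]) ** (1.0 / (tv[ok] - 1.0))
    mean_df = float(dfi.mean())
    if mean_df <= 0:
        return NeResult(math.nan, UNDEFINED, details={"mean_deltaF": mean_df})
    return NeResult(1.0 / (2.0 * mean_df), None,
                    details={"mean_deltaF": mean_df, "n": int(ok.sum())})


def ne_birthyear_regression(F: pd.Series, birth_year: pd.Series,
                            L: float) -> NeResult:
    """Ne from the regression of F on birth year: ΔF = b_year * L."""
    x = birth_year.to_numpy(dtype=float)
    y = F.reindex(birth_year.index).to_numpy(dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3 or len(np.unique(x[ok])) < 3:
        return NeResult(math.nan, UNDEFINED, details={"reason": "<3 birth years"})
    res = stats.linregress(x[ok], y[ok])
    return _ne_from_slope(float(res.slope) * L,
                          {"slope_per_year": float(res.slope), "L": L})


def ne_log_regression(F: pd.Series, generation: pd.Series) -> NeResult:
    """Ne = −1/(2s) with s the slope of ln(1 − F̄_g) on generation number g."""
    df = pd.DataFrame({"g": generation.to_numpy(dtype=float),
                       "F": F.reindex(generation.index).to_numpy(dtype=float)})
    df = df.dropna()
    gm = df.groupby("g")["F"].mean()
    if (gm >= 1).any():
        raise AnalysisError("mean F reached 1; log regression undefined")
    if len(gm) < 2:
        return NeResult(math.nan, UNDEFINED, details={"reason": "degenerate"})
    res = stats.linregress(gm.index.to_numpy(), np.log(1.0 - gm.to_numpy()))
    s = float(res.slope)
    if not np.isfinite(s) or s >= 0:
        return NeResult(math.nan, UNDEFINED, details={"slope": s})
    return NeResult(-1.0 / (2.0 * s), None, details={"slope": s})


def ne_coancestry(ped: PedigreeTable, reference_ids,
                  t: pd.Series | None = None,
                  max_pairs: int = 5_000_000, seed: int = 0) -> NeResult:
    """Ne from the pairwise rate of coancestry.

    For each pair (j, k) of reference animals with mean equivalent
    generations g = (g_j + g_k)/2 > 0:
    Δc_jk = 1 − (1 − c_jk)^(1/g), and Ne = 1/(2 mean Δc). Pair sets larger
    than ``max_pairs`` are subsampled deterministically from ``seed``.
    """
    from .pedigree import generation_metrics
    ref = [ped.index_of(a) for a in reference_ids]
    if len(ref) < 2:
        raise AnalysisError("need at least two reference animals")
    if t is None:
        t = generation_metrics(ped)["equivalent_complete_generations"]
    g = t.to_numpy(dtype=float)[ref] if len(t) == ped.n_animals else \
        t.reindex([ped.ids[i] for i in ref]).to_numpy(dtype=float)

    F = inbreeding_ml(ped).to_numpy()
    dv = _dvec(ped, F)
    m = len(ref)
    n = ped.n_animals
    # coancestry columns for the reference animals via A = T D T'
    A_ref = np.empty((m, m))
    for k, j in enumerate(ref):
        x = np.zeros(n)
        x[j] = 1.0
        z = a_times_x(ped, x, F=F, dvec=dv)
        A_ref[:, k] = z[ref]
    c = A_ref / 2.0

    iu, ju = np.triu_indices(m, k=1)
    gbar = (g[iu] + g[ju]) / 2.0
    ok = gbar > 0
    iu, ju, gbar = iu[ok], ju[ok], gbar[ok]
    if len(iu) == 0:
        return NeResult(math.nan, UNDEFINED,
                        details={"reason": "no pairs with generation depth"})
    if len(iu) > max_pairs:
        rng = np.random.default_rng(seed)
        pick = rng.choice(len(iu), size=max_pairs, replace=False)
        iu, ju, gbar = iu[pick], ju[pick], gbar[pick]
    cpair = np.clip(c[iu, ju], 0.0, 1.0 - 1e-12)
    dc = 1.0 - (1.0 - cpair) ** (1.0 / gbar)
    mean_dc = float(dc.mean())
    if mean_dc <= 0:
        return NeResult(math.nan, UNDEFINED, details={"mean_deltaC": mean_dc})
    return NeResult(1.0 / (2.0 * mean_dc), None,
                    details={"mean_deltaC": mean_dc, "n_pairs": len(iu)})


# ---------------------------------------------------------------------------
# Genomic LD method
# ---------------------------------------------------------------------------

def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-standardize to mean 0 / unit norm; returns (X~, keep mask)."""
    Xc = X - X.mean(axis=0)
    norms = np.sqrt((Xc ** 2).sum(axis=0))
    keep = norms > 0
    Xs = Xc[:, keep] / norms[keep]
    return Xs, keep


def _mean_interchrom_r2(X: np.ndarray, chrom: np.ndarray) -> float:
    """Mean squared correlation over pairs of SNPs on different
    chromosomes, via the sample-side Gram matrix (O(L * S^2))."""
    Xs, keep = _standardize(X)
    ch = chrom[keep]
    L = Xs.shape[1]
    K = Xs @ Xs.T
    total = float(np.sum(K * K))           # sum of r^2 over all ordered pairs
    within = 0.0
    npairs_within = 0
    for c in np.unique(ch):
        m = ch == c
        Xc = Xs[:, m]
        Kc = Xc @ Xc.T
        within += float(np.sum(Kc * Kc))
        npairs_within += int(m.sum()) ** 2
    denom = L * L - npairs_within
    if denom <= 0:
        raise AnalysisError("no inter-chromosomal SNP pairs")
    return (total - within) / denom


def _waples_correction(S: float) -> float:
    if S >= 30:
        return 1.0 / S + 3.19 / S ** 2
    return 0.0018 + 0.907 / S + 4.44 / S ** 2


def _ne_from_r2(r2p: float, S: float) -> float:
    """Published LD-method point estimate for random mating; returns inf
    when the corrected r^2 admits no finite solution."""
    if r2p <= 0:
        return math.inf
    if S >= 30:
        disc = 1.0 / 9.0 - 2.76 * r2p
        if disc < 0:
            disc = 0.0
        return (1.0 / 3.0 + math.sqrt(disc)) / (2.0 * r2p)
    disc = 0.308 ** 2 - 2.08 * r2p
    if disc < 0:
        disc = 0.0
    return (0.308 + math.sqrt(disc)) / (2.0 * r2p)


def ne_ld(gd: GenotypeDataset, *, max_jackknife: int | None = None,
          seed: int = 0) -> NeResult:
    """LD-method Ne from inter-chromosomal mean r².

    The sample-size expectation (Waples & Do) is subtracted from the mean
    squared correlation before inverting the drift relationship; the
    confidence interval is a delete-one jackknife over individuals.
    Monomorphic markers are excluded globally; residual missing genotypes
    are mean-imputed per marker.
    """
    S = gd.n_samples
    if S < 10:
        raise AnalysisError("LD method requires at least 10 individuals")
    X = gd.geno.astype(float)
    miss = X < 0
    if miss.any():
        p2 = np.nanmean(np.where(miss, np.nan, X), axis=0)
        X = np.where(miss, p2[None, :], X)
    chrom = gd.markers["chrom"].to_numpy()

    r2 = _mean_interchrom_r2(X, chrom)
    r2p = r2 - _waples_correction(S)
    ne = _ne_from_r2(r2p, S)
    details = {"mean_r2": r2, "r2_corrected": r2p, "S": S}
    if not math.isfinite(ne):
        return NeResult(math.inf, "unbounded", details=details)

    # delete-one jackknife over individuals
    idx = np.arange(S)
    if max_jackknife is not None and max_jackknife < S:
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(S, size=max_jackknife, replace=False))
    reps = []
    for i in idx:
        keep = np.ones(S, dtype=bool)
        keep[i] = False
        r2_i = _mean_interchrom_r2(X[keep], chrom)
        reps.append(_ne_from_r2(r2_i - _waples_correction(S - 1), S - 1))
    reps = np.array([r for r in reps if math.isfinite(r)])
    if len(reps) >= 3:
        m = len(reps)
        var = (m - 1) / m * np.sum((reps - reps.mean()) ** 2)
        se = math.sqrt(var)
        lo, hi = max(ne - 1.96 * se, 0.0), ne + 1.96 * se
    else:
        lo = hi = math.nan
    return NeResult(ne, None, ci_low=lo, ci_high=hi, details=details)
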