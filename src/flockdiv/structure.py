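"""Genomic population structure: pairwise flock FST and subsampled PCA.

FST uses the Weir-Cockerham (1984) theta estimator per locus, combined
across loci as a ratio of sums, with percentile confidence intervals from
bootstrap resampling of loci. PCA operates on the centered VanRaden
genomic relationship of per-flock subsamples so that large flocks do not
dominate the leading axes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AnalysisError
from .genomic import grm_vanraden1
from .genotypes import GenotypeDataset


# ---------------------------------------------------------------------------
# Weir-Cockerham FST
# ---------------------------------------------------------------------------

def _wc_components(g1: np.ndarray, g2: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus Weir-Cockerham variance components (a, b, c) for two
    populations. Loci where either population has no calls return zeros
    (they drop out of the ratio of sums)."""
    r = 2.0
    comps = []
    for g in (g1, g2):
        obs = g >= 0
        n = obs.sum(axis=0).astype(float)
        cnt = np.where(obs, g, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n > 0, cnt / (2 * n), np.nan)
            h = np.where(n > 0, (g == 1).sum(axis=0) / n, np.nan)
        comps.append((n, p, h))
    n1, p1, h1 = comps[0]
    n2, p2, h2 = comps[1]
    ok = (n1 > 0) & (n2 > 0) & (n1 + n2 > 2)
    nbar = (n1 + n2) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = nbar / nc * (s2 - 1.0 / (nbar - 1) *
                         (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4))
        b = nbar / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 -
                                 (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
    for arr in (a, b, c):
        arr[~ok] = 0.0
        arr[~np.isfinite(arr)] = 0.0
    return a, b, c


def wc_theta(g1: np.ndarray, g2: np.ndarray) -> float:
    """Weir-Cockerham theta for two populations, ratio of sums over loci."""
    a, b, c = _wc_components(g1, g2)
    denom = np.sum(a + b + c)
    if denom == 0:
        return math.nan
    return float(np.sum(a) / denom)


@dataclass
class FstMatrix:
    point: pd.DataFrame
    ci_low: pd.DataFrame
    ci_high: pd.DataFrame
    overall_mean: float
    excluded_flocks: list


def pairwise_fst(gd: GenotypeDataset, flocks: pd.Series | None = None,
                 n_boot: int = 100, seed: int = 0,
                 size_weighted_mean: bool = False) -> FstMatrix:
    """Pairwise flock FST with bootstrap (over loci) percentile CIs.

    Flocks with fewer than two genotyped animals are excluded with a
    warning. Negative per-pair theta values are retained. The overall
    mean is the unweighted mean of pairwise estimates unless
    ``size_weighted_mean`` (weights = sum of pair sizes).
    """
    if flocks is None:
        flocks = gd.samples["flock"]
    flocks = pd.Series(flocks.to_numpy(), index=gd.samples["id"])
    counts = flocks.value_counts()
    labels = sorted(counts.index[counts >= 2])
    excluded = sorted(set(counts.index) - set(labels))
    if excluded:
        warnings.warn(f"flocks with <2 animals excluded from FST: {excluded}")
    if len(labels) < 2:
        raise AnalysisError("need at least two flocks with >= 2 animals")

    rng = np.random.default_rng(seed)
    nL = gd.n_markers
    boot_idx = rng.integers(0, nL, size=(n_boot, nL)) if n_boot > 1 else None

    point = pd.DataFrame(0.0, index=labels, columns=labels)
    lo = pd.DataFrame(0.0, index=labels, columns=labels)
    hi = pd.DataFrame(0.0, index=labels, columns=labels)
    flat = flocks.to_numpy()
    vals, weights = [], []
    for i, la in enumerate(labels):
        for lb in labels[i + 1:]:
            ga = gd.geno[flat == la]
            gb = gd.geno[flat == lb]
            a, b, c = _wc_components(ga, gb)
            denom = np.sum(a + b + c)
            theta = float(np.sum(a) / denom) if denom else math.nan
            if boot_idx is not None:
                abc = a + b + c
                num = a[boot_idx].sum(axis=1)
                den = abc[boot_idx].sum(axis=1)
                with np.errstate(invalid="ignore", divide="ignore"):
                    thetas = num / den
                qs = np.nanpercentile(thetas, [2.5, 97.5])
            else:
                qs = (theta, theta)
            point.loc[la, lb] = point.loc[lb, la] = theta
            lo.loc[la, lb] = lo.loc[lb, la] = qs[0]
            hi.loc[la, lb] = hi.loc[lb, la] = qs[1]
            vals.append(theta)
            weights.append(len(ga) + len(gb))
    if size_weighted_mean:
        overall = float(np.average(vals, weights=weights))
    else:
        overall = float(np.mean(vals))
    return FstMatrix(point=point, ci_low=lo, ci_high=hi,
                     overall_mean=overall, excluded_flocks=excluded)


# ---------------------------------------------------------------------------
# PCA with per-flock subsampling
# ---------------------------------------------------------------------------

@dataclass
class PcaReplicate:
    scores: pd.DataFrame         # id, flock, PC1..PC3
    pct_variance: np.ndarray     # per retained PC, percent of total
    eigenvalues: np.ndarray
    members: list


@dataclass
class PcaResult:
    replicates: list


def pca_with_subsampling(gd: GenotypeDataset, flocks: pd.Series | None = None,
                         max_per_flock: int = 30, n_replicates: int = 5,
                         n_components: int = 3, seed: int = 0) -> PcaResult:
    """PCA of the centered genomic relationship of per-flock subsamples.

    Flocks above ``max_per_flock`` are subsampled without replacement per
    replicate; smaller flocks are fully included in every replicate.
    Percent variance is each eigenvalue over the sum of non-negative
    eigenvalues.
    """
    if flocks is None:
        flocks = gd.samples["flock"]
    flocks = pd.Series(flocks.to_numpy(), index=gd.samples["id"])
    rng = np.random.default_rng(seed)
    reps = []
    for rep in range(n_replicates):
        pick = []
        for lab in sorted(flocks.dropna().unique()):
            idx = np.flatnonzero((flocks == lab).to_numpy())
            if len(idx) > max_per_flock:
                idx = np.sort(rng.choice(idx, size=max_per_flock,
                                         replace=False))
            pick.extend(idx.tolist())
        pick = np.array(sorted(pick))
        if len(pick) < 3:
            raise AnalysisError("fewer than 3 samples after subsampling")
        sub = gd.subset(sample_mask=pick)
        G, _ = grm_vanraden1(sub)
        # double-center so scores have zero column means
        row = G.mean(axis=0)
        Gc = G - row[None, :] - row[:, None] + row.mean()
        evals, evecs = np.linalg.eigh(Gc)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        pos = np.clip(evals, 0.0, None)
        total = pos.sum()
        k = min(n_components, len(evals))
        scores = evecs[:, :k] * np.sqrt(pos[:k])[None, :]
        df = pd.DataFrame(scores, columns=[f"PC{i+1}" for i in range(k)])
        df.insert(0, "flock", flocks.iloc[pick].to_numpy())
        df.insert(0, "id", sub.samples["id"].to_numpy())
        pct = 100.0 * pos[:k] / total if total > 0 else np.zeros(k)
        reps.append(PcaReplicate(scores=df, pct_variance=pct,
                                 eigenvalues=evals,
                                 members=list(sub.samples["id"])))
    return PcaResult(replicates=reps)
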