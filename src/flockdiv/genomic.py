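"""Genomic diversity and inbreeding estimators.

Implements the genomic half of the diversity toolkit: the MAF spectrum,
expected/observed heterozygosity with the per-animal heterozygosity-based
inbreeding coefficient F_IND and group-level F_IS, run-of-homozygosity
(ROH) detection with length-class partitioning of F_ROH, a single-rate
two-state hidden Markov model of homozygosity-by-descent (F_HBD),
VanRaden method-1 genomic relationships (F_GRM = G_ii − 1), LD decay, and
the Pearson correlation matrix among inbreeding estimators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AnalysisError
from .genotypes import GenotypeDataset

ROH_CLASSES = ((1e6, 6e6, "1-6Mb"), (6e6, 12e6, "6-12Mb"),
               (12e6, 24e6, "12-24Mb"), (24e6, math.inf, ">24Mb"))


# ---------------------------------------------------------------------------
# Allele-frequency spectrum and heterozygosity
# ---------------------------------------------------------------------------

def maf_spectrum(gd: GenotypeDataset, bin_width: float = 0.05) -> pd.DataFrame:
    """Counts and proportions of markers per MAF bin.

    The first bin is [0, w]; later bins are (k*w, (k+1)*w]."""
    maf = gd.maf()
    maf = maf[np.isfinite(maf)]
    nbins = int(round(0.5 / bin_width))
    edges = bin_width * np.arange(1, nbins)
    idx = np.digitize(maf, edges, right=True)
    counts = np.bincount(idx, minlength=nbins)
    lows = bin_width * np.arange(nbins)
    return pd.DataFrame({
        "bin_low": lows,
        "bin_high": lows + bin_width,
        "count": counts,
        "proportion": counts / counts.sum() if counts.sum() else counts * 0.0,
    })


@dataclass
class HetResult:
    """Heterozygosity summary.

    h_e : mean expected heterozygosity 2p(1-p) over markers
    h_o : overall observed heterozygote fraction
    hnb : Nei's non-biased heterozygosity, H_E * 2n/(2n-1)
    f_is : 1 - H_O / Hnb
    f_ind : per-animal (H_E - H_O,i)/H_E
    by_group : optional per-group table of the same quantities
    """
    h_e: float
    h_o: float
    hnb: float
    f_is: float
    f_ind: pd.Series
    mean_f_ind: float
    by_group: pd.DataFrame | None = None
    flag: str | None = None


def _het_core(geno: np.ndarray, ids) -> dict:
    obs = geno >= 0
    n_called = obs.sum(axis=0)
    cnt = np.where(obs, geno, 0).sum(axis=0)
    with np.errstate(invalid="ignore"):
        p = np.where(n_called > 0, cnt / (2.0 * n_called), np.nan)
    poly = np.isfinite(p)
    he = float(np.mean(2 * p[poly] * (1 - p[poly]))) if poly.any() else 0.0
    het = geno == 1
    ho = float(het[:, poly].sum() / obs[:, poly].sum()) if poly.any() else 0.0
    n = geno.shape[0]
    hnb = he * 2 * n / (2 * n - 1) if n > 1 else he
    fis = 1 - ho / hnb if hnb > 0 else math.nan
    with np.errstate(invalid="ignore", divide="ignore"):
        ho_i = np.where(obs[:, poly].sum(axis=1) > 0,
                        het[:, poly].sum(axis=1) / obs[:, poly].sum(axis=1),
                        np.nan)
    f_ind = (he - ho_i) / he if he > 0 else np.full(n, np.nan)
    return {"h_e": he, "h_o": ho, "hnb": hnb, "f_is": fis,
            "f_ind": pd.Series(f_ind, index=ids, name="F_IND"), "n": n}


def heterozygosity(gd: GenotypeDataset,
                   groups: pd.Series | None = None) -> HetResult:
    """Population heterozygosity, per-animal F_IND, and (optionally)
    per-group H_E/Hnb/H_O/F_IS computed on each group's own frequencies."""
    core = _het_core(gd.geno, gd.samples["id"])
    flag = None
    if core["h_e"] == 0.0:
        flag = "all markers monomorphic; F_IND undefined"
    by_group = None
    if groups is not None:
        groups = pd.Series(groups.to_numpy(),
                           index=gd.samples["id"]) if len(groups) == gd.n_samples \
            else groups
        rows = []
        for lab in sorted(groups.dropna().unique()):
            mask = (groups == lab).to_numpy()
            sub = _het_core(gd.geno[mask], gd.samples["id"][mask])
            rows.append({"group": lab, "n": int(mask.sum()),
                         "H_E": sub["h_e"], "Hnb": sub["hnb"],
                         "H_O": sub["h_o"], "F_IS": sub["f_is"]})
        by_group = pd.DataFrame(rows).set_index("group")
    fi = core["f_ind"].to_numpy()
    mean_fi = float(np.nanmean(fi)) if np.isfinite(fi).any() else math.nan
    return HetResult(h_e=core["h_e"], h_o=core["h_o"], hnb=core["hnb"],
                     f_is=core["f_is"], f_ind=core["f_ind"],
                     mean_f_ind=mean_fi, by_group=by_group, flag=flag)


# ---------------------------------------------------------------------------
# Runs of homozygosity
# ---------------------------------------------------------------------------

@dataclass
class RohParams:
    """Sliding-window ROH detection parameters (medium-density defaults)."""
    window_snps: int = 50
    min_length_bp: int = 1_000_000
    max_gap_bp: int = 250_000
    min_snps: int = 30
    max_missing_in_window: int = 1
    max_het_in_window: int = 1
    window_threshold: float = 0.05


def _classify_length(length: float) -> str:
    for lo, hi, name in ROH_CLASSES:
        if lo <= length <= hi:
            return name
    return "<1Mb"


def detect_roh(gd: GenotypeDataset, params: RohParams | None = None,
               ) -> pd.DataFrame:
    """Detect ROH segments per animal.

    Windows of ``window_snps`` advance one SNP at a time; a window is
    compliant if it has at most ``max_het_in_window`` heterozygotes and
    ``max_missing_in_window`` missing calls. A SNP is run-eligible when
    the fraction of compliant windows covering it exceeds
    ``window_threshold``. Maximal stretches of eligible SNPs are split at
    adjacent gaps above ``max_gap_bp`` and kept if they span at least
    ``min_length_bp`` and contain at least ``min_snps`` SNPs.

    Returns a segment table (animal, chrom, start_bp, end_bp, n_snps,
    length_bp, roh_class). Chromosomes with fewer SNPs than the window
    are skipped.
    """
    p = params or RohParams()
    w = p.window_snps
    chrom = gd.markers["chrom"].to_numpy()
    bp = gd.markers["bp"].to_numpy()
    ids = gd.samples["id"].to_numpy()
    segs = []
    skipped: list = []
    for c in np.unique(chrom):
        cm = chrom == c
        L = int(cm.sum())
        if L < w:
            skipped.append(int(c))
            continue
        g = gd.geno[:, cm]
        pos = bp[cm]
        het = (g == 1).astype(np.int32)
        mis = (g < 0).astype(np.int32)
        # window sums via cumulative sums along markers
        chet = np.concatenate([np.zeros((g.shape[0], 1), np.int32),
                               np.cumsum(het, axis=1)], axis=1)
        cmis = np.concatenate([np.zeros((g.shape[0], 1), np.int32),
                               np.cumsum(mis, axis=1)], axis=1)
        nwin = L - w + 1
        het_w = chet[:, w:] - chet[:, :-w]
        mis_w = cmis[:, w:] - cmis[:, :-w]
        compliant = ((het_w <= p.max_het_in_window) &
                     (mis_w <= p.max_missing_in_window)).astype(np.int32)
        ccomp = np.concatenate([np.zeros((g.shape[0], 1), np.int32),
                                np.cumsum(compliant, axis=1)], axis=1)
        # windows covering SNP j are starts in [j-w+1, j] ∩ [0, nwin-1]
        lo = np.maximum(np.arange(L) - w + 1, 0)
        hi = np.minimum(np.arange(L), nwin - 1)
        n_cover = hi - lo + 1
        ncomp = ccomp[:, hi + 1] - ccomp[:, lo]
        score = ncomp / n_cover[None, :]
        eligible = score > p.window_threshold

        gap_break = np.diff(pos) > p.max_gap_bp
        for a in range(len(ids)):
            e = eligible[a]
            j = 0
            while j < L:
                if not e[j]:
                    j += 1
                    continue
                k = j
                while k + 1 < L and e[k + 1] and not gap_break[k]:
                    k += 1
                length = pos[k] - pos[j]
                nsnp = k - j + 1
                if length >= p.min_length_bp and nsnp >= p.min_snps:
                    segs.append((ids[a], int(c), int(pos[j]), int(pos[k]),
                                 int(nsnp), int(length),
                                 _classify_length(length)))
                j = k + 1
    out = pd.DataFrame(segs, columns=["animal", "chrom", "start_bp", "end_bp",
                                      "n_snps", "length_bp", "roh_class"])
    out.attrs["skipped_chromosomes"] = skipped
    return out


def f_roh(segments: pd.DataFrame, gd: GenotypeDataset) -> pd.DataFrame:
    """Per-animal F_ROH (total and per length class).

    The denominator is the genome span covered by SNPs after QC: the sum
    over chromosomes of (last SNP bp − first SNP bp).
    """
    span = 0.0
    for c, grp in gd.markers.groupby("chrom"):
        span += float(grp["bp"].max() - grp["bp"].min())
    if span <= 0:
        raise AnalysisError("zero genome span")
    ids = gd.samples["id"].to_numpy()
    class_names = [name for _, _, name in ROH_CLASSES]
    out = pd.DataFrame(0.0, index=ids,
                       columns=["F_ROH"] + [f"F_ROH_{n}" for n in class_names])
    out["n_segments"] = 0
    if len(segments):
        for animal, grp in segments.groupby("animal"):
            if animal not in out.index:
                continue
            out.loc[animal, "F_ROH"] = grp["length_bp"].sum() / span
            out.loc[animal, "n_segments"] = len(grp)
            for name, cg in grp.groupby("roh_class"):
                col = f"F_ROH_{name}"
                if col in out.columns:
                    out.loc[animal, col] = cg["length_bp"].sum() / span
    out.index.name = "id"
    return out


# ---------------------------------------------------------------------------
# Homozygosity-by-descent hidden Markov model
# ---------------------------------------------------------------------------

@dataclass
class HbdModelParams:
    """Single-rate two-state HBD model.

    rate : expected number of segment-ending recombination events per
           Morgan (larger -> shorter expected HBD segments)
    mixing : prior probability of the HBD state at a reset
    error : genotyping error probability (heterozygote emission in HBD)
    freq_clip : bound applied to allele frequencies inside emissions
    """
    rate: float = 20.0
    mixing: float = 0.05
    error: float = 0.002
    freq_clip: float = 1e-4

    def __post_init__(self):
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        for name in ("mixing", "error"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")


@dataclass
class HbdResult:
    posterior: np.ndarray        # (n_samples, n_markers) P(HBD)
    f_hbd: pd.Series
    loglik_forward: np.ndarray
    loglik_backward: np.ndarray


def _hbd_emissions(g: np.ndarray, p: np.ndarray, e: float) -> np.ndarray:
    """Emission probabilities, shape (n, L, 2) for states (HBD, non-HBD).

    HBD emits heterozygotes with the error probability and homozygotes in
    proportion to the allele frequency; non-HBD emits Hardy-Weinberg
    genotype probabilities. Missing genotypes emit 1 in both states.
    """
    n, L = g.shape
    B = np.ones((n, L, 2))
    P = np.broadcast_to(p, (n, L))
    hom2 = g == 2
    het = g == 1
    hom0 = g == 0
    B[..., 0] = np.where(hom2, (1 - e) * P,
                np.where(het, e,
                np.where(hom0, (1 - e) * (1 - P), 1.0)))
    B[..., 1] = np.where(hom2, P ** 2,
                np.where(het, 2 * P * (1 - P),
                np.where(hom0, (1 - P) ** 2, 1.0)))
    return B


def hbd_posterior(gd: GenotypeDataset, params: HbdModelParams | None = None,
                  freqs: np.ndarray | None = None,
                  cM_per_Mb: float = 1.0) -> HbdResult:
    """Forward-backward posteriors of the HBD state along each genome.

    The transition over map distance d Morgans leaves the current state
    with probability 1 − exp(−rate·d) and re-draws it from the mixing
    prior, i.e. T = exp(−rate·d)·I + (1 − exp(−rate·d))·1πᵀ. F_HBD is the
    mean posterior HBD probability over all markers.
    """
    p = params or HbdModelParams()
    if freqs is None:
        freqs = gd.allele_freq()
    freqs = np.clip(np.nan_to_num(freqs, nan=0.5), p.freq_clip, 1 - p.freq_clip)
    chrom = gd.markers["chrom"].to_numpy()
    bp = gd.markers["bp"].to_numpy()
    n = gd.n_samples
    pi = np.array([p.mixing, 1.0 - p.mixing])
    post = np.empty((n, gd.n_markers))
    ll_f = np.zeros(n)
    ll_b = np.zeros(n)
    for c in np.unique(chrom):
        cm = chrom == c
        g = gd.geno[:, cm]
        L = int(cm.sum())
        d_m = np.diff(bp[cm]) / 1e6 * cM_per_Mb / 100.0
        stay = np.exp(-p.rate * d_m)
        B = _hbd_emissions(g, freqs[cm], p.error)
        if not np.all(np.isfinite(B)) or np.any(B.sum(axis=2) <= 0):
            bad = int(np.argmax(~np.isfinite(B).all(axis=(0, 2))))
            raise AnalysisError(f"non-finite emission at marker index {bad}")

        # forward with scaling, vectorized over animals
        alpha = np.empty((n, L, 2))
        cscale = np.empty((n, L))
        a = pi[None, :] * B[:, 0, :]
        cscale[:, 0] = a.sum(axis=1)
        alpha[:, 0] = a / cscale[:, 0, None]
        for l in range(1, L):
            s = stay[l - 1]
            pred = s * alpha[:, l - 1] + (1 - s) * pi[None, :]
            a = pred * B[:, l, :]
            cscale[:, l] = a.sum(axis=1)
            alpha[:, l] = a / cscale[:, l, None]
        if np.any(cscale <= 0) or not np.all(np.isfinite(cscale)):
            bad = int(np.argmax(~(np.isfinite(cscale) & (cscale > 0)).all(axis=0)))
            raise AnalysisError(f"non-finite likelihood at marker index {bad}")
        ll_f += np.log(cscale).sum(axis=1)

        # backward with its own scaling
        beta = np.empty((n, L, 2))
        dscale = np.empty((n, L))
        beta[:, L - 1] = 1.0
        dscale[:, L - 1] = 1.0
        for l in range(L - 2, -1, -1):
            s = stay[l]
            nb = B[:, l + 1, :] * beta[:, l + 1]
            # T @ (B*beta): rows of T are s*e_i + (1-s)*pi
            mix = nb @ pi
            b = s * nb + (1 - s) * mix[:, None]
            dscale[:, l] = b.sum(axis=1)
            beta[:, l] = b / dscale[:, l, None]
        first = (pi[None, :] * B[:, 0, :] * beta[:, 0]).sum(axis=1)
        ll_b += np.log(first) + np.log(dscale[:, :-1]).sum(axis=1) \
            if L > 1 else np.log(first)

        gamma = alpha * beta
        gamma /= gamma.sum(axis=2, keepdims=True)
        post[:, cm] = gamma[..., 0]
    fhbd = pd.Series(post.mean(axis=1), index=gd.samples["id"], name="F_HBD")
    return HbdResult(posterior=post, f_hbd=fhbd,
                     loglik_forward=ll_f, loglik_backward=ll_b)


# ---------------------------------------------------------------------------
# Genomic relationship matrix
# ---------------------------------------------------------------------------

def grm_vanraden1(gd: GenotypeDataset, freqs: np.ndarray | None = None
                  ) -> tuple[np.ndarray, pd.Series]:
    """VanRaden method-1 GRM: G = ZZᵀ / Σ2p(1−p) with Z = M − 2p.

    Missing genotypes are mean-imputed per marker (frequency-consistent).
    Returns (G, F_GRM = diag(G) − 1). Frequencies default to the analyzed
    sample; founder frequencies can be supplied for simulations.
    """
    if freqs is None:
        freqs = gd.allele_freq()
    freqs = np.nan_to_num(freqs, nan=0.0)
    denom = float(np.sum(2 * freqs * (1 - freqs)))
    if denom <= 0:
        raise AnalysisError("all markers monomorphic; GRM undefined")
    X = gd.geno.astype(float)
    miss = X < 0
    if miss.any():
        X = np.where(miss, (2 * freqs)[None, :], X)
    Z = X - 2 * freqs[None, :]
    G = Z @ Z.T / denom
    fgrm = pd.Series(np.diag(G) - 1.0, index=gd.samples["id"], name="F_GRM")
    return G, fgrm


# ---------------------------------------------------------------------------
# LD decay
# ---------------------------------------------------------------------------

@dataclass
class LdDecayResult:
    bins: pd.DataFrame           # dist_low, dist_high, mean_r2, n_pairs
    adjacent_mean_dist_bp: float
    adjacent_mean_r2: float


def ld_decay(gd: GenotypeDataset, max_dist_bp: int = 10_000_000,
             bin_width_bp: int = 100_000) -> LdDecayResult:
    """Within-chromosome r² binned by physical distance, plus the
    adjacent-SNP-pair summary."""
    chrom = gd.markers["chrom"].to_numpy()
    bp = gd.markers["bp"].to_numpy()
    nbins = int(math.ceil(max_dist_bp / bin_width_bp))
    sums = np.zeros(nbins)
    counts = np.zeros(nbins, dtype=np.int64)
    adj_d, adj_r2 = [], []
    X = gd.geno.astype(float)
    miss = X < 0
    if miss.any():
        col_mean = np.nanmean(np.where(miss, np.nan, X), axis=0)
        X = np.where(miss, col_mean[None, :], X)
    for c in np.unique(chrom):
        cm = chrom == c
        if cm.sum() < 2:
            continue
        Xc = X[:, cm] - X[:, cm].mean(axis=0)
        norms = np.sqrt((Xc ** 2).sum(axis=0))
        safe = np.where(norms > 0, norms, 1.0)
        Xs = Xc / safe
        r2 = (Xs.T @ Xs) ** 2
        r2[norms == 0, :] = np.nan
        r2[:, norms == 0] = np.nan
        pos = bp[cm]
        iu, ju = np.triu_indices(len(pos), k=1)
        dist = pos[ju] - pos[iu]
        ok = (dist <= max_dist_bp) & np.isfinite(r2[iu, ju])
        bins = np.minimum((dist[ok] // bin_width_bp).astype(int), nbins - 1)
        np.add.at(sums, bins, r2[iu, ju][ok])
        np.add.at(counts, bins, 1)
        adjacent = ju == iu + 1
        okadj = adjacent & np.isfinite(r2[iu, ju])
        adj_d.extend(dist[okadj].tolist())
        adj_r2.extend(r2[iu, ju][okadj].tolist())
    with np.errstate(invalid="ignore"):
        mean_r2 = np.where(counts > 0, sums / counts, np.nan)
    lows = bin_width_bp * np.arange(nbins)
    bins_df = pd.DataFrame({"dist_low": lows, "dist_high": lows + bin_width_bp,
                            "mean_r2": mean_r2, "n_pairs": counts})
    return LdDecayResult(
        bins=bins_df,
        adjacent_mean_dist_bp=float(np.mean(adj_d)) if adj_d else math.nan,
        adjacent_mean_r2=float(np.mean(adj_r2)) if adj_r2 else math.nan)


# ---------------------------------------------------------------------------
# Estimator correlations
# ---------------------------------------------------------------------------

@dataclass
class CorrelationResult:
    matrix: pd.DataFrame
    undefined: list[str]


def inbreeding_correlations(tbl: pd.DataFrame) -> CorrelationResult:
    """Pairwise Pearson correlations among inbreeding estimators.

    Zero-variance columns yield undefined (NaN) entries and are reported
    in ``undefined`` rather than silently dropped.
    """
    complete = tbl.dropna()
    if len(complete) < 3:
        raise AnalysisError("need at least 3 complete rows")
    undefined = [c for c in complete.columns
                 if float(complete[c].std(ddof=0)) == 0.0]
    corr = complete.corr(method="pearson")
    for c in undefined:
        corr.loc[c, :] = np.nan
        corr.loc[:, c] = np.nan
    np.fill_diagonal(corr.values, 1.0)
    return CorrelationResult(matrix=corr, undefined=undefined)
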