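"""Pedigree-based inbreeding, relatedness and probability-of-gene-origin
analyses.

Core quantities:

* F -- individual inbreeding coefficient, computed with the Meuwissen-Luo
  ancestor-tracing algorithm (linear memory, no relationship matrix).
* AR -- average relatedness: twice the mean coancestry of an animal with
  every animal in the pedigree, itself included; computed indirectly via
  the A = T D T' decomposition (Colleau-style matrix-vector products).
* ΔF trend -- cohort rate of inbreeding and its regression on cohort.
* f_e, f_a, GCI -- effective numbers of founders and ancestors (Boichard
  marginal contributions) and the per-animal genetic conservation index.
* Coancestry-based flock differentiation: Wright's FST from mean within-
  vs whole-population coancestry, and Nei's minimum distance.

Unknown parent slots of non-founders are treated as distinct phantom
founders in the gene-origin accounting, so expected contributions always
sum to one.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisError
from .pedigree import PedigreeTable


# ---------------------------------------------------------------------------
# Inbreeding (Meuwissen & Luo) and average relatedness
# ---------------------------------------------------------------------------

def inbreeding_ml(ped: PedigreeTable) -> pd.Series:
    """Per-animal inbreeding coefficients by the Meuwissen-Luo algorithm.

    For each animal i the algorithm traces its ancestor list, accumulating
    L_j coefficients from descendant to ancestor, and evaluates
    1 + F_i = sum_j L_j^2 d_j with d_j the within-family variance of
    ancestor j. Runs in roughly O(n * mean pedigree depth^2) time and O(n)
    memory.
    """
    n = ped.n_animals
    s, d = ped.sire_idx, ped.dam_idx
    F = np.zeros(n)
    dvar = np.empty(n)
    for i in range(n):
        si, di = s[i], d[i]
        if si >= 0 and di >= 0:
            dvar[i] = 0.5 - 0.25 * (F[si] + F[di])
        elif si >= 0:
            dvar[i] = 0.75 - 0.25 * F[si]
        elif di >= 0:
            dvar[i] = 0.75 - 0.25 * F[di]
        else:
            dvar[i] = 1.0
        if si < 0 or di < 0:
            F[i] = 0.0       # parent unknown -> F = 0 by convention
            continue
        # trace ancestors of i from youngest to oldest
        L = {i: 1.0}
        heap = [-i]
        acc = 0.0
        while heap:
            j = -heapq.heappop(heap)
            Lj = L.pop(j)
            acc += Lj * Lj * dvar[j]
            for p in (s[j], d[j]):
                if p >= 0:
                    if p in L:
                        L[p] += 0.5 * Lj
                    else:
                        L[p] = 0.5 * Lj
                        heapq.heappush(heap, -p)
        F[i] = acc - 1.0
    return pd.Series(F, index=ped.ids, name="F")


def _dvec(ped: PedigreeTable, F: np.ndarray) -> np.ndarray:
    """Mendelian sampling variances d (diagonal of D in A = T D T')."""
    s, d = ped.sire_idx, ped.dam_idx
    out = np.ones(ped.n_animals)
    both = (s >= 0) & (d >= 0)
    out[both] = 0.5 - 0.25 * (F[s[both]] + F[d[both]])
    only_s = (s >= 0) & (d < 0)
    out[only_s] = 0.75 - 0.25 * F[s[only_s]]
    only_d = (d >= 0) & (s < 0)
    out[only_d] = 0.75 - 0.25 * F[d[only_d]]
    return out


def a_times_x(ped: PedigreeTable, x: np.ndarray, F: np.ndarray | None = None,
              dvec: np.ndarray | None = None) -> np.ndarray:
    """Product A @ x of the additive relationship matrix with a vector,
    without forming A (via A = T D T')."""
    n = ped.n_animals
    s, d = ped.sire_idx, ped.dam_idx
    if F is None:
        F = inbreeding_ml(ped).to_numpy()
    if dvec is None:
        dvec = _dvec(ped, F)
    u = np.array(x, dtype=float)
    for i in range(n - 1, -1, -1):       # u = T' x
        if s[i] >= 0:
            u[s[i]] += 0.5 * u[i]
        if d[i] >= 0:
            u[d[i]] += 0.5 * u[i]
    u *= dvec
    z = u                                 # z = T (D T' x)
    for i in range(n):
        acc = z[i]
        if s[i] >= 0:
            acc += 0.5 * z[s[i]]
        if d[i] >= 0:
            acc += 0.5 * z[d[i]]
        z[i] = acc
    return z


def average_relatedness(ped: PedigreeTable,
                        F: pd.Series | None = None) -> pd.Series:
    """AR_i = mean additive relationship of animal i with the whole
    pedigree (including itself); twice the mean coancestry."""
    n = ped.n_animals
    Fv = (F if F is not None else inbreeding_ml(ped)).to_numpy()
    z = a_times_x(ped, np.full(n, 1.0 / n), F=Fv)
    return pd.Series(z, index=ped.ids, name="AR")


# ---------------------------------------------------------------------------
# Rate of inbreeding over time
# ---------------------------------------------------------------------------

@dataclass
class DeltaFResult:
    """Cohort-level rate of inbreeding.

    ``cohorts`` holds per-cohort mean F and ΔF; ``mean_delta_f`` is the
    mean per-generation rate; ``slope``/``p_value`` test whether ΔF
    changes across cohorts (OLS, two-sided).
    """
    cohorts: pd.DataFrame
    mean_delta_f: float
    slope: float
    p_value: float
    flag: str | None = None


def delta_f_trend(F: pd.Series, birth_year: pd.Series,
                  L: float) -> DeltaFResult:
    """Bin animals into L-year generation cohorts (anchored at the
    earliest birth year) and compute ΔF_g = (F̄_g − F̄_{g−1})/(1 − F̄_{g−1})."""
    ok = birth_year.notna()
    y = birth_year[ok].astype(float)
    f = F[ok]
    if len(y) == 0:
        raise AnalysisError("no animals with known birth year")
    cohort = np.floor((y - y.min()) / L).astype(int)
    tab = pd.DataFrame({"cohort": cohort, "F": f}).groupby("cohort")["F"] \
        .agg(["mean", "size"]).rename(columns={"mean": "mean_F", "size": "n"})
    tab = tab.sort_index()
    prev = tab["mean_F"].shift(1)
    tab["delta_F"] = (tab["mean_F"] - prev) / (1.0 - prev)
    flag = None
    dF = tab["delta_F"].dropna()
    if len(tab) < 3:
        flag = "fewer than 3 cohorts"
        return DeltaFResult(tab, float(dF.mean()) if len(dF) else math.nan,
                            math.nan, math.nan, flag)
    res = stats.linregress(dF.index.to_numpy(dtype=float), dF.to_numpy())
    return DeltaFResult(tab, float(dF.mean()), float(res.slope),
                        float(res.pvalue), flag)


# ---------------------------------------------------------------------------
# Probability of gene origin
# ---------------------------------------------------------------------------

def founder_contribution_matrix(ped: PedigreeTable
                                ) -> tuple[np.ndarray, list[str]]:
    """Expected founder-genome proportions per animal.

    Returns (C, slot_names): C[i, k] is the expected fraction of animal
    i's genome descending from founder slot k. Each pedigree founder is
    one slot; every unknown-parent side of a non-founder adds a distinct
    phantom slot, so rows sum to one.
    """
    n = ped.n_animals
    s, d = ped.sire_idx, ped.dam_idx
    founder = ped.is_founder
    slots: list[str] = [ped.ids[i] for i in np.flatnonzero(founder)]
    slot_of_founder = {i: k for k, i in enumerate(np.flatnonzero(founder))}
    # count phantom slots first
    phantom: dict[tuple[int, str], int] = {}
    for i in range(n):
        if founder[i]:
            continue
        for pidx, side in ((s[i], "s"), (d[i], "d")):
            if pidx < 0:
                phantom[(i, side)] = len(slots)
                slots.append(f"phantom:{ped.ids[i]}:{side}")
    C = np.zeros((n, len(slots)))
    for i in range(n):
        if founder[i]:
            C[i, slot_of_founder[i]] = 1.0
            continue
        for pidx, side in ((s[i], "s"), (d[i], "d")):
            if pidx >= 0:
                C[i] += 0.5 * C[pidx]
            else:
                C[i, phantom[(i, side)]] += 0.5
    return C, slots


@dataclass
class FounderResult:
    q: pd.Series           # expected founder contributions to the reference set
    f_e: float              # effective number of founders


def founder_contributions(ped: PedigreeTable, reference_ids,
                          C: np.ndarray | None = None,
                          slots: list[str] | None = None) -> FounderResult:
    """Expected founder contributions q_k to a reference set and
    f_e = 1 / sum(q_k^2)."""
    ref = [ped.index_of(a) for a in reference_ids]
    if not ref:
        raise AnalysisError("empty reference set")
    if C is None:
        C, slots = founder_contribution_matrix(ped)
    q = C[ref].mean(axis=0)
    f_e = 1.0 / np.sum(q ** 2)
    return FounderResult(q=pd.Series(q, index=slots, name="q"), f_e=float(f_e))


@dataclass
class AncestorResult:
    """Marginal (Boichard) ancestor contributions to a reference set."""
    table: pd.DataFrame     # rank, id, marginal, accumulated
    f_a: float
    n_50: float             # smallest prefix explaining >= 50%; NaN if never


def marginal_ancestors(ped: PedigreeTable, reference_ids,
                       max_ancestors: int | None = None,
                       tol: float = 1e-9) -> AncestorResult:
    """Greedy selection of ancestors with the highest marginal genetic
    contribution to the reference set.

    Each round propagates reference-genome weight up the pedigree,
    blocking paths through previously selected ancestors (their genes are
    already attributed), and selects the candidate with the largest
    remaining weight. Ties break by older birth year, then lexical id.
    """
    n = ped.n_animals
    s, d = ped.sire_idx, ped.dam_idx
    ref = [ped.index_of(a) for a in reference_ids]
    if not ref:
        raise AnalysisError("empty reference set")

    # candidates: strict ancestors of at least one reference animal
    is_anc = np.zeros(n, dtype=bool)
    seed = np.zeros(n, dtype=bool)
    seed[ref] = True
    for i in range(n - 1, -1, -1):
        if seed[i] or is_anc[i]:
            for p in (s[i], d[i]):
                if p >= 0:
                    is_anc[p] = True
    candidates = np.flatnonzero(is_anc)
    if max_ancestors is None:
        max_ancestors = len(candidates)

    years = ped.birth_year
    ids = ped.ids
    selected: list[int] = []
    marg: list[float] = []
    sel_mask = np.zeros(n, dtype=bool)
    w0 = np.zeros(n)
    for r in ref:
        w0[r] += 1.0 / len(ref)
    for _ in range(max_ancestors):
        w = w0.copy()
        for i in range(n - 1, -1, -1):
            if w[i] > 0 and not sel_mask[i]:
                wi = w[i]
                if s[i] >= 0:
                    w[s[i]] += 0.5 * wi
                if d[i] >= 0:
                    w[d[i]] += 0.5 * wi
        cand = candidates[~sel_mask[candidates]]
        if len(cand) == 0:
            break
        scores = w[cand]
        best = scores.max()
        if best < tol:
            break
        top = cand[scores >= best - 1e-15]
        # deterministic tie-break: older birth year, then lexical id
        key = sorted(top, key=lambda i: (
            years[i] if not np.isnan(years[i]) else np.inf, ids[i]))
        pick = key[0]
        selected.append(pick)
        marg.append(float(w[pick]))
        sel_mask[pick] = True

    marg_arr = np.array(marg)
    acc = np.cumsum(marg_arr)
    table = pd.DataFrame({
        "rank": np.arange(1, len(selected) + 1),
        "id": [ids[i] for i in selected],
        "marginal": marg_arr,
        "accumulated": acc,
    })
    f_a = 1.0 / np.sum(marg_arr ** 2) if len(marg_arr) else math.nan
    above = np.flatnonzero(acc >= 0.5)
    n_50 = float(above[0] + 1) if len(above) else math.nan
    return AncestorResult(table=table, f_a=float(f_a), n_50=n_50)


def gci(ped: PedigreeTable, C: np.ndarray | None = None) -> pd.Series:
    """Genetic conservation index: per animal, the effective number of
    founders in its own ancestry, 1 / sum(P_i^2)."""
    if C is None:
        C, _ = founder_contribution_matrix(ped)
    val = 1.0 / np.sum(C ** 2, axis=1)
    return pd.Series(val, index=ped.ids, name="GCI")


# ---------------------------------------------------------------------------
# Coancestry-based flock differentiation
# ---------------------------------------------------------------------------

@dataclass
class FlockDifferentiation:
    """Within/between-flock coancestries, Wright's FST and Nei's minimum
    distance computed from the pedigree additive relationship (f = a/2,
    self-coancestries (1+F)/2 included in the means)."""
    flock_mean_coancestry: pd.Series
    population_mean_coancestry: float
    fst: float
    fst_per_flock: pd.Series
    nei_distance: pd.DataFrame
    flock_sizes: pd.Series = field(default=None)


def pedigree_fst_nei(ped: PedigreeTable,
                     flocks: pd.Series | None = None) -> FlockDifferentiation:
    """Wright's FST = (f̄ − f̃)/(1 − f̃) with f̄ the size-weighted mean
    within-flock coancestry, and Nei's minimum distance
    D_ij = (f_ii + f_jj)/2 − f_ij for all flock pairs."""
    if flocks is None:
        flocks = pd.Series(ped.df["flock"].to_numpy(), index=ped.ids)
    flocks = flocks.dropna()
    labels = sorted(set(flocks))
    if len(labels) < 1:
        raise AnalysisError("no flock labels")
    members = {lab: [ped.index_of(a) for a in flocks.index[flocks == lab]]
               for lab in labels}
    for lab, m in members.items():
        if len(m) == 0:
            raise AnalysisError(f"flock {lab} is empty")

    n = ped.n_animals
    F = inbreeding_ml(ped).to_numpy()
    dv = _dvec(ped, F)
    idx_all = sorted({i for m in members.values() for i in m})
    x_all = np.zeros(n)
    x_all[idx_all] = 1.0 / len(idx_all)
    z_all = a_times_x(ped, x_all, F=F, dvec=dv)
    f_tilde = float(z_all[idx_all].mean() / 2.0)

    fbar = {}
    cross = pd.DataFrame(index=labels, columns=labels, dtype=float)
    zcols = {}
    for lab in labels:
        x = np.zeros(n)
        x[members[lab]] = 1.0 / len(members[lab])
        zcols[lab] = a_times_x(ped, x, F=F, dvec=dv)
    for la in labels:
        for lb in labels:
            cross.loc[la, lb] = float(zcols[lb][members[la]].mean() / 2.0)
        fbar[la] = cross.loc[la, la]
    sizes = pd.Series({lab: len(members[lab]) for lab in labels})
    wbar = float(np.average([fbar[lab] for lab in labels],
                            weights=sizes[labels]))
    fst = (wbar - f_tilde) / (1.0 - f_tilde)
    fst_per = pd.Series({lab: (fbar[lab] - f_tilde) / (1.0 - f_tilde)
                         for lab in labels})
    nei = pd.DataFrame(index=labels, columns=labels, dtype=float)
    for la in labels:
        for lb in labels:
            nei.loc[la, lb] = ((cross.loc[la, la] + cross.loc[lb, lb]) / 2.0
                               - cross.loc[la, lb])
    np.fill_diagonal(nei.values, 0.0)
    return FlockDifferentiation(
        flock_mean_coancestry=pd.Series(fbar),
        population_mean_coancestry=f_tilde,
        fst=float(fst),
        fst_per_flock=fst_per,
        nei_distance=nei,
        flock_sizes=sizes,
    )
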