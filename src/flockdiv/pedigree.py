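"""Pedigree container, validation, and structural analyses.

The central object is :class:`PedigreeTable`, a validated, topologically
ordered animal/sire/dam table with sex, birth year and flock attributes.
Structural analyses operate on integer parent indexes for speed:
generation-depth metrics, pedigree completeness (MacCluer), subgroup
construction, and the four-path generation interval.

Unknown parents are encoded as ``"0"`` (or empty) on disk and as index
``-1`` internally.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CycleError, PedigreeError, SexConflictError

UNKNOWN = "0"

_SEX_MAP = {
    "M": "M", "m": "M", "1": "M",
    "F": "F", "f": "F", "2": "F",
    "U": "U", "u": "U", "0": "U", "": "U",
}


def _norm_id(x) -> str | None:
    if x is None:
        return None
    s = str(x).strip()
    if s in ("", UNKNOWN, "nan", "NA", "<NA>", "None"):
        return None
    return s


class PedigreeTable:
    """Validated pedigree with records topologically ordered (parents first).

    Parameters
    ----------
    df:
        Frame with columns ``id, sire, dam`` and optionally
        ``sex, birth_year, flock``. Unknown parents may be ``None``,
        ``NaN`` or ``"0"``.
    add_missing_parents:
        If True (default), identifiers referenced as parents but lacking
        their own record are appended as founder records.
    check_birth_years:
        If True (default), a known parent birth year that is not strictly
        earlier than the offspring's is a hard error.
    """

    def __init__(self, df: pd.DataFrame, *, add_missing_parents: bool = True,
                 check_birth_years: bool = True, allow_selfing: bool = False):
        df = df.copy()
        for col in ("id", "sire", "dam"):
            if col not in df.columns:
                raise PedigreeError(f"missing required column {col!r}")
        for col, default in (("sex", "U"), ("birth_year", np.nan), ("flock", None)):
            if col not in df.columns:
                df[col] = default

        df["id"] = df["id"].map(_norm_id)
        if df["id"].isna().any():
            raise PedigreeError("blank animal id")
        df["sire"] = df["sire"].map(_norm_id)
        df["dam"] = df["dam"].map(_norm_id)
        df["sex"] = df["sex"].map(lambda s: _SEX_MAP.get(str(s).strip(), None))
        if df["sex"].isna().any():
            bad = df.loc[df["sex"].isna(), "id"].iloc[0]
            raise PedigreeError(f"unrecognized sex code for animal {bad}")
        df["birth_year"] = pd.to_numeric(df["birth_year"], errors="coerce")
        df["flock"] = df["flock"].map(lambda x: None if x is None or
                                      (isinstance(x, float) and math.isnan(x)) or
                                      str(x).strip() in ("", "nan", UNKNOWN)
                                      else str(x).strip())

        if df["id"].duplicated().any():
            dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
            raise PedigreeError(f"duplicate animal id {dup}")

        known = set(df["id"])
        if add_missing_parents:
            extra = []
            for col, sex in (("sire", "M"), ("dam", "F")):
                for pid in df[col].dropna():
                    if pid not in known:
                        known.add(pid)
                        extra.append({"id": pid, "sire": None, "dam": None,
                                      "sex": sex, "birth_year": np.nan,
                                      "flock": None})
            if extra:
                df = pd.concat([pd.DataFrame(extra), df], ignore_index=True)
        else:
            for col in ("sire", "dam"):
                missing = set(df[col].dropna()) - known
                if missing:
                    raise PedigreeError(
                        f"{col} {sorted(missing)[0]} has no pedigree record")

        # sex-role consistency (hermaphroditic selfing only via explicit flag)
        as_sire = set(df["sire"].dropna())
        as_dam = set(df["dam"].dropna())
        if not allow_selfing:
            both = as_sire & as_dam
            if both:
                raise SexConflictError(
                    f"id {sorted(both)[0]} is used both as sire and as dam")
            sex_by_id = dict(zip(df["id"], df["sex"]))
            for pid in as_sire:
                if sex_by_id[pid] == "F":
                    raise SexConflictError(f"female {pid} used as a sire")
            for pid in as_dam:
                if sex_by_id[pid] == "M":
                    raise SexConflictError(f"male {pid} used as a dam")
            # infer sex from parental role where unrecorded
            df.loc[df["id"].isin(as_sire) & (df["sex"] == "U"), "sex"] = "M"
            df.loc[df["id"].isin(as_dam) & (df["sex"] == "U"), "sex"] = "F"

        df = self._toposort(df)
        df = df.reset_index(drop=True)

        self.df = df
        self._index = {a: i for i, a in enumerate(df["id"])}
        self.sire_idx = np.array([self._index.get(s, -1) if s is not None else -1
                                  for s in df["sire"]], dtype=np.int64)
        self.dam_idx = np.array([self._index.get(d, -1) if d is not None else -1
                                 for d in df["dam"]], dtype=np.int64)
        self.birth_year = df["birth_year"].to_numpy(dtype=float)

        if check_birth_years:
            for pidx in (self.sire_idx, self.dam_idx):
                ok = pidx >= 0
                py = np.where(ok, self.birth_year[np.clip(pidx, 0, None)], np.nan)
                bad = ok & ~np.isnan(py) & ~np.isnan(self.birth_year) & (py >= self.birth_year)
                if bad.any():
                    i = int(np.argmax(bad))
                    raise PedigreeError(
                        f"parent of {df['id'][i]} born in {py[i]:.0f}, "
                        f"not earlier than offspring year {self.birth_year[i]:.0f}")

    @staticmethod
    def _toposort(df: pd.DataFrame) -> pd.DataFrame:
        """Kahn's algorithm over parent links; raises CycleError."""
        ids = list(df["id"])
        pos = {a: i for i, a in enumerate(ids)}
        n = len(ids)
        indeg = np.zeros(n, dtype=np.int64)
        children: list[list[int]] = [[] for _ in range(n)]
        for i, (s, d) in enumerate(zip(df["sire"], df["dam"])):
            for p in (s, d):
                if p is not None:
                    indeg[i] += 1
                    children[pos[p]].append(i)
        queue = deque(i for i in range(n) if indeg[i] == 0)
        order = []
        while queue:
            i = queue.popleft()
            order.append(i)
            for c in children[i]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    queue.append(c)
        if len(order) != n:
            member = ids[int(np.argmax(indeg > 0))]
            raise CycleError(f"pedigree contains a cycle involving {member}")
        return df.iloc[order]

    # -- basic accessors -------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_animals(self) -> int:
        return len(self.df)

    @property
    def ids(self) -> list[str]:
        return list(self.df["id"])

    def index_of(self, animal_id: str) -> int:
        return self._index[animal_id]

    @property
    def is_founder(self) -> np.ndarray:
        """Both parents unknown."""
        return (self.sire_idx < 0) & (self.dam_idx < 0)

    def has_progeny(self) -> np.ndarray:
        out = np.zeros(self.n_animals, dtype=bool)
        out[self.sire_idx[self.sire_idx >= 0]] = True
        out[self.dam_idx[self.dam_idx >= 0]] = True
        return out

    # -- i/o -------------------------------------------------------------
    @classmethod
    def read_csv(cls, path, *, sep: str = ",", **kwargs) -> "PedigreeTable":
        df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
        return cls(df, **kwargs)

    def write_csv(self, path, *, sep: str = ",") -> None:
        out = self.df.copy()
        out["sire"] = out["sire"].map(lambda x: x if x is not None else UNKNOWN)
        out["dam"] = out["dam"].map(lambda x: x if x is not None else UNKNOWN)
        out["flock"] = out["flock"].map(lambda x: x if x is not None else UNKNOWN)
        out["birth_year"] = out["birth_year"].map(
            lambda y: UNKNOWN if pd.isna(y) else str(int(y)))
        out.to_csv(path, sep=sep, index=False)


def read_pedigree(path, *, sep: str = ",", **kwargs) -> PedigreeTable:
    """Read a delimited pedigree file (columns id, sire, dam, ...)."""
    return PedigreeTable.read_csv(path, sep=sep, **kwargs)


# ---------------------------------------------------------------------------
# Generation-depth metrics
# ---------------------------------------------------------------------------

def generation_metrics(ped: PedigreeTable) -> pd.DataFrame:
    """Per-animal generation-depth metrics.

    * ``max_generations`` -- generations to the furthest known ancestor.
    * ``complete_generations`` -- deepest generation at which *all*
      ancestors are known (founder = 0).
    * ``equivalent_complete_generations`` -- sum over known ancestors of
      (1/2)^n with n the generation distance; the symbol *t* used by the
      individual-rate effective-size estimators.
    """
    n = ped.n_animals
    s, d = ped.sire_idx, ped.dam_idx
    maxg = np.zeros(n, dtype=np.int64)
    comp = np.zeros(n, dtype=np.int64)
    equiv = np.zeros(n, dtype=float)
    for i in range(n):
        si, di = s[i], d[i]
        if si >= 0 and di >= 0:
            maxg[i] = 1 + max(maxg[si], maxg[di])
            comp[i] = 1 + min(comp[si], comp[di])
            equiv[i] = 0.5 * (1 + equiv[si]) + 0.5 * (1 + equiv[di])
        elif si >= 0:
            maxg[i] = 1 + maxg[si]
            equiv[i] = 0.5 * (1 + equiv[si])
        elif di >= 0:
            maxg[i] = 1 + maxg[di]
            equiv[i] = 0.5 * (1 + equiv[di])
    return pd.DataFrame({
        "id": ped.ids,
        "max_generations": maxg,
        "complete_generations": comp,
        "equivalent_complete_generations": equiv,
    }).set_index("id")


def pci(ped: PedigreeTable, depth: int = 5) -> pd.Series:
    """Pedigree completeness index (MacCluer) over ``depth`` generations.

    For each parent line, C = (1/d) * sum_i a_i where a_i is the
    proportion of known ancestors in generation i of that line; the index
    is the harmonic-style mean 2*Cs*Cd/(Cs+Cd), 0 if either side is
    entirely unknown.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    n = ped.n_animals
    s, d = ped.sire_idx, ped.dam_idx
    # known[i, g] = number of known ancestors of i at generation g+1
    known = np.zeros((n, depth), dtype=np.int64)
    for i in range(n):
        for p in (s[i], d[i]):
            if p >= 0:
                known[i, 0] += 1
                known[i, 1:] += known[p, :-1]
    denom = 2.0 ** np.arange(depth)  # slots per generation of one parent line

    out = np.zeros(n, dtype=float)
    for i in range(n):
        cs = cd = 0.0
        if s[i] >= 0:
            a = np.ones(depth)
            a[1:] = known[s[i], :-1] / denom[1:]
            cs = a.mean()
        if d[i] >= 0:
            a = np.ones(depth)
            a[1:] = known[d[i], :-1] / denom[1:]
            cd = a.mean()
        if cs > 0 and cd > 0:
            out[i] = 2 * cs * cd / (cs + cd)
    return pd.Series(out, index=ped.ids, name="pci")


# ---------------------------------------------------------------------------
# Subgroups
# ---------------------------------------------------------------------------

def subgroup_birth_years(ped: PedigreeTable, start: int, end: int) -> set[str]:
    """Animals born in [start, end] inclusive."""
    y = ped.birth_year
    mask = ~np.isnan(y) & (y >= start) & (y <= end)
    return {a for a, m in zip(ped.ids, mask) if m}


def subgroup_min_complete(ped: PedigreeTable, base: set[str],
                          min_complete: int = 4,
                          metrics: pd.DataFrame | None = None) -> set[str]:
    """Members of ``base`` with at least ``min_complete`` fully known
    ancestral generations."""
    if metrics is None:
        metrics = generation_metrics(ped)
    ok = metrics["complete_generations"] >= min_complete
    return {a for a in base if ok.get(a, False)}

def subgroup_id_list(ped: PedigreeTable, ids) -> set[str]:
    """Supplied id list intersected with the pedigree."""
    present = set(ped.ids)
    return {str(a) for a in ids} & present


def subgroup_sires_of(ped: PedigreeTable, base: set[str]) -> set[str]:
    """Sires of the animals in ``base``."""
    out = set()
    for a in base:
        i = ped.index_of(a)
        if ped.sire_idx[i] >= 0:
            out.add(ped.ids[ped.sire_idx[i]])
    return out


def build_subgroup(ped: PedigreeTable, kind: str, **kw) -> set[str]:
    """Dispatch on subgroup kind: ``birth_years``, ``min_complete``,
    ``id_list`` or ``sires_of``."""
    if kind == "birth_years":
        return subgroup_birth_years(ped, kw["start"], kw["end"])
    if kind == "min_complete":
        return subgroup_min_complete(ped, kw["base"], kw.get("min_complete", 4),
                                     kw.get("metrics"))
    if kind == "id_list":
        return subgroup_id_list(ped, kw["ids"])
    if kind == "sires_of":
        return subgroup_sires_of(ped, kw["base"])
    raise ValueError(f"unknown subgroup kind {kind!r}")


# ---------------------------------------------------------------------------
# Generation intervals (four-path method)
# ---------------------------------------------------------------------------

PATHS = ("sire_son", "sire_daughter", "dam_son", "dam_daughter")


@dataclass
class GenerationIntervalResult:
    """Four-path generation intervals and their weighted mean L.

    A parent-offspring path contributes only when the offspring itself has
    recorded progeny (the classical 'parents of selected offspring' rule).
    """
    path_means: dict = field(default_factory=dict)
    path_se: dict = field(default_factory=dict)
    path_counts: dict = field(default_factory=dict)
    L: float = float("nan")
    L_se: float = float("nan")
    flag: str | None = None


def generation_intervals(ped: PedigreeTable) -> GenerationIntervalResult:
    values: dict[str, list[float]] = {p: [] for p in PATHS}
    has_prog = ped.has_progeny()
    y = ped.birth_year
    sex = ped.df["sex"].to_numpy()
    for i in range(ped.n_animals):
        if not has_prog[i] or np.isnan(y[i]) or sex[i] == "U":
            continue
        child_role = "son" if sex[i] == "M" else "daughter"
        for pidx, prole in ((ped.sire_idx[i], "sire"), (ped.dam_idx[i], "dam")):
            if pidx >= 0 and not np.isnan(y[pidx]):
                values[f"{prole}_{child_role}"].append(y[i] - y[pidx])

    res = GenerationIntervalResult()
    total_n = 0
    for p in PATHS:
        v = np.asarray(values[p], dtype=float)
        res.path_counts[p] = len(v)
        total_n += len(v)
        if len(v) == 0:
            res.path_means[p] = float("nan")
            res.path_se[p] = float("nan")
        else:
            res.path_means[p] = float(v.mean())
            res.path_se[p] = float(v.std(ddof=1) / math.sqrt(len(v))) if len(v) > 1 else float("nan")
    if total_n == 0:
        res.flag = "no eligible parent-offspring path"
        return res
    w = np.array([res.path_counts[p] / total_n for p in PATHS])
    m = np.array([res.path_means[p] for p in PATHS])
    se = np.array([res.path_se[p] for p in PATHS])
    use = w > 0
    res.L = float(np.sum(w[use] * m[use]))
    if np.all(~np.isnan(se[use])):
        res.L_se = float(math.sqrt(np.sum((w[use] * se[use]) ** 2)))
    return res
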