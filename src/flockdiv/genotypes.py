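"""Genotype container and PLINK-format input/output.

Genotypes are stored as an int8 sample-by-marker matrix of minor-allele
dosages in {0, 1, 2} with -1 for missing, alongside a marker map
(chromosome, bp, alleles) and sample metadata. Both the text PED/MAP and
the binary BED/BIM/FAM (v1.9, SNP-major) PLINK layouts are supported.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import GenotypeError

MISSING = -1
_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])


@dataclass
class GenotypeDataset:
    """Sample-by-marker dosage matrix plus metadata.

    samples : DataFrame with columns id, sex, birth_year, flock
    markers : DataFrame with columns chrom, snp_id, cM, bp, a1, a2
              (a1 is the counted allele); positions strictly increasing
              within each chromosome
    geno    : int8 array (n_samples, n_markers), values in {-1, 0, 1, 2}
    """
    samples: pd.DataFrame
    markers: pd.DataFrame
    geno: np.ndarray

    def __post_init__(self):
        self.samples = self.samples.reset_index(drop=True)
        self.markers = self.markers.reset_index(drop=True)
        self.geno = np.asarray(self.geno, dtype=np.int8)
        if self.geno.shape != (len(self.samples), len(self.markers)):
            raise GenotypeError(
                f"genotype matrix shape {self.geno.shape} does not match "
                f"{len(self.samples)} samples x {len(self.markers)} markers")
        bad = ~np.isin(self.geno, (-1, 0, 1, 2))
        if bad.any():
            raise GenotypeError("genotype values outside {-1, 0, 1, 2}")
        for c, grp in self.markers.groupby("chrom", sort=False):
            pos = grp["bp"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise GenotypeError(
                    f"marker positions not strictly increasing on chrom {c}")

    # -- shapes ---------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    # -- summaries ------------------------------------------------------
    def allele_freq(self) -> np.ndarray:
        """Frequency of the counted allele (a1) from non-missing calls."""
        g = self.geno
        obs = g >= 0
        cnt = np.where(obs, g, 0).sum(axis=0)
        denom = 2.0 * obs.sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(denom > 0, cnt / denom, np.nan)

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def sample_call_rate(self) -> np.ndarray:
        return (self.geno >= 0).mean(axis=1)

    def marker_call_rate(self) -> np.ndarray:
        return (self.geno >= 0).mean(axis=0)

    # -- subsetting -----------------------------------------------------
    def subset(self, sample_mask=None, marker_mask=None) -> "GenotypeDataset":
        s = np.arange(self.n_samples) if sample_mask is None else np.asarray(sample_mask)
        m = np.arange(self.n_markers) if marker_mask is None else np.asarray(marker_mask)
        if s.dtype == bool:
            s = np.flatnonzero(s)
        if m.dtype == bool:
            m = np.flatnonzero(m)
        return GenotypeDataset(samples=self.samples.iloc[s],
                               markers=self.markers.iloc[m],
                               geno=self.geno[np.ix_(s, m)])

    # -- PED/MAP --------------------------------------------------------
    def write_ped_map(self, prefix) -> None:
        prefix = Path(prefix)
        sexcode = {"M": "1", "F": "2", "U": "0"}
        a1 = self.markers["a1"].to_numpy()
        a2 = self.markers["a2"].to_numpy()
        with open(prefix.with_suffix(".ped"), "w") as fh:
            for i in range(self.n_samples):
                row = self.samples.iloc[i]
                fid = row.get("flock") or "0"
                parts = [str(fid), str(row["id"]), "0", "0",
                         sexcode.get(row.get("sex", "U"), "0"), "-9"]
                g = self.geno[i]
                for j in range(self.n_markers):
                    if g[j] == 2:
                        parts += [a1[j], a1[j]]
                    elif g[j] == 1:
                        parts += [a1[j], a2[j]]
                    elif g[j] == 0:
                        parts += [a2[j], a2[j]]
                    else:
                        parts += ["0", "0"]
                fh.write(" ".join(parts) + "\n")
        with open(prefix.with_suffix(".map"), "w") as fh:
            for _, m in self.markers.iterrows():
                fh.write(f"{m['chrom']} {m['snp_id']} {m['cM']:g} {int(m['bp'])}\n")

    @classmethod
    def read_ped_map(cls, prefix) -> "GenotypeDataset":
        prefix = Path(prefix)
        markers = _read_map(prefix.with_suffix(".map"))
        n_mark = len(markers)
        ids, sexes, flocks, rows = [], [], [], []
        sexname = {"1": "M", "2": "F"}
        with open(prefix.with_suffix(".ped")) as fh:
            for ln, line in enumerate(fh, 1):
                f = line.split()
                if not f:
                    continue
                if len(f) != 6 + 2 * n_mark:
                    raise GenotypeError(
                        f"PED line {ln}: expected {6 + 2 * n_mark} fields, "
                        f"got {len(f)}")
                flocks.append(None if f[0] == "0" else f[0])
                ids.append(f[1])
                sexes.append(sexname.get(f[4], "U"))
                rows.append(f[6:])
        allele_pairs = np.array(rows, dtype="U4").reshape(len(ids), n_mark, 2)
        geno, a1, a2 = _recode_minor(allele_pairs)
        markers["a1"] = a1
        markers["a2"] = a2
        samples = pd.DataFrame({"id": ids, "sex": sexes,
                                "birth_year": np.nan, "flock": flocks})
        return cls(samples=samples, markers=markers, geno=geno)

    # -- BED/BIM/FAM ----------------------------------------------------
    def write_bed(self, prefix) -> None:
        prefix = Path(prefix)
        n = self.n_samples
        with open(prefix.with_suffix(".fam"), "w") as fh:
            sexcode = {"M": "1", "F": "2", "U": "0"}
            for _, row in self.samples.iterrows():
                fid = row.get("flock") or "0"
                fh.write(f"{fid} {row['id']} 0 0 "
                         f"{sexcode.get(row.get('sex', 'U'), '0')} -9\n")
        with open(prefix.with_suffix(".bim"), "w") as fh:
            for _, m in self.markers.iterrows():
                fh.write(f"{m['chrom']} {m['snp_id']} {m['cM']:g} "
                         f"{int(m['bp'])} {m['a1']} {m['a2']}\n")
        # SNP-major 2-bit codes: 00 hom-a1, 01 missing, 10 het, 11 hom-a2
        code = np.empty_like(self.geno, dtype=np.uint8)
        code[self.geno == 2] = 0b00
        code[self.geno == MISSING] = 0b01
        code[self.geno == 1] = 0b10
        code[self.geno == 0] = 0b11
        nbytes = (n + 3) // 4
        padded = np.zeros((self.n_markers, nbytes * 4), dtype=np.uint8)
        padded[:, :n] = code.T
        shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
        packed = (padded.reshape(self.n_markers, nbytes, 4) <<
                  shifts).sum(axis=2).astype(np.uint8)
        with open(prefix.with_suffix(".bed"), "wb") as fh:
            fh.write(_BED_MAGIC)
            fh.write(packed.tobytes())

    @classmethod
    def read_bed(cls, prefix) -> "GenotypeDataset":
        prefix = Path(prefix)
        fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None,
                          names=["fid", "id", "pat", "mat", "sex", "pheno"],
                          dtype=str)
        sexname = {"1": "M", "2": "F"}
        samples = pd.DataFrame({
            "id": fam["id"], "sex": fam["sex"].map(lambda s: sexname.get(s, "U")),
            "birth_year": np.nan,
            "flock": fam["fid"].map(lambda f: None if f == "0" else f)})
        bim = pd.read_csv(prefix.with_suffix(".bim"), sep=r"\s+", header=None,
                          names=["chrom", "snp_id", "cM", "bp", "a1", "a2"])
        n, n_mark = len(fam), len(bim)
        raw = Path(prefix.with_suffix(".bed")).read_bytes()
        if raw[:3] != _BED_MAGIC:
            raise GenotypeError("bad BED magic bytes (expected v1.9 SNP-major)")
        nbytes = (n + 3) // 4
        body = np.frombuffer(raw[3:], dtype=np.uint8)
        if len(body) != n_mark * nbytes:
            raise GenotypeError(
                f"BED payload is {len(body)} bytes; expected {n_mark * nbytes}")
        body = body.reshape(n_mark, nbytes)
        shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
        codes = ((body[:, :, None] >> shifts) & 0b11).reshape(n_mark, nbytes * 4)
        codes = codes[:, :n].T
        geno = np.empty((n, n_mark), dtype=np.int8)
        geno[codes == 0b00] = 2
        geno[codes == 0b01] = MISSING
        geno[codes == 0b10] = 1
        geno[codes == 0b11] = 0
        markers = bim[["chrom", "snp_id", "cM", "bp", "a1", "a2"]].copy()
        return cls(samples=samples, markers=markers, geno=geno)


def _read_map(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            f = line.split()
            if not f:
                continue
            if len(f) != 4:
                raise GenotypeError(f"MAP line {ln}: expected 4 fields")
            rows.append((int(f[0]), f[1], float(f[2]), int(f[3])))
    return pd.DataFrame(rows, columns=["chrom", "snp_id", "cM", "bp"])


def _recode_minor(allele_pairs: np.ndarray
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Recode observed allele pairs as minor-allele dosages.

    '0' denotes a missing allele (the '0 0' PLINK convention). The counted
    allele a1 is the lower-frequency one; ties break lexicographically.
    """
    n, n_mark, _ = allele_pairs.shape
    geno = np.full((n, n_mark), MISSING, dtype=np.int8)
    a1 = np.empty(n_mark, dtype=object)
    a2 = np.empty(n_mark, dtype=object)
    for j in range(n_mark):
        col = allele_pairs[:, j, :]
        obs = col[col != "0"]
        uniq, counts = np.unique(obs, return_counts=True)
        if len(uniq) > 2:
            raise GenotypeError(f"marker column {j}: more than two alleles")
        if len(uniq) == 0:
            a1[j], a2[j] = "A", "B"
            continue
        if len(uniq) == 1:
            # monomorphic: the counted (minor) allele was never observed
            a1[j] = "A" if uniq[0] != "A" else "B"
            a2[j] = uniq[0]
            order = [a1[j], a2[j]]
        else:
            if counts[0] < counts[1] or (counts[0] == counts[1] and
                                         uniq[0] < uniq[1]):
                order = [uniq[0], uniq[1]]
            else:
                order = [uniq[1], uniq[0]]
            a1[j], a2[j] = order
        minor = order[0]
        called = ~np.any(col == "0", axis=1)
        geno[called, j] = (col[called] == minor).sum(axis=1)
    return geno, a1.astype(str), a2.astype(str)


def intersect_datasets(datasets: list[GenotypeDataset]
                       ) -> tuple[GenotypeDataset, list[str]]:
    """Merge datasets on shared markers (chrom + position + alleles).

    Markers present in every dataset are kept; a dataset whose allele
    labels are swapped relative to the first has its dosage flipped
    (2 - dosage). Markers with irreconcilable alleles are dropped and
    reported. Samples are concatenated with a ``dataset`` source label.
    """
    if not datasets:
        raise GenotypeError("no datasets to intersect")
    keysets = []
    for ds in datasets:
        keysets.append({(c, b): i for i, (c, b) in
                        enumerate(zip(ds.markers["chrom"], ds.markers["bp"]))})
    common = set(keysets[0])
    for ks in keysets[1:]:
        common &= set(ks)
    dropped: list[str] = []
    ref = datasets[0]
    keep_keys = []
    flip_flags = []   # per key, list of per-dataset flip booleans
    for key in sorted(common):
        i0 = keysets[0][key]
        ra1, ra2 = ref.markers["a1"].iloc[i0], ref.markers["a2"].iloc[i0]
        flips = [False]
        ok = True
        for ds, ks in zip(datasets[1:], keysets[1:]):
            i = ks[key]
            a1, a2 = ds.markers["a1"].iloc[i], ds.markers["a2"].iloc[i]
            if (a1, a2) == (ra1, ra2):
                flips.append(False)
            elif (a1, a2) == (ra2, ra1):
                flips.append(True)
            else:
                dropped.append(f"chrom {key[0]} bp {key[1]}: alleles "
                               f"{a1}/{a2} vs {ra1}/{ra2}")
                ok = False
                break
        if ok:
            keep_keys.append(key)
            flip_flags.append(flips)
    if not keep_keys:
        raise GenotypeError("empty marker intersection")

    blocks = []
    samples = []
    for k, ds in enumerate(datasets):
        ks = keysets[k]
        idx = np.array([ks[key] for key in keep_keys])
        g = ds.geno[:, idx].copy()
        flip = np.array([fl[k] for fl in flip_flags])
        if flip.any():
            sub = g[:, flip]
            miss = sub == MISSING
            sub = (2 - sub).astype(np.int8)
            sub[miss] = MISSING
            g[:, flip] = sub
        blocks.append(g)
        s = ds.samples.copy()
        s["dataset"] = f"ds{k}"
        samples.append(s)
    i0s = [keysets[0][key] for key in keep_keys]
    markers = ref.markers.iloc[i0s].reset_index(drop=True)
    merged = GenotypeDataset(samples=pd.concat(samples, ignore_index=True),
                             markers=markers,
                             geno=np.vstack(blocks))
    return merged, dropped
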