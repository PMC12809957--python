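import numpy as np
import pandas as pd
import pytest

from flockdiv import GenotypeDataset, PedigreeTable


def make_pedigree(rows) -> PedigreeTable:
    """Rows of (id, sire, dam, sex, birth_year, flock)."""
    return PedigreeTable(pd.DataFrame(
        rows, columns=["id", "sire", "dam", "sex", "birth_year", "flock"]))


def make_dataset(geno, bp=None, chrom=None, flocks=None,
                 spacing=100_000) -> GenotypeDataset:
    geno = np.asarray(geno, dtype=np.int8)
    n, L = geno.shape
    if bp is None:
        bp = (np.arange(L) + 1) * spacing
    if chrom is None:
        chrom = np.ones(L, dtype=int)
    samples = pd.DataFrame({
        "id": [f"s{i}" for i in range(n)],
        "sex": "M", "birth_year": 2000,
        "flock": flocks if flocks is not None else "1"})
    markers = pd.DataFrame({
        "chrom": chrom, "snp_id": [f"m{j}" for j in range(L)],
        "cM": np.asarray(bp) / 1e6, "bp": bp, "a1": "A", "a2": "B"})
    return GenotypeDataset(samples=samples, markers=markers, geno=geno)


@pytest.fixture
def fullsib_line() -> PedigreeTable:
    """Repeated full-sib mating: generation g >= 2 has
    F = 0.25, 0.375, 0.5, 0.59375, ..."""
    rows = [("s0", None, None, "M", 2000, "1"),
            ("d0", None, None, "F", 2000, "1")]
    for g in range(1, 6):
        rows.append((f"s{g}", f"s{g-1}", f"d{g-1}", "M", 2000 + g, "1"))
        rows.append((f"d{g}", f"s{g-1}", f"d{g-1}", "F", 2000 + g, "1"))
    return make_pedigree(rows)
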