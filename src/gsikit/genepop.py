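"""GENEPOP interchange format (two-digit allele codes).

Allele 1 is coded "01", allele 2 "02" and missing "00"; a missing genotype is
"0000".  Populations are separated by lines consisting of "Pop" and
individuals are named before a comma.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import BaselineDataset, GenotypeMatrix

_GENO_FROM_DOSAGE = {2.0: "0101", 1.0: "0102", 0.0: "0202"}
_DOSAGE_FROM_GENO = {
    frozenset(("01", "01")): 2.0,
    frozenset(("01", "02")): 1.0,
    frozenset(("02", "02")): 0.0,
}


def write_genepop(baseline: BaselineDataset, path, title: str = "gsikit export") -> None:
    dos = baseline.genotypes.dosage
    labels = baseline.labels()
    with open(path, "w") as fh:
        fh.write(title + "\n")
        for m in dos.columns:
            fh.write(str(m) + "\n")
        for pop in dict.fromkeys(labels):
            fh.write("Pop\n")
            for ind in labels.index[labels == pop]:
                codes = [
                    _GENO_FROM_DOSAGE.get(dos.at[ind, m], "0000") for m in dos.columns
                ]
                fh.write(f"{ind} ,  " + " ".join(codes) + "\n")


def read_genepop(path) -> BaselineDataset:
    """Parse a GENEPOP file into a BaselineDataset.

    Population labels are pop1, pop2, ... in file order (GENEPOP itself does
    not name populations); "00" alleles are missing.  Malformed lines raise
    with the offending line number.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ValueError("empty GENEPOP file")
    loci: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        for name in lines[i].split(","):
            if name.strip():
                loci.append(name.strip())
        i += 1
    if i == len(lines):
        raise ValueError("no 'Pop' separator found")

    ids, dosages, pops = [], [], []
    pop_idx = 0
    for lineno, raw in enumerate(lines[i:], start=i + 1):
        line = raw.strip()
        if not line:
            continue
        if line.lower() == "pop":
            pop_idx += 1
            continue
        if "," not in line:
            raise ValueError(f"line {lineno}: expected 'name , genotypes'")
        name, genos = line.split(",", 1)
        codes = genos.split()
        if len(codes) != len(loci):
            raise ValueError(
                f"line {lineno}: expected {len(loci)} genotypes, got {len(codes)}"
            )
        row = []
        for code in codes:
            if len(code) != 4 or not code.isdigit():
                raise ValueError(f"line {lineno}: malformed genotype {code!r}")
            a1, a2 = code[:2], code[2:]
            if a1 == "00" or a2 == "00":
                row.append(np.nan)
            else:
                key = frozenset((a1, a2))
                if key not in _DOSAGE_FROM_GENO:
                    raise ValueError(f"line {lineno}: unknown allele codes {code!r}")
                row.append(_DOSAGE_FROM_GENO[key])
        ids.append(name.strip())
        pops.append(f"pop{pop_idx}")
        dosages.append(row)
    if not ids:
        raise ValueError("no individuals found")
    dosage = pd.DataFrame(dosages, index=ids, columns=loci)
    meta = pd.DataFrame(
        {
            "individual": ids,
            "population": pops,
            "stage": 3,
            "quarter": np.nan,
            "spawning": True,
        }
    )
    return BaselineDataset(GenotypeMatrix(dosage), meta)
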