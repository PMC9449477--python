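"""In-memory containers shared across the pipeline.

Genotypes are held as allele-1 dosages (0/1/2) in a pandas DataFrame with
``NaN`` for missing calls; categorical call strings ("hom1", "het", "hom2",
"missing") are derived views.  Read counts are a pair of aligned integer
DataFrames (allele-1 and allele-2 counts).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CALL_FROM_DOSAGE = {2.0: "hom1", 1.0: "het", 0.0: "hom2"}
DOSAGE_FROM_CALL = {"hom1": 2.0, "het": 1.0, "hom2": 0.0, "missing": np.nan}


@dataclass
class GenotypeMatrix:
    """Individuals x markers dosage matrix (count of allele 1, NaN missing)."""

    dosage: pd.DataFrame  # float values in {0,1,2,NaN}

    def __post_init__(self) -> None:
        vals = self.dosage.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosages must be 0, 1, 2 or NaN")
        self.dosage = self.dosage.astype(float)

    @property
    def individuals(self) -> list[str]:
        return list(self.dosage.index)

    @property
    def markers(self) -> list[str]:
        return list(self.dosage.columns)

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosage.shape[1]

    def calls(self) -> pd.DataFrame:
        """Categorical view: hom1 / het / hom2 / missing."""
        vals = self.dosage.to_numpy(dtype=float)
        out = np.full(vals.shape, "missing", dtype=object)
        for d, name in CALL_FROM_DOSAGE.items():
            out[vals == d] = name
        return pd.DataFrame(out, index=self.dosage.index, columns=self.dosage.columns)

    def n_called(self) -> pd.Series:
        """Number of non-missing calls per individual."""
        return self.dosage.notna().sum(axis=1)

    def subset(self, individuals=None, markers=None) -> "GenotypeMatrix":
        d = self.dosage
        if individuals is not None:
            d = d.loc[list(individuals)]
        if markers is not None:
            d = d[list(markers)]
        return GenotypeMatrix(d.copy())

    @classmethod
    def from_calls(cls, calls: pd.DataFrame) -> "GenotypeMatrix":
        vals = calls.to_numpy(dtype=object)
        unknown = set(vals.ravel()) - set(DOSAGE_FROM_CALL)
        if unknown:
            raise ValueError(f"unknown calls: {sorted(map(str, unknown))}")
        out = np.full(vals.shape, np.nan)
        for call, d in DOSAGE_FROM_CALL.items():
            out[vals == call] = d
        return cls(pd.DataFrame(out, index=calls.index, columns=calls.columns))


@dataclass
class AlleleCountTable:
    """Per individual x marker read counts for each of the two alleles."""

    count1: pd.DataFrame
    count2: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.count1.index.equals(self.count2.index) or not self.count1.columns.equals(
            self.count2.columns
        ):
            raise ValueError("count1 and count2 must be aligned")
        if (self.count1.to_numpy() < 0).any() or (self.count2.to_numpy() < 0).any():
            raise ValueError("read counts must be non-negative")

    @property
    def individuals(self) -> list[str]:
        return list(self.count1.index)

    @property
    def markers(self) -> list[str]:
        return list(self.count1.columns)

    def depth(self) -> pd.DataFrame:
        return self.count1 + self.count2

    def to_long(self) -> pd.DataFrame:
        long1 = self.count1.stack().rename("count_allele1")
        long2 = self.count2.stack().rename("count_allele2")
        out = pd.concat([long1, long2], axis=1).reset_index()
        out.columns = ["individual", "marker", "count_allele1", "count_allele2"]
        return out

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "AlleleCountTable":
        c1 = df.pivot(index="individual", columns="marker", values="count_allele1")
        c2 = df.pivot(index="individual", columns="marker", values="count_allele2")
        return cls(c1.fillna(0).astype(int), c2.fillna(0).astype(int))


METADATA_COLUMNS = ("individual", "population", "stage", "quarter", "spawning")


@dataclass
class BaselineDataset:
    """Genotypes plus per-individual metadata with population labels."""

    genotypes: GenotypeMatrix
    metadata: pd.DataFrame  # columns: individual, population, stage, quarter, spawning

    def __post_init__(self) -> None:
        meta = self.metadata.set_index("individual", drop=False) if (
            self.metadata.index.name != "individual"
            and "individual" in self.metadata.columns
        ) else self.metadata
        missing = set(self.genotypes.individuals) - set(meta.index)
        if missing:
            raise ValueError(f"metadata missing for individuals: {sorted(missing)[:5]} ...")
        self.metadata = meta.loc[self.genotypes.individuals]

    @property
    def populations(self) -> list[str]:
        return list(dict.fromkeys(self.metadata["population"]))

    def labels(self) -> pd.Series:
        return self.metadata["population"]

    def subset(self, individuals) -> "BaselineDataset":
        individuals = list(individuals)
        return BaselineDataset(
            self.genotypes.subset(individuals=individuals),
            self.metadata.loc[individuals].reset_index(drop=True),
        )

    def group_sizes(self) -> pd.Series:
        return self.metadata["population"].value_counts()
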