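"""SNP marker panel description.

A panel is a small table of amplicon markers: each marker has an id, a
chromosome, a locus-block id (markers within a block are physically linked
and behave as one locus), the two alleles of the SNP, and optional per-marker
overrides of the genotype-caller ratio zones.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

REQUIRED_COLUMNS = ("marker", "chrom", "block", "allele1", "allele2")


@dataclass
class MarkerPanel:
    """Table of markers with locus-block structure.

    Parameters
    ----------
    table
        DataFrame with columns ``marker, chrom, block, allele1, allele2``.
    thresholds
        Optional per-marker caller-threshold overrides keyed by marker id;
        values are :class:`~gsikit.genotyping.CallerThresholds`.
    """

    table: pd.DataFrame
    thresholds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"panel table missing columns: {missing}")
        if self.table["marker"].duplicated().any():
            raise ValueError("duplicate marker ids in panel")
        self.table = self.table.reset_index(drop=True)

    @property
    def markers(self) -> list[str]:
        return list(self.table["marker"])

    @property
    def blocks(self) -> list:
        """Distinct locus-block ids in panel order."""
        return list(dict.fromkeys(self.table["block"]))

    @property
    def n_markers(self) -> int:
        return len(self.table)

    def block_of(self, marker: str):
        row = self.table.loc[self.table["marker"] == marker]
        if row.empty:
            raise KeyError(f"unknown marker {marker!r}")
        return row["block"].iloc[0]

    def markers_in_block(self, block) -> list[str]:
        return list(self.table.loc[self.table["block"] == block, "marker"])

    @classmethod
    def from_csv(cls, path) -> "MarkerPanel":
        return cls(pd.read_csv(path, comment="#"))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def default_panel() -> MarkerPanel:
    """A 45-marker panel grouped into 14 locus blocks on 8 chromosomes.

    Mirrors the geometry of a typical herring stock-discrimination panel:
    linked markers are deliberately retained within blocks for redundancy
    against missing genotypes.
    """
    # block sizes sum to 45; blocks spread over 8 chromosomes
    block_sizes = [4, 3, 3, 4, 3, 3, 3, 3, 3, 4, 3, 3, 3, 3]
    block_chrom = [1, 1, 2, 2, 3, 3, 4, 4, 5, 5, 6, 6, 7, 8]
    rows = []
    for b, (size, chrom) in enumerate(zip(block_sizes, block_chrom), start=1):
        for j in range(size):
            rows.append(
                {
                    "marker": f"chr{chrom}_b{b:02d}_m{j + 1}",
                    "chrom": chrom,
                    "block": b,
                    "allele1": "A",
                    "allele2": "G",
                }
            )
    return MarkerPanel(pd.DataFrame(rows))
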