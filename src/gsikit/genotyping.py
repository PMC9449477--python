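"""Amplicon demultiplexing and allele-ratio genotype calling.

Reads carry an 11 bp combinatorial barcode at each end (96 barcodes, half
tagged with an M13-R universal tail and half with a CAG tail, giving 48 x 48
usable pairs); inside the barcodes sit locus-specific primers.  Reads are
sorted hierarchically into five categories and only reads with two barcodes
and two matching primers are counted.

Genotypes are called from the allele-1 / allele-2 read-count ratio r:
hom1 for r >= 5.0, hom2 for r <= 0.2, het for 0.3 <= r <= 3.33, and no call
in the gap zones (0.2, 0.3) and (3.33, 5.0) or when total depth < 10 reads.
"""
from __future__ import annotations

import enum
import gzip
import logging
import math
from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd

from .containers import AlleleCountTable, BaselineDataset, GenotypeMatrix
from .panel import MarkerPanel

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class ReadCategory(enum.Enum):
    NO_BARCODE = "no_barcode"
    ONE_BARCODE = "one_barcode"
    TWO_BARCODES_NO_PRIMERS = "two_barcodes_no_primers"
    TWO_BARCODES_NONMATCHING_PRIMERS = "two_barcodes_nonmatching_primers"
    TWO_BARCODES_MATCHING_PRIMERS = "two_barcodes_matching_primers"


@dataclass
class CallerThresholds:
    """Allele-ratio zones for the genotype caller.

    The zones are closed on the called side: hom1 on [hom1_min_ratio, +inf],
    hom2 on [0, hom2_max_ratio], het on [het_lo, het_hi]; everything between
    is a no-call (NA) zone, as is any cell with total depth < min_depth.
    """

    min_depth: int = 10
    hom1_min_ratio: float = 5.0
    hom2_max_ratio: float = 0.2
    het_lo: float = 0.3
    het_hi: float = 3.33

    def __post_init__(self) -> None:
        if not (0 < self.hom2_max_ratio < self.het_lo < 1 < self.het_hi < self.hom1_min_ratio):
            raise ValueError(
                "thresholds must satisfy 0 < hom2_max_ratio < het_lo < 1 "
                "< het_hi < hom1_min_ratio"
            )
        if self.min_depth < 0:
            raise ValueError("min_depth must be >= 0")


@dataclass
class BarcodeScheme:
    """96 combinatorial 11 bp barcodes and the (forward, reverse) -> individual map.

    ``tail_assignment`` tags each barcode with its universal tail class
    ("M13-R" or "CAG", 48 each); a valid pair combines one barcode of each
    class, which is what makes 48 x 48 = 2304 combinations addressable.
    """

    barcodes: dict  # barcode id -> 11 bp sequence
    tail_assignment: dict  # barcode id -> "M13-R" | "CAG"
    pair_to_individual: dict  # (fwd barcode id, rev barcode id) -> individual id

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.barcodes.values()}
        if lengths and lengths != {11}:
            raise ValueError("barcodes must be 11 bp")
        counts = pd.Series(list(self.tail_assignment.values())).value_counts()
        classes = set(self.tail_assignment.values())
        if not classes <= {"M13-R", "CAG"}:
            raise ValueError(f"unknown tail classes: {classes - {'M13-R', 'CAG'}}")
        # injectivity of the pair map
        targets = list(self.pair_to_individual.values())
        if len(targets) != len(set(targets)):
            raise ValueError("pair_to_individual must be injective")
        self._by_seq = {seq: bid for bid, seq in self.barcodes.items()}

    @classmethod
    def from_csv(cls, barcode_path, pairs_path=None) -> "BarcodeScheme":
        bc = pd.read_csv(barcode_path, comment="#")
        barcodes = dict(zip(bc["barcode"], bc["sequence"]))
        tails = dict(zip(bc["barcode"], bc["tail"]))
        pairs = {}
        if pairs_path is not None:
            pr = pd.read_csv(pairs_path, comment="#")
            pairs = {
                (row["forward"], row["reverse"]): row["individual"] for _, row in pr.iterrows()
            }
        return cls(barcodes, tails, pairs)


def levenshtein(a: str, b: str) -> int:
    """Edit distance via edlib (global alignment)."""
    return edlib.align(a, b, task="distance")["editDistance"]


def match_barcode(sequence_end: str, scheme: BarcodeScheme, max_distance: int = 1):
    """Best barcode within ``max_distance`` edits of ``sequence_end``.

    Returns the barcode id, or None when nothing is close enough or when two
    barcodes tie at the minimum distance (ambiguity is never guessed).
    """
    if max_distance < 0:
        raise ValueError("max_distance must be >= 0")
    seq = sequence_end.upper()
    best_id, best_d, tie = None, None, False
    for bid, bseq in scheme.barcodes.items():
        d = levenshtein(seq, bseq)
        if best_d is None or d < best_d:
            best_id, best_d, tie = bid, d, False
        elif d == best_d:
            tie = True
    if best_d is None or best_d > max_distance or tie:
        return None
    return best_id


def _match_primer(segment: str, primers: dict, max_distance: int):
    """Best marker whose primer is a prefix of ``segment`` (<= max_distance edits)."""
    best, best_d, tie = None, None, False
    for marker, primer in primers.items():
        window = segment[: len(primer)]
        d = levenshtein(window, primer)
        if best_d is None or d < best_d:
            best, best_d, tie = marker, d, False
        elif d == best_d:
            tie = True
    if best_d is None or best_d > max_distance or tie:
        return None
    return best


def categorize_read(
    read: str,
    scheme: BarcodeScheme,
    primer_set: dict,
    max_distance: int = 1,
):
    """Hierarchical sorting of one read into exactly one of five categories.

    ``primer_set`` maps marker id -> (forward primer, reverse primer).
    Returns ``(ReadCategory, individual id or None, marker id or None,
    trimmed insert or None)``; individual/marker are only produced for
    TWO_BARCODES_MATCHING_PRIMERS.  The barcode (and primer) sequence is
    removed from the returned insert before downstream counting.
    """
    read = read.strip().upper()
    if len(read) < 22:
        return ReadCategory.NO_BARCODE, None, None, None
    fwd = match_barcode(read[:11], scheme, max_distance)
    rev = match_barcode(reverse_complement(read[-11:]), scheme, max_distance)
    n_found = (fwd is not None) + (rev is not None)
    if n_found == 0:
        return ReadCategory.NO_BARCODE, None, None, None
    if n_found == 1:
        return ReadCategory.ONE_BARCODE, None, None, None

    core = read[11:-11]
    fwd_primers = {m: p[0] for m, p in primer_set.items()}
    rev_primers = {m: p[1] for m, p in primer_set.items()}
    m_fwd = _match_primer(core, fwd_primers, max_distance)
    m_rev = _match_primer(reverse_complement(core), rev_primers, max_distance)
    if m_fwd is None and m_rev is None:
        return ReadCategory.TWO_BARCODES_NO_PRIMERS, None, None, None
    if m_fwd is None or m_rev is None or m_fwd != m_rev:
        return ReadCategory.TWO_BARCODES_NONMATCHING_PRIMERS, None, None, None

    individual = scheme.pair_to_individual.get((fwd, rev))
    fwd_len = len(fwd_primers[m_fwd])
    rev_len = len(rev_primers[m_rev])
    insert = core[fwd_len : len(core) - rev_len]
    return ReadCategory.TWO_BARCODES_MATCHING_PRIMERS, individual, m_fwd, insert


def demultiplex_fastq(
    fastq_path,
    scheme: BarcodeScheme,
    primer_set: dict,
    out_dir=None,
    max_distance: int = 1,
):
    """Sort a FASTQ file (gzip-aware) into the five category FASTA files.

    Returns a DataFrame of per-category counts and, for matching reads, a
    long table of (individual, marker, insert) assignments.  When ``out_dir``
    is given, writes one FASTA per category named exactly after the category.
    """
    from Bio import SeqIO
    from pathlib import Path

    opener = gzip.open if str(fastq_path).endswith(".gz") else open
    buckets = {cat: [] for cat in ReadCategory}
    assignments = []
    with opener(fastq_path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            cat, indiv, marker, insert = categorize_read(
                str(rec.seq), scheme, primer_set, max_distance
            )
            buckets[cat].append(rec)
            if cat is ReadCategory.TWO_BARCODES_MATCHING_PRIMERS:
                assignments.append(
                    {"read": rec.id, "individual": indiv, "marker": marker, "insert": insert}
                )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for cat, recs in buckets.items():
            SeqIO.write(recs, out_dir / f"{cat.value}.fasta", "fasta")
    counts = pd.DataFrame(
        {"category": [c.value for c in ReadCategory], "n_reads": [len(buckets[c]) for c in ReadCategory]}
    )
    return counts, pd.DataFrame(assignments)


def call_genotype(count1: int, count2: int, thresholds: CallerThresholds = None) -> str:
    """Allele-ratio genotype call for one cell.

    r = count1/count2 with r = +inf when count2 == 0.  Returns one of
    "hom1", "het", "hom2", "missing".
    """
    if thresholds is None:
        thresholds = CallerThresholds()
    if count1 < 0 or count2 < 0:
        raise ValueError("read counts must be non-negative")
    if count1 + count2 < thresholds.min_depth:
        return "missing"
    r = math.inf if count2 == 0 else count1 / count2
    if r >= thresholds.hom1_min_ratio:
        return "hom1"
    if r <= thresholds.hom2_max_ratio:
        return "hom2"
    if thresholds.het_lo <= r <= thresholds.het_hi:
        return "het"
    return "missing"


def call_matrix(counts: AlleleCountTable, panel: MarkerPanel) -> GenotypeMatrix:
    """Apply the ratio caller cell-wise, honouring per-marker threshold overrides."""
    unknown = set(counts.markers) - set(panel.markers)
    if unknown:
        raise ValueError(f"count table has markers absent from panel: {sorted(unknown)}")
    c1 = counts.count1.to_numpy(dtype=float)
    c2 = counts.count2.to_numpy(dtype=float)
    out = np.full(c1.shape, np.nan)
    default = CallerThresholds()
    for j, marker in enumerate(counts.markers):
        th = panel.thresholds.get(marker, default)
        col1, col2 = c1[:, j], c2[:, j]
        depth = col1 + col2
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(col2 == 0, np.inf, col1 / np.where(col2 == 0, 1, col2))
        called = depth >= th.min_depth
        out[called & (r >= th.hom1_min_ratio), j] = 2.0
        out[called & (r <= th.hom2_max_ratio), j] = 0.0
        out[called & (r >= th.het_lo) & (r <= th.het_hi), j] = 1.0
    return GenotypeMatrix(
        pd.DataFrame(out, index=counts.count1.index, columns=counts.count1.columns)
    )


def filter_individuals(matrix: GenotypeMatrix, min_calls: int = 40):
    """Keep individuals with at least ``min_calls`` non-missing genotypes.

    Returns ``(retained GenotypeMatrix, list of dropped individual ids)``.
    """
    if min_calls > matrix.n_markers:
        raise ValueError("min_calls exceeds panel size")
    n_called = matrix.n_called()
    keep = n_called >= min_calls
    dropped = list(n_called.index[~keep])
    return matrix.subset(individuals=n_called.index[keep]), dropped


def select_baseline(
    matrix: GenotypeMatrix, metadata: pd.DataFrame, stage: int = 3
) -> BaselineDataset:
    """Baseline selection: spawning-ground collections at the given maturity stage.

    Individuals without a maturity value are excluded with a logged warning;
    individuals from samples not flagged as spawning collections are excluded
    even at the right stage.
    """
    meta = metadata.set_index("individual", drop=False)
    meta = meta.loc[[i for i in matrix.individuals if i in meta.index]]
    no_stage = meta["stage"].isna()
    if no_stage.any():
        logger.warning(
            "excluding %d individuals with missing maturity stage", int(no_stage.sum())
        )
    keep = (~no_stage) & (meta["stage"] == stage) & meta["spawning"].astype(bool)
    kept_ids = list(meta.index[keep])
    return BaselineDataset(
        matrix.subset(individuals=kept_ids), meta.loc[kept_ids].reset_index(drop=True)
    )


def propose_ratio_zones(count1, count2, min_depth: int = 10):
    """Diagnostic: propose per-marker ratio zone boundaries from observed counts.

    Fits the histogram of log-ratios with a three-component view (hom2, het,
    hom1 modes) and proposes boundaries at the midpoints between component
    means on the log scale.  Purely advisory: defaults are never silently
    overridden.
    """
    c1 = np.asarray(count1, dtype=float)
    c2 = np.asarray(count2, dtype=float)
    depth = c1 + c2
    ok = depth >= min_depth
    logr = np.log((c1[ok] + 0.5) / (c2[ok] + 0.5))
    # crude mode assignment: negative, near-zero, positive log-ratio clusters
    groups = np.digitize(logr, [-1.0, 1.0])
    means = [logr[groups == g].mean() if (groups == g).any() else np.nan for g in range(3)]
    lo = np.exp(np.nanmean([means[0], means[1]])) if not np.isnan(means[0]) else None
    hi = np.exp(np.nanmean([means[1], means[2]])) if not np.isnan(means[2]) else None
    return {"hom2_het_boundary": lo, "het_hom1_boundary": hi, "component_log_means": means}
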