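"""Synthetic population-structured SNP data with known truth.

Generates baselines for K populations whose allele frequencies differ in a
block-structured way (markers within a locus block shift together, emulating
physical linkage), draws Hardy-Weinberg genotypes within populations, emulates
amplicon read counts with negative-binomial depth and per-read error, and
builds mixed samples with known origin proportions.

Seeding: every operation takes an integer seed; internally a
(seed, stream-offset) pair feeds ``numpy.random.default_rng`` so the
operations can be re-run independently and are bit-reproducible.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import AlleleCountTable, BaselineDataset, GenotypeMatrix
from .panel import MarkerPanel

# fixed per-operation stream offsets (see module docstring)
_STREAM_FREQS = 11
_STREAM_GENO = 23
_STREAM_READS = 37
_STREAM_MIX = 53


def _rng(seed: int, offset: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), offset]))


@dataclass
class PopulationSpec:
    """One population: a name, a size, and per-marker allele-1 frequencies."""

    name: str
    n_individuals: int
    allele_freqs: pd.Series  # index = marker ids, values in [0, 1]

    def __post_init__(self) -> None:
        freqs = np.asarray(self.allele_freqs, dtype=float)
        if np.any((freqs < 0) | (freqs > 1)) or np.any(np.isnan(freqs)):
            raise ValueError("allele frequencies must lie in [0, 1]")
        if self.n_individuals < 0:
            raise ValueError("n_individuals must be >= 0")


@dataclass
class MixtureSpec:
    """A mixed sample: origin proportions (summing to 1) and a size."""

    proportions: dict  # population name -> fraction
    n_individuals: int

    def __post_init__(self) -> None:
        fracs = np.asarray(list(self.proportions.values()), dtype=float)
        if np.any(fracs < 0):
            raise ValueError("mixture proportions must be >= 0")
        if abs(fracs.sum() - 1.0) > 1e-9:
            raise ValueError(f"mixture proportions sum to {fracs.sum()}, not 1")
        if self.n_individuals <= 0:
            raise ValueError("n_individuals must be positive")


@dataclass
class ReadSimParams:
    """Amplicon read-depth model.

    mean_depth: expected reads per individual x marker cell.
    dispersion: negative-binomial shape (smaller = more over-dispersed);
        the default 2.0 emulates typical amplicon over-dispersion.
    error_rate: per-read probability of reporting the wrong allele.
    missing_rate: fraction of cells forced to zero coverage (dropout).
    """

    mean_depth: float = 100.0
    dispersion: float = 2.0
    error_rate: float = 0.005
    missing_rate: float = 0.02

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")
        if not (0 <= self.error_rate < 0.5):
            raise ValueError("error_rate must be in [0, 0.5)")
        if not (0 <= self.missing_rate <= 1):
            raise ValueError("missing_rate must be in [0, 1]")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")


def simulate_allele_frequencies(
    n_pops: int,
    panel: MarkerPanel,
    differentiation,
    seed: int,
    base_freq=None,
    pop_names=None,
    n_individuals: int = 100,
) -> list[PopulationSpec]:
    """Population allele frequencies with block-structured differentiation.

    ``differentiation`` is either a scalar delta applied to every locus block
    or a mapping ``block id -> delta``; delta is the total allele-frequency
    spread across the populations at that block.  All markers in a block
    receive the same per-population shift (one latent draw per population and
    block), so linked markers move together, reproducing block-level LD.

    Population ``p`` (0-based) sits at position ``p/(n_pops-1)`` along the
    delta spread, so two populations with delta 1 and base frequency 0 end up
    fixed for opposite alleles.

    ``base_freq`` is the allele-1 frequency before shifting: a scalar, a
    per-marker array, or None to draw Uniform(0.2, 0.5) per block (seeded).
    """
    if n_pops < 1:
        raise ValueError("n_pops must be >= 1")
    blocks = panel.blocks
    if np.isscalar(differentiation):
        deltas = {b: float(differentiation) for b in blocks}
    else:
        deltas = {b: float(d) for b, d in dict(differentiation).items()}
        unknown = set(deltas) - set(blocks)
        if unknown:
            raise ValueError(f"differentiation references unknown blocks: {sorted(unknown)}")
        for b in blocks:
            deltas.setdefault(b, 0.0)
    if any(not (0 <= d <= 1) for d in deltas.values()):
        raise ValueError("deltas must lie in [0, 1]")

    rng = _rng(seed, _STREAM_FREQS)
    markers = panel.markers
    if base_freq is None:
        per_block_base = {b: rng.uniform(0.2, 0.5) for b in blocks}
        base = np.array([per_block_base[panel.block_of(m)] for m in markers])
    else:
        base = np.broadcast_to(np.asarray(base_freq, dtype=float), (len(markers),)).copy()

    if pop_names is None:
        pop_names = [f"pop{i + 1}" for i in range(n_pops)]
    positions = np.linspace(0.0, 1.0, n_pops) if n_pops > 1 else np.array([0.0])

    block_col = np.array([panel.block_of(m) for m in markers], dtype=object)
    specs = []
    for p, name in enumerate(pop_names):
        freqs = base.copy()
        for b in blocks:
            shift = deltas[b] * positions[p]
            freqs[block_col == b] += shift
        freqs = np.clip(freqs, 0.0, 1.0)
        specs.append(
            PopulationSpec(
                name=name,
                n_individuals=n_individuals,
                allele_freqs=pd.Series(freqs, index=markers),
            )
        )
    return specs


def expected_wc_fst(specs: list[PopulationSpec]) -> pd.Series:
    """Closed-form large-sample limit of the Weir-Cockerham estimator.

    For known per-population frequencies p_i (HWE within populations, equal
    large sample sizes), theta converges per locus to

        s^2 / ( p_bar (1 - p_bar) + s^2 / r )

    with s^2 the (r-1)-denominator variance of p_i across the r populations.
    Monomorphic loci (all frequencies equal at 0 or 1) return NaN.
    """
    freqs = np.vstack([np.asarray(s.allele_freqs, dtype=float) for s in specs])
    r = freqs.shape[0]
    p_bar = freqs.mean(axis=0)
    s2 = freqs.var(axis=0, ddof=1)
    denom = p_bar * (1 - p_bar) + s2 / r
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(denom > 0, s2 / denom, np.nan)
    return pd.Series(theta, index=specs[0].allele_freqs.index)


def expected_multilocus_fst(specs: list[PopulationSpec]) -> float:
    """Ratio-of-sums combination of the per-locus closed form.

    Combines numerator s^2 and denominator p_bar(1-p_bar)+s^2/r across loci,
    matching the multi-locus a/(a+b+c) convention of the estimator.
    """
    freqs = np.vstack([np.asarray(s.allele_freqs, dtype=float) for s in specs])
    r = freqs.shape[0]
    p_bar = freqs.mean(axis=0)
    s2 = freqs.var(axis=0, ddof=1)
    denom = p_bar * (1 - p_bar) + s2 / r
    keep = denom > 0
    return float(s2[keep].sum() / denom[keep].sum())


def simulate_baseline_genotypes(
    specs: list[PopulationSpec],
    missing_rate: float = 0.0,
    seed: int = 0,
    stage: int = 3,
    quarter: int = 4,
    spawning: bool = True,
) -> BaselineDataset:
    """HWE genotype draws within each population.

    Dosages are Binomial(2, freq) per individual x marker; a Bernoulli
    missing mask at ``missing_rate`` knocks out cells.  Metadata rows default
    to spawning-ground, maturity-stage-3 collections (baseline-eligible).
    """
    if not specs:
        raise ValueError("empty population spec list")
    if not (0 <= missing_rate < 1):
        raise ValueError("missing_rate must be in [0, 1)")
    rng = _rng(seed, _STREAM_GENO)
    markers = list(specs[0].allele_freqs.index)
    rows, ids, meta = [], [], []
    for spec in specs:
        freqs = np.asarray(spec.allele_freqs, dtype=float)
        dos = rng.binomial(2, freqs, size=(spec.n_individuals, len(markers))).astype(float)
        if missing_rate > 0:
            mask = rng.random(dos.shape) < missing_rate
            dos[mask] = np.nan
        rows.append(dos)
        for i in range(spec.n_individuals):
            ident = f"{spec.name}_{i + 1:04d}"
            ids.append(ident)
            meta.append(
                {
                    "individual": ident,
                    "population": spec.name,
                    "stage": stage,
                    "quarter": quarter,
                    "spawning": spawning,
                }
            )
    dosage = pd.DataFrame(np.vstack(rows), index=ids, columns=markers)
    return BaselineDataset(GenotypeMatrix(dosage), pd.DataFrame(meta))


def simulate_read_counts(
    genotypes: GenotypeMatrix, params: ReadSimParams, seed: int
) -> AlleleCountTable:
    """Allele-specific read counts for each genotype cell.

    Depth per cell is negative binomial (mean ``mean_depth``, shape
    ``dispersion``); given the true genotype, allele-1 reads are
    Binomial(depth, q) with q = 1-e (hom1), e (hom2) or 0.5 (het, symmetric
    error cancels).  Cells hit by ``missing_rate`` (and cells missing in the
    input) get zero coverage.
    """
    rng = _rng(seed, _STREAM_READS)
    dos = genotypes.dosage.to_numpy(dtype=float)
    n, m = dos.shape
    shape = params.dispersion
    p_nb = shape / (shape + params.mean_depth)
    depth = rng.negative_binomial(shape, p_nb, size=(n, m))
    dropout = rng.random((n, m)) < params.missing_rate
    depth[dropout | np.isnan(dos)] = 0

    q = np.full((n, m), 0.5)
    q[dos == 2.0] = 1.0 - params.error_rate
    q[dos == 0.0] = params.error_rate
    c1 = rng.binomial(depth, q)
    c2 = depth - c1
    idx, cols = genotypes.dosage.index, genotypes.dosage.columns
    return AlleleCountTable(
        pd.DataFrame(c1, index=idx, columns=cols),
        pd.DataFrame(c2, index=idx, columns=cols),
    )


def simulate_mixed_sample(
    specs: list[PopulationSpec],
    mix: MixtureSpec,
    seed: int,
    missing_rate: float = 0.0,
    prefix: str = "mix",
):
    """A mixed sample with known origins.

    Each individual's origin is drawn from ``mix.proportions``; genotypes are
    HWE draws from the origin's frequencies.  Returns ``(GenotypeMatrix,
    truth)`` where ``truth`` is a Series of origin labels indexed by
    individual id.
    """
    by_name = {s.name: s for s in specs}
    unknown = set(mix.proportions) - set(by_name)
    if unknown:
        raise ValueError(f"mixture references unknown populations: {sorted(unknown)}")
    rng = _rng(seed, _STREAM_MIX)
    names = list(mix.proportions)
    probs = np.asarray([mix.proportions[k] for k in names], dtype=float)
    origins = rng.choice(len(names), size=mix.n_individuals, p=probs)
    markers = list(specs[0].allele_freqs.index)
    freq_matrix = np.vstack([np.asarray(by_name[k].allele_freqs, dtype=float) for k in names])
    dos = rng.binomial(2, freq_matrix[origins, :]).astype(float)
    if missing_rate > 0:
        dos[rng.random(dos.shape) < missing_rate] = np.nan
    ids = [f"{prefix}_{i + 1:04d}" for i in range(mix.n_individuals)]
    truth = pd.Series([names[o] for o in origins], index=ids, name="origin")
    return GenotypeMatrix(pd.DataFrame(dos, index=ids, columns=markers)), truth


def write_baseline_csv(baseline: BaselineDataset, path) -> None:
    """One row per individual: id, population, stage, quarter, then markers 0/1/2/NA."""
    meta = baseline.metadata[["individual", "population", "stage", "quarter"]].reset_index(
        drop=True
    )
    dos = baseline.genotypes.dosage.reset_index(drop=True)
    out = pd.concat([meta, dos], axis=1)
    out.to_csv(path, index=False, na_rep="NA")


def read_baseline_csv(path) -> BaselineDataset:
    df = pd.read_csv(path, comment="#", na_values=["NA"])
    meta_cols = [c for c in ("individual", "population", "stage", "quarter") if c in df.columns]
    marker_cols = [c for c in df.columns if c not in meta_cols]
    meta = df[meta_cols].copy()
    if "spawning" not in meta.columns:
        meta["spawning"] = True
    dosage = df[marker_cols].astype(float)
    dosage.index = df["individual"]
    return BaselineDataset(GenotypeMatrix(dosage), meta)
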