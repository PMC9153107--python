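"""Synthetic two-condition transcriptome cohorts with known hypoxia genes.

The generator emulates a corpus of bulk RNA-seq samples split between a
normoxic and a hypoxic condition, in which a configurable subset of
"responsive" genes rises in the within-sample expression ranking under
hypoxia.  Every downstream stage (feature selection, tree induction,
ensemble evaluation, spatial classification) is tested against the known
truth genes and labels.

Effect sizes are parameterized directly in **percentile points** — the unit
every classifier consumes — rather than fold change: a calibration against
the baseline abundance distribution converts the requested rank shift into a
log-abundance offset per gene.  Responsive genes are drawn from the
mid-expressed band of the transcriptome, mirroring the fact that usable
signature genes must be widely expressed; per-gene effects are jittered so
no single gene is always the best marker.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from hyporank.ranks import ExpressionMatrix, RankPercentileMatrix, rank_percentile

__all__ = ["SyntheticConfig", "LabeledDataset", "generate_cohort", "generate_spatial"]

NORMOXIC = "normoxic"
HYPOXIC = "hypoxic"

# Responsive genes are sampled from this baseline-percentile band: hypoxia
# signature genes must be detectably expressed, and a gene already at the
# very top of the ranking has no headroom to shift into.
_RESPONSIVE_BAND = (30.0, 70.0)
_EFFECT_JITTER = 0.25  # per-gene effect multiplier drawn from 1 +/- this


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of a simulated normoxia/hypoxia cohort.

    Attributes
    ----------
    n_genes:
        Transcriptome size (>= 50).
    n_samples_per_class:
        Samples per condition; the default gives a cohort of roughly the
        size of the 425-sample training corpus the method was built for.
    de_genes:
        Number of hypoxia-responsive genes.
    effect:
        Mean within-sample rank-percentile shift (points, 0-100] of
        responsive genes under hypoxia.
    noise_sd:
        SD of per-gene, per-sample Gaussian jitter on log2 abundance.
    dropout_p:
        Probability that a gene's count is zeroed in a sample; applied
        before ranking so the tie-at-zero regime of real RNA-seq is
        exercised.
    libsize_range:
        Interval of the multiplicative sequencing-depth factor drawn per
        sample.
    seed:
        Integer seed; the same seed reproduces the dataset bitwise.
    structure_seed:
        Seed for the gene universe (baseline abundances, responsive-gene
        identities, per-gene effects).  Defaults to ``seed``; fix it while
        varying ``seed`` to draw independent cohorts from the *same*
        underlying transcriptome, e.g. matched train/validation/test
        cohorts or a spatial section sharing its training cohort's truth.
    """

    n_genes: int = 1000
    n_samples_per_class: int = 212
    de_genes: int = 25
    effect: float = 20.0
    noise_sd: float = 0.5
    dropout_p: float = 0.05
    libsize_range: tuple[float, float] = (0.5, 2.0)
    seed: int = 0
    structure_seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_genes < 50:
            raise ValueError("n_genes must be >= 50")
        if self.n_samples_per_class < 5:
            raise ValueError("n_samples_per_class must be >= 5")
        if not 1 <= self.de_genes < self.n_genes:
            raise ValueError("de_genes must satisfy 1 <= de_genes < n_genes")
        if not 0.0 < self.effect <= 100.0:
            raise ValueError("effect must lie in (0, 100]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0.0 <= self.dropout_p < 1.0:
            raise ValueError("dropout_p must lie in [0, 1)")
        lo, hi = self.libsize_range
        if not 0 < lo <= hi:
            raise ValueError("libsize_range must be 0 < low <= high")


@dataclass(frozen=True)
class LabeledDataset:
    """An expression (or percentile) matrix with per-sample class labels.

    ``truth`` lists the identifiers of the genes that genuinely respond to
    hypoxia (empty for real data).  ``coords`` carries per-spot x/y
    positions for spatial datasets, indexed by barcode.
    """

    matrix: ExpressionMatrix | RankPercentileMatrix
    labels: pd.Series
    truth: tuple[str, ...] = field(default_factory=tuple)
    coords: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        if list(self.labels.index) != self.matrix.sample_ids:
            raise ValueError("labels must cover every sample, in matrix order")
        bad = set(self.labels.unique()) - {NORMOXIC, HYPOXIC}
        if bad:
            raise ValueError(f"unknown labels {sorted(bad)}")
        missing_truth = set(self.truth) - set(self.matrix.gene_ids)
        if missing_truth:
            raise ValueError(f"truth genes absent from matrix: {sorted(missing_truth)[:5]}")

    @property
    def sample_ids(self) -> list[str]:
        return self.matrix.sample_ids

    def to_percentiles(self) -> "LabeledDataset":
        """Return the same dataset in rank-percentile space."""
        if isinstance(self.matrix, RankPercentileMatrix):
            return self
        return replace(self, matrix=rank_percentile(self.matrix))


def _baseline_log_abundance(rng: np.random.Generator, n_genes: int) -> np.ndarray:
    # log2 abundances; wide spread gives a well-resolved ranking with a
    # low-count tail that rounds into ties.
    return rng.normal(loc=5.0, scale=2.5, size=n_genes)


def _percentile_to_value(baseline: np.ndarray, pct: np.ndarray) -> np.ndarray:
    """Map target rank percentiles to log2 abundances by interpolation.

    Percentiles above 100 extrapolate beyond the most expressed baseline
    gene (one point = 1% of the baseline range), so a maximal effect pushes
    responsive genes strictly above the whole transcriptome.
    """
    order = np.sort(baseline)
    grid = 100.0 * np.arange(order.size) / (order.size - 1)
    values = np.interp(np.minimum(pct, 100.0), grid, order)
    span = order[-1] - order[0]
    over = pct > 100.0
    if np.any(over):
        values = values.copy()
        values[over] = order[-1] + (pct[over] - 100.0) * span / 100.0
    return values


def _simulate_counts(
    config: SyntheticConfig,
    hypoxic_mask: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw a counts matrix (genes x samples) and the responsive-gene index.

    Two decoupled random streams: the *structure* stream (baselines,
    responsive-gene choice, per-gene effects) derives from
    ``structure_seed`` and the *sampling* stream (noise, library size,
    dropout) from ``seed``, so cohorts can share a gene universe while
    being statistically independent.
    """
    n_genes = config.n_genes
    n_samples = hypoxic_mask.size
    structure_seed = config.seed if config.structure_seed is None else config.structure_seed
    rng_structure = np.random.default_rng(np.random.SeedSequence([structure_seed, 0]))
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    baseline = _baseline_log_abundance(rng_structure, n_genes)
    base_pct = 100.0 * (rankdata(baseline) - 1.0) / (n_genes - 1.0)

    lo, hi = _RESPONSIVE_BAND
    pool = np.flatnonzero((base_pct >= lo) & (base_pct <= hi))
    if pool.size < config.de_genes:
        raise ValueError(
            f"infeasible effect: only {pool.size} genes sit below the expression "
            f"ceiling with headroom for a {config.effect}-point shift, "
            f"need {config.de_genes}"
        )
    responsive = np.sort(rng_structure.choice(pool, size=config.de_genes, replace=False))
    if np.any(base_pct[responsive] >= 99.9):
        raise ValueError("infeasible effect: responsive gene already at ranking ceiling")

    gene_effect = config.effect * rng_structure.uniform(
        1.0 - _EFFECT_JITTER, 1.0 + _EFFECT_JITTER, size=config.de_genes
    )
    target_pct = base_pct[responsive] + gene_effect
    hypoxic_value = _percentile_to_value(baseline, target_pct)

    log_mean = np.tile(baseline[:, None], (1, n_samples))
    log_mean[responsive[:, None], np.flatnonzero(hypoxic_mask)[None, :]] = hypoxic_value[:, None]

    noise = rng.normal(0.0, config.noise_sd, size=(n_genes, n_samples)) if config.noise_sd else 0.0
    libsize = rng.uniform(*config.libsize_range, size=n_samples)
    counts = np.rint(libsize[None, :] * np.exp2(log_mean + noise))
    if config.dropout_p:
        counts[rng.random((n_genes, n_samples)) < config.dropout_p] = 0.0
    return counts, responsive


def _gene_ids(n_genes: int) -> list[str]:
    width = len(str(n_genes))
    return [f"g{i:0{width}d}" for i in range(1, n_genes + 1)]


def generate_cohort(config: SyntheticConfig) -> LabeledDataset:
    """Simulate a labeled two-condition cohort.

    Normoxic samples come first, then hypoxic; all randomness derives from
    ``config.seed``, so the same config is bitwise reproducible.
    """
    n = config.n_samples_per_class
    hypoxic_mask = np.repeat([False, True], n)
    counts, responsive = _simulate_counts(config, hypoxic_mask)

    genes = _gene_ids(config.n_genes)
    samples = [f"norm_{i + 1:03d}" for i in range(n)] + [f"hypo_{i + 1:03d}" for i in range(n)]
    labels = pd.Series(
        np.where(hypoxic_mask, HYPOXIC, NORMOXIC), index=samples, name="label"
    )
    matrix = ExpressionMatrix(pd.DataFrame(counts, index=genes, columns=samples))
    truth = tuple(genes[i] for i in responsive)
    return LabeledDataset(matrix=matrix, labels=labels, truth=truth)


def generate_spatial(
    config: SyntheticConfig,
    grid: tuple[int, int],
    center: tuple[float, float],
    radius: float,
) -> LabeledDataset:
    """Simulate a spatial grid with a hypoxic disc-shaped core.

    Spots lie on a ``rows x cols`` lattice; those within ``radius`` (in
    spot widths) of ``center`` (row, col) are hypoxic, the rest normoxic.
    Each spot is one sample drawn as in :func:`generate_cohort`; spot
    coordinates are attached as ``coords`` (x = column, y = row).
    """
    rows, cols = grid
    if rows < 1 or cols < 1:
        raise ValueError("grid must have positive dimensions")
    r0, c0 = center
    if not (r0 - radius >= -0.5 and r0 + radius <= rows - 0.5
            and c0 - radius >= -0.5 and c0 + radius <= cols - 0.5):
        raise ValueError("hypoxic core disc does not fit inside the grid")

    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    rr, cc = rr.ravel(), cc.ravel()
    hypoxic_mask = (rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2
    if not hypoxic_mask.any():
        raise ValueError("empty hypoxic core: no spot falls inside the disc")
    if hypoxic_mask.all():
        raise ValueError("empty exterior: every spot falls inside the disc")

    counts, responsive = _simulate_counts(config, hypoxic_mask)

    genes = _gene_ids(config.n_genes)
    barcodes = [f"spot_r{r}_c{c}" for r, c in zip(rr, cc)]
    labels = pd.Series(
        np.where(hypoxic_mask, HYPOXIC, NORMOXIC), index=barcodes, name="label"
    )
    coords = pd.DataFrame({"x": cc, "y": rr}, index=pd.Index(barcodes, name="barcode"))
    matrix = ExpressionMatrix(pd.DataFrame(counts, index=genes, columns=barcodes))
    truth = tuple(genes[i] for i in responsive)
    return LabeledDataset(matrix=matrix, labels=labels, truth=truth, coords=coords)
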