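"""Poisson molecule-sampling detection model and mutation-rate estimation.

A monoclonal population founded by a single cell undergoes ``G`` binary
divisions.  A heterozygous mutation arising in a daughter cell at division
generation ``n`` (n = 1 is the founder's first division) is carried by a
fraction ``2**-n`` of the final cells and therefore by a fraction
``2**-(n+1)`` of template molecules (one of two alleles).  When an amplicon
assay samples ``N`` template molecules per locus, the number of mutant
molecules drawn is Poisson with mean

    lambda_n = N / 2**(n+1)

and the mutation is detectable iff at least one mutant molecule is sampled,
with probability ``1 - exp(-lambda_n)``.  Summing that detection probability
over the division generations gives the *detection factor* F: the expected
number of detectable sub-clonal mutations per unit per-cell per-generation
mutation rate.  Dividing an observed sub-clonal mutation count by F (and by
the fraction of candidate sites actually assayed) yields the rate estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RateModel",
    "RateEstimate",
    "molecule_lambda",
    "detection_probability",
    "detection_factor",
    "estimate_rate",
    "per_nucleotide_rate",
    "divisions_from_cell_count",
    "subclone_division_rate",
    "DEFAULT_N_MOLECULES",
    "DEFAULT_GENERATIONS",
    "DEFAULT_DIPLOID_GENOME_SIZE",
]

#: template molecules per assay: 5 ng human genomic DNA ~ 750 diploid
#: genomes ~ 1,500 allele copies per locus
DEFAULT_N_MOLECULES = 1500

#: binary divisions of the default expansion (1.35e7 cells from one founder)
DEFAULT_GENERATIONS = 24

#: diploid human genome size used for per-nucleotide conversion
DEFAULT_DIPLOID_GENOME_SIZE = 6.6e9


def molecule_lambda(n_molecules: float, generation: int) -> float:
    """Mean number of mutant template molecules for a mutation of generation n.

    ``lambda_n = n_molecules / 2**(n+1)``.  Generation 0 denotes a clonal
    (founder) mutation, present on half of all molecules.
    """
    if n_molecules <= 0:
        raise ValueError(f"n_molecules must be positive, got {n_molecules}")
    if generation < 0:
        raise ValueError(f"generation must be >= 0, got {generation}")
    lam = n_molecules / 2.0 ** (generation + 1)
    if not math.isfinite(lam):
        raise ValueError("lambda is non-finite")
    return lam


def detection_probability(lam: float) -> float:
    """P(X > 0) for X ~ Poisson(lam): probability of sampling >= 1 mutant molecule."""
    if lam < 0:
        raise ValueError(f"lambda must be >= 0, got {lam}")
    return -math.expm1(-lam)


def detection_factor(
    n_molecules: float = DEFAULT_N_MOLECULES,
    generations: int = DEFAULT_GENERATIONS,
    include_clonal: bool = False,
) -> float:
    """Expected detectable sub-clonal mutations per unit mutation rate.

    Sums ``1 - exp(-lambda_n)`` over division generations ``n = 1..G``.
    With ``include_clonal=True`` the ``n = 0`` clonal term (detection
    probability ~1) is added; clonal mutations are normally counted
    separately as the population-wide shared set, so the default excludes it.
    """
    if generations < 1:
        raise ValueError(f"generations must be >= 1, got {generations}")
    start = 0 if include_clonal else 1
    return sum(
        detection_probability(molecule_lambda(n_molecules, n))
        for n in range(start, generations + 1)
    )


@dataclass(frozen=True)
class RateModel:
    """Molecule-sampling detection model for one amplicon assay design."""

    n_molecules: float = DEFAULT_N_MOLECULES
    generations: int = DEFAULT_GENERATIONS

    def __post_init__(self) -> None:
        if self.n_molecules <= 0:
            raise ValueError("n_molecules must be positive")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")

    def lambda_n(self, generation: int) -> float:
        return molecule_lambda(self.n_molecules, generation)

    @property
    def lambdas(self) -> np.ndarray:
        """lambda_n for n = 0..G (index = generation)."""
        return np.array(
            [self.lambda_n(n) for n in range(self.generations + 1)]
        )

    @property
    def detection_probabilities(self) -> np.ndarray:
        """P(X > 0) per generation n = 0..G."""
        return -np.expm1(-self.lambdas)

    def detection_factor(self, include_clonal: bool = False) -> float:
        return detection_factor(
            self.n_molecules, self.generations, include_clonal=include_clonal
        )


@dataclass(frozen=True)
class RateEstimate:
    """Per-line and summary mutation-rate estimates.

    ``mean`` is in SNVs per cell per generation; ``sd`` is the sample
    (n-1) standard deviation across lines, or None for a single line.
    """

    per_line: tuple[float, ...]
    mean: float
    sd: float | None
    factor: float
    assay_fractions: tuple[float, ...] = field(default=())

    def per_nucleotide(
        self, genome_size: float = DEFAULT_DIPLOID_GENOME_SIZE
    ) -> float:
        return per_nucleotide_rate(self.mean, genome_size)


def estimate_rate(
    detected_counts,
    assay_fractions,
    factor: float,
) -> RateEstimate:
    """Convert per-line detected sub-clonal counts into per-generation rates.

    Each line's rate is ``count / (assay_fraction * factor)``: the detected
    count scaled up for the fraction of candidate sites assayed and divided
    by the detection factor.  The summary is the mean and sample SD across
    lines.

    Parameters
    ----------
    detected_counts
        Sub-clonal mutations detected per line (non-negative).
    assay_fractions
        Fraction of candidate sites assayed per line, in (0, 1].
    factor
        Detection factor F (> 0), e.g. from :func:`detection_factor`.
    """
    counts = np.asarray(detected_counts, dtype=float)
    fractions = np.asarray(assay_fractions, dtype=float)
    if counts.shape != fractions.shape or counts.ndim != 1 or counts.size == 0:
        raise ValueError("counts and fractions must be equal-length 1-D, non-empty")
    if np.any(counts < 0):
        raise ValueError("detected counts must be >= 0")
    if np.any(fractions <= 0) or np.any(fractions > 1):
        raise ValueError("assay fractions must be in (0, 1]")
    if factor <= 0:
        raise ValueError("detection factor must be > 0")
    rates = counts / (fractions * factor)
    sd = float(np.std(rates, ddof=1)) if rates.size > 1 else None
    return RateEstimate(
        per_line=tuple(float(r) for r in rates),
        mean=float(np.mean(rates)),
        sd=sd,
        factor=float(factor),
        assay_fractions=tuple(float(f) for f in fractions),
    )


def per_nucleotide_rate(
    rate_per_cell: float, genome_size: float = DEFAULT_DIPLOID_GENOME_SIZE
) -> float:
    """Per-nucleotide per-generation rate: rate_per_cell / genome_size."""
    if genome_size <= 0:
        raise ValueError("genome_size must be > 0")
    if rate_per_cell < 0:
        raise ValueError("rate must be >= 0")
    return rate_per_cell / genome_size


def divisions_from_cell_count(final_cells: float) -> int:
    """Number of binary divisions implied by a final cell count: round(log2)."""
    if final_cells < 1:
        raise ValueError(f"final_cells must be >= 1, got {final_cells}")
    return round(math.log2(final_cells))


def subclone_division_rate(snv_count, divisions: int = 60):
    """SNVs per cell per division for serially expanded subclones.

    ``snv_count`` may be a scalar or a sequence of replicate subclone counts;
    replicates are summarised as (mean, sample SD).
    """
    if divisions <= 0:
        raise ValueError(f"divisions must be > 0, got {divisions}")
    counts = np.atleast_1d(np.asarray(snv_count, dtype=float))
    if np.any(counts < 0):
        raise ValueError("SNV counts must be >= 0")
    rates = counts / divisions
    if np.isscalar(snv_count) or counts.size == 1:
        return float(rates[0])
    return float(np.mean(rates)), float(np.std(rates, ddof=1))
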