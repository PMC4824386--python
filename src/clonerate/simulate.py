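"""Synthetic clonal expansions, amplicon read counts, read pairs and catalogs.

The generator mirrors the statistical structure the downstream analysis
assumes: a single founder cell expands by strictly binary division, every
daughter acquires Poisson(mu) new heterozygous mutations at birth, and a
mutation born at division generation ``n`` is therefore carried by
``2**-n`` of the final cells and ``2**-(n+1)`` of template molecules.  Deep
amplicon sequencing is modelled as Poisson sampling of mutant template
molecules followed by binomial read sampling with uniform per-base
substitution error.  No cell death or selection is simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .rate_model import molecule_lambda

__all__ = [
    "DivisionTree",
    "TruthVariant",
    "SimulatedReadPair",
    "EXACT_GENERATION_CAP",
    "simulate_expansion",
    "simulate_expansion_counts",
    "simulate_amplicon",
    "simulate_lineage_mutations",
    "simulate_read_pairs",
    "simulate_catalog",
    "truth_table",
]

#: exact cell-by-cell simulation is limited to trees of <= 2**17 - 1 nodes;
#: larger expansions use the per-generation count approximation
EXACT_GENERATION_CAP = 16


class GenerationCapError(ValueError):
    """Raised when an exact tree simulation would exceed the node cap."""


@dataclass(frozen=True)
class TruthVariant:
    """Ground truth for one simulated heterozygous mutation.

    ``origin_generation`` 0 means clonal (present in the founder); a
    mutation of generation n >= 1 arose in one daughter at the n-th
    division.  ``molecule_fraction`` is half the cell fraction because the
    mutation sits on one of two alleles.
    """

    mutation_id: int
    origin_generation: int

    @property
    def cell_fraction(self) -> float:
        return 2.0 ** -self.origin_generation

    @property
    def molecule_fraction(self) -> float:
        return 2.0 ** -(self.origin_generation + 1)

    def expected_molecules(self, n_molecules: float) -> float:
        """lambda_n: mean mutant template molecules in an assay of N molecules."""
        return molecule_lambda(n_molecules, self.origin_generation)


@dataclass
class DivisionTree:
    """A simulated binary cell genealogy with per-branch mutation lists.

    Nodes are tuples of 0/1 child choices from the root ``()``; a node of
    length d is a cell alive after d divisions.  ``branch_mutations[node]``
    lists mutations acquired by that cell at birth.
    """

    generations: int
    founder_mutations: int
    branch_mutations: dict[tuple[int, ...], list[int]]
    mutation_origin: dict[int, int]

    @property
    def cell_count(self) -> int:
        return 2 ** self.generations

    @property
    def n_mutations(self) -> int:
        return len(self.mutation_origin)

    def leaves(self) -> list[tuple[int, ...]]:
        import itertools

        return [tuple(bits) for bits in itertools.product((0, 1), repeat=self.generations)]

    def leaf_mutations(self, leaf: tuple[int, ...]) -> set[int]:
        """All mutations carried by one leaf cell: founder set + ancestral branches."""
        if len(leaf) != self.generations:
            raise ValueError("leaf must have one bit per generation")
        carried = set(range(self.founder_mutations))
        for d in range(1, self.generations + 1):
            carried.update(self.branch_mutations.get(leaf[:d], ()))
        return carried

    def carrier_leaves(self, mutation_id: int) -> list[tuple[int, ...]]:
        """Leaves descending from the branch on which the mutation arose."""
        origin = self.mutation_origin[mutation_id]
        if origin == 0:
            return self.leaves()
        node = next(
            n for n, muts in self.branch_mutations.items() if mutation_id in muts
        )
        import itertools

        tail = self.generations - len(node)
        return [node + tuple(bits) for bits in itertools.product((0, 1), repeat=tail)]

    def truth_variants(self) -> list[TruthVariant]:
        return [
            TruthVariant(mutation_id=m, origin_generation=n)
            for m, n in sorted(self.mutation_origin.items())
        ]


def simulate_expansion(
    mu: float,
    generations: int,
    founder_mutations: int = 0,
    seed: int | np.random.Generator = 0,
) -> DivisionTree:
    """Simulate a binary clonal expansion cell by cell.

    Each of the ``2**n`` daughters born at division n draws Poisson(mu) new
    mutations.  Exact simulation is capped at ``EXACT_GENERATION_CAP``
    generations; beyond that use :func:`simulate_expansion_counts`, which is
    equivalent in distribution for site-level analyses.
    """
    if mu < 0:
        raise ValueError(f"mu must be >= 0, got {mu}")
    if generations < 0:
        raise ValueError(f"generations must be >= 0, got {generations}")
    if founder_mutations < 0:
        raise ValueError("founder_mutations must be >= 0")
    if generations > EXACT_GENERATION_CAP:
        raise GenerationCapError(
            f"exact simulation capped at {EXACT_GENERATION_CAP} generations "
            f"(requested {generations}); use simulate_expansion_counts for the "
            "per-generation Poisson-count approximation"
        )
    rng = np.random.default_rng(seed)
    branch_mutations: dict[tuple[int, ...], list[int]] = {}
    mutation_origin: dict[int, int] = {m: 0 for m in range(founder_mutations)}
    next_id = founder_mutations
    nodes: list[tuple[int, ...]] = [()]
    for n in range(1, generations + 1):
        children = [parent + (bit,) for parent in nodes for bit in (0, 1)]
        counts = rng.poisson(mu, size=len(children))
        for child, k in zip(children, counts):
            muts = list(range(next_id, next_id + int(k)))
            next_id += int(k)
            branch_mutations[child] = muts
            for m in muts:
                mutation_origin[m] = n
        nodes = children
    return DivisionTree(
        generations=generations,
        founder_mutations=founder_mutations,
        branch_mutations=branch_mutations,
        mutation_origin=mutation_origin,
    )


def simulate_expansion_counts(
    mu: float,
    generations: int,
    founder_mutations: int = 0,
    seed: int | np.random.Generator = 0,
) -> list[TruthVariant]:
    """Per-generation count approximation of :func:`simulate_expansion`.

    Draws the total number of new mutations of generation n as
    Poisson(mu * 2**n) — the superposition of the 2**n independent daughter
    draws — and assigns molecule fractions analytically.  Suitable for
    large expansions where cells need not be materialised.
    """
    if mu < 0 or generations < 0 or founder_mutations < 0:
        raise ValueError("mu, generations and founder_mutations must be >= 0")
    rng = np.random.default_rng(seed)
    variants = [
        TruthVariant(mutation_id=m, origin_generation=0)
        for m in range(founder_mutations)
    ]
    next_id = founder_mutations
    for n in range(1, generations + 1):
        k = int(rng.poisson(mu * 2.0 ** n))
        variants.extend(
            TruthVariant(mutation_id=next_id + j, origin_generation=n)
            for j in range(k)
        )
        next_id += k
    return variants


def simulate_lineage_mutations(
    mu: float, generations: int, seed: int | np.random.Generator = 0
) -> list[TruthVariant]:
    """Mutations accumulated along a single sampled cell lineage.

    A single descendant cell (e.g. the founder of a derived clone line)
    carries Poisson(mu) mutations from each of the ``generations`` divisions
    on its ancestry; the mutation of generation n still has population
    molecule fraction ``2**-(n+1)``.
    """
    if mu < 0 or generations < 0:
        raise ValueError("mu and generations must be >= 0")
    rng = np.random.default_rng(seed)
    variants: list[TruthVariant] = []
    next_id = 0
    for n in range(1, generations + 1):
        for _ in range(int(rng.poisson(mu))):
            variants.append(TruthVariant(mutation_id=next_id, origin_generation=n))
            next_id += 1
    return variants


def simulate_amplicon(
    truth: TruthVariant | None,
    n_molecules: int,
    depth: int,
    error_rate: float,
    seed: int | np.random.Generator = 0,
    alt_error_fraction: float = 1.0 / 3.0,
) -> tuple[int, int]:
    """Simulate deep amplicon sequencing of one site: (ref_reads, alt_reads).

    The number of mutant template molecules k is Poisson(lambda_n) (capped
    at n_molecules); reads sample templates binomially at fraction
    k / n_molecules.  Per-base errors flip a read to a uniform wrong base,
    so a fraction ``alt_error_fraction`` of errored reference reads are
    counted as the specific alternate base.  ``truth=None`` simulates a
    truly absent variant (lambda = 0).
    """
    if n_molecules <= 0:
        raise ValueError("n_molecules must be > 0")
    if depth < 0:
        raise ValueError("depth must be >= 0")
    if not 0 <= error_rate < 1:
        raise ValueError("error_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    if truth is None:
        k = 0
    else:
        lam = truth.expected_molecules(n_molecules)
        k = min(int(rng.poisson(lam)), n_molecules)
    alt_frac = k / n_molecules
    true_alt = rng.binomial(depth, alt_frac) if depth else 0
    true_ref = depth - true_alt
    # errors: ref reads -> alt with rate e/3; alt reads leave alt with rate e
    ref_to_alt = rng.binomial(true_ref, error_rate * alt_error_fraction)
    ref_to_other = rng.binomial(true_ref - ref_to_alt,
                                error_rate * (1 - alt_error_fraction)
                                / (1 - error_rate * alt_error_fraction)
                                if error_rate else 0.0)
    alt_lost = rng.binomial(true_alt, error_rate)
    alt_to_ref = rng.binomial(alt_lost, alt_error_fraction) if alt_lost else 0
    alt_reads = true_alt - alt_lost + ref_to_alt
    ref_reads = true_ref - ref_to_alt - ref_to_other + alt_to_ref
    return int(ref_reads), int(alt_reads)


_BASES = np.frombuffer(b"ACGT", dtype="S1")
_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}


@dataclass
class SimulatedReadPair:
    """One overlapping read pair with per-base Phred qualities.

    ``offset1``/``offset2`` are 0-based start positions of each read on the
    truth template; the overlap is their intersection.
    """

    read1: str
    read2: str
    qual1: np.ndarray
    qual2: np.ndarray
    offset1: int
    offset2: int
    truth: str
    pair_id: int = 0

    def __post_init__(self) -> None:
        if len(self.read1) != len(self.qual1) or len(self.read2) != len(self.qual2):
            raise ValueError("read and quality lengths differ")
        if np.any(self.qual1 < 2) or np.any(self.qual1 > 41) or \
           np.any(self.qual2 < 2) or np.any(self.qual2 > 41):
            raise ValueError("qualities must lie in [2, 41]")

    @property
    def overlap_interval(self) -> tuple[int, int]:
        """Template coordinates [start, end) covered by both reads."""
        start = max(self.offset1, self.offset2)
        end = min(self.offset1 + len(self.read1), self.offset2 + len(self.read2))
        return start, max(start, end)

    @property
    def overlap_length(self) -> int:
        start, end = self.overlap_interval
        return end - start


def _mutate_bases(seq: np.ndarray, error_rate: float, rng: np.random.Generator) -> np.ndarray:
    out = seq.copy()
    hits = np.nonzero(rng.random(seq.size) < error_rate)[0]
    for i in hits:
        choices = _BASES[_BASES != seq[i]]
        out[i] = rng.choice(choices)
    return out


def simulate_read_pairs(
    template: str,
    overlap: int,
    quality_profile: int | np.ndarray = 30,
    error_rate: float = 0.0,
    n_pairs: int = 1,
    seed: int | np.random.Generator = 0,
    read_length: int | None = None,
) -> list[SimulatedReadPair]:
    """Simulate overlapping read pairs from one amplicon template.

    Read 1 starts at the template's 5' end and read 2 ends at its 3' end
    (both given in template orientation); their overlap has the requested
    length.  Per-base substitution errors are injected independently in each
    read; qualities come from ``quality_profile`` (a constant Phred score or
    a per-position array).
    """
    if read_length is None:
        if (len(template) + overlap) % 2:
            raise ValueError(
                "template length + overlap must be even when read_length is "
                "not given"
            )
        read_length = (len(template) + overlap) // 2
    if overlap > read_length:
        raise ValueError(f"overlap {overlap} exceeds read length {read_length}")
    if overlap < 0 or read_length > len(template):
        raise ValueError("invalid overlap/read_length for this template")
    if not 0 <= error_rate < 1:
        raise ValueError("error_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    offset1 = 0
    offset2 = len(template) - read_length
    if offset1 + read_length - offset2 != overlap:
        # honour the requested overlap exactly by shifting read 2
        offset2 = offset1 + read_length - overlap
        if offset2 < 0 or offset2 + read_length > len(template):
            raise ValueError("requested overlap does not fit the template")
    t1 = np.frombuffer(template[offset1:offset1 + read_length].encode(), dtype="S1")
    t2 = np.frombuffer(template[offset2:offset2 + read_length].encode(), dtype="S1")
    if np.isscalar(quality_profile):
        q = np.full(read_length, int(quality_profile), dtype=int)
    else:
        q = np.asarray(quality_profile, dtype=int)
        if q.size != read_length:
            raise ValueError("quality profile length must equal read length")
    pairs = []
    for i in range(n_pairs):
        r1 = _mutate_bases(t1, error_rate, rng)
        r2 = _mutate_bases(t2, error_rate, rng)
        pairs.append(
            SimulatedReadPair(
                read1=r1.tobytes().decode(),
                read2=r2.tobytes().decode(),
                qual1=q.copy(),
                qual2=q.copy(),
                offset1=offset1,
                offset2=offset2,
                truth=template,
                pair_id=i,
            )
        )
    return pairs


def simulate_catalog(
    signatures,
    exposures,
    n_mutations: int,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Multinomial draw of a 96-channel mutation catalog from a signature mix.

    ``signatures`` is a (k, 96) array of probability vectors; ``exposures``
    the k mixing weights (sum 1).  Returns integer counts over the 96
    channels in the standard label order (see :mod:`clonerate.spectra`).
    """
    sigs = np.atleast_2d(np.asarray(signatures, dtype=float))
    w = np.asarray(exposures, dtype=float)
    if sigs.shape[1] != 96:
        raise ValueError(f"signatures must have 96 channels, got {sigs.shape[1]}")
    if np.any(sigs < 0):
        raise ValueError("signatures must be non-negative")
    if not np.allclose(sigs.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("each signature must sum to 1")
    if w.shape != (sigs.shape[0],) or not np.isclose(w.sum(), 1.0, atol=1e-6) \
            or np.any(w < 0):
        raise ValueError("exposures must be non-negative weights summing to 1")
    if n_mutations < 0:
        raise ValueError("n_mutations must be >= 0")
    rng = np.random.default_rng(seed)
    mixture = w @ sigs
    return rng.multinomial(n_mutations, mixture / mixture.sum())


def truth_table(variants) -> "pandas.DataFrame":  # noqa: F821
    """Truth table as a DataFrame (one row per simulated mutation)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "mutation_id": [v.mutation_id for v in variants],
            "origin_generation": [v.origin_generation for v in variants],
            "cell_fraction": [v.cell_fraction for v in variants],
            "molecule_fraction": [v.molecule_fraction for v in variants],
        }
    )
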