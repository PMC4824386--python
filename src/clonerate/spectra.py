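"""Mutational spectra over 96 trinucleotide channels and NNMF signatures.

Single-base substitutions are classified by the substituted pyrimidine
(C>A, C>G, C>T, T>A, T>C, T>G) and its two flanking bases, giving 96
channels; purine-reference variants are reverse-complemented first.  A
samples x 96 count catalog is factorised by non-negative matrix
factorisation (multiplicative updates minimising the generalised
Kullback-Leibler divergence, the natural choice for count data) into
signatures — probability vectors over the 96 channels interpreted as
mutational processes — and per-sample exposures.  Signature stability is
scored across random restarts by Hungarian-matched cosine similarity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment, nnls

__all__ = [
    "CHANNELS_96",
    "SUBSTITUTIONS_6",
    "SpectrumCatalog",
    "SignatureSet",
    "classify_96",
    "classify_variants",
    "spectrum",
    "collapse_6",
    "nnmf_extract",
    "attribute",
    "ReferenceMismatchError",
]

SUBSTITUTIONS_6 = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: fixed channel order: substitution class major, then 5' x 3' context
#: lexicographically — "A[C>A]A", "A[C>A]C", ..., "T[T>G]T"
CHANNELS_96 = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS_6
    for five in "ACGT"
    for three in "ACGT"
)
_CHANNEL_INDEX = {c: i for i, c in enumerate(CHANNELS_96)}


class ReferenceMismatchError(ValueError):
    """The variant's stated reference base disagrees with the FASTA."""


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def classify_96(contig: str, position: int, ref: str, alt: str, reference) -> str | None:
    """Assign one SNV to its trinucleotide channel label, e.g. "A[C>T]G".

    ``position`` is 1-based; ``reference`` is a FASTA accessor such as a
    ``pyfaidx.Fasta`` (or any mapping of contig -> sequence).  Variants with
    a purine reference are reverse-complemented (context and alternate)
    before labelling.  Returns None when the trinucleotide context contains
    an ambiguous base, which callers should log and skip.
    """
    ref, alt = ref.upper(), alt.upper()
    if ref == alt or len(ref) != 1 or len(alt) != 1:
        raise ValueError(f"need distinct single bases, got {ref}>{alt}")
    if ref not in "ACGT" or alt not in "ACGT":
        raise ValueError(f"non-ACGT allele {ref}>{alt}")
    seq = reference[contig]
    triplet = str(seq[position - 2: position + 1]).upper()
    if len(triplet) < 3:
        return None  # contig edge: no flanking context
    if triplet[1] != ref:
        raise ReferenceMismatchError(
            f"{contig}:{position} reference is {triplet[1]}, variant says {ref}"
        )
    if ref in "AG":
        triplet = _revcomp(triplet)
        alt = alt.translate(_COMPLEMENT)
    if any(b not in "ACGT" for b in triplet):
        return None
    return f"{triplet[0]}[{triplet[1]}>{alt}]{triplet[2]}"


def classify_variants(variants, reference):
    """Channel counts for an iterable of (contig, position, ref, alt).

    Returns (counts over the 96 channels, list of skipped variants with
    reasons).  Conservation holds: counts sum to n minus skipped.
    """
    counts = np.zeros(96, dtype=np.int64)
    skipped = []
    for contig, position, ref, alt in variants:
        label = classify_96(contig, position, ref, alt, reference)
        if label is None:
            skipped.append(
                {"variant": (contig, position, ref, alt), "reason": "ambiguous context"}
            )
            continue
        counts[_CHANNEL_INDEX[label]] += 1
    return counts, skipped


@dataclass
class SpectrumCatalog:
    """samples x 96 count matrix with channels in ``CHANNELS_96`` order."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if tuple(self.counts.columns) != CHANNELS_96:
            if set(self.counts.columns) == set(CHANNELS_96):
                self.counts = self.counts[list(CHANNELS_96)]
            else:
                raise ValueError("catalog columns must be the 96 channel labels")
        if (self.counts.values < 0).any():
            raise ValueError("catalog counts must be non-negative")

    @classmethod
    def from_counts(cls, counts, sample_ids=None) -> "SpectrumCatalog":
        arr = np.atleast_2d(np.asarray(counts))
        if sample_ids is None:
            sample_ids = [f"sample{i}" for i in range(arr.shape[0])]
        return cls(pd.DataFrame(arr, index=sample_ids, columns=list(CHANNELS_96)))

    @property
    def samples(self) -> list[str]:
        return list(self.counts.index)


def spectrum(counts) -> np.ndarray:
    """Normalise one sample's 96-channel counts to a probability vector."""
    arr = np.asarray(counts, dtype=float)
    if arr.shape != (96,):
        raise ValueError("expected a 96-vector")
    total = arr.sum()
    if total <= 0:
        raise ValueError("empty sample: no mutations to normalise")
    return arr / total


def collapse_6(counts) -> pd.Series:
    """Collapse 96 channels to the six substitution classes (sums preserved)."""
    arr = np.asarray(counts, dtype=float)
    if arr.shape != (96,):
        raise ValueError("expected a 96-vector")
    return pd.Series(
        arr.reshape(6, 16).sum(axis=1), index=list(SUBSTITUTIONS_6)
    )


@dataclass
class SignatureSet:
    """NNMF result: signatures (k x 96, rows sum to 1) and exposures.

    ``stability`` holds the mean Hungarian-matched cosine similarity of each
    signature across restarts; ``objective_trace`` is the per-iteration
    generalised KL divergence of the best restart (non-increasing).
    """

    signatures: pd.DataFrame
    exposures: pd.DataFrame
    reconstruction_error: float
    stability: np.ndarray
    objective_trace: np.ndarray


def _gkl(V: np.ndarray, WH: np.ndarray) -> float:
    mask = V > 0
    div = np.sum(V[mask] * np.log(V[mask] / WH[mask])) - V.sum() + WH.sum()
    return float(div)


def _mu_kl_nmf(V, k, max_iter, tol, rng):
    """Multiplicative-update NMF under generalised KL divergence.

    Lee-Seung updates; the objective is non-increasing at every step.
    Returns (W, H, trace of the objective per iteration).
    """
    eps = 1e-12
    n, m = V.shape
    scale = np.sqrt(V.mean() / k)
    W = rng.uniform(eps, 1.0, size=(n, k)) * scale
    H = rng.uniform(eps, 1.0, size=(k, m)) * scale
    trace = []
    prev = np.inf
    for _ in range(max_iter):
        WH = W @ H + eps
        H *= (W.T @ (V / WH)) / np.maximum(W.sum(axis=0)[:, None], eps)
        WH = W @ H + eps
        W *= ((V / WH) @ H.T) / np.maximum(H.sum(axis=1)[None, :], eps)
        obj = _gkl(V, W @ H + eps)
        trace.append(obj)
        if prev - obj < tol * max(prev, 1.0):
            break
        prev = obj
    return W, H, np.array(trace)


def _cosine_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    an = A / np.maximum(np.linalg.norm(A, axis=1, keepdims=True), 1e-30)
    bn = B / np.maximum(np.linalg.norm(B, axis=1, keepdims=True), 1e-30)
    return an @ bn.T


def nnmf_extract(
    catalog: SpectrumCatalog | pd.DataFrame | np.ndarray,
    k: int,
    restarts: int = 50,
    max_iter: int = 2000,
    tol: float = 1e-8,
    seed: int | np.random.Generator = 0,
) -> SignatureSet:
    """Extract k mutational signatures from a catalog by KL-NNMF.

    Runs ``restarts`` random initialisations, keeps the factorisation with
    the lowest generalised KL divergence, and scores per-signature
    stability as the mean cosine similarity between each best-run signature
    and its Hungarian-matched counterpart in every other restart.
    """
    if isinstance(catalog, SpectrumCatalog):
        V = catalog.counts.values.astype(float)
        sample_ids = catalog.samples
    else:
        V = np.atleast_2d(np.asarray(catalog, dtype=float))
        sample_ids = list(getattr(catalog, "index", range(V.shape[0])))
    if np.any(V < 0):
        raise ValueError("catalog must be non-negative")
    if V.sum() == 0:
        raise ValueError("catalog is all zero")
    if not 1 <= k <= min(V.shape):
        raise ValueError(f"k must be in [1, {min(V.shape)}], got {k}")
    rng = np.random.default_rng(seed)
    runs = []
    for _ in range(restarts):
        W, H, trace = _mu_kl_nmf(V, k, max_iter, tol, rng)
        runs.append((trace[-1], W, H, trace))
    runs.sort(key=lambda r: r[0])
    best_err, W, H, trace = runs[0]
    # stability: match each other restart's signatures onto the best run's
    sims = []
    for _, _, H_other, _ in runs[1:]:
        cos = _cosine_matrix(H, H_other)
        row, col = linear_sum_assignment(-cos)
        matched = np.empty(k)
        matched[row] = cos[row, col]
        sims.append(matched)
    stability = np.mean(sims, axis=0) if sims else np.ones(k)
    # normalise signatures to probability rows, fold scale into exposures
    row_sums = H.sum(axis=1)
    signatures = H / row_sums[:, None]
    exposures = W * row_sums[None, :]
    order = np.argsort(-exposures.sum(axis=0))
    signatures, exposures, stability = (
        signatures[order], exposures[:, order], stability[order]
    )
    sig_ids = [f"signature_{i + 1}" for i in range(k)]
    return SignatureSet(
        signatures=pd.DataFrame(signatures, index=sig_ids, columns=list(CHANNELS_96)),
        exposures=pd.DataFrame(exposures, index=sample_ids, columns=sig_ids),
        reconstruction_error=float(best_err),
        stability=stability,
        objective_trace=trace,
    )


def attribute(sample_spectrum, signatures) -> np.ndarray:
    """Non-negative least-squares exposures of a spectrum to fixed signatures.

    ``signatures`` is (k, 96) with probability rows; returns exposure
    proportions summing to 1 (all-zero spectrum gives all-zero exposures).
    Near-duplicate signatures make the problem ill-conditioned; NNLS then
    returns one minimum-norm representative and a warning is emitted.
    """
    import warnings

    S = np.atleast_2d(np.asarray(signatures, dtype=float))
    v = np.asarray(sample_spectrum, dtype=float)
    if S.shape[1] != 96 or v.shape != (96,):
        raise ValueError("expected (k, 96) signatures and a 96-vector spectrum")
    if not np.allclose(S.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("signature rows must sum to 1")
    if v.sum() == 0:
        return np.zeros(S.shape[0])
    if S.shape[0] > 1 and np.linalg.matrix_rank(S, tol=1e-8) < S.shape[0]:
        warnings.warn("degenerate (linearly dependent) signatures; exposures "
                      "are a minimum-norm solution", stacklevel=2)
    x, _ = nnls(S.T, v / v.sum())
    total = x.sum()
    return x / total if total > 0 else x
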