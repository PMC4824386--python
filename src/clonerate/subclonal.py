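"""Sub-clonal variant calling against a matched control.

Each candidate site is tested with a two-way contingency chi-square on the
(reference, mutant) read counts of the test population versus the matched
control; Bonferroni correction controls the family-wise error over the
batch, and a call is made only when the test population's mutant allele
frequency (MAF) exceeds the control's.  Variants are classified clonal
(MAF >= 30%, consistent with a heterozygous mutation carried by every cell
of a diploid population) or sub-clonal (MAF < 30%).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "VariantSite",
    "SubclonalCall",
    "test_site",
    "bonferroni",
    "classify_clonality",
    "call_subclonal",
    "SUBCLONAL_MAF_THRESHOLD",
]

SUBCLONAL_MAF_THRESHOLD = 0.30


@dataclass
class VariantSite:
    """One candidate SNV with per-sample (ref_count, alt_count) pairs."""

    contig: str
    position: int  # 1-based
    ref: str
    alt: str
    counts: dict[str, tuple[int, int]]

    def maf(self, sample: str) -> float:
        """Mutant allele frequency alt/(ref+alt); NaN at zero depth."""
        ref_count, alt_count = self.counts[sample]
        depth = ref_count + alt_count
        if depth == 0:
            return float("nan")
        return alt_count / depth

    def depth(self, sample: str) -> int:
        ref_count, alt_count = self.counts[sample]
        return ref_count + alt_count


@dataclass
class SubclonalCall:
    site: VariantSite
    statistic: float
    p_value: float
    p_adjusted: float
    detected: bool
    clonality: str  # 'clonal' | 'subclonal' | 'unclassified'
    degenerate: bool = False


def test_site(
    sample: tuple[int, int],
    control: tuple[int, int],
    continuity_correction: bool = False,
) -> tuple[float, float, bool]:
    """Pearson chi-square on the 2x2 (ref, alt) x (sample, control) table.

    Returns (statistic, two-sided p, degenerate).  A table with a zero
    margin (e.g. no mutant reads anywhere) carries no evidence either way
    and is returned as (0, 1, degenerate=True) rather than raising.
    Yates continuity correction is off by default.
    """
    table = np.array([sample, control], dtype=float)
    if np.any(table < 0):
        raise ValueError("read counts must be >= 0")
    if table[0].sum() == 0 or table[1].sum() == 0:
        raise ValueError("each sample must contribute at least one read")
    if np.any(table.sum(axis=0) == 0):
        return 0.0, 1.0, True
    stat, p, _, _ = stats.chi2_contingency(table, correction=continuity_correction)
    return float(stat), float(p), False


def bonferroni(p_values, alpha: float = 0.05):
    """Bonferroni adjustment: p * m capped at 1; significant iff adjusted < alpha."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    adjusted = np.minimum(p * p.size, 1.0)
    return adjusted, adjusted < alpha


def classify_clonality(maf: float, threshold: float = SUBCLONAL_MAF_THRESHOLD) -> str:
    """'subclonal' iff MAF < threshold (strict), else 'clonal'; NaN → 'unclassified'."""
    if maf is None or np.isnan(maf):
        return "unclassified"
    if not 0 <= maf <= 1:
        raise ValueError(f"MAF must be in [0, 1], got {maf}")
    return "subclonal" if maf < threshold else "clonal"


def call_subclonal(
    sites,
    sample_id: str,
    control_id: str,
    alpha: float = 0.05,
    continuity_correction: bool = False,
) -> tuple[list[SubclonalCall], list[dict]]:
    """Call sub-clonal variants over a batch of sites.

    The Bonferroni family is the set of sites tested in this invocation.
    A site is ``detected`` iff its adjusted p is below ``alpha`` AND the
    test sample's MAF exceeds the control's (one-sided semantics applied as
    a direction filter on the two-sided test).  Sites without usable counts
    in either sample are skipped and reported in the skip log.
    """
    tested: list[tuple[VariantSite, float, float, bool]] = []
    skipped: list[dict] = []
    for site in sites:
        missing = [s for s in (sample_id, control_id) if s not in site.counts]
        if missing:
            skipped.append(
                {"site": site, "reason": f"missing counts for {','.join(missing)}"}
            )
            continue
        if site.depth(sample_id) == 0 or site.depth(control_id) == 0:
            skipped.append({"site": site, "reason": "zero depth"})
            continue
        stat, p, degen = test_site(
            site.counts[sample_id],
            site.counts[control_id],
            continuity_correction=continuity_correction,
        )
        tested.append((site, stat, p, degen))
    if not tested:
        return [], skipped
    adjusted, significant = bonferroni([t[2] for t in tested], alpha=alpha)
    calls = []
    for (site, stat, p, degen), p_adj, sig in zip(tested, adjusted, significant):
        maf_sample = site.maf(sample_id)
        maf_control = site.maf(control_id)
        detected = bool(sig) and maf_sample > maf_control
        calls.append(
            SubclonalCall(
                site=site,
                statistic=stat,
                p_value=p,
                p_adjusted=float(p_adj),
                detected=detected,
                clonality=classify_clonality(maf_sample),
                degenerate=degen,
            )
        )
    return calls, skipped
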