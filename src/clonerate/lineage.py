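"""Lineage reconstruction from variant sharing and allele-frequency structure.

Clone lines derived from single cells of a monoclonal expansion inherit the
mutations of their founding cell's ancestry, so the pattern of variant
sharing across lines encodes the early cell genealogy: variants shared by
all lines (and clonal in the bulk population) predate the expansion,
variants shared by a subset mark internal branches, and private variants
mark terminal branches.  Within the bulk population the mutant allele
frequency of a variant born at division generation g concentrates at
2**-(g+1) (0.5 clonal, 0.25 first division, 0.125 second, ...), so MAFs
cluster into division-generation sub-populations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

__all__ = [
    "SharingMatrix",
    "MAFCluster",
    "CloneTree",
    "partition_variants",
    "cluster_mafs",
    "build_tree",
    "generation_label_for_maf",
]


@dataclass
class SharingMatrix:
    """Boolean variants x samples presence matrix with optional bulk MAFs.

    ``presence`` columns are clone-line identifiers; ``bulk_maf`` (indexed
    like ``presence``) gives each variant's MAF in the bulk population where
    assayed (NaN elsewhere).
    """

    presence: pd.DataFrame
    bulk_maf: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.presence.empty:
            raise ValueError("presence matrix is empty")
        absent = ~self.presence.any(axis=1)
        if absent.any():
            bad = list(self.presence.index[absent])[:5]
            raise ValueError(f"variants present in no sample: {bad}")
        if self.bulk_maf is not None:
            self.bulk_maf = self.bulk_maf.reindex(self.presence.index)

    @property
    def lines(self) -> list[str]:
        return list(self.presence.columns)


def partition_variants(
    matrix: SharingMatrix,
    clonal_maf_band: tuple[float, float] = (0.4, 0.6),
) -> dict[str, list]:
    """Split variants into in-vivo clonal / culture-shared / private sets.

    * ``in_vivo_clonal``: present in every line and clonal in the bulk
      population (bulk MAF inside ``clonal_maf_band``) — acquired before the
      expansion's founder cell.
    * ``culture_shared``: present in two or more but not all lines, or in
      all lines but sub-clonal in the bulk — acquired during early culture
      divisions.
    * ``private``: present in exactly one line.

    Variants in all lines without a bulk MAF measurement cannot be confirmed
    clonal and fall into ``culture_shared``.
    """
    if len(matrix.lines) < 2:
        raise ValueError("need at least two clone lines")
    lo, hi = clonal_maf_band
    n_lines = len(matrix.lines)
    n_present = matrix.presence.sum(axis=1)
    out: dict[str, list] = {"in_vivo_clonal": [], "culture_shared": [], "private": []}
    for variant in matrix.presence.index:
        k = int(n_present.loc[variant])
        if k == 1:
            out["private"].append(variant)
        elif k == n_lines:
            maf = (
                float(matrix.bulk_maf.loc[variant])
                if matrix.bulk_maf is not None
                else float("nan")
            )
            if lo <= maf <= hi:
                out["in_vivo_clonal"].append(variant)
            else:
                out["culture_shared"].append(variant)
        else:
            out["culture_shared"].append(variant)
    return out


def generation_label_for_maf(maf: float) -> int:
    """Nearest division-generation label g for a MAF near 2**-(g+1).

    0 = clonal, 1 = fixed at the first division, etc.
    """
    if not 0 < maf <= 1:
        raise ValueError(f"MAF must be in (0, 1], got {maf}")
    return max(0, round(-math.log2(maf) - 1))


@dataclass
class MAFCluster:
    cluster_id: int
    members: list
    central_maf: float
    generation_label: int


def _dp_gibbs(
    alt: np.ndarray,
    depth: np.ndarray,
    concentration: float,
    n_sweeps: int,
    rng: np.random.Generator,
    a0: float = 1.0,
    b0: float = 1.0,
):
    """Collapsed Gibbs sampler for a DP mixture of binomials, Beta(a0,b0) base.

    Cluster predictive for item (k, n) given cluster sufficient statistics
    (K, N) is Beta-Binomial with parameters (a0 + K, b0 + N - K); the
    binomial coefficient is shared across clusters and omitted.
    """
    lgamma = math.lgamma

    def lbeta(a: float, b: float) -> float:
        return lgamma(a) + lgamma(b) - lgamma(a + b)

    m = alt.size
    assign = np.zeros(m, dtype=int)
    sum_k = {0: float(alt.sum())}
    sum_n = {0: float(depth.sum())}
    size = {0: m}
    next_label = 1
    k_history = []
    snapshots: dict[int, tuple] = {}  # latest state seen at each cluster count
    log_conc = math.log(concentration)
    new_norm = lbeta(a0, b0)

    for sweep in range(n_sweeps):
        for i in range(m):
            ki, ni = alt[i], depth[i]
            c = assign[i]
            size[c] -= 1
            sum_k[c] -= ki
            sum_n[c] -= ni
            if size[c] == 0:
                del size[c], sum_k[c], sum_n[c]
            labels = list(size)
            logw = [
                math.log(size[c2])
                + lbeta(a0 + sum_k[c2] + ki, b0 + sum_n[c2] - sum_k[c2] + ni - ki)
                - lbeta(a0 + sum_k[c2], b0 + sum_n[c2] - sum_k[c2])
                for c2 in labels
            ]
            logw.append(log_conc + lbeta(a0 + ki, b0 + ni - ki) - new_norm)
            top = max(logw)
            w = [math.exp(v - top) for v in logw]
            total = sum(w)
            u = rng.random() * total
            choice = 0
            acc = w[0]
            while acc < u and choice < len(w) - 1:
                choice += 1
                acc += w[choice]
            if choice == len(labels):
                c_new = next_label
                next_label += 1
                size[c_new] = 0
                sum_k[c_new] = 0.0
                sum_n[c_new] = 0.0
            else:
                c_new = labels[choice]
            assign[i] = c_new
            size[c_new] += 1
            sum_k[c_new] += ki
            sum_n[c_new] += ni
        k_history.append(len(size))
        snapshots[len(size)] = (
            assign.copy(), {c: (sum_k[c], sum_n[c]) for c in size}
        )
    # posterior mode of the cluster count over the second half of the chain;
    # report the most recent state with that many clusters
    tail = k_history[len(k_history) // 2:]
    mode_k = int(pd.Series(tail).mode().iloc[0])
    state = snapshots.get(mode_k, snapshots[k_history[-1]])
    return state[0], state[1], mode_k, k_history


def cluster_mafs(
    alt_counts,
    depths,
    model: str = "dp",
    seed: int | np.random.Generator = 0,
    n_sweeps: int = 200,
    concentration: float = 1.0,
    max_levels: int = 7,
    variant_ids=None,
    merge_levels: bool = True,
) -> list[MAFCluster]:
    """Cluster variant MAFs into division-generation sub-populations.

    Each variant contributes its mutant read count and total depth (the
    binomial denominator).  ``model='dp'`` runs a collapsed-Gibbs Dirichlet
    process over binomial success probabilities (Beta(1,1) base measure);
    ``model='em'`` fits a finite binomial mixture by EM with component
    centres fixed at the halving series 0.5, 0.25, ..., 2**-max_levels and
    drops empty components.  Cluster labels come from the nearest expected
    level 2**-(g+1).

    The DP posterior is known to split a level into several clusters with
    near-identical centres; since the division generation is the quantity
    of interest, clusters sharing a generation label are pooled by default
    (``merge_levels=False`` returns the raw partition).
    """
    alt = np.asarray(alt_counts, dtype=float)
    depth = np.asarray(depths, dtype=float)
    if alt.shape != depth.shape or alt.ndim != 1 or alt.size == 0:
        raise ValueError("alt counts and depths must be equal-length 1-D, non-empty")
    if np.all(depth == 0):
        raise ValueError("all depths are zero")
    if np.any(alt > depth) or np.any(alt < 0):
        raise ValueError("need 0 <= alt <= depth")
    ids = list(variant_ids) if variant_ids is not None else list(range(alt.size))
    rng = np.random.default_rng(seed)

    if model == "dp":
        assign, suffstats, _, _ = _dp_gibbs(alt, depth, concentration, n_sweeps, rng)
        pooled: dict = {}
        for label in sorted(suffstats, key=lambda c: -suffstats[c][0]):
            members = [i for i in np.nonzero(assign == label)[0]]
            K, N = suffstats[label]
            centre = (K + 1.0) / (N + 2.0)  # Beta(1,1) posterior mean
            key = generation_label_for_maf(centre) if merge_levels else label
            if key in pooled:
                pooled[key] = (
                    pooled[key][0] + members,
                    pooled[key][1] + K,
                    pooled[key][2] + N,
                )
            else:
                pooled[key] = (members, K, N)
        clusters = []
        for cid, (members, K, N) in enumerate(
            sorted(pooled.values(), key=lambda t: -(t[1] + 1) / (t[2] + 2))
        ):
            centre = (K + 1.0) / (N + 2.0)
            clusters.append(
                MAFCluster(
                    cluster_id=cid,
                    members=[ids[i] for i in members],
                    central_maf=float(centre),
                    generation_label=generation_label_for_maf(centre),
                )
            )
        return clusters
    if model == "em":
        return _em_fixed_levels(alt, depth, ids, max_levels)
    raise ValueError(f"unknown model {model!r}")


def _em_fixed_levels(alt, depth, ids, max_levels, n_iter: int = 200):
    """EM over mixing weights with binomial components at the halving series."""
    centres = 2.0 ** -(np.arange(max_levels) + 1.0)
    logp = (
        alt[:, None] * np.log(centres[None, :])
        + (depth - alt)[:, None] * np.log1p(-centres[None, :])
    )
    weights = np.full(max_levels, 1.0 / max_levels)
    for _ in range(n_iter):
        logr = logp + np.log(weights[None, :])
        logr -= logsumexp(logr, axis=1, keepdims=True)
        r = np.exp(logr)
        new_weights = r.mean(axis=0)
        if np.allclose(new_weights, weights, atol=1e-10):
            weights = new_weights
            break
        weights = new_weights
    hard = np.argmax(logp + np.log(np.maximum(weights, 1e-300))[None, :], axis=1)
    clusters = []
    for cid, g in enumerate(sorted(set(hard.tolist()))):
        members = [ids[i] for i in np.nonzero(hard == g)[0]]
        obs = alt[hard == g].sum() / max(depth[hard == g].sum(), 1.0)
        clusters.append(
            MAFCluster(
                cluster_id=cid,
                members=members,
                central_maf=float(obs),
                generation_label=int(g),
            )
        )
    return clusters


@dataclass
class CloneTree:
    """Inferred cellular genealogy over derived clone lines.

    ``edges`` maps each clade (frozenset of leaf lines) to the variants
    whose carrier set equals that clade; the count on an edge is a minimum,
    since sub-clonal detection is incomplete.  ``conflicts`` lists variants
    whose carrier sets were incompatible with the accepted tree.
    """

    leaves: tuple[str, ...]
    edges: dict[frozenset, list]
    conflicts: list = field(default_factory=list)

    @property
    def edge_counts(self) -> dict[frozenset, int]:
        return {clade: len(v) for clade, v in self.edges.items()}

    @property
    def clades(self) -> list[frozenset]:
        """Non-trivial internal clades (excluding root and single leaves)."""
        full = frozenset(self.leaves)
        return [c for c in self.edges if 1 < len(c) < len(full)]

    def newick(self) -> str:
        """Serialize as newick with edge mutation counts in the length slot."""
        full = frozenset(self.leaves)
        children: dict[frozenset, list[frozenset]] = {}
        nodes = sorted(set(self.edges) | {full}, key=len)
        for node in nodes:
            if node == full:
                continue
            parents = [p for p in nodes if node < p]
            parent = min(parents, key=len)
            children.setdefault(parent, []).append(node)
        # leaves not explicitly present hang off their smallest containing clade
        for leaf in self.leaves:
            s = frozenset([leaf])
            if s not in nodes:
                parent = min((p for p in nodes if s < p), key=len)
                children.setdefault(parent, []).append(s)

        def render(node: frozenset) -> str:
            count = len(self.edges.get(node, []))
            if len(node) == 1:
                return f"{next(iter(node))}:{count}"
            parts = ",".join(
                render(c) for c in sorted(children.get(node, []), key=sorted)
            )
            return f"({parts}):{count}"

        return render(full) + ";"


def build_tree(
    presence: pd.DataFrame | SharingMatrix,
    conflict_threshold: float = 0.5,
) -> CloneTree:
    """Build the clone tree from variant carrier sets.

    Each variant's carrier set (the lines it appears in) should map to one
    clade of the true genealogy; the tree is the laminar family of carrier
    sets.  Incompatible (non-nested, overlapping) sets are resolved by
    maximum compatibility: distinct carrier sets are accepted greedily in
    decreasing order of supporting-variant count, and variants of rejected
    sets are reported as conflicts, never silently dropped.  If more than
    ``conflict_threshold`` of variants end up in conflict the sharing
    pattern is considered irreconcilable and an error is raised.
    """
    if isinstance(presence, SharingMatrix):
        presence = presence.presence
    if presence.empty:
        raise ValueError("presence matrix is empty")
    if (~presence.any(axis=1)).any():
        raise ValueError("every variant must be present in at least one line")
    lines = tuple(presence.columns)
    carrier: dict[frozenset, list] = {}
    for variant, row in presence.iterrows():
        clade = frozenset(presence.columns[row.values.astype(bool)])
        carrier.setdefault(clade, []).append(variant)
    order = sorted(
        carrier, key=lambda c: (-len(carrier[c]), -len(c), tuple(sorted(c)))
    )
    accepted: list[frozenset] = []
    edges: dict[frozenset, list] = {}
    conflicts: list = []
    for clade in order:
        compatible = all(
            clade <= other or other <= clade or not (clade & other)
            for other in accepted
        )
        if compatible:
            accepted.append(clade)
            edges[clade] = list(carrier[clade])
        else:
            conflicts.extend(carrier[clade])
    n_variants = len(presence)
    if n_variants and len(conflicts) / n_variants > conflict_threshold:
        raise ValueError(
            f"irreconcilable sharing patterns: {len(conflicts)}/{n_variants} "
            "variants conflict with the maximum-compatibility tree"
        )
    return CloneTree(leaves=lines, edges=edges, conflicts=conflicts)
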