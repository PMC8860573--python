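"""Variant similarity networks over signed gene sets.

Each variant v carries a signed set I_v of (gene, sign) pairs: under
*transcripts* semantics the sign is the direction of transcript change for
the alternative allele; under *motifs* semantics it is the direction of the
binding-score change, restricted by default to addition/deletion effects
(the functionally sharpest classes).  The similarity of two variants is the
Jaccard index of their signed sets — a sign mismatch on the same gene makes
the elements distinct — and the similarity network connects two variants
iff their similarity is greater than zero.

Communities are detected with the Louvain modularity algorithm on the
similarity-weighted graph.  LD helpers (dosage r-squared and windowed
greedy pruning at 250 kb) allow rebuilding networks from variants not in
linkage disequilibrium.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .association import AssociationResult
from .datamodel import GenotypeMatrix, Variant
from .motifs import MotifImpact

__all__ = [
    "SignedGeneSet",
    "Community",
    "build_signed_sets",
    "jaccard",
    "build_network",
    "detect_communities",
    "ld_r2",
    "ld_filter",
    "similarity_profile",
]

log = logging.getLogger(__name__)

DEFAULT_MOTIF_EFFECTS = frozenset({"addition", "deletion"})


@dataclass(frozen=True)
class SignedGeneSet:
    """The set I_v of (gene-or-factor, sign) pairs attached to one variant."""

    variant_id: str
    elements: frozenset[tuple[str, str]]  # (gene, '+'|'-')
    semantics: str  # "transcripts" | "motifs"

    def __post_init__(self) -> None:
        if self.semantics not in ("transcripts", "motifs"):
            raise ValueError(f"unknown semantics {self.semantics!r}")
        for _, sign in self.elements:
            if sign not in ("+", "-"):
                raise ValueError(f"invalid sign {sign!r}")


@dataclass
class Community:
    community_id: int
    members: frozenset[str]
    modularity_contribution: float = np.nan


def build_signed_sets(
    results: Sequence[AssociationResult] | Sequence[MotifImpact],
    semantics: str,
    motif_effects: Iterable[str] = DEFAULT_MOTIF_EFFECTS,
    models: Iterable[str] | None = None,
) -> list[SignedGeneSet]:
    """Build per-variant signed sets from association or motif results.

    Transcripts semantics: one (gene, sign(beta1)) element per retained
    association; the three genetic models are pooled unless ``models``
    restricts them.  Motifs semantics: one (factor, sign) element per
    retained motif result whose label is in ``motif_effects``; motifs are
    aggregated to their factor symbol, and when several motifs of one
    factor disagree in sign at a variant the sign of the largest absolute
    score change wins.
    """
    if semantics == "transcripts":
        elements: dict[str, set] = defaultdict(set)
        for r in results:
            if models is not None and r.model not in models:
                continue
            sign = "+" if r.beta1 > 0 else "-"
            elements[r.variant_id].add((r.gene_id, sign))
        return [
            SignedGeneSet(vid, frozenset(els), "transcripts")
            for vid, els in elements.items()
        ]
    if semantics == "motifs":
        effects = set(motif_effects)
        # (variant, factor) -> (|delta|, sign) keeping the largest |delta|
        best: dict[tuple[str, str], tuple[float, str]] = {}
        for im in results:
            if im.label not in effects or im.direction == "none":
                continue
            sign = "+" if im.direction == "increase" else "-"
            delta = im.delta
            weight = abs(delta) if delta is not None else np.inf
            key = (im.variant_id, im.factor)
            if key not in best or weight > best[key][0]:
                best[key] = (weight, sign)
        elements = defaultdict(set)
        for (vid, factor), (_, sign) in best.items():
            elements[vid].add((factor, sign))
        return [
            SignedGeneSet(vid, frozenset(els), "motifs")
            for vid, els in elements.items()
        ]
    raise ValueError(f"unknown semantics {semantics!r}")


def jaccard(set_a: SignedGeneSet, set_b: SignedGeneSet) -> float:
    """Jaccard index |A n B| / |A u B| over signed elements."""
    if set_a.semantics != set_b.semantics:
        raise ValueError("cannot compare sets with different semantics")
    a, b = set_a.elements, set_b.elements
    if not a or not b:
        raise ValueError("Jaccard similarity is undefined for empty sets")
    inter = len(a & b)
    if inter == 0:
        return 0.0
    return inter / len(a | b)


def build_network(sets: Sequence[SignedGeneSet]) -> nx.Graph:
    """Similarity network: edge (v1, v2) iff Jaccard > 0, weighted by it.

    Variants with empty sets are excluded (similarity undefined) with a log
    note; isolated variants with nonempty sets are retained as nodes.  An
    inverted element index restricts pair comparisons to variants sharing
    at least one element, so the complexity is driven by the number of
    intersecting pairs rather than all n^2 pairs.
    """
    usable = []
    for s in sets:
        if not s.elements:
            log.info("variant %s has an empty signed set; excluded", s.variant_id)
            continue
        usable.append(s)
    graph = nx.Graph()
    graph.add_nodes_from(s.variant_id for s in usable)
    by_element: dict[tuple[str, str], list[int]] = defaultdict(list)
    for i, s in enumerate(usable):
        for el in s.elements:
            by_element[el].append(i)
    candidate_pairs = {
        (i, j)
        for members in by_element.values()
        for ai, i in enumerate(members)
        for j in members[ai + 1:]
    }
    for i, j in candidate_pairs:
        sim = jaccard(usable[i], usable[j])
        if sim > 0:
            union = len(usable[i].elements | usable[j].elements)
            graph.add_edge(usable[i].variant_id, usable[j].variant_id,
                           weight=sim, union_size=union)
    return graph


def detect_communities(graph: nx.Graph, seed: int = 0) -> tuple[list[Community], float]:
    """Louvain communities of the non-isolated nodes, with modularity.

    Isolated variants are excluded (they carry no similarity evidence).
    Returns the communities sorted by decreasing size and the weighted
    modularity of the partition; an empty or edgeless graph yields an empty
    partition with modularity NaN.
    """
    core = graph.subgraph([n for n, d in graph.degree() if d > 0])
    if core.number_of_nodes() == 0:
        return [], float("nan")
    partition = nx.community.louvain_communities(core, weight="weight", seed=seed)
    partition = sorted(partition, key=lambda c: (-len(c), min(c)))
    modularity = nx.community.modularity(core, partition, weight="weight")
    m = core.size(weight="weight")
    communities = []
    for cid, members in enumerate(partition):
        sub = core.subgraph(members)
        internal = sub.size(weight="weight")
        degree_sum = sum(d for _, d in core.degree(members, weight="weight"))
        contribution = internal / m - (degree_sum / (2 * m)) ** 2
        communities.append(Community(cid, frozenset(members), contribution))
    return communities, float(modularity)


def ld_r2(geno_a: np.ndarray, geno_b: np.ndarray) -> float:
    """Squared Pearson correlation of allele dosages, pairwise-deleted.

    NaN when either vector is constant (or fewer than two complete pairs).
    """
    a = np.asarray(geno_a, float)
    b = np.asarray(geno_b, float)
    mask = ~(np.isnan(a) | np.isnan(b))
    a, b = a[mask], b[mask]
    if len(a) < 2 or np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def ld_filter(
    variants: Sequence[Variant],
    genotypes: GenotypeMatrix,
    window_bp: int = 250_000,
    r2_max: float = 0.5,
) -> list[Variant]:
    """Greedy windowed LD pruning, first-kept-wins in coordinate order.

    Scanning variants by (chrom, pos), a variant is dropped when its dosage
    r-squared with any already-retained variant within ``window_bp`` on the
    same chromosome exceeds ``r2_max``.  This approximates PLINK-style
    windowed pruning; it is not a PLINK clone.
    """
    order = sorted(range(len(variants)),
                   key=lambda i: (variants[i].chrom, variants[i].pos))
    col = {vid: k for k, vid in enumerate(genotypes.variant_ids)}
    retained: list[int] = []
    for i in order:
        v = variants[i]
        drop = False
        for j in reversed(retained):
            u = variants[j]
            if u.chrom != v.chrom or v.pos - u.pos > window_bp:
                break
            r2 = ld_r2(genotypes.codes[:, col[v.id]], genotypes.codes[:, col[u.id]])
            if not np.isnan(r2) and r2 > r2_max:
                drop = True
                break
        if not drop:
            retained.append(i)
    return [variants[i] for i in sorted(retained)]


def similarity_profile(
    graph: nx.Graph,
    bins: Sequence[float] = tuple(np.linspace(0, 1, 11)),
) -> pd.DataFrame:
    """Distribution of edge similarities with per-bin union cardinalities.

    Returns one row per similarity bin: edge count, and mean/median of the
    union cardinality of the signed sets joined by edges in that bin.
    Empty graphs yield an empty table.
    """
    edges = [
        (d["weight"], d.get("union_size", np.nan))
        for _, _, d in graph.edges(data=True)
    ]
    if not edges:
        return pd.DataFrame(columns=["bin_low", "bin_high", "n_edges",
                                     "mean_union", "median_union"])
    sims = np.array([e[0] for e in edges])
    unions = np.array([e[1] for e in edges], dtype=float)
    bins = np.asarray(bins, float)
    rows = []
    for lo, hi in zip(bins[:-1], bins[1:]):
        last = hi == bins[-1]
        mask = (sims >= lo) & ((sims <= hi) if last else (sims < hi))
        if mask.any():
            rows.append((lo, hi, int(mask.sum()),
                         float(np.mean(unions[mask])),
                         float(np.median(unions[mask]))))
        else:
            rows.append((lo, hi, 0, np.nan, np.nan))
    return pd.DataFrame(rows, columns=["bin_low", "bin_high", "n_edges",
                                       "mean_union", "median_union"])
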