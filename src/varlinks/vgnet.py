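"""Directed bipartite variant-gene networks.

Nodes are variants and genes.  An edge runs variant -> gene when the
variant's genotype associates with the gene's transcript level (sign =
sign of the genotype coefficient), and gene -> variant when the gene's
product binds at the variant locus, instantiated from retained motif-impact
results for that factor at that variant (sign = direction of the
binding-score change; additions are '+', deletions '-').

The module computes strongly connected components, degree / betweenness /
closeness centralities, fits heavy-tailed degree-distribution models
(discrete power law vs discrete log-normal, compared by a Vuong likelihood
ratio test), enumerates 2-cycles — variant-gene pairs with edges in both
directions, the network's feedback-loop candidates — and tests 2-cycle
variants for functional-marker enrichment with Fisher's exact test.

Closeness uses outgoing reachability with the Wasserman-Faust component
normalization: nodes that reach nothing (in particular all nodes outside
the strongly connected core) get closeness 0, reproducing the
characteristic two-peak closeness profile of these networks.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .annotation import MarkerAnnotation
from .association import AssociationResult
from .motifs import MotifImpact

__all__ = [
    "TwoCycle",
    "DegreeFit",
    "build_vg_graph",
    "strongly_connected_components",
    "centralities",
    "fit_degree_distribution",
    "enumerate_2cycles",
    "twocycle_marker_enrichment",
]

DEFAULT_EDGE_EFFECTS = frozenset({"change", "addition", "deletion"})


@dataclass(frozen=True)
class TwoCycle:
    variant_id: str
    factor_gene_id: str
    association_sign: str  # '+' | '-'
    binding_sign: str      # '+' | '-'


def build_vg_graph(
    associations: Sequence[AssociationResult],
    motif_impacts: Sequence[MotifImpact] = (),
    motif_effects: Iterable[str] = DEFAULT_EDGE_EFFECTS,
) -> nx.DiGraph:
    """Assemble the bipartite digraph from the two result tables.

    One variant->gene edge per associated (variant, gene) pair (when
    several models associate the same pair, the most significant result
    provides sign and evidence) and one gene->variant edge per (factor,
    variant) with a retained motif result whose label is in
    ``motif_effects`` (largest absolute score change wins the sign).
    """
    effects = set(motif_effects)
    graph = nx.DiGraph()
    best_assoc: dict[tuple[str, str], AssociationResult] = {}
    for r in associations:
        key = (r.variant_id, r.gene_id)
        if key not in best_assoc or r.p < best_assoc[key].p:
            best_assoc[key] = r
    best_motif: dict[tuple[str, str], tuple[float, MotifImpact]] = {}
    for im in motif_impacts:
        if im.label not in effects or im.direction == "none":
            continue
        key = (im.factor, im.variant_id)
        weight = abs(im.delta) if im.delta is not None else np.inf
        if key not in best_motif or weight > best_motif[key][0]:
            best_motif[key] = (weight, im)
    variant_ids = {v for v, _ in best_assoc} | {v for _, v in best_motif}
    gene_ids = {g for _, g in best_assoc} | {g for g, _ in best_motif}
    clash = variant_ids & gene_ids
    if clash:
        raise ValueError(f"ids used both as variant and gene: {sorted(clash)[:5]}")
    graph.add_nodes_from(variant_ids, kind="variant")
    graph.add_nodes_from(gene_ids, kind="gene")
    for (vid, gene), r in best_assoc.items():
        graph.add_edge(vid, gene, direction_type="variant_to_gene",
                       sign="+" if r.beta1 > 0 else "-", evidence=r.model)
    for (factor, vid), (_, im) in best_motif.items():
        graph.add_edge(factor, vid, direction_type="gene_to_variant",
                       sign="+" if im.direction == "increase" else "-",
                       evidence=im.label)
    return graph


def strongly_connected_components(graph: nx.DiGraph) -> list[frozenset[str]]:
    """SCCs sorted by decreasing size (ties by smallest member)."""
    comps = [frozenset(c) for c in nx.strongly_connected_components(graph)]
    return sorted(comps, key=lambda c: (-len(c), min(c)))


def centralities(graph: nx.DiGraph) -> pd.DataFrame:
    """Per-node degree (in+out), betweenness and closeness.

    Betweenness counts all-shortest-path pair fractions on the directed,
    unweighted graph (raw, unnormalized).  Closeness is outgoing-distance
    based with component normalization; nodes reaching nothing score 0.
    """
    deg = dict(graph.degree())
    btw = nx.betweenness_centrality(graph, normalized=False)
    cls = nx.closeness_centrality(graph.reverse())
    rows = [
        (node, deg[node], btw[node], cls[node],
         graph.nodes[node].get("kind", ""))
        for node in graph.nodes
    ]
    return pd.DataFrame(rows, columns=["node", "degree", "betweenness",
                                       "closeness", "kind"])


# ---------------------------------------------------------------------------
# Degree-distribution model selection


@dataclass
class DegreeFit:
    """Discrete power-law vs log-normal tail fit with a Vuong LR test.

    ``preferred`` is the model with the larger likelihood; ``p_vuong``
    (two-sided normal) qualifies how decisive the preference is.
    ``preferred == 'inconclusive'`` when there are too few points or the
    models are indistinguishable on the data.
    """

    x_min: int = 0
    alpha: float = np.nan
    mu: float = np.nan
    sigma: float = np.nan
    loglik_ratio: float = np.nan            # powerlaw minus lognormal
    loglik_ratio_corrected: float = np.nan  # plus Schwarz parameter penalty
    p_vuong: float = np.nan
    preferred: str = "inconclusive"
    n_tail: int = 0


def _powerlaw_logpmf(k: np.ndarray, alpha: float, x_min: int) -> np.ndarray:
    return -alpha * np.log(k) - np.log(special.zeta(alpha, x_min))


def _fit_powerlaw(k: np.ndarray, x_min: int) -> float:
    def nll(alpha: float) -> float:
        return -float(_powerlaw_logpmf(k, alpha, x_min).sum())

    res = optimize.minimize_scalar(nll, bounds=(1.01, 12.0), method="bounded")
    return float(res.x)


def _lognormal_logpmf(k: np.ndarray, mu: float, sigma: float, x_min: int
                      ) -> np.ndarray:
    """Discretized log-normal on integers >= x_min: mass of [k-0.5, k+0.5]
    under the continuous log-normal, renormalized to the tail."""
    upper = stats.norm.cdf((np.log(k + 0.5) - mu) / sigma)
    lower = stats.norm.cdf((np.log(np.maximum(k - 0.5, 1e-12)) - mu) / sigma)
    tail = stats.norm.sf((np.log(max(x_min - 0.5, 1e-12)) - mu) / sigma)
    with np.errstate(divide="ignore"):
        return np.log(np.maximum(upper - lower, 1e-300)) - np.log(max(tail, 1e-300))


_LOGNORMAL_BOUNDS = ((-10.0, 15.0), (0.05, 3.0))


def _fit_lognormal(k: np.ndarray, x_min: int) -> tuple[float, float]:
    """ML fit of the discretized log-normal tail.

    mu and sigma are bounded to the identifiable region: as sigma grows
    with mu/sigma^2 held fixed, the tail-truncated log-normal collapses
    onto a pure power law, which would make the model comparison
    meaningless.  The bounds are far wider than any realistic degree
    distribution.
    """
    logs = np.log(k)
    x0 = np.array([np.clip(logs.mean(), *_LOGNORMAL_BOUNDS[0]),
                   np.clip(logs.std() + 0.05, *_LOGNORMAL_BOUNDS[1])])

    def nll(theta: np.ndarray) -> float:
        mu, sigma = theta
        return -float(_lognormal_logpmf(k, mu, sigma, x_min).sum())

    res = optimize.minimize(nll, x0=x0, method="Nelder-Mead",
                            bounds=_LOGNORMAL_BOUNDS)
    mu, sigma = res.x
    return float(mu), float(sigma)


def _ks_powerlaw(k: np.ndarray, alpha: float, x_min: int) -> float:
    values = np.arange(x_min, k.max() + 1)
    pmf = np.exp(_powerlaw_logpmf(values, alpha, x_min))
    cdf = np.cumsum(pmf)
    emp = np.searchsorted(np.sort(k), values, side="right") / len(k)
    return float(np.max(np.abs(emp - cdf)))


def estimate_x_min(degrees: np.ndarray, max_candidates: int = 50) -> int:
    """Clauset-style x_min: the tail start minimizing the KS distance of the
    fitted discrete power law, scanned over observed degree values."""
    uniq = np.unique(degrees)
    uniq = uniq[uniq >= 1]
    # keep enough tail to fit: require >= 10 points above the candidate
    candidates = [int(x) for x in uniq[:max_candidates]
                  if (degrees >= x).sum() >= 10]
    best_x, best_ks = int(uniq[0]), np.inf
    for x in candidates:
        tail = degrees[degrees >= x]
        alpha = _fit_powerlaw(tail, x)
        ks = _ks_powerlaw(tail, alpha, x)
        if ks < best_ks:
            best_x, best_ks = x, ks
    return best_x


def fit_degree_distribution(degrees: Sequence[int],
                            x_min: int | None = 1) -> DegreeFit:
    """Fit and compare power-law and log-normal models to a degree sample.

    Both models are fitted by maximum likelihood to ``k >= x_min``.  The
    default ``x_min = 1`` fits the full positive-degree range: restricting
    the comparison to a KS-estimated tail start (pass ``x_min=None`` to do
    so, or an explicit value) discards exactly the body of the
    distribution where the two hypotheses differ, and on the tail alone
    they are usually indistinguishable.  The preferred model is decided by
    the sign of the Vuong log-likelihood ratio (power law minus
    log-normal) with Schwarz's correction for the log-normal's extra
    parameter; the uncorrected ratio and its two-sided Vuong p-value are
    also reported.  Fewer than 30 nonzero degrees, or a degenerate sample,
    yields an inconclusive result.
    """
    k = np.asarray([d for d in degrees if d > 0], dtype=float)
    if len(k) < 30 or np.ptp(k) == 0:
        return DegreeFit(n_tail=len(k))
    if x_min is None:
        x_min = estimate_x_min(k)
    tail = k[k >= x_min]
    if len(tail) < 30 or np.ptp(tail) == 0:
        return DegreeFit(x_min=x_min, n_tail=len(tail))
    alpha = _fit_powerlaw(tail, x_min)
    mu, sigma = _fit_lognormal(tail, x_min)
    ll_pl = _powerlaw_logpmf(tail, alpha, x_min)
    ll_ln = _lognormal_logpmf(tail, mu, sigma, x_min)
    diffs = ll_pl - ll_ln
    ratio = float(diffs.sum())
    n = len(tail)
    # Schwarz correction: the log-normal spends one more parameter
    corrected = ratio + 0.5 * np.log(n)
    sd = float(diffs.std(ddof=1))
    if sd == 0:
        return DegreeFit(x_min=x_min, alpha=alpha, mu=mu, sigma=sigma,
                         loglik_ratio=ratio, loglik_ratio_corrected=corrected,
                         n_tail=n)
    z = ratio / (sd * np.sqrt(n))
    p = float(2 * stats.norm.sf(abs(z)))
    preferred = "powerlaw" if corrected > 0 else "lognormal"
    return DegreeFit(x_min=x_min, alpha=alpha, mu=mu, sigma=sigma,
                     loglik_ratio=ratio, loglik_ratio_corrected=corrected,
                     p_vuong=p, preferred=preferred, n_tail=n)


# ---------------------------------------------------------------------------
# 2-cycles


def enumerate_2cycles(graph: nx.DiGraph) -> list[TwoCycle]:
    """All (variant, gene) pairs with edges in both directions.

    Complete and duplicate-free: one record per unordered reciprocal pair,
    discovered by scanning variant->gene edges and checking the reverse.
    """
    cycles = []
    for u, v, data in graph.edges(data=True):
        if data.get("direction_type") != "variant_to_gene":
            continue
        if graph.has_edge(v, u):
            back = graph.edges[v, u]
            cycles.append(
                TwoCycle(
                    variant_id=u,
                    factor_gene_id=v,
                    association_sign=data.get("sign", "+"),
                    binding_sign=back.get("sign", "+"),
                )
            )
    return sorted(cycles, key=lambda c: (c.variant_id, c.factor_gene_id))


def twocycle_marker_enrichment(
    graph: nx.DiGraph,
    marker_annotations: Sequence[MarkerAnnotation],
    cycles: Sequence[TwoCycle] | None = None,
) -> tuple[float, float, np.ndarray]:
    """Fisher's exact test of functional-marker enrichment in 2-cycle
    variants.

    Builds the 2x2 table (in-2-cycle vs not) x (has-marker vs not) over the
    variant nodes of the graph.  Returns (odds ratio, two-sided p, table);
    degenerate margins give p = 1 with a warning.
    """
    if cycles is None:
        cycles = enumerate_2cycles(graph)
    in_cycle = {c.variant_id for c in cycles}
    marked = {m.variant_id for m in marker_annotations}
    variant_nodes = [n for n, d in graph.nodes(data=True)
                     if d.get("kind") == "variant"]
    table = np.zeros((2, 2), dtype=int)
    for node in variant_nodes:
        i = 0 if node in in_cycle else 1
        j = 0 if node in marked else 1
        table[i, j] += 1
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        warnings.warn("degenerate 2x2 margin in 2-cycle enrichment; p = 1",
                      stacklevel=2)
        return float("nan"), 1.0, table
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return float(odds), float(p), table
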