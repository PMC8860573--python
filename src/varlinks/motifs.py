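"""Allele-aware binding-motif impact scoring.

For every (variant, motif) pair the flanking sequence is scored with the
reference and with the alternative allele spliced in, using log-odds
position weight matrices.  Two scores drive everything downstream:

* ``la`` — the log-odds score of the best motif placement,
  ``sum_i log2(p_i(b_i) / q(b_i))`` over motif columns, with column
  probabilities ``p`` from counts plus a pseudocount and background ``q``;
* ``lm`` — the maximum achievable log-odds score,
  ``sum_i log2(max_b p_i(b) / q(b))``.

Score significance is assessed against a motif-specific empirical null:
exhaustive enumeration of all ``4^L`` sequences for short motifs,
background sampling for longer ones.  A (variant, motif) result is retained
when the best placement overlapping the variant satisfies all of:

(i)   the placement overlaps the variant site;
(ii)  ``la`` for the reference OR the alternative allele reaches the score
      floor (6 for TFBS motifs, 2 for the generally shorter RBP motifs);
(iii) the empirical score p-value for either allele is < 0.001;
(iv)  the normalized ``la/lm`` ratio for either allele is > 0.5.

Retained results are classified as ``match`` (relative score difference
< 10%), ``change`` (>= 10%), ``addition`` (alternative allele creates a
positive-scoring site where the reference scores negative) or ``deletion``
(the opposite).  For small insertions, any motif match starting inside the
inserted bases is an addition by definition.

RBP motifs are evaluated only for variants annotated as UTR (3' or 5').
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import Pfm, Variant

__all__ = [
    "MotifScanConfig",
    "MotifScore",
    "MotifImpact",
    "NullDistribution",
    "RatioNormalization",
    "log_odds_matrix",
    "score_window",
    "build_null",
    "apply_variant",
    "evaluate_motif",
    "classify",
    "scan_variants",
    "impacts_to_frame",
]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_COMPLEMENT = np.array([3, 2, 1, 0, 4])  # A<->T, C<->G, N->N


@dataclass(frozen=True)
class MotifScanConfig:
    """Tunable parameters of the motif-impact scan.

    Defaults follow TESS-style pattern matching: score floor 6 for TFBS and
    2 for RBP motifs, empirical p-value cutoff 0.001, normalized la/lm ratio
    floor 0.5, and a 30 bp flank on each side of the allele span (large
    enough that every placement overlapping the variant is scoreable for
    motifs up to 30 bp).
    """

    flank: int = 30
    pseudocount: float = 0.01
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    min_score_tfbs: float = 6.0
    min_score_rbp: float = 2.0
    p_max: float = 0.001
    ratio_min: float = 0.5
    match_change_cutoff: float = 0.10
    enum_max_len: int = 10      # enumerate 4^L nulls for motifs up to this length
    null_samples: int = 100_000
    seed: int = 0

    def min_score(self, motif_kind: str) -> float:
        return self.min_score_rbp if motif_kind == "rbp" else self.min_score_tfbs


@dataclass
class MotifScore:
    """Best-placement score of one allele's window against one motif."""

    la: float
    lm: float
    offset: int
    strand: str  # '+' or '-'
    ratio: float = field(init=False)
    norm_ratio: float | None = None
    pvalue: float | None = None

    def __post_init__(self) -> None:
        self.ratio = self.la / self.lm if self.lm != 0 else 0.0


@dataclass
class MotifImpact:
    variant_id: str
    motif_id: str
    factor: str
    ref_score: MotifScore | None
    alt_score: MotifScore | None
    label: str       # match | change | addition | deletion
    direction: str   # increase | decrease | none

    @property
    def delta(self) -> float | None:
        if self.ref_score is None or self.alt_score is None:
            return None
        return self.alt_score.la - self.ref_score.la


def seq_to_indices(seq: str) -> np.ndarray:
    """Map an ACGTN string to integer codes; other letters are rejected."""
    try:
        return np.fromiter((_BASE_INDEX[b] for b in seq.upper()), dtype=np.int64,
                           count=len(seq))
    except KeyError as exc:
        raise ValueError(f"sequence contains unsupported base {exc.args[0]!r}") from exc


def log_odds_matrix(pfm: Pfm, pseudocount: float = 0.01,
                    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25)) -> np.ndarray:
    """Log2-odds scoring matrix, shape (5, L); the 5th row (N) scores 0."""
    probs = pfm.probabilities(pseudocount)
    q = np.asarray(background, dtype=float).reshape(4, 1)
    mat = np.zeros((5, probs.shape[1]))
    mat[:4] = np.log2(probs / q)
    return mat


def max_score(score_matrix: np.ndarray) -> float:
    """lm: the maximum log-odds score attainable over ACGT sequences."""
    return float(score_matrix[:4].max(axis=0).sum())


def _placement_scores(score_matrix: np.ndarray, idx: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Scores of every placement on the forward and reverse strands.

    The reverse-strand score at offset ``o`` is the forward score of the
    reverse-complemented window, computed by scoring against the
    reverse-complemented matrix.
    """
    L = score_matrix.shape[1]
    windows = np.lib.stride_tricks.sliding_window_view(idx, L)
    cols = np.arange(L)
    fwd = score_matrix[windows, cols].sum(axis=1)
    rc = score_matrix[_COMPLEMENT][:, ::-1]
    rev = rc[windows, cols].sum(axis=1)
    return fwd, rev


def _best_placement(fwd: np.ndarray, rev: np.ndarray,
                    offsets: np.ndarray) -> tuple[float, int, str]:
    """Max score over placements; ties broken by smallest offset, then '+'."""
    scores = np.concatenate([fwd[offsets], rev[offsets]])
    offs = np.concatenate([offsets, offsets])
    strand_rank = np.repeat([0, 1], len(offsets))
    k = np.lexsort((strand_rank, offs, -scores))[0]
    return float(scores[k]), int(offs[k]), "+-"[strand_rank[k]]


def score_window(pfm: Pfm, seq: str, config: MotifScanConfig = MotifScanConfig()
                 ) -> MotifScore | None:
    """Best log-odds score of ``seq`` against ``pfm`` over all offsets and
    both strands; ``None`` when the sequence is shorter than the motif."""
    if len(seq) < pfm.length:
        return None
    mat = log_odds_matrix(pfm, config.pseudocount, config.background)
    idx = seq_to_indices(seq)
    fwd, rev = _placement_scores(mat, idx)
    la, off, strand = _best_placement(fwd, rev, np.arange(len(fwd)))
    return MotifScore(la=la, lm=max_score(mat), offset=off, strand=strand)


# ---------------------------------------------------------------------------
# Empirical null distributions


@dataclass
class NullDistribution:
    """Motif-specific empirical score distribution.

    Enumeration mode holds the scores of all ``4^L`` sequences (exact
    p-values); sampling mode holds scores of ``n`` background draws and uses
    the add-one estimator so p-values never vanish.
    """

    motif_id: str
    sorted_scores: np.ndarray
    build_mode: str  # "enumeration" | "sampling"
    n: int

    def pvalue(self, score: float | np.ndarray) -> np.ndarray | float:
        """P(null score >= observed), vectorized."""
        pos = np.searchsorted(self.sorted_scores, score, side="left")
        exceed = self.n - pos
        if self.build_mode == "enumeration":
            p = np.maximum(exceed, 1) / self.n
        else:
            p = (exceed + 1) / (self.n + 1)
        return float(p) if np.isscalar(score) else p


def _enumerate_scores(mat: np.ndarray) -> np.ndarray:
    """Scores of all 4^L sequences via iterated outer sums over columns."""
    scores = np.zeros(1)
    for col in mat[:4].T:
        scores = (scores[:, None] + col[None, :]).ravel()
    return scores


def build_null(pfm: Pfm, mode: str = "auto", n_samples: int = 100_000,
               background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
               seed: int = 0, pseudocount: float = 0.01,
               enum_max_len: int = 10) -> NullDistribution:
    """Build the empirical score null for one motif.

    ``mode`` is ``enumeration`` (all 4^L length-L sequences), ``sampling``
    (``n_samples`` background draws) or ``auto`` (enumeration up to
    ``enum_max_len`` columns, sampling beyond).
    """
    L = pfm.length
    if mode == "auto":
        mode = "enumeration" if L <= enum_max_len else "sampling"
    mat = log_odds_matrix(pfm, pseudocount, background)
    if mode == "enumeration":
        if L > enum_max_len:
            raise ValueError(
                f"motif {pfm.motif_id}: enumeration of 4^{L} sequences exceeds "
                f"the configured cap (length {enum_max_len}); use sampling"
            )
        scores = _enumerate_scores(mat)
    elif mode == "sampling":
        rng = np.random.default_rng(seed)
        idx = rng.choice(4, size=(n_samples, L), p=np.asarray(background, float))
        scores = mat[idx, np.arange(L)].sum(axis=1)
    else:
        raise ValueError(f"unknown null mode {mode!r}")
    scores.sort()
    return NullDistribution(pfm.motif_id, scores, mode, len(scores))


# ---------------------------------------------------------------------------
# Allele substitution


def apply_variant(window_ref: str, variant: Variant, flank: int,
                  flank_left: int | None = None) -> tuple[str, tuple[int, int] | None]:
    """Splice the alternative allele into the reference window.

    ``window_ref`` must hold ``flank_left`` bases, the reference allele, and
    the right flank.  Returns the alternative window and, for insertions,
    the window-relative coordinate range of the inserted bases (used by the
    insertion classification rule); ``None`` otherwise.
    """
    if flank_left is None:
        flank_left = flank
    ref, alt = variant.ref.upper(), variant.alt.upper()
    center = window_ref[flank_left:flank_left + len(ref)].upper()
    if center != ref:
        raise ValueError(
            f"variant {variant.id}: window center {center!r} does not match "
            f"reference allele {ref!r}"
        )
    window_alt = window_ref[:flank_left] + alt + window_ref[flank_left + len(ref):]
    inserted: tuple[int, int] | None = None
    if variant.is_insertion:
        cp = 0
        while cp < len(ref) and cp < len(alt) and ref[cp] == alt[cp]:
            cp += 1
        inserted = (flank_left + cp, flank_left + len(alt))
    return window_alt, inserted


# ---------------------------------------------------------------------------
# Run-level ratio normalization


@dataclass
class RatioNormalization:
    """Run-level normalization of raw ``la/lm`` ratios.

    The divisor for a motif of length L is the mean of (a) the grand mean of
    raw ratios across all positive-scoring placements in the run and (b) the
    mean ratio among motifs of length L.  An empty run normalizes by 1.
    """

    global_mean: float = 1.0
    length_means: dict[int, float] = field(default_factory=dict)

    @classmethod
    def fit(cls, records: Iterable[tuple[int, float]]) -> "RatioNormalization":
        """Fit from (motif length, raw ratio) pairs of positive-scoring
        placements."""
        by_len: dict[int, list[float]] = {}
        all_ratios: list[float] = []
        for L, ratio in records:
            by_len.setdefault(L, []).append(ratio)
            all_ratios.append(ratio)
        if not all_ratios:
            return cls()
        return cls(
            global_mean=float(np.mean(all_ratios)),
            length_means={L: float(np.mean(v)) for L, v in by_len.items()},
        )

    def divisor(self, length: int) -> float:
        lm = self.length_means.get(length, self.global_mean)
        d = 0.5 * (self.global_mean + lm)
        return d if d > 0 else 1.0

    def normalize(self, ratio: float, length: int) -> float:
        return ratio / self.divisor(length)


# ---------------------------------------------------------------------------
# Retention and classification


def classify(ref_pass: bool, alt_pass: bool, la_ref: float | None,
             la_alt: float | None, is_insertion_start_inside: bool = False,
             match_change_cutoff: float = 0.10) -> tuple[str, str]:
    """Label a retained (variant, motif) result.

    Returns ``(label, direction)``.  A motif match starting inside the bases
    added by a small insertion is an addition in all cases.  Otherwise: a
    positive alternative score against a negative (or absent) reference
    score is an addition, the opposite a deletion; when both alleles score
    positive the result is a match when the relative score difference
    ``|la_ref - la_alt| / max(la_ref, la_alt)`` is below 10% and a change
    otherwise.
    """
    if not (ref_pass or alt_pass):
        raise ValueError("classify() requires at least one passing allele")
    ref_la = la_ref if la_ref is not None else -np.inf
    alt_la = la_alt if la_alt is not None else -np.inf
    if is_insertion_start_inside:
        return "addition", "increase"
    if alt_la > 0 >= ref_la:
        return "addition", "increase"
    if ref_la > 0 >= alt_la:
        return "deletion", "decrease"
    denom = max(ref_la, alt_la)
    rel = abs(ref_la - alt_la) / denom if denom > 0 else np.inf
    if rel < match_change_cutoff:
        return "match", "none"
    return "change", "increase" if alt_la > ref_la else "decrease"


def _best_overlapping(mat: np.ndarray, idx: np.ndarray, span: tuple[int, int],
                      lm: float) -> MotifScore | None:
    """Best placement whose footprint overlaps the window span [s, e)."""
    L = mat.shape[1]
    n_off = len(idx) - L + 1
    if n_off <= 0:
        return None
    s, e = span
    lo = max(0, s - L + 1)
    hi = min(n_off - 1, max(e - 1, s))  # offsets o with o <= e-1 and o+L > s
    if lo > hi:
        return None
    fwd, rev = _placement_scores(mat, idx)
    offsets = np.arange(lo, hi + 1)
    la, off, strand = _best_placement(fwd, rev, offsets)
    return MotifScore(la=la, lm=lm, offset=off, strand=strand)


def evaluate_motif(
    variant: Variant,
    pfm: Pfm,
    window_ref: str,
    null: NullDistribution,
    config: MotifScanConfig = MotifScanConfig(),
    normalizer: RatioNormalization | None = None,
    flank_left: int | None = None,
) -> MotifImpact | None:
    """Score both alleles of one variant against one motif and apply the
    retention criteria; returns ``None`` when no placement is retained."""
    if null is None:
        raise ValueError("evaluate_motif requires a built null distribution")
    if normalizer is None:
        normalizer = RatioNormalization()
    fl = config.flank if flank_left is None else flank_left
    window_alt, inserted = apply_variant(window_ref, variant, config.flank, fl)
    mat = log_odds_matrix(pfm, config.pseudocount, config.background)
    lm = max_score(mat)
    ref_span = (fl, fl + len(variant.ref))
    alt_span = (fl, fl + len(variant.alt))
    ref_score = _best_overlapping(mat, seq_to_indices(window_ref), ref_span, lm)
    alt_score = _best_overlapping(mat, seq_to_indices(window_alt), alt_span, lm)
    if ref_score is None and alt_score is None:
        return None
    for score in (ref_score, alt_score):
        if score is not None:
            score.pvalue = null.pvalue(score.la)
            score.norm_ratio = normalizer.normalize(score.ratio, pfm.length)
    floor = config.min_score(pfm.motif_kind)

    def _ok(s: MotifScore | None, crit: str) -> bool:
        if s is None:
            return False
        if crit == "score":
            return s.la >= floor
        if crit == "p":
            return s.pvalue < config.p_max
        return s.norm_ratio > config.ratio_min

    if not (_ok(ref_score, "score") or _ok(alt_score, "score")):
        return None
    if not (_ok(ref_score, "p") or _ok(alt_score, "p")):
        return None
    if not (_ok(ref_score, "ratio") or _ok(alt_score, "ratio")):
        return None

    def _passes(s: MotifScore | None) -> bool:
        return s is not None and _ok(s, "score") and _ok(s, "p") and _ok(s, "ratio")

    starts_inside = (
        inserted is not None
        and alt_score is not None
        and inserted[0] <= alt_score.offset < inserted[1]
    )
    label, direction = classify(
        _passes(ref_score) or _passes(alt_score),  # retention already OR-based
        _passes(alt_score),
        ref_score.la if ref_score is not None else None,
        alt_score.la if alt_score is not None else None,
        starts_inside,
        config.match_change_cutoff,
    )
    return MotifImpact(
        variant_id=variant.id,
        motif_id=pfm.motif_id,
        factor=pfm.factor,
        ref_score=ref_score,
        alt_score=alt_score,
        label=label,
        direction=direction,
    )


# ---------------------------------------------------------------------------
# Scan driver


def extract_window(genome: Mapping[str, str], variant: Variant, flank: int
                   ) -> tuple[str, int]:
    """Reference window around the allele span, clipped at chromosome edges.

    Returns ``(sequence, flank_left)`` where ``flank_left`` is the realized
    left-flank length (shorter than ``flank`` only near the 5' edge).
    """
    chrom = str(genome[variant.chrom])
    start = max(0, variant.pos - 1 - flank)
    end = min(len(chrom), variant.pos - 1 + len(variant.ref) + flank)
    return chrom[start:end], variant.pos - 1 - start


def build_nulls(pfms: Sequence[Pfm], config: MotifScanConfig
                ) -> dict[str, NullDistribution]:
    """One seeded null per motif; child seeds derive from the run seed and
    the motif's position in the input so runs are reproducible."""
    nulls = {}
    for i, pfm in enumerate(pfms):
        nulls[pfm.motif_id] = build_null(
            pfm, mode="auto", n_samples=config.null_samples,
            background=config.background, seed=np.random.default_rng(
                [config.seed, i]).integers(2**31),
            pseudocount=config.pseudocount, enum_max_len=config.enum_max_len,
        )
    return nulls


def scan_variants(
    genome: Mapping[str, str],
    variants: Sequence[Variant],
    pfms: Sequence[Pfm],
    config: MotifScanConfig = MotifScanConfig(),
    nulls: Mapping[str, NullDistribution] | None = None,
) -> list[MotifImpact]:
    """Full allele-aware scan of all variants against all motifs.

    Two passes: the first scores every (variant, motif) pair and collects
    positive-scoring raw ratios to fit the run-level ratio normalization;
    the second applies the retention criteria and classifies.  RBP motifs
    are evaluated only at UTR variants.
    """
    if nulls is None:
        nulls = build_nulls(pfms, config)
    pairs = []
    ratio_records: list[tuple[int, float]] = []
    for v in variants:
        window_ref, fl = extract_window(genome, v, config.flank)
        for pfm in pfms:
            if pfm.motif_kind == "rbp" and v.annotation not in ("utr3", "utr5"):
                continue
            mat = log_odds_matrix(pfm, config.pseudocount, config.background)
            lm = max_score(mat)
            window_alt, _ = apply_variant(window_ref, v, config.flank, fl)
            r = _best_overlapping(mat, seq_to_indices(window_ref),
                                  (fl, fl + len(v.ref)), lm)
            a = _best_overlapping(mat, seq_to_indices(window_alt),
                                  (fl, fl + len(v.alt)), lm)
            for s in (r, a):
                if s is not None and s.la > 0:
                    ratio_records.append((pfm.length, s.ratio))
            pairs.append((v, pfm, window_ref, fl))
    normalizer = RatioNormalization.fit(ratio_records)
    impacts = []
    for v, pfm, window_ref, fl in pairs:
        impact = evaluate_motif(v, pfm, window_ref, nulls[pfm.motif_id],
                                config, normalizer, fl)
        if impact is not None:
            impacts.append(impact)
    return impacts


def impacts_to_frame(impacts: Sequence[MotifImpact]) -> pd.DataFrame:
    """Tabular view of retained impacts (one row per variant-motif result)."""
    rows = []
    for im in impacts:
        r, a = im.ref_score, im.alt_score
        rows.append(
            {
                "variant_id": im.variant_id,
                "motif_id": im.motif_id,
                "factor": im.factor,
                "strand": (a or r).strand,
                "offset": (a or r).offset,
                "la_ref": r.la if r else np.nan,
                "la_alt": a.la if a else np.nan,
                "lm": (a or r).lm,
                "p_ref": r.pvalue if r else np.nan,
                "p_alt": a.pvalue if a else np.nan,
                "norm_ratio_ref": r.norm_ratio if r else np.nan,
                "norm_ratio_alt": a.norm_ratio if a else np.nan,
                "label": im.label,
                "direction": im.direction,
            }
        )
    cols = ["variant_id", "motif_id", "factor", "strand", "offset", "la_ref",
            "la_alt", "lm", "p_ref", "p_alt", "norm_ratio_ref",
            "norm_ratio_alt", "label", "direction"]
    return pd.DataFrame(rows, columns=cols)
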