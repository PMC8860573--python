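"""Regulatory annotation of variants from ChIP-seq peaks and consensus
regulatory-region markers.

A ChIP-seq experiment supports a variant only when the variant's genomic
position falls inside a peak in *every* replicate of that experiment.
Support counts are aggregated per (variant, factor, cell line/tissue) and,
because narrow- and broad-peak experiments are distinct assays, per peak
kind.  Marker annotation is plain interval overlap with promoter /
enhancer / active-enhancer consensus tracks.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .datamodel import MARKER_CLASSES, PeakInterval, Variant

__all__ = [
    "PeakSupport",
    "MarkerAnnotation",
    "annotate_peaks",
    "annotate_markers",
    "summarize_annotation",
]


@dataclass(frozen=True)
class PeakSupport:
    """Number of experiments of one factor in one cell line/tissue whose
    peaks (in all replicates) cover the variant position."""

    variant_id: str
    factor: str
    cell_or_tissue: str
    peak_kind: str
    n_supporting_experiments: int


@dataclass(frozen=True)
class MarkerAnnotation:
    variant_id: str
    marker: str  # promoter | enhancer | active_enhancer
    tissue: str

    def __post_init__(self) -> None:
        if self.marker not in MARKER_CLASSES:
            raise ValueError(f"unknown marker label {self.marker!r}")


def _replicate_trees(peaks: Iterable[PeakInterval]):
    """Group peaks by experiment, then replicate, as per-chromosome trees."""
    experiments: dict[str, dict] = {}
    for p in peaks:
        exp = experiments.setdefault(
            p.experiment_id,
            {"factor": p.factor, "cell_or_tissue": p.cell_or_tissue,
             "peak_kind": p.peak_kind, "replicates": defaultdict(dict)},
        )
        trees = exp["replicates"][p.replicate_id]
        trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end)
    return experiments


def annotate_peaks(
    variants: Sequence[Variant],
    peaks: Sequence[PeakInterval],
    peak_kinds: tuple[str, ...] = ("narrow", "broad"),
) -> list[PeakSupport]:
    """Count, per (variant, factor, cell/tissue, peak kind), the experiments
    whose peaks cover the variant in all replicates.

    ``peak_kinds`` restricts the assay types considered; entries with a
    count of zero are omitted.
    """
    experiments = _replicate_trees(peaks)
    for exp_id, exp in experiments.items():
        if not exp["replicates"]:
            raise ValueError(f"experiment {exp_id} has no replicates")
    counts: dict[tuple[str, str, str, str], int] = defaultdict(int)
    for v in variants:
        point = v.pos - 1  # 1-based variant position -> 0-based coordinate
        for exp in experiments.values():
            if exp["peak_kind"] not in peak_kinds:
                continue
            supported = all(
                chrom_trees.get(v.chrom) is not None
                and bool(chrom_trees[v.chrom][point])
                for chrom_trees in exp["replicates"].values()
            )
            if supported:
                key = (v.id, exp["factor"], exp["cell_or_tissue"], exp["peak_kind"])
                counts[key] += 1
    return [
        PeakSupport(vid, factor, cot, kind, n)
        for (vid, factor, cot, kind), n in counts.items()
    ]


MarkerTracks = Mapping[str, Sequence[tuple[str, int, int, str]]]


def annotate_markers(
    variants: Sequence[Variant], marker_tracks: MarkerTracks
) -> list[MarkerAnnotation]:
    """Overlap variants with marker BED tracks.

    ``marker_tracks`` maps tissue -> intervals ``(chrom, start, end, marker)``
    with marker in {promoter, enhancer, active_enhancer}.  Returns one record
    per overlapping (variant, marker, tissue).
    """
    trees: dict[str, dict[str, IntervalTree]] = {}
    for tissue, intervals in marker_tracks.items():
        per_chrom = trees.setdefault(tissue, {})
        for chrom, start, end, marker in intervals:
            if marker not in MARKER_CLASSES:
                raise ValueError(f"unknown marker label {marker!r} in tissue {tissue}")
            per_chrom.setdefault(chrom, IntervalTree()).addi(start, end, marker)
    out = []
    for v in variants:
        point = v.pos - 1
        for tissue, per_chrom in trees.items():
            tree = per_chrom.get(v.chrom)
            if tree is None:
                continue
            markers = sorted({iv.data for iv in tree[point]})
            for marker in markers:
                out.append(MarkerAnnotation(v.id, marker, tissue))
    return out


def summarize_annotation(peak_supports: Sequence[PeakSupport]) -> pd.DataFrame:
    """Per-tissue distribution of supporting peak counts per variant.

    For each cell line/tissue, the per-variant totals of supporting
    experiments are summarized by median and quartiles (linear-interpolation
    quantiles).  Empty input yields an empty frame.
    """
    if not peak_supports:
        return pd.DataFrame(
            columns=["cell_or_tissue", "n_variants", "q25", "median", "q75"]
        )
    df = pd.DataFrame(
        {
            "variant_id": [s.variant_id for s in peak_supports],
            "cell_or_tissue": [s.cell_or_tissue for s in peak_supports],
            "n": [s.n_supporting_experiments for s in peak_supports],
        }
    )
    per_variant = (
        df.groupby(["cell_or_tissue", "variant_id"])["n"].sum().reset_index()
    )
    rows = []
    for tissue, grp in per_variant.groupby("cell_or_tissue"):
        q25, med, q75 = np.quantile(grp["n"].to_numpy(float), [0.25, 0.5, 0.75])
        rows.append((tissue, len(grp), q25, med, q75))
    return pd.DataFrame(rows, columns=["cell_or_tissue", "n_variants", "q25",
                                       "median", "q75"])
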