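"""Self-contained synthetic fixtures with known ground truth.

The generator emulates the statistical structure the framework assumes:

* a random background genome with binding-motif consensus sequences
  embedded at chosen variant loci; a configured fraction of variants are
  *disruptors* whose alternative allele breaks the consensus at the motif
  center (expected impact: change/deletion with decreasing score), the
  rest fall in motif-free background (expected: no retained impact);
* genotypes under Hardy-Weinberg equilibrium with haplotype-block LD
  induced by haplotype copying (each variant's haplotype copies its left
  neighbour within the block with probability ``ld_copy_prob``, else
  redraws from the block allele frequency);
* normalized expression with planted genotype effects of stated size on
  chosen (variant, gene, model) triples, plus age/sex/ancestry-PC
  covariate effects and Gaussian noise;
* planted variant<->TF 2-cycles: a variant that both disrupts a factor's
  motif and associates with that factor's transcript.

Planted motifs are long (12-14 columns) and highly informative
(near-invariant columns), so that planted disruptions are unambiguous and
chance background hits passing the retention thresholds are rare; this is
an identifiability choice, not a statement about typical motif information
content.  Every output is a pure function of the configuration (which
includes the mandatory seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    CovariateTable,
    ExpressionMatrix,
    GenotypeMatrix,
    Pfm,
    Variant,
    write_matrix_tsv,
    write_pfms,
    write_variants_vcf,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "Fixture",
    "simulate_genome_and_motifs",
    "simulate_genotypes",
    "simulate_expression",
    "simulate_2cycles",
    "write_fixture",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of the synthetic fixture.

    Desk-scale defaults: 500 samples, 200 variants, 300 genes, 20 motifs.
    ``disruptor_fraction`` of variants get a planted motif-breaking allele.
    ``effect_size`` is the planted genotype coefficient on the normalized
    expression scale and ``noise_sd`` the residual standard deviation.
    """

    seed: int
    n_samples: int = 500
    n_variants: int = 200
    n_genes: int = 300
    n_factors: int = 20
    variant_spacing: int = 150
    genome_margin: int = 100
    motif_length_range: tuple[int, int] = (12, 14)
    motif_consensus_count: float = 994.0
    motif_other_count: float = 2.0
    disruptor_fraction: float = 0.3
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 5
    ld_copy_prob: float = 0.9
    n_planted_assoc: int = 10
    n_2cycles: int = 3
    effect_size: float = 1.0
    noise_sd: float = 0.5
    marker_background_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.n_variants < 1 or self.n_samples < 1 or self.n_genes < 1:
            raise ValueError("all counts must be positive")
        if not 0 <= self.disruptor_fraction <= 1:
            raise ValueError("disruptor_fraction must be in [0, 1]")


@dataclass
class GroundTruth:
    """Planted facts sufficient to score every downstream module."""

    planted_impacts: list[tuple[str, str, str, str]] = field(default_factory=list)
    # (variant_id, motif_id, expected label, expected direction)
    neutral_variants: list[str] = field(default_factory=list)
    planted_associations: list[tuple[str, str, str, float]] = field(default_factory=list)
    # (variant_id, gene_id, model, beta1)
    planted_2cycles: list[tuple[str, str]] = field(default_factory=list)
    # (variant_id, factor gene)
    marker_variants: list[str] = field(default_factory=list)
    maf: dict[str, float] = field(default_factory=dict)
    ld_blocks: list[tuple[str, ...]] = field(default_factory=list)


@dataclass
class Fixture:
    config: SimulationConfig
    genome: dict[str, str]
    pfms: list[Pfm]
    variants: list[Variant]
    truth: GroundTruth
    genotypes: GenotypeMatrix | None = None
    expression: ExpressionMatrix | None = None
    covariates: CovariateTable | None = None


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stage])


def _random_pfm(rng: np.random.Generator, motif_id: str, factor: str,
                config: SimulationConfig) -> Pfm:
    length = int(rng.integers(config.motif_length_range[0],
                              config.motif_length_range[1] + 1))
    consensus = rng.integers(0, 4, size=length)
    counts = np.full((4, length), config.motif_other_count)
    counts[consensus, np.arange(length)] = config.motif_consensus_count
    return Pfm(motif_id=motif_id, factor=factor, counts=counts, source="synthetic")


def simulate_genome_and_motifs(config: SimulationConfig
                               ) -> tuple[dict[str, str], list[Pfm],
                                          list[Variant], GroundTruth]:
    """Background genome with embedded motif occurrences and the variant
    list: disruptors hit a planted consensus, neutral variants hit plain
    background."""
    rng = _rng(config, 0)
    chrom = "chr1"
    genome_len = 2 * config.genome_margin + config.n_variants * config.variant_spacing
    max_len = config.motif_length_range[1]
    if max_len > config.variant_spacing:
        raise ValueError("motif longer than the per-variant genome window")
    seq = rng.integers(0, 4, size=genome_len)
    factors = [f"TF{i + 1:02d}" for i in range(config.n_factors)]
    pfms = [_random_pfm(rng, f"M{i + 1:03d}", factors[i], config)
            for i in range(config.n_factors)]
    n_disrupt = int(round(config.disruptor_fraction * config.n_variants))
    disrupt_idx = set(rng.choice(config.n_variants, size=n_disrupt,
                                 replace=False).tolist())
    variants: list[Variant] = []
    truth = GroundTruth()
    for i in range(config.n_variants):
        pos = config.genome_margin + i * config.variant_spacing + 1  # 1-based
        vid = f"rs{i + 1:04d}"
        if i in disrupt_idx:
            pfm = pfms[i % config.n_factors]
            consensus_idx = pfm.counts.argmax(axis=0)
            center = pfm.length // 2
            start0 = pos - 1 - center
            seq[start0:start0 + pfm.length] = consensus_idx
            ref_code = int(consensus_idx[center])
            alt_code = (ref_code + 1) % 4  # any non-consensus base: low count
            variants.append(Variant(id=vid, chrom=chrom, pos=pos,
                                    ref=str(_BASES[ref_code]),
                                    alt=str(_BASES[alt_code])))
            truth.planted_impacts.append((vid, pfm.motif_id, "change", "decrease"))
        else:
            ref_code = int(seq[pos - 1])
            alt_code = int((ref_code + 1 + rng.integers(3)) % 4)
            variants.append(Variant(id=vid, chrom=chrom, pos=pos,
                                    ref=str(_BASES[ref_code]),
                                    alt=str(_BASES[alt_code])))
            truth.neutral_variants.append(vid)
    genome = {chrom: "".join(_BASES[seq])}
    return genome, pfms, variants, truth


def simulate_genotypes(config: SimulationConfig, variants: Sequence[Variant],
                       truth: GroundTruth) -> GenotypeMatrix:
    """HWE genotypes with haplotype-block LD by copying with redraw.

    Variants are grouped into consecutive blocks of ``ld_block_size``; all
    variants of a block share an allele frequency drawn from ``maf_range``.
    Within a block each haplotype column copies its left neighbour with
    probability ``ld_copy_prob`` (adjacent dosage r-squared approximately
    the square of that), otherwise redraws.  Realized (folded) MAFs and the
    block structure are recorded in the truth object.
    """
    rng = _rng(config, 1)
    n_hap = 2 * config.n_samples
    m = len(variants)
    haps = np.zeros((n_hap, m), dtype=np.int8)
    block_starts = range(0, m, config.ld_block_size)
    for start in block_starts:
        stop = min(start + config.ld_block_size, m)
        p = rng.uniform(*config.maf_range)
        haps[:, start] = rng.random(n_hap) < p
        for j in range(start + 1, stop):
            copy = rng.random(n_hap) < config.ld_copy_prob
            fresh = rng.random(n_hap) < p
            haps[:, j] = np.where(copy, haps[:, j - 1], fresh)
        truth.ld_blocks.append(tuple(v.id for v in variants[start:stop]))
    codes = (haps[: config.n_samples] + haps[config.n_samples:]).astype(float)
    sample_ids = [f"S{i + 1:04d}" for i in range(config.n_samples)]
    for j, v in enumerate(variants):
        af = codes[:, j].mean() / 2.0
        truth.maf[v.id] = round(min(af, 1.0 - af), 6)
    return GenotypeMatrix(sample_ids, [v.id for v in variants], codes)


def _encode(codes: np.ndarray, model: str) -> np.ndarray:
    if model == "additive":
        return codes
    if model == "dominant":
        return (codes >= 1).astype(float)
    return (codes == 2).astype(float)


def _class_counts_ok(codes: np.ndarray, model: str, min_n: int = 3) -> bool:
    if model == "additive":
        groups = [codes == 0, codes == 1, codes == 2]
    elif model == "dominant":
        groups = [codes == 0, codes >= 1]
    else:
        groups = [codes <= 1, codes == 2]
    return all(g.sum() >= min_n for g in groups)


def simulate_expression(
    config: SimulationConfig,
    genotypes: GenotypeMatrix,
    truth: GroundTruth,
    gene_ids: Sequence[str] | None = None,
    planted: Sequence[tuple[str, str, str]] | None = None,
) -> tuple[ExpressionMatrix, CovariateTable]:
    """Expression with covariate effects, noise and planted genotype
    effects.

    ``planted`` lists (variant_id, gene_id, model) triples to receive an
    ``effect_size`` genotype coefficient; when omitted,
    ``n_planted_assoc`` triples are drawn at random among variants whose
    realized genotype classes satisfy the per-class minimum (redrawing
    with a warning, bounded retries, when a drawn variant is ineligible).
    Covariates: age ~ Uniform(20, 80), sex ~ Bernoulli(0.5), PCs ~ N(0,1);
    each gene carries small random covariate coefficients.
    """
    rng = _rng(config, 2)
    n = config.n_samples
    if gene_ids is None:
        gene_ids = [f"G{i + 1:03d}" for i in range(config.n_genes)]
    gene_ids = list(gene_ids)
    age = rng.uniform(20, 80, size=n)
    sex = rng.integers(0, 2, size=n).astype(float)
    pcs = rng.normal(0, 1, size=(n, 3))
    cov = pd.DataFrame(
        {"age": age, "sex": sex, "pc1": pcs[:, 0], "pc2": pcs[:, 1],
         "pc3": pcs[:, 2]},
        index=[f"S{i + 1:04d}" for i in range(n)],
    )
    cov.index.name = "sample_id"
    n_genes = len(gene_ids)
    baseline = rng.normal(8.0, 1.0, size=n_genes)
    b_age = rng.normal(0.0, 0.005, size=n_genes)
    b_sex = rng.normal(0.0, 0.2, size=n_genes)
    b_pc = rng.normal(0.0, 0.15, size=(3, n_genes))
    E = (baseline[None, :] + np.outer(age - 50.0, b_age) + np.outer(sex, b_sex)
         + pcs @ b_pc + rng.normal(0, config.noise_sd, size=(n, n_genes)))
    models = ("additive", "dominant", "recessive")
    if planted is None:
        planted = []
        genes_avail = [g for g in gene_ids]
        rng.shuffle(genes_avail)
        tries = 0
        vi = 0
        order = rng.permutation(len(genotypes.variant_ids))
        while len(planted) < config.n_planted_assoc and tries < 10 * config.n_planted_assoc:
            tries += 1
            j = order[vi % len(order)]
            vi += 1
            vid = genotypes.variant_ids[j]
            model = models[len(planted) % 3]
            if not _class_counts_ok(genotypes.codes[:, j], model):
                warnings.warn(
                    f"planted variant {vid} ineligible under {model}; redrawing",
                    stacklevel=2,
                )
                continue
            planted.append((vid, genes_avail[len(planted)], model))
    for vid, gene, model in planted:
        j = genotypes.variant_ids.index(vid)
        gi = gene_ids.index(gene)
        g_enc = _encode(genotypes.codes[:, j], model)
        E[:, gi] += config.effect_size * g_enc
        truth.planted_associations.append((vid, gene, model, config.effect_size))
    expr = ExpressionMatrix(list(genotypes.sample_ids), gene_ids, E)
    return expr, CovariateTable(cov)


def simulate_2cycles(config: SimulationConfig) -> Fixture:
    """Combined fixture with planted variant<->TF 2-cycles.

    Factor gene symbols are included among the expression genes.  For each
    planted cycle a disruptor variant of factor F also receives a planted
    additive association with F's transcript, so the variant-gene network
    holds both the variant->gene association edge and the gene->variant
    binding edge.  The cycle variants are recorded as marker-annotated
    (enhancer) for the 2-cycle enrichment analysis, on top of a sparse
    random marker background.
    """
    genome, pfms, variants, truth = simulate_genome_and_motifs(config)
    genotypes = simulate_genotypes(config, variants, truth)
    rng = _rng(config, 3)
    factor_of_motif = {p.motif_id: p.factor for p in pfms}
    # candidate cycle variants: disruptors eligible under the additive model
    candidates = []
    for vid, motif_id, _, _ in truth.planted_impacts:
        j = genotypes.variant_ids.index(vid)
        if _class_counts_ok(genotypes.codes[:, j], "additive"):
            candidates.append((vid, factor_of_motif[motif_id]))
    if len(candidates) < config.n_2cycles:
        raise ValueError("not enough eligible disruptor variants for the "
                         "requested number of 2-cycles")
    pick = rng.choice(len(candidates), size=config.n_2cycles, replace=False)
    cycle_planted = [candidates[i] for i in sorted(pick)]
    factors = [p.factor for p in pfms]
    filler = [f"G{i + 1:03d}" for i in range(config.n_genes - len(factors))]
    gene_ids = factors + filler
    planted = [(vid, factor, "additive") for vid, factor in cycle_planted]
    # additional background associations on filler genes
    extra_n = max(0, config.n_planted_assoc - len(planted))
    models = ("additive", "dominant", "recessive")
    order = rng.permutation(len(genotypes.variant_ids))
    gi = 0
    for j in order:
        if len(planted) - len(cycle_planted) >= extra_n:
            break
        vid = genotypes.variant_ids[j]
        model = models[len(planted) % 3]
        if vid in {v for v, _ in cycle_planted}:
            continue
        if not _class_counts_ok(genotypes.codes[:, j], model):
            continue
        planted.append((vid, filler[gi], model))
        gi += 1
    expression, covariates = simulate_expression(
        config, genotypes, truth, gene_ids=gene_ids, planted=planted
    )
    truth.planted_2cycles = [(vid, factor) for vid, factor in cycle_planted]
    marker = {vid for vid, _ in cycle_planted}
    for v in variants:
        if v.id not in marker and rng.random() < config.marker_background_fraction:
            marker.add(v.id)
    truth.marker_variants = sorted(marker)
    variants = [
        Variant(id=v.id, chrom=v.chrom, pos=v.pos, ref=v.ref, alt=v.alt,
                maf=truth.maf[v.id], annotation=v.annotation)
        for v in variants
    ]
    return Fixture(config=config, genome=genome, pfms=pfms, variants=variants,
                   truth=truth, genotypes=genotypes, expression=expression,
                   covariates=covariates)


def write_fixture(fixture: Fixture, outdir: str | Path) -> None:
    """Write the fixture as FASTA, VCF, PFM and TSV files plus truth tables.

    Output is deterministic: the same configuration writes byte-identical
    files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "genome.fa", "w") as fh:
        for chrom, seq in fixture.genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")
    write_variants_vcf(fixture.variants, outdir / "variants.vcf")
    write_pfms(fixture.pfms, outdir / "motifs.jaspar")
    if fixture.genotypes is not None:
        write_matrix_tsv(outdir / "genotypes.tsv", fixture.genotypes.sample_ids,
                         fixture.genotypes.variant_ids, fixture.genotypes.codes)
    if fixture.expression is not None:
        write_matrix_tsv(outdir / "expression.tsv", fixture.expression.sample_ids,
                         fixture.expression.gene_ids, fixture.expression.values)
    if fixture.covariates is not None:
        fixture.covariates.table.to_csv(outdir / "covariates.tsv", sep="\t",
                                        float_format="%.6g")
    t = fixture.truth
    pd.DataFrame(t.planted_impacts,
                 columns=["variant_id", "motif_id", "label", "direction"]
                 ).to_csv(outdir / "truth_impacts.tsv", sep="\t", index=False)
    pd.DataFrame(t.planted_associations,
                 columns=["variant_id", "gene_id", "model", "beta1"]
                 ).to_csv(outdir / "truth_associations.tsv", sep="\t", index=False)
    pd.DataFrame(t.planted_2cycles, columns=["variant_id", "factor"]
                 ).to_csv(outdir / "truth_2cycles.tsv", sep="\t", index=False)
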