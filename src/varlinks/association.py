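"""Association of variant genotypes with transcript levels.

For each (variant, gene, model) triple an ordinary least-squares fit of

    E ~ b0 + b1*G + b2*age + b3*sex + b4*PC1 + b5*PC2 + b6*PC3

is performed, where G is the model-specific genotype encoding:

* additive  — allele dosage 0/1/2 with classes {0}, {1}, {2};
* dominant  — 0 vs 1 with heterozygous pooled with alternative homozygous;
* recessive — 0 vs 1 with heterozygous pooled with reference homozygous.

A variant is tested only when every genotype class of the model holds at
least ``min_class_n`` samples (default 3).  The association p-value is a
two-tailed t-test on the genotype coefficient b1 against b1 = 0.  For each
(variant, model), p-values are Benjamini-Hochberg corrected across all
tested genes; associations with adjusted p below ``alpha_adj`` (default
0.005) are retained.

Missing genotypes and missing covariates drop the affected sample from
that test only.  Constant covariate columns (for example single-sex
cohorts) are dropped from the design with a warning, and the residual
degrees of freedom adjust accordingly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datamodel import CovariateTable, ExpressionMatrix, GenotypeMatrix

__all__ = [
    "MODELS",
    "AssociationModelSpec",
    "AssociationResult",
    "encode_genotype",
    "test_association",
    "bh_adjust",
    "run_association_scan",
    "results_to_frame",
]

MODELS = ("additive", "dominant", "recessive")


@dataclass(frozen=True)
class AssociationModelSpec:
    model: str = "additive"
    min_class_n: int = 3
    alpha_adj: float = 0.005

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown association model {self.model!r}")
        if self.min_class_n < 1:
            raise ValueError("min_class_n must be >= 1")
        if not 0 < self.alpha_adj < 1:
            raise ValueError("alpha_adj must be in (0, 1)")


@dataclass
class AssociationResult:
    variant_id: str
    gene_id: str
    model: str
    beta1: float
    se: float
    p: float
    p_adj: float = np.nan
    n_used: int = 0
    cis_trans: str = "unknown"

    @property
    def direction(self) -> str:
        return "increase" if self.beta1 > 0 else "decrease"


def encode_genotype(codes: np.ndarray, model: str
                    ) -> tuple[np.ndarray, dict[int, int]]:
    """Encode allele dosages under one genetic model.

    Returns the design vector (NaN preserved for missing genotypes) and the
    per-class sample counts keyed by encoded value, used for the
    eligibility rule.
    """
    codes = np.asarray(codes, dtype=float)
    if model == "additive":
        enc = codes.copy()
        classes = {k: int(np.sum(codes == k)) for k in (0, 1, 2)}
    elif model == "dominant":
        enc = np.where(np.isnan(codes), np.nan, (codes >= 1).astype(float))
        classes = {0: int(np.sum(codes == 0)), 1: int(np.sum(codes >= 1))}
    elif model == "recessive":
        enc = np.where(np.isnan(codes), np.nan, (codes == 2).astype(float))
        classes = {0: int(np.sum((codes == 0) | (codes == 1))),
                   1: int(np.sum(codes == 2))}
    else:
        raise ValueError(f"unknown association model {model!r}")
    return enc, classes


def _ols_beta1(y: np.ndarray, X: np.ndarray) -> tuple[float, float, float, int]:
    """OLS fit returning (beta1, se1, p, df); column 1 of X is the genotype."""
    n, k = X.shape
    keep = [0, 1]
    for j in range(2, k):
        if np.ptp(X[:, j]) > 0:
            keep.append(j)
        else:
            warnings.warn(f"dropping constant design column {j}", stacklevel=2)
    X = X[:, keep]
    k = X.shape[1]
    df = n - k
    if df <= 0:
        raise ValueError("not enough samples for the design")
    xtx_inv = np.linalg.pinv(X.T @ X)
    beta = xtx_inv @ (X.T @ y)
    resid = y - X @ beta
    sigma2 = float(resid @ resid) / df
    se1 = float(np.sqrt(sigma2 * xtx_inv[1, 1]))
    b1 = float(beta[1])
    t = b1 / se1 if se1 > 0 else np.inf
    p = 2.0 * stats.t.sf(abs(t), df)
    return b1, se1, float(p), df


def test_association(
    expr: np.ndarray,
    codes: np.ndarray,
    covariates: np.ndarray,
    spec: AssociationModelSpec = AssociationModelSpec(),
    variant_id: str = "",
    gene_id: str = "",
) -> AssociationResult | None:
    """Test one (variant, gene) pair under one model; ``None`` when skipped.

    ``covariates`` is the (n, 5) block [age, sex, pc1, pc2, pc3] aligned
    with ``expr`` and ``codes``.  Samples with missing genotype, expression
    or covariates are excluded; the per-class minimum is then applied.
    """
    expr = np.asarray(expr, float)
    covariates = np.asarray(covariates, float)
    enc, _ = encode_genotype(codes, spec.model)
    mask = ~(np.isnan(enc) | np.isnan(expr) | np.isnan(covariates).any(axis=1))
    enc, y, cov = enc[mask], expr[mask], covariates[mask]
    _, classes = encode_genotype(np.asarray(codes, float)[mask], spec.model)
    if any(n < spec.min_class_n for n in classes.values()):
        return None
    X = np.column_stack([np.ones(len(y)), enc, cov])
    b1, se1, p, _ = _ols_beta1(y, X)
    return AssociationResult(
        variant_id=variant_id, gene_id=gene_id, model=spec.model,
        beta1=b1, se=se1, p=p, n_used=int(mask.sum()),
    )


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_association_scan(
    genotypes: GenotypeMatrix,
    expression: ExpressionMatrix,
    covariates: CovariateTable,
    models: Sequence[str] = MODELS,
    spec: AssociationModelSpec = AssociationModelSpec(),
    keep_all: bool = False,
) -> list[AssociationResult]:
    """Scan every (variant, gene, model) triple over the shared samples.

    For each eligible (variant, model) the OLS fit is vectorized across all
    genes (the design is fixed; only the response changes).  BH adjustment
    is applied per (variant, model) across the tested genes, and results
    with adjusted p < ``alpha_adj`` are retained unless ``keep_all``.
    Use :func:`label_cis_trans` to add cis/trans labels afterwards.
    """
    shared = [s for s in genotypes.sample_ids if s in set(expression.sample_ids)
              and s in set(covariates.sample_ids)]
    if not shared:
        raise ValueError("no shared samples between genotype, expression "
                         "and covariate tables")
    g_idx = [genotypes.sample_ids.index(s) for s in shared]
    e_idx = [expression.sample_ids.index(s) for s in shared]
    G = genotypes.codes[g_idx, :]
    E = expression.values[e_idx, :]
    C = covariates.design_columns(shared)
    cov_ok = ~np.isnan(C).any(axis=1)
    results: list[AssociationResult] = []
    for j, vid in enumerate(genotypes.variant_ids):
        codes = G[:, j]
        for model in models:
            mspec = AssociationModelSpec(model, spec.min_class_n, spec.alpha_adj)
            enc_all, _ = encode_genotype(codes, model)
            mask = ~np.isnan(enc_all) & cov_ok & ~np.isnan(E).any(axis=1)
            _, classes = encode_genotype(codes[mask], model)
            if any(n < mspec.min_class_n for n in classes.values()):
                continue
            y_block = E[mask]
            X = np.column_stack([np.ones(mask.sum()), enc_all[mask], C[mask]])
            keep = [0, 1] + [2 + k for k in range(C.shape[1])
                             if np.ptp(X[:, 2 + k]) > 0]
            X = X[:, keep]
            n, k = X.shape
            df = n - k
            if df <= 0:
                continue
            xtx_inv = np.linalg.pinv(X.T @ X)
            betas = xtx_inv @ (X.T @ y_block)            # (k, n_genes)
            resid = y_block - X @ betas
            sigma2 = (resid * resid).sum(axis=0) / df
            se1 = np.sqrt(sigma2 * xtx_inv[1, 1])
            b1 = betas[1]
            with np.errstate(divide="ignore", invalid="ignore"):
                tvals = np.where(se1 > 0, b1 / se1, np.inf)
            pvals = 2.0 * stats.t.sf(np.abs(tvals), df)
            padj = bh_adjust(pvals)
            for gi, gene in enumerate(expression.gene_ids):
                if not keep_all and padj[gi] >= mspec.alpha_adj:
                    continue
                results.append(
                    AssociationResult(
                        variant_id=vid, gene_id=gene, model=model,
                        beta1=float(b1[gi]), se=float(se1[gi]),
                        p=float(pvals[gi]), p_adj=float(padj[gi]), n_used=n,
                    )
                )
    return results


def label_cis_trans(
    results: Sequence[AssociationResult],
    variant_loci: dict[str, tuple[str, int]],
    gene_loci: dict[str, tuple[str, int, int]],
    cis_window: int = 1_000_000,
) -> None:
    """Label results cis when the variant lies within ``cis_window`` of the
    gene span (same chromosome); trans otherwise; unknown when loci are
    missing.  Mutates results in place."""
    for r in results:
        v = variant_loci.get(r.variant_id)
        g = gene_loci.get(r.gene_id)
        if v is None or g is None:
            r.cis_trans = "unknown"
            continue
        vchrom, vpos = v
        gchrom, gstart, gend = g
        if vchrom == gchrom and gstart - cis_window <= vpos - 1 < gend + cis_window:
            r.cis_trans = "cis"
        else:
            r.cis_trans = "trans"


def results_to_frame(results: Sequence[AssociationResult]) -> pd.DataFrame:
    cols = ["variant_id", "gene_id", "model", "beta1", "se", "p", "p_adj",
            "direction", "n_used", "cis_trans"]
    rows = [
        (r.variant_id, r.gene_id, r.model, r.beta1, r.se, r.p, r.p_adj,
         r.direction, r.n_used, r.cis_trans)
        for r in results
    ]
    return pd.DataFrame(rows, columns=cols)
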