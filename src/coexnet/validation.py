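"""Candidate-gene validation against a quantitative trait.

Downstream statistics for a two-group expression fixture: per-group trait
summaries, fold changes, covariate-adjusted regression of the trait on
expression (trait = mu + expression + age [+ housekeeping] + residual),
expression-trait correlation, and PCA of the candidate-gene expression
matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats


@dataclass
class ValidationFixture:
    """One animal/sample of the two-group validation experiment."""

    animal_id: str
    group: str
    age_months: float
    imf_percent: float
    expression: dict[str, float] = field(default_factory=dict)
    housekeeping: float = 1.0

    def __post_init__(self) -> None:
        if self.group not in ("low", "high"):
            raise ValueError(f"group must be 'low' or 'high', got {self.group!r}")
        if self.imf_percent < 0:
            raise ValueError("imf_percent must be non-negative")
        if self.age_months <= 0:
            raise ValueError("age_months must be positive")


@dataclass
class GroupStats:
    group: str
    n: int
    mean: float
    sd: float
    sem: float


@dataclass
class RegressionReport:
    """OLS fit of trait on expression plus covariates for one gene."""

    gene_id: str
    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    expression_t: float
    expression_p: float
    residual_df: int


@dataclass
class PCAReport:
    gene_ids: list[str]
    sample_ids: list[str]
    loadings: np.ndarray  # genes x components
    scores: np.ndarray  # samples x components
    variance_ratio: np.ndarray
    cumulative_variance: np.ndarray
    pc2_relationship: dict[str, str]


def _groups(fixture: list[ValidationFixture]) -> dict[str, list[ValidationFixture]]:
    out: dict[str, list[ValidationFixture]] = {}
    for f in fixture:
        out.setdefault(f.group, []).append(f)
    return out


def group_stats(fixture: list[ValidationFixture]) -> dict[str, GroupStats]:
    """Per-group n, mean, sample SD (n-1 denominator), and SEM of the trait."""
    stats_out = {}
    for group, members in _groups(fixture).items():
        if len(members) < 2:
            raise ValueError(f"group {group!r} has n={len(members)} < 2; SEM undefined")
        vals = np.array([f.imf_percent for f in members])
        sd = float(vals.std(ddof=1))
        stats_out[group] = GroupStats(
            group=group,
            n=len(members),
            mean=float(vals.mean()),
            sd=sd,
            sem=sd / math.sqrt(len(members)),
        )
    return stats_out


def fold_change(fixture: list[ValidationFixture], gene: str) -> float:
    """Ratio of high-group to low-group mean normalized expression."""
    groups = _groups(fixture)
    for needed in ("low", "high"):
        if needed not in groups:
            raise ValueError(f"fixture has no {needed!r} group")
    means = {
        g: float(np.mean([f.expression[gene] for f in members]))
        for g, members in groups.items()
    }
    if means["low"] <= 0:
        raise ValueError(
            f"low-group mean expression {means['low']} <= 0; fold change undefined"
        )
    return means["high"] / means["low"]


def _collinear_columns(design: np.ndarray, names: list[str]) -> list[str]:
    offenders = []
    for j in range(1, design.shape[1]):
        rank_with = np.linalg.matrix_rank(design[:, : j + 1])
        rank_without = np.linalg.matrix_rank(design[:, :j])
        if rank_with == rank_without:
            offenders.append(names[j])
    return offenders


def trait_regression(
    fixture: list[ValidationFixture],
    gene: str,
    covariates: tuple[str, ...] = ("age", "housekeeping"),
) -> RegressionReport:
    """OLS of the trait on a gene's expression plus covariates.

    ``covariates`` may contain "age" (slaughtering age in months) and/or
    "housekeeping" (normalized housekeeping-gene expression). Reports the
    expression coefficient with its t-statistic and two-sided p-value on
    the residual degrees of freedom.
    """
    allowed = {"age", "housekeeping"}
    unknown = set(covariates) - allowed
    if unknown:
        raise ValueError(f"unknown covariates: {sorted(unknown)}")
    y = np.array([f.imf_percent for f in fixture], dtype=float)
    cols = [np.ones(len(fixture)), np.array([f.expression[gene] for f in fixture])]
    names = ["intercept", "expression"]
    if "age" in covariates:
        cols.append(np.array([f.age_months for f in fixture], dtype=float))
        names.append("age_months")
    if "housekeeping" in covariates:
        cols.append(np.array([f.housekeeping for f in fixture], dtype=float))
        names.append("housekeeping")
    design = np.column_stack(cols)
    n, p = design.shape
    if n <= p:
        raise ValueError(f"n={n} samples cannot identify {p} coefficients")
    if np.linalg.matrix_rank(design) < p:
        offenders = _collinear_columns(design, names)
        raise ValueError(f"design matrix is rank deficient; collinear columns: {offenders}")
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    df = n - p
    sigma2 = float(resid @ resid) / df
    cov = sigma2 * np.linalg.inv(design.T @ design)
    se = np.sqrt(np.diag(cov))
    expr_idx = names.index("expression")
    if se[expr_idx] == 0:
        t_stat = math.inf if coef[expr_idx] != 0 else 0.0
        p_val = 0.0 if coef[expr_idx] != 0 else 1.0
    else:
        t_stat = float(coef[expr_idx] / se[expr_idx])
        p_val = float(2.0 * stats.t.sf(abs(t_stat), df))
    return RegressionReport(
        gene_id=gene,
        coefficients=dict(zip(names, map(float, coef))),
        standard_errors=dict(zip(names, map(float, se))),
        expression_t=t_stat,
        expression_p=p_val,
        residual_df=df,
    )


def expression_trait_correlation(
    fixture: list[ValidationFixture], gene: str
) -> tuple[float, float]:
    """Pearson r between a gene's expression and the trait, with the t-transform p.

    p is two-sided from t = r*sqrt((n-2)/(1-r^2)) on n-2 degrees of
    freedom; |r| = 1 yields p = 0.
    """
    x = np.array([f.expression[gene] for f in fixture], dtype=float)
    y = np.array([f.imf_percent for f in fixture], dtype=float)
    n = len(fixture)
    if n < 3:
        raise ValueError("correlation requires at least 3 samples")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in expression or trait")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(min(r, 1.0), -1.0)
    if abs(r) == 1.0:
        return r, 0.0
    t_stat = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = float(2.0 * stats.t.sf(abs(t_stat), n - 2))
    return r, p


def normalize_delta_ct(ct_gene: np.ndarray, ct_housekeeping: np.ndarray) -> np.ndarray:
    """Convenience 2**-(Ct_gene - Ct_housekeeping) normalization of qPCR cycles."""
    return 2.0 ** -(np.asarray(ct_gene, float) - np.asarray(ct_housekeeping, float))


def candidate_pca(
    fixture: list[ValidationFixture], genes: list[str], scale: bool = True
) -> PCAReport:
    """PCA of the samples x genes candidate expression matrix.

    Each gene is centered; with ``scale=True`` (default) it is also
    divided by its sample SD (correlation-matrix PCA). Loading signs are
    fixed so the largest-magnitude loading of each component is positive.
    The sign of each gene's PC2 loading is reported as its
    positive/negative relationship with the second component.
    """
    if len(genes) < 2:
        raise ValueError("PCA requires at least 2 genes")
    if len(fixture) < 2:
        raise ValueError("PCA requires at least 2 samples")
    x = np.array([[f.expression[g] for g in genes] for f in fixture], dtype=float)
    sd = x.std(axis=0, ddof=1)
    constant = [g for g, s in zip(genes, sd) if s == 0]
    if constant:
        raise ValueError(f"constant expression for gene(s): {constant}")
    centered = x - x.mean(axis=0)
    if scale:
        centered = centered / sd
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    # deterministic sign: largest |loading| positive per component
    for c in range(vt.shape[0]):
        pivot = np.argmax(np.abs(vt[c]))
        if vt[c, pivot] < 0:
            vt[c] *= -1.0
            u[:, c] *= -1.0
    scores = u * s
    loadings = vt.T
    var = s**2 / (len(fixture) - 1)
    total = var.sum()
    ratio = var / total if total > 0 else var
    relationship = {}
    if loadings.shape[1] >= 2:
        relationship = {
            g: ("positive" if loadings[i, 1] >= 0 else "negative")
            for i, g in enumerate(genes)
        }
    return PCAReport(
        gene_ids=list(genes),
        sample_ids=[f.animal_id for f in fixture],
        loadings=loadings,
        scores=scores,
        variance_ratio=ratio,
        cumulative_variance=np.cumsum(ratio),
        pc2_relationship=relationship,
    )
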