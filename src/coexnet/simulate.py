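"""Synthetic expression data with planted modules, hubs, and a linked trait.

Each planted module is driven by a latent factor: gene g in module m is
loading_g * factor_m + noise, so the expected correlation between two
module mates with loadings (u, v) is

    u*v / sqrt((u^2 + sd^2) * (v^2 + sd^2))

which equals ``within_module_cor`` when both loadings take the baseline
value sd * sqrt(rho / (1 - rho)). A designated hub fraction gets an
elevated loading. Background genes are independent noise. A quantitative
trait can be tied to the latent factor(s) of designated genes.

The module also provides the two-group qRT-PCR-style validation fixture,
including the published 12-steer cohort (6 low- and 6 high-marbled
animals with ages and intramuscular-fat percentages) and the published
per-gene group mean expression values for the 11 candidate genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import truncnorm

from coexnet.preprocess import ExpressionMatrix
from coexnet.validation import ValidationFixture

#: Published 12-steer cohort: (animal id, group, age in months, IMF %).
REFERENCE_ANIMALS: tuple[tuple[str, str, float, float], ...] = (
    ("509", "low", 26, 7.11),
    ("537", "low", 27, 6.02),
    ("539", "low", 26, 11.56),
    ("543", "low", 27, 6.6),
    ("590", "low", 27, 12.6),
    ("706", "low", 28, 13.37),
    ("508", "high", 26, 27.97),
    ("582", "high", 31, 18.94),
    ("603", "high", 31, 18.3),
    ("648", "high", 29, 20.78),
    ("652", "high", 29, 17.89),
    ("685", "high", 29, 21.2),
)

#: Published mean normalized expression (low group, high group) per candidate gene.
REFERENCE_GROUP_MEANS: dict[str, tuple[float, float]] = {
    "MAEL": (0.29, 0.33),
    "HINT1": (0.41, 0.25),
    "KIAA1712": (0.34, 0.21),
    "TMEM60": (0.34, 0.76),
    "RHEBL1": (0.45, 0.31),
    "FAM40A": (0.54, 0.30),
    "S100A11": (0.34, 0.36),
    "CD53": (0.41, 0.28),
    "DPYD": (0.26, 0.84),
    "ELOVL4": (0.38, 0.33),
    "CTSS": (0.33, 0.23),
}


@dataclass(frozen=True)
class SyntheticDesign:
    """Parameters of the planted-structure expression generator.

    ``module_sizes`` may sum to less than ``n_genes``; the remainder are
    independent background genes. ``within_module_cor`` is either one
    target correlation shared by all modules or one per module.
    """

    n_genes: int
    n_samples: int
    module_sizes: tuple[int, ...] = ()
    within_module_cor: float | tuple[float, ...] = 0.8
    hub_fraction: float = 0.1
    hub_loading_boost: float = 1.5
    trait_genes: tuple[int, ...] = ()
    trait_effect: float = 0.0
    trait_intercept: float = 15.0
    trait_noise_sd: float = 1.0
    noise_sd: float = 1.0
    seed: int = 0

    def module_correlations(self) -> tuple[float, ...]:
        if isinstance(self.within_module_cor, (int, float)):
            return tuple(float(self.within_module_cor) for _ in self.module_sizes)
        return tuple(float(c) for c in self.within_module_cor)

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be a positive integer")
        if self.n_samples < 1:
            raise ValueError("n_samples must be a positive integer")
        if any(s < 0 for s in self.module_sizes):
            raise ValueError("module_sizes entries must be non-negative")
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError("module_sizes sum exceeds n_genes")
        cors = self.module_correlations()
        if len(cors) != len(self.module_sizes):
            raise ValueError("within_module_cor length must match module_sizes")
        if any(not 0 < c < 1 for c in cors):
            raise ValueError("within_module_cor values must lie in (0, 1)")
        if not 0 <= self.hub_fraction <= 1:
            raise ValueError("hub_fraction must lie in [0, 1]")
        if self.hub_loading_boost <= 0:
            raise ValueError("hub_loading_boost must be positive")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.trait_noise_sd < 0:
            raise ValueError("trait_noise_sd must be non-negative")
        if any(not 0 <= g < self.n_genes for g in self.trait_genes):
            raise ValueError("trait_genes indices must lie in [0, n_genes)")


@dataclass
class SyntheticDataset:
    """Expression plus the planted ground truth used to generate it."""

    expression: ExpressionMatrix
    module_labels: np.ndarray  # 0 = background, 1..M = planted module
    hub_genes: list[str]
    trait: np.ndarray  # one value per sample
    factors: np.ndarray  # modules x samples latent factors


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i + 1:0{width}d}" for i in range(n)]


def _sample_ids(n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"S{i + 1:0{width}d}" for i in range(n)]


def generate_dataset(design: SyntheticDesign) -> SyntheticDataset:
    """Generate expression, planted labels, hub list, and linked trait.

    Deterministic given ``design.seed``.
    """
    design.validate()
    rng = np.random.default_rng(design.seed)
    n_g, n_s = design.n_genes, design.n_samples
    cors = design.module_correlations()
    gene_ids = _gene_ids(n_g)
    values = np.empty((n_g, n_s))
    labels = np.zeros(n_g, dtype=int)
    hubs: list[str] = []
    n_modules = len(design.module_sizes)
    factors = rng.standard_normal((n_modules, n_s)) if n_modules else np.empty((0, n_s))
    row = 0
    for m, (size, rho) in enumerate(zip(design.module_sizes, cors)):
        if size == 0:
            continue
        base_loading = design.noise_sd * math.sqrt(rho / (1.0 - rho))
        n_hubs = int(math.ceil(design.hub_fraction * size)) if size else 0
        loadings = np.full(size, base_loading)
        loadings[:n_hubs] *= design.hub_loading_boost
        noise = rng.normal(0.0, design.noise_sd, size=(size, n_s))
        values[row : row + size] = loadings[:, None] * factors[m][None, :] + noise
        labels[row : row + size] = m + 1
        hubs.extend(gene_ids[row : row + n_hubs])
        row += size
    if row < n_g:
        values[row:] = rng.normal(0.0, design.noise_sd, size=(n_g - row, n_s))
    trait_modules = sorted({labels[g] for g in design.trait_genes if labels[g] > 0})
    if trait_modules and design.trait_effect != 0.0:
        driver = factors[[m - 1 for m in trait_modules]].mean(axis=0)
    else:
        driver = np.zeros(n_s)
    trait = (
        design.trait_intercept
        + design.trait_effect * driver
        + rng.normal(0.0, design.trait_noise_sd, size=n_s)
    )
    expression = ExpressionMatrix(
        gene_ids=gene_ids, sample_ids=_sample_ids(n_s), values=values
    )
    return SyntheticDataset(
        expression=expression,
        module_labels=labels,
        hub_genes=hubs,
        trait=trait,
        factors=factors,
    )


def generate_expression(design: SyntheticDesign) -> ExpressionMatrix:
    """Expression matrix only; see :func:`generate_dataset` for ground truth."""
    return generate_dataset(design).expression


def generate_validation_fixture(
    n_per_group: int,
    group_means: tuple[float, float],
    group_sds: tuple[float, float],
    n_genes: int,
    effect_genes: list[str] | None = None,
    seed: int = 0,
    effect_slope: float = 0.05,
    expression_base: float = 0.5,
    expression_noise_sd: float = 0.05,
) -> list[ValidationFixture]:
    """Two-group fixture with trait-linked expression for designated genes.

    IMF is drawn per group from a normal truncated at zero with the given
    mean/SD; ages are uniform on [26, 31] months. Genes listed in
    ``effect_genes`` get expression ``base + effect_slope * IMF + noise``;
    all other genes are unrelated to the trait.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2 (SEM undefined otherwise)")
    if n_genes < 0:
        raise ValueError("n_genes must be non-negative")
    effect = set(effect_genes or [])
    genes = _gene_ids(n_genes)
    unknown = effect - set(genes)
    if unknown:
        raise ValueError(f"effect_genes not among generated genes: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    fixture: list[ValidationFixture] = []
    for group, mean, sd in zip(("low", "high"), group_means, group_sds):
        if sd < 0:
            raise ValueError("group SDs must be non-negative")
        if sd == 0:
            imf = np.full(n_per_group, float(mean))
        else:
            a = (0.0 - mean) / sd  # truncate at zero: fat content cannot be negative
            imf = truncnorm.rvs(
                a, np.inf, loc=mean, scale=sd, size=n_per_group, random_state=rng
            )
        ages = rng.uniform(26.0, 31.0, size=n_per_group)
        for i in range(n_per_group):
            expr = {}
            for g in genes:
                level = expression_base + rng.normal(0.0, expression_noise_sd)
                if g in effect:
                    level += effect_slope * imf[i]
                expr[g] = float(level)
            fixture.append(
                ValidationFixture(
                    animal_id=f"{group}{i + 1:02d}",
                    group=group,
                    age_months=float(ages[i]),
                    imf_percent=float(imf[i]),
                    expression=expr,
                    housekeeping=float(1.0 + rng.normal(0.0, expression_noise_sd)),
                )
            )
    return fixture


def generate_trait_regression_fixture(
    n: int,
    expression_slope: float,
    age_slope: float = 0.0,
    housekeeping_slope: float = 0.0,
    intercept: float = 20.0,
    noise_sd: float = 0.5,
    gene: str = "G0001",
    seed: int = 0,
) -> list[ValidationFixture]:
    """Fixture generated under the trait regression model itself.

    trait = intercept + expression_slope * expression + age_slope * age
    + housekeeping_slope * housekeeping + N(0, noise_sd), with standard
    normal expression. Used for coefficient-recovery checks where the
    generating slope is the oracle. Samples are split into low/high
    groups by the trait median for bookkeeping only.
    """
    if n < 5:
        raise ValueError("n must be >= 5")
    rng = np.random.default_rng(seed)
    expr = rng.standard_normal(n)
    ages = rng.uniform(26.0, 31.0, size=n)
    hk = 1.0 + 0.1 * rng.standard_normal(n)
    trait = (
        intercept
        + expression_slope * expr
        + age_slope * ages
        + housekeeping_slope * hk
        + rng.normal(0.0, noise_sd, size=n)
    )
    trait = np.maximum(trait, 0.0)
    median = np.median(trait)
    return [
        ValidationFixture(
            animal_id=f"A{i + 1:03d}",
            group="low" if trait[i] <= median else "high",
            age_months=float(ages[i]),
            imf_percent=float(trait[i]),
            expression={gene: float(expr[i])},
            housekeeping=float(hk[i]),
        )
        for i in range(n)
    ]


def reference_group_means() -> dict[str, tuple[float, float]]:
    """Published (low, high) mean normalized expression per candidate gene."""
    return dict(REFERENCE_GROUP_MEANS)


def reference_cohort(include_expression: bool = True) -> list[ValidationFixture]:
    """The published 12-steer validation cohort (6 low + 6 high marbled).

    Animal ids, ages, groups, and intramuscular-fat percentages are the
    printed values. With ``include_expression=True`` each animal carries
    its group's published mean normalized expression for the 11 candidate
    genes (per-animal values were not published). Housekeeping expression
    is set to 1.0 (not published).
    """
    fixture = []
    for animal, group, age, imf in REFERENCE_ANIMALS:
        expr = {}
        if include_expression:
            col = 0 if group == "low" else 1
            expr = {g: means[col] for g, means in REFERENCE_GROUP_MEANS.items()}
        fixture.append(
            ValidationFixture(
                animal_id=animal,
                group=group,
                age_months=float(age),
                imf_percent=float(imf),
                expression=expr,
                housekeeping=1.0,
            )
        )
    return fixture
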