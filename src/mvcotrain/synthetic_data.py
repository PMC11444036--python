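"""Synthetic two-view, imbalanced, partially labeled clinical datasets.

The generator emulates the statistical shape of the study cohort that the
package targets: 1,176 labeled subjects at a ≈1:6.79 positive:negative
imbalance (151 severe-hypoglycemia cases, 1,025 controls) plus 9,068
unlabeled subjects, with two feature views that are each individually
predictive of the outcome — view 1 holds four continuous glycemic summary
variables and view 2 holds six continuous management variables plus seven
binary medication indicators, mirroring the 17 modeling variables of the
expert feature list.  It does not attempt to match real units, covariances
or clinical ranges; it targets the shape (imbalance, two sufficient views,
longitudinal missingness) that the pipeline must handle.

Class labels are drawn by quota (exact counts), continuous features are
class-shifted Gaussians with an optional shared latent factor ρ that
induces cross-view redundancy, and binary indicators are Bernoulli with
class-dependent rates.  A companion routine emits raw longitudinal panels
with missing cells for exercising imputation and summarization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_data import NEGATIVE, POSITIVE, UNKNOWN, FeatureTable, ViewSpec
from .exceptions import ConfigurationError
from .preprocessing import MD_SCHEMA

#: shipped view split over the 17 summary variables
VIEW1_FEATURES = ("hba1c_mean", "hba1c_std", "fpg_mean", "fpg_std")
VIEW2_CONTINUOUS = (
    "g1check_mean", "g1check_std", "g1diabed_mean",
    "g1diabed_std", "g1nutrit_mean", "g1nutrit_std",
)
VIEW2_BINARY = (
    "sulfonylurea_mean", "meglitinide_mean", "nphl_insulin_mean",
    "reg_insulin_mean", "la_insulin_mean", "othbol_insulin_mean",
    "premix_insulin_mean",
)
MD_VIEWS = ViewSpec(VIEW1_FEATURES, VIEW2_CONTINUOUS + VIEW2_BINARY)


@dataclass
class SyntheticConfig:
    """Cohort shape and effect sizes for the generator.

    ``delta1``/``delta2`` are the per-class mean shifts (in units of the
    noise scale ``sigma``) of the continuous features of each view;
    ``rate_diff`` is the positive-minus-negative event-rate difference of
    the binary medication indicators; ``rho`` adds a shared latent Gaussian
    to both views' continuous features, making the views redundant
    (``rho = 0`` gives conditional independence given the class).
    """

    n_labeled: int = 1176
    n_unlabeled: int = 9068
    prevalence: float = 151 / 1176
    delta1: float = 1.0
    delta2: float = 0.8
    rate_diff: float = 0.25
    base_rate: float = 0.30
    sigma: float = 1.0
    rho: float = 0.0
    visits: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.prevalence < 1:
            raise ConfigurationError("prevalence must be in (0, 1)")
        if self.delta1 < 0 or self.delta2 < 0:
            raise ConfigurationError("effect sizes must be >= 0")
        if not 0 <= self.rho <= 1:
            raise ConfigurationError("rho must be in [0, 1]")
        if self.sigma < 0:
            raise ConfigurationError("sigma must be >= 0")
        if not 0 <= self.base_rate <= 1 or not 0 <= self.base_rate + self.rate_diff <= 1:
            raise ConfigurationError("binary rates must stay within [0, 1]")


def _quota_labels(n: int, prevalence: float, rng: np.random.Generator) -> np.ndarray:
    """Exact-count class assignment: round(prevalence*n) positives, shuffled."""
    n_pos = int(np.floor(prevalence * n + 0.5))
    y = np.zeros(n, dtype=int)
    y[:n_pos] = 1
    return y[rng.permutation(n)]


def _features(
    y: np.ndarray, cfg: SyntheticConfig, rng: np.random.Generator
) -> pd.DataFrame:
    n = len(y)
    z = rng.standard_normal(n)  # shared latent factor for cross-view redundancy
    cols = {}
    for name in VIEW1_FEATURES:
        eps = rng.standard_normal(n)
        noise = np.sqrt(1 - cfg.rho) * eps + np.sqrt(cfg.rho) * z
        cols[name] = cfg.delta1 * y + cfg.sigma * noise
    for name in VIEW2_CONTINUOUS:
        eps = rng.standard_normal(n)
        noise = np.sqrt(1 - cfg.rho) * eps + np.sqrt(cfg.rho) * z
        cols[name] = cfg.delta2 * y + cfg.sigma * noise
    for name in VIEW2_BINARY:
        rate = cfg.base_rate + cfg.rate_diff * y
        cols[name] = (rng.random(n) < rate).astype(float)
    return pd.DataFrame(cols)


def generate(
    config: SyntheticConfig | None = None,
) -> tuple[FeatureTable, FeatureTable, pd.Series, ViewSpec]:
    """Generate a labeled table, an unlabeled table, hidden truth, and views.

    The labeled table carries positive/negative outcomes at exact quota
    counts (the default preset yields 151 positives and 1,025 negatives);
    the unlabeled table carries ``unknown`` outcomes, with the true latent
    class returned separately so oracle tests can score pseudo-labels.
    Bit-identical output for identical config (including seed).
    """
    cfg = config or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)

    y_lab = _quota_labels(cfg.n_labeled, cfg.prevalence, rng)
    y_unl = _quota_labels(cfg.n_unlabeled, cfg.prevalence, rng)

    lab_data = _features(y_lab, cfg, rng)
    lab_data.index = pd.Index([f"L{i:05d}" for i in range(cfg.n_labeled)], name="subject_id")
    unl_data = _features(y_unl, cfg, rng)
    unl_data.index = pd.Index([f"U{i:05d}" for i in range(cfg.n_unlabeled)], name="subject_id")

    labeled = FeatureTable(
        lab_data, pd.Series(np.where(y_lab == 1, POSITIVE, NEGATIVE), index=lab_data.index)
    )
    unlabeled = FeatureTable(unl_data, pd.Series(UNKNOWN, index=unl_data.index))
    truth = pd.Series(np.where(y_unl == 1, POSITIVE, NEGATIVE), index=unl_data.index)
    return labeled, unlabeled, truth, MD_VIEWS


def generate_panel(
    config: SyntheticConfig | None = None,
    missing_rate: float = 0.0,
    n_subjects: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a raw longitudinal panel with missing cells punched in.

    Each subject gets ``config.visits`` visit rows over the 12 raw
    variables of the expert schema (continuous clinical variables plus 0/1
    medication indicators).  Cells go missing independently at
    ``missing_rate``.  Returns ``(panel_with_holes, complete_panel)`` so
    imputation error can be measured against the hidden complete values.
    """
    cfg = config or SyntheticConfig()
    if not 0 <= missing_rate < 1:
        raise ConfigurationError("missing_rate must be in [0, 1)")
    n = n_subjects if n_subjects is not None else cfg.n_labeled
    rng = np.random.default_rng(cfg.seed + 1)

    subjects = np.repeat([f"P{i:05d}" for i in range(n)], cfg.visits)
    visits = np.tile(np.arange(1, cfg.visits + 1), n)
    data = {"subject_id": subjects, "visit": visits}
    for var, stats in MD_SCHEMA.items():
        if "std" in stats:  # continuous clinical variable
            subject_mean = rng.standard_normal(n)[np.repeat(np.arange(n), cfg.visits)]
            data[var] = subject_mean + cfg.sigma * rng.standard_normal(n * cfg.visits)
        else:  # medication indicator, 0/1 per visit
            rate = rng.uniform(0.1, 0.6, n)[np.repeat(np.arange(n), cfg.visits)]
            data[var] = (rng.random(n * cfg.visits) < rate).astype(float)
    complete = pd.DataFrame(data)
    holey = complete.copy()
    variables = list(MD_SCHEMA)
    mask = rng.random((len(holey), len(variables))) < missing_rate
    for j, var in enumerate(variables):
        holey.loc[mask[:, j], var] = np.nan
    return holey, complete
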