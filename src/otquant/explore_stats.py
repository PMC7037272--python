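"""Correlation screening, PCA and summary-statistic comparisons.

Used to explore which sediment properties (TOC, PAH, grain-size fractions,
heavy metals, AVS...) track ionization suppression or extraction losses.
Spearman rank correlation is used because the property-suppression links are
monotone at best, and n is small; PCA on standardized variables gives the
biplot coordinates for visual screening.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_model import SedimentProfile, ValidationError, profiles_to_frame


class InsufficientDataError(ValueError):
    """Too few complete pairs/samples for the statistic."""


class UndefinedCorrelationError(ValueError):
    """Zero variance in the ranks of one variable."""


class DegenerateVariableError(ValueError):
    """A PCA variable has zero variance and cannot be standardized."""


@dataclass(frozen=True)
class CorrelationCell:
    """One Spearman correlation between a response and a sediment property."""

    response: str
    property: str
    rho: float
    p_value: float  # two-sided
    n: int

    def __post_init__(self) -> None:
        if abs(self.rho) > 1 + 1e-12:
            raise ValidationError("|rho| must be <= 1")

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


@dataclass(frozen=True)
class PcaModel:
    """Full-rank PCA of standardized variables (zero mean, unit variance)."""

    variables: tuple[str, ...]
    loadings: np.ndarray  # (n_vars, n_components), orthonormal columns
    scores: np.ndarray  # (n_samples, n_components)
    singular_values: np.ndarray
    variance_explained: np.ndarray  # %, sums to 100 over all components
    sample_ids: tuple[str, ...]

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


def spearman(
    x: Sequence[float], y: Sequence[float], response: str = "x", property: str = "y"
) -> CorrelationCell:
    """Spearman rank correlation with average ranks for ties.

    rho is the product-moment correlation of the rank-transformed data; the
    two-sided p-value uses the t approximation with n - 2 degrees of freedom
    (adequate at the n = 10 scale this screen runs at). Missing pairs are
    dropped; fewer than 4 complete pairs is an error.
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if len(xv) != len(yv):
        raise ValueError("x and y must have equal length")
    keep = ~(np.isnan(xv) | np.isnan(yv))
    xv, yv = xv[keep], yv[keep]
    n = len(xv)
    if n < 4:
        raise InsufficientDataError(f"need >= 4 complete pairs, got {n}")
    if np.all(xv == xv[0]) or np.all(yv == yv[0]):
        raise UndefinedCorrelationError("one variable has zero rank variance")
    rho, p = stats.spearmanr(xv, yv)
    if abs(rho) >= 1.0:  # t approximation degenerates; p underflows to 0
        p = float(np.finfo(float).tiny)
    return CorrelationCell(response=response, property=property, rho=float(rho), p_value=float(p), n=n)


def correlation_screen(
    responses: pd.DataFrame,
    profiles: Sequence[SedimentProfile] | pd.DataFrame,
) -> list[CorrelationCell]:
    """Spearman screen of every (response, sediment property) pair.

    ``responses`` is a DataFrame indexed by matrix_id (e.g. columns
    ``ME_A TBT``, ``RE TPhT``); properties with no overlapping complete pairs
    are omitted rather than reported as NaN.
    """
    if isinstance(profiles, pd.DataFrame):
        prof = profiles
    else:
        prof = profiles_to_frame(profiles)
    joined = responses.join(prof, how="inner")
    cells: list[CorrelationCell] = []
    for resp in responses.columns:
        for prop in prof.columns:
            pair = joined[[resp, prop]].astype(float).dropna()
            if len(pair) < 4:
                continue
            try:
                cells.append(
                    spearman(pair[resp], pair[prop], response=resp, property=prop)
                )
            except UndefinedCorrelationError:
                continue
    return cells


def pca(
    profiles: Sequence[SedimentProfile] | pd.DataFrame,
    variables: Optional[Sequence[str]] = None,
) -> PcaModel:
    """PCA of standardized sediment properties via singular values.

    Samples with any missing selected variable are excluded listwise; every
    variable is centred and scaled to unit variance (the properties mix %,
    mS, mg/kg and ug/kg units, so covariance PCA would be meaningless).
    Scores, orthonormal loadings and % variance are returned for all
    components.
    """
    if isinstance(profiles, pd.DataFrame):
        df = profiles.copy()
    else:
        df = profiles_to_frame(profiles)
    if variables is not None:
        df = df[list(variables)]
    df = df.astype(float).dropna(axis=0, how="any")
    if df.shape[0] < 3:
        raise InsufficientDataError("need >= 3 complete samples")
    if df.shape[1] < 2:
        raise InsufficientDataError("need >= 2 variables")
    sds = df.std(ddof=1)
    dead = sds[sds == 0].index.tolist()
    if dead:
        raise DegenerateVariableError(f"zero-variance variable(s): {', '.join(dead)}")
    z = (df - df.mean()) / sds
    u, s, vt = np.linalg.svd(z.to_numpy(), full_matrices=False)
    var = s**2 / np.sum(s**2) * 100.0
    return PcaModel(
        variables=tuple(df.columns),
        loadings=vt.T,
        scores=u * s,
        singular_values=s,
        variance_explained=var,
        sample_ids=tuple(str(i) for i in df.index),
    )


def biplot_data(
    model: PcaModel, component_pair: tuple[int, int]
) -> dict[str, object]:
    """Plottable coordinates for a biplot of two components (1-based indices).

    Returns sample scores and loading-arrow endpoints (loadings scaled by the
    singular values over sqrt(n - 1), i.e. correlation-scaled arrows). Pure
    data; no plotting side effects.
    """
    i, j = component_pair
    if not (1 <= i <= model.n_components and 1 <= j <= model.n_components):
        raise IndexError(
            f"component pair {component_pair} out of range for a "
            f"{model.n_components}-component model"
        )
    ii, jj = i - 1, j - 1
    n = model.scores.shape[0]
    scale = model.singular_values / np.sqrt(n - 1)
    arrows = model.loadings[:, [ii, jj]] * scale[[ii, jj]]
    return {
        "components": (i, j),
        "variance_explained": (
            float(model.variance_explained[ii]),
            float(model.variance_explained[jj]),
        ),
        "scores": pd.DataFrame(
            model.scores[:, [ii, jj]], index=list(model.sample_ids), columns=[f"PC{i}", f"PC{j}"]
        ),
        "arrows": pd.DataFrame(
            arrows, index=list(model.variables), columns=[f"PC{i}", f"PC{j}"]
        ),
    }


def welch_t_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, float]:
    """Welch two-sample t-test from summary statistics (mean, sd, n).

    Returns (t statistic, two-sided p). With both sds zero and equal means
    the groups are indistinguishable and p is reported as 1.
    """
    if n1 < 2 or n2 < 2:
        raise ValidationError("both groups need n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValidationError("standard deviations must be >= 0")
    if sd1 == 0 and sd2 == 0:
        if mean1 == mean2:
            return 0.0, 1.0
        return float(np.inf) if mean1 > mean2 else float(-np.inf), 0.0
    t_stat, p = stats.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=False
    )
    return float(t_stat), float(p)


__all__ = [
    "CorrelationCell",
    "PcaModel",
    "spearman",
    "correlation_screen",
    "pca",
    "biplot_data",
    "welch_t_from_summary",
    "InsufficientDataError",
    "UndefinedCorrelationError",
    "DegenerateVariableError",
]
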