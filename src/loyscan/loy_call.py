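"""Bimodal-peak LoY classification and the array expression-ratio caller.

The Y-index distribution of a male tumor cohort is bimodal: a lower mode for
samples that lost Y and an upper mode for samples that retained it. A
Gaussian KDE is fitted, the two highest well-separated local maxima are
taken as the peaks, and samples are labeled by position relative to the
peaks: strictly below the lower peak -> LOY, strictly above the upper peak
-> RETAINED, otherwise (including exact ties) UNCERTAIN.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

LOY = "LOY"
RETAINED = "RETAINED"
UNCERTAIN = "UNCERTAIN"


class UnimodalityError(ValueError):
    """Raised when fewer than two qualifying density maxima are found."""

    def __init__(self, message: str, mode: float):
        super().__init__(message)
        self.mode = mode


class DegenerateInputError(ValueError):
    """Raised when an input matrix carries no variance to decompose."""


@dataclass(frozen=True)
class BimodalFit:
    """Two density modes of a Y-index (or PC-score) distribution."""

    peak_low: float
    peak_high: float
    bandwidth: float
    grid: np.ndarray
    density: np.ndarray

    def __post_init__(self):
        if not self.peak_low < self.peak_high:
            raise ValueError("peak_low must be < peak_high")


def fit_bimodal(
    values,
    bandwidth: float | str | None = None,
    min_separation: float = 0.2,
    grid_size: int = 512,
) -> BimodalFit:
    """Fit a Gaussian KDE and locate the two dominant density modes.

    Parameters
    ----------
    values:
        At least 20 finite values.
    bandwidth:
        ``scipy.stats.gaussian_kde`` bandwidth method; defaults to
        Silverman's rule.
    min_separation:
        Minimum distance between the two returned peaks.

    Raises
    ------
    UnimodalityError
        When no second local maximum lies at least ``min_separation`` from
        the dominant one; the error carries the single mode found.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 20:
        raise ValueError(f"need at least 20 finite values, got {x.size}")
    kde = stats.gaussian_kde(x, bw_method=bandwidth if bandwidth is not None else "silverman")
    lo, hi = x.min(), x.max()
    pad = 0.1 * (hi - lo) if hi > lo else 1.0
    grid = np.linspace(lo - pad, hi + pad, grid_size)
    density = kde(grid)

    interior = np.flatnonzero(
        (density[1:-1] > density[:-2]) & (density[1:-1] >= density[2:])
    ) + 1
    if interior.size == 0:
        raise UnimodalityError("no interior density maximum found", float(grid[np.argmax(density)]))
    order = interior[np.argsort(density[interior])[::-1]]
    first = order[0]
    second = None
    for cand in order[1:]:
        if abs(grid[cand] - grid[first]) >= min_separation:
            second = cand
            break
    if second is None:
        raise UnimodalityError(
            f"only one density mode at {grid[first]:.4g} "
            f"(no second maximum separated by >= {min_separation})",
            float(grid[first]),
        )
    peaks = sorted((float(grid[first]), float(grid[second])))
    h = float(np.sqrt(kde.covariance[0, 0]))
    return BimodalFit(peaks[0], peaks[1], h, grid, density)


def classify_loy(y_indices, fit: BimodalFit) -> pd.DataFrame:
    """Three-way label by position relative to the two fitted peaks.

    ``y_indices`` may be a ``pandas.Series`` (index = sample ids) or an
    array. Values exactly equal to a peak are UNCERTAIN; NaN values are
    dropped with a warning.
    """
    series = pd.Series(y_indices, dtype=float)
    n_missing = int(series.isna().sum())
    if n_missing:
        logger.warning("classify_loy: dropping %d samples without a Y index", n_missing)
        series = series.dropna()
    labels = np.where(
        series.values < fit.peak_low,
        LOY,
        np.where(series.values > fit.peak_high, RETAINED, UNCERTAIN),
    )
    out = pd.DataFrame(
        {
            "y_index": series.values,
            "label": labels,
            "peak_low": fit.peak_low,
            "peak_high": fit.peak_high,
        },
        index=series.index,
    )
    out.index.name = "sample_id"
    return out


# ---------------------------------------------------------------------------
# Array expression-ratio pipeline


@dataclass
class ExpressionRatioMatrix:
    """Probe x male-sample dosage ratios plus the reference values used.

    ratio(probe, sample) = (x - mean_female) / (mean_male_normal - mean_female),
    so male normals average 1 per probe by construction and a sample at the
    female background level scores 0.
    """

    ratios: pd.DataFrame
    female_mean: pd.Series
    male_normal_adjusted_mean: pd.Series
    groups: pd.Series  # per male sample: normal / dysplasia / tumor


def expression_ratio(
    intensities: pd.DataFrame,
    sex: pd.Series,
    groups: pd.Series,
    probes=None,
) -> ExpressionRatioMatrix:
    """Three-step female-background dosage ratio for each male sample.

    (1) average each probe over all female samples (background); (2) subtract
    that background from every male sample; (3) divide by the
    background-subtracted average of the male normal samples. Probes whose
    male-normal adjusted mean is <= 0 are dropped with a warning.
    """
    sex = pd.Series(sex)
    groups = pd.Series(groups)
    if probes is not None:
        intensities = intensities.loc[list(probes)]
    females = sex.index[sex == "female"]
    males = sex.index[sex == "male"]
    male_normals = [s for s in males if groups.get(s) == "normal"]
    if len(females) == 0:
        raise ValueError("expression_ratio requires at least one female sample")
    if len(male_normals) == 0:
        raise ValueError("expression_ratio requires at least one male normal sample")

    female_mean = intensities[list(females)].mean(axis=1)
    adjusted = intensities[list(males)].sub(female_mean, axis=0)
    normal_mean = adjusted[male_normals].mean(axis=1)
    bad = normal_mean <= 0
    if bad.any():
        logger.warning(
            "expression_ratio: dropping %d probes with non-positive male-normal mean: %s",
            int(bad.sum()), ", ".join(map(str, normal_mean.index[bad])),
        )
    keep = normal_mean.index[~bad]
    ratios = adjusted.loc[keep].div(normal_mean.loc[keep], axis=0)
    return ExpressionRatioMatrix(
        ratios=ratios,
        female_mean=female_mean.loc[keep],
        male_normal_adjusted_mean=normal_mean.loc[keep],
        groups=groups.loc[list(males)],
    )


def pc_loy(
    ratio_matrix: ExpressionRatioMatrix,
    bandwidth: float | str | None = None,
    min_separation: float | None = None,
) -> tuple[pd.Series, BimodalFit, pd.DataFrame]:
    """First-principal-component LoY call from probe dosage ratios.

    Probes are mean-centered (not scaled — the ratios share a scale by
    construction), the first PC is extracted, and its sign is oriented so
    that the male-normal mean score is positive. The scores are then passed
    through :func:`fit_bimodal` and :func:`classify_loy`.
    """
    ratios = ratio_matrix.ratios
    if ratios.shape[0] < 2:
        raise ValueError("pc_loy requires at least 2 probes")
    if ratios.shape[1] < 20:
        raise ValueError("pc_loy requires at least 20 male samples")
    X = ratios.T.to_numpy(dtype=float)  # samples x probes
    X = X - X.mean(axis=0, keepdims=True)
    if not np.any(np.abs(X) > 1e-12):
        raise DegenerateInputError("ratio matrix is constant; nothing to decompose")
    u, s, _vt = np.linalg.svd(X, full_matrices=False)
    scores = pd.Series(u[:, 0] * s[0], index=ratios.columns, name="pc1")
    normals = [c for c in ratios.columns if ratio_matrix.groups.get(c) == "normal"]
    reference = scores[normals] if normals else scores
    if reference.mean() < 0:
        scores = -scores
    if min_separation is None:
        fit = fit_bimodal(scores.values, bandwidth=bandwidth)
    else:
        fit = fit_bimodal(scores.values, bandwidth=bandwidth, min_separation=min_separation)
    calls = classify_loy(scores, fit)
    calls = calls.rename(columns={"y_index": "pc1"})
    return scores, fit, calls


def explained_variance_ratio(ratio_matrix: ExpressionRatioMatrix) -> np.ndarray:
    """Fraction of variance carried by each principal component."""
    X = ratio_matrix.ratios.T.to_numpy(dtype=float)
    X = X - X.mean(axis=0, keepdims=True)
    _u, s, _vt = np.linalg.svd(X, full_matrices=False)
    var = s ** 2
    total = var.sum()
    if total == 0:
        raise DegenerateInputError("ratio matrix is constant; nothing to decompose")
    return var / total
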