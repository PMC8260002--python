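"""Voxelwise encoding models.

A brain response matrix R (time-by-voxel) is modeled as a linear function of
delay-embedded scene features, R = X W + noise, where X concatenates copies of
the K-dimensional scene-vector series lagged by 3, 4, 5 and 6 s so that the
linear weights absorb hemodynamic latency. W is estimated by L2-regularized
least squares; the regularization strength is selected by repeated random
80/20 resampling of the training data, scoring each candidate by the
voxel-mean Pearson correlation between held-out predictions and responses.
Prediction accuracy on the independent test set is the per-voxel Pearson r,
with per-voxel significance from the t-transform and Benjamini–Hochberg FDR.

The public surface is the sklearn-style :class:`VoxelEncoder` estimator plus
module-level functions mirroring the individual pipeline steps.
"""

from __future__ import annotations

import logging

import numpy as np
import scipy.ndimage
import scipy.stats
from sklearn.base import BaseEstimator, RegressorMixin

from .stats import fdr_bh
from .types import (
    AccuracyProfile,
    EncodingModel,
    ResponseSeries,
    SceneFeatureSeries,
)

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_DELAYS",
    "default_lambda_grid",
    "detrend_standardize",
    "delay_embed",
    "fit_encoding_model",
    "score_model",
    "significant_fraction",
    "r_threshold",
    "region_summary",
    "VoxelEncoder",
]

#: Hemodynamic delays (seconds, = samples at TR 1 s) used for delay embedding.
DEFAULT_DELAYS: tuple[int, ...] = (3, 4, 5, 6)


def default_lambda_grid() -> np.ndarray:
    """17 log-spaced regularization candidates, 1e0 .. 1e8."""
    return np.logspace(0.0, 8.0, 17)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def detrend_standardize(
    raw: np.ndarray,
    window_seconds: int = 120,
    tr_seconds: float = 1.0,
    region_labels=None,
    split=None,
) -> ResponseSeries:
    """Remove slow drift with a running median and z-score each voxel.

    The median filter runs over a ``window_seconds`` window (coerced to the
    nearest odd sample count, reflect padding at the edges); the filtered
    signal is subtracted from the raw signal and the residual standardized to
    zero mean and unit sample variance. A voxel with zero variance after
    detrending is an error (it carries no signal to model).
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2:
        raise ValueError("raw responses must be a time-by-voxel matrix")
    window = int(round(window_seconds / tr_seconds))
    if window % 2 == 0:
        window += 1
    if raw.shape[0] <= window:
        raise ValueError(
            f"series length {raw.shape[0]} must exceed the {window}-sample window"
        )
    trend = scipy.ndimage.median_filter(raw, size=(window, 1), mode="reflect")
    resid = raw - trend
    sd = resid.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise ValueError(f"voxel {int(zero[0])} has zero variance after detrending")
    values = (resid - resid.mean(axis=0)) / sd
    return ResponseSeries(
        values=values, region_labels=region_labels, split=split,
        tr_seconds=tr_seconds,
    )


# ---------------------------------------------------------------------------
# delay embedding
# ---------------------------------------------------------------------------

def delay_embed(features, delays=DEFAULT_DELAYS) -> np.ndarray:
    """Concatenate lagged copies of the feature series.

    Block d of row t holds the feature row at time t - d, zero-filled where no
    history exists; blocks are laid out in the order the delays are given.
    Zeros at the boundary are the mean once responses are z-scored.
    """
    if isinstance(features, SceneFeatureSeries):
        features = features.values
    F = np.asarray(features, dtype=float)
    if F.ndim != 2:
        raise ValueError("features must be a time-by-feature matrix")
    delays = tuple(int(d) for d in delays)
    if not delays:
        raise ValueError("delays must be nonempty")
    if any(d < 1 for d in delays):
        raise ValueError("delays must be positive integers (in TR units)")
    S, K = F.shape
    if any(d >= S for d in delays):
        raise ValueError(f"delay >= series length {S}")
    X = np.zeros((S, K * len(delays)))
    for i, d in enumerate(delays):
        X[d:, i * K:(i + 1) * K] = F[:-d]
    return X


def delay_embed_split(
    features: SceneFeatureSeries, delays=DEFAULT_DELAYS
) -> tuple[np.ndarray, np.ndarray]:
    """Delay-embed the train and test segments separately.

    The two segments come from separate scans, so neither sees the other's
    history; each is zero-padded at its own onset.
    """
    return (
        delay_embed(features.train_values(), delays),
        delay_embed(features.test_values(), delays),
    )


# ---------------------------------------------------------------------------
# correlation utilities
# ---------------------------------------------------------------------------

def _columnwise_pearson(a: np.ndarray, b: np.ndarray, warn: bool = False) -> np.ndarray:
    """Pearson r per column pair; zero-variance columns get r = 0."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    num = np.einsum("ij,ij->j", a, b)
    den = np.sqrt(np.einsum("ij,ij->j", a, a) * np.einsum("ij,ij->j", b, b))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    if warn and np.any(den == 0):
        logger.warning(
            "%d zero-variance series in correlation; r set to 0",
            int((den == 0).sum()),
        )
    return np.clip(r, -1.0, 1.0)


# ---------------------------------------------------------------------------
# ridge fit with resampled lambda selection
# ---------------------------------------------------------------------------

def fit_encoding_model(
    X: np.ndarray,
    R,
    lambda_grid=None,
    n_resamples: int = 10,
    train_fraction: float = 0.8,
    seed: int = 0,
    delays=DEFAULT_DELAYS,
    feature_kind: str = "trained",
) -> EncodingModel:
    """Fit ridge weights on delay-embedded features with resampled selection.

    For each candidate lambda the training rows are split at random into
    ``train_fraction`` fitting and held-out validation subsets, ``n_resamples``
    times; the score of a lambda is the resample-mean of the voxel-mean
    Pearson r between validation predictions and responses. The best lambda
    (ties going to the smaller value) is refit on all training rows by solving
    the penalized normal equations, here through the SVD of X.
    """
    if isinstance(R, ResponseSeries):
        R = R.train_values() if (R.split == "test").any() else R.values
    R = np.asarray(R, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.shape[0] != R.shape[0]:
        raise ValueError(f"{X.shape[0]} feature rows but {R.shape[0]} response rows")
    if lambda_grid is None:
        lambda_grid = default_lambda_grid()
    grid = np.unique(np.asarray(lambda_grid, dtype=float))
    if grid.size == 0 or np.any(grid < 0):
        raise ValueError("lambda grid must be nonempty and nonnegative")
    S = X.shape[0]
    n_fit = int(round(train_fraction * S))
    if n_fit < 2 or S - n_fit < 3:
        raise ValueError("not enough samples for the resampling split")

    rng = np.random.default_rng(seed)
    scores = np.zeros(grid.size)
    for _ in range(n_resamples):
        perm = rng.permutation(S)
        fit_idx, val_idx = perm[:n_fit], perm[n_fit:]
        U, s, Vt = np.linalg.svd(X[fit_idx], full_matrices=False)
        B = U.T @ R[fit_idx]          # rank x N
        A = X[val_idx] @ Vt.T         # n_val x rank
        R_val = R[val_idx]
        for gi, lam in enumerate(grid):
            shrink = s / (s**2 + lam)
            pred = (A * shrink) @ B
            scores[gi] += _columnwise_pearson(pred, R_val, warn=True).mean()
    scores /= n_resamples
    if not np.any(np.isfinite(scores)):
        raise ValueError("validation score non-finite for every lambda")
    best = int(np.nanargmax(scores))  # grid ascending: first max = smallest lambda
    lam = float(grid[best])

    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    shrink = s / (s**2 + lam)
    weights = Vt.T @ (shrink[:, None] * (U.T @ R))
    return EncodingModel(
        weights=weights,
        delays=delays,
        lambda_=lam,
        feature_kind=feature_kind,
        fit_meta={
            "n_resamples": int(n_resamples),
            "train_fraction": float(train_fraction),
            "seed": int(seed),
            "lambda_grid": grid.tolist(),
            "validation_scores": scores.tolist(),
            "validation_score": float(scores[best]),
        },
    )


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def pearson_p_values(r: np.ndarray, n: int, sided: str = "two") -> np.ndarray:
    """p-values for Pearson correlations via the Student-t transform."""
    if n < 4:
        raise ValueError("need n >= 4 for the t-transform")
    r = np.clip(np.asarray(r, dtype=float), -1 + 1e-15, 1 - 1e-15)
    t = r * np.sqrt((n - 2) / (1 - r**2))
    if sided == "two":
        return 2 * scipy.stats.t.sf(np.abs(t), df=n - 2)
    if sided == "one":
        return scipy.stats.t.sf(t, df=n - 2)
    raise ValueError("sided must be 'one' or 'two'")


def score_model(model: EncodingModel, X_test: np.ndarray, R_test, q: float = 0.05) -> AccuracyProfile:
    """Per-voxel test-set prediction accuracy with FDR significance.

    Accuracy is the Pearson r between predicted and measured responses;
    significance uses two-sided t-transform p-values corrected across all
    voxels with Benjamini–Hochberg FDR at level ``q``.
    """
    region_labels = None
    if isinstance(R_test, ResponseSeries):
        region_labels = R_test.region_labels
        R_test = R_test.test_values() if (R_test.split == "test").any() else R_test.values
    R_test = np.asarray(R_test, dtype=float)
    X_test = np.asarray(X_test, dtype=float)
    if X_test.shape[0] < 3:
        raise ValueError("need at least 3 test rows")
    pred = X_test @ model.weights
    r = _columnwise_pearson(pred, R_test, warn=True)
    p = pearson_p_values(r, n=X_test.shape[0], sided="two")
    mask = fdr_bh(p, q=q)
    return AccuracyProfile(
        per_voxel_r=r,
        n_test=X_test.shape[0],
        p_values=p,
        significant_mask=mask,
        region_labels=region_labels,
    )


def significant_fraction(profile: AccuracyProfile) -> float:
    """Fraction of voxels whose prediction accuracy passes FDR significance."""
    return float(profile.significant_mask.mean())


def r_threshold(n: int, alpha: float, sided: str = "two") -> float:
    """Correlation magnitude reaching significance ``alpha`` at sample size n.

    Inverts the t-transform t = r * sqrt((n-2) / (1-r^2)): the returned r
    satisfies that relation at the alpha quantile of Student's t with n-2
    degrees of freedom.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie strictly between 0 and 1")
    if sided == "two":
        tq = scipy.stats.t.ppf(1 - alpha / 2, df=n - 2)
    elif sided == "one":
        tq = scipy.stats.t.ppf(1 - alpha, df=n - 2)
    else:
        raise ValueError("sided must be 'one' or 'two'")
    return float(tq / np.sqrt(n - 2 + tq**2))


def region_summary(profile: AccuracyProfile):
    """Mean accuracy and significant-voxel fraction per cortical region.

    The significance mask is the global FDR mask; the per-region fraction just
    restricts it to the region's voxels. Returns a DataFrame indexed by region
    label in order of first appearance.
    """
    import pandas as pd

    if profile.region_labels is None:
        raise ValueError("profile carries no region labels")
    labels = pd.unique(profile.region_labels)
    rows = []
    for lab in labels:
        in_region = profile.region_labels == lab
        if not in_region.any():
            raise ValueError(f"region {lab!r} is empty")
        rows.append(
            {
                "region": lab,
                "n_voxels": int(in_region.sum()),
                "mean_r": float(profile.per_voxel_r[in_region].mean()),
                "significant_fraction": float(
                    profile.significant_mask[in_region].mean()
                ),
            }
        )
    return pd.DataFrame(rows).set_index("region")


# ---------------------------------------------------------------------------
# sklearn-style estimator
# ---------------------------------------------------------------------------

class VoxelEncoder(BaseEstimator, RegressorMixin):
    """Delay-embedded ridge encoder for voxel response matrices.

    Parameters
    ----------
    delays : tuple of int
        Hemodynamic lags in TR units; lagged feature copies are concatenated.
    lambda_grid : array-like or None
        Ridge penalty candidates; ``None`` uses 17 log-spaced values 1e0..1e8.
    n_resamples, train_fraction : int, float
        Random-resampling schedule for penalty selection (default 10 x 80/20).
    random_state : int
        Seed for the resampling splits.

    Fitted attributes: ``weights_`` ((K * n_delays)-by-N), ``lambda_``,
    ``cv_scores_`` (one validation score per grid point) and ``model_`` (the
    :class:`~semrdm.types.EncodingModel`).
    """

    def __init__(
        self,
        delays=DEFAULT_DELAYS,
        lambda_grid=None,
        n_resamples: int = 10,
        train_fraction: float = 0.8,
        random_state: int = 0,
        feature_kind: str = "trained",
    ):
        self.delays = delays
        self.lambda_grid = lambda_grid
        self.n_resamples = n_resamples
        self.train_fraction = train_fraction
        self.random_state = random_state
        self.feature_kind = feature_kind

    def fit(self, X, y):
        """Fit on raw (not yet delay-embedded) S-by-K features and S-by-N responses."""
        Xd = delay_embed(X, self.delays)
        model = fit_encoding_model(
            Xd,
            y,
            lambda_grid=self.lambda_grid,
            n_resamples=self.n_resamples,
            train_fraction=self.train_fraction,
            seed=self.random_state,
            delays=tuple(int(d) for d in self.delays),
            feature_kind=self.feature_kind,
        )
        self.model_ = model
        self.weights_ = model.weights
        self.lambda_ = model.lambda_
        self.cv_scores_ = np.asarray(model.fit_meta["validation_scores"])
        self.n_features_in_ = np.asarray(X).shape[1] if np.ndim(X) == 2 else (
            X.n_features if isinstance(X, SceneFeatureSeries) else None
        )
        return self

    def predict(self, X) -> np.ndarray:
        return delay_embed(X, self.delays) @ self.weights_

    def score(self, X, y, sample_weight=None) -> float:
        """Voxel-mean Pearson r between predictions and responses.

        Note: prediction accuracy in this field is a correlation, not R^2.
        """
        y = y.values if isinstance(y, ResponseSeries) else np.asarray(y, dtype=float)
        return float(_columnwise_pearson(self.predict(X), y).mean())

    def score_profile(self, X, y, q: float = 0.05) -> AccuracyProfile:
        """Full per-voxel accuracy profile (r, p, FDR mask) on held-out data."""
        return score_model(self.model_, delay_embed(X, self.delays), y, q=q)
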