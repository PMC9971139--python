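"""Dexterity, decision-making and performance scoring of exercises.

The scoring stack turns per-exercise kinematic features into three indices:

* **Dexterity** ``Dx = (∫ |jerk|² dt) · Δt⁵ / s²`` — the dimensionless
  integrated squared jerk of the whole exercise, normalized by duration and
  pathlength.  Lower is smoother / more focused.
* **Decision making** ``DM = wf1·n_J_extr′ + wf2·HE′ + wf3·(1/ST)′ +
  wf4·t_Firefly′`` — a weighted sum of the extreme-jerk-peak count, the
  handling-error count, the path tortuosity ``e^{-ln ST} = 1/ST`` and the
  fluorescence-mode time, each min–max normalized across the cohort (′).
  The weights lie on the 0.02-step simplex grid and are chosen to maximize
  the R² of the linear fit between DM and total pathlength, the field's
  benchmark measure of economy of movement.  The fluency sub-score is
  ``F = wf3·(1/ST)′ + wf4·t_Firefly′``.
* **Performance** ``PS = wf_Dx·P_Dx + wf_DM·P_DM`` — Dx and DM are first
  linearly rescaled into performance components anchored at the cohort's
  group medians (median of exercises *with* handling errors → 0.6, median
  *without* → 0.9, clamped to [0, 1]); the two component weights are the
  normalized absolute first-principal-component loadings of the standardized
  pair.

An exercise is rated proficient when its PS is not below mean − 2·SD of the
PS values of the error-free exercises (lower Z-bound only).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinematics import KinematicFeatures, Track, jerk_integral

WEIGHT_GRID_STEP = 0.02
ANCHOR_WITH_ERRORS = 0.6
ANCHOR_NO_ERRORS = 0.9
Z_MULTIPLIER = 2.0

#: Feature columns entering the DM index, in weight order wf1..wf4.
DM_FEATURES = ("n_J_extr", "HE", "inv_ST", "t_firefly_s")


@dataclass
class WeightFactors:
    """DM composition weights (wf1..wf4) and PS composition weights."""

    wf1: float
    wf2: float
    wf3: float
    wf4: float
    wf_dx: float = 0.5
    wf_dm: float = 0.5

    def __post_init__(self) -> None:
        w = np.array([self.wf1, self.wf2, self.wf3, self.wf4])
        if np.any(w < 0) or np.any(w > 1):
            raise ValueError("DM weights must lie in [0, 1]")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("DM weights must sum to 1")
        if abs(self.wf_dx + self.wf_dm - 1.0) > 1e-9:
            raise ValueError("wf_dx + wf_dm must equal 1")

    @property
    def dm_weights(self) -> np.ndarray:
        return np.array([self.wf1, self.wf2, self.wf3, self.wf4])


@dataclass
class ScoreSet:
    """Scores of one exercise."""

    exercise_id: str
    Dx: float
    DM: float
    F: float
    P_Dx: float
    P_DM: float
    PS: float
    proficient: bool


# ---------------------------------------------------------------------------
# Eq. 1 — dexterity
# ---------------------------------------------------------------------------

def dexterity_index(source, window: int = 7, polyorder: int = 3) -> float:
    """Dimensionless dexterity index of a track or feature record.

    For a :class:`Track` the jerk integral is computed directly; for a
    :class:`KinematicFeatures` record it is assembled from the stored
    ``J``, ``t_task_s`` and ``s_m``.
    """
    if isinstance(source, Track):
        _, core = jerk_integral(source, window=window, polyorder=polyorder)
        return core
    if isinstance(source, KinematicFeatures):
        if source.s_m == 0:
            raise ValueError("dexterity undefined for zero pathlength")
        return source.J * source.t_task_s**5 / source.s_m**2
    raise TypeError(f"expected Track or KinematicFeatures, got {type(source).__name__}")


def dexterity_from_frame(features: pd.DataFrame) -> np.ndarray:
    """Vectorized Dx = J · t_task⁵ / s² over a feature table."""
    s = features["s_m"].to_numpy(float)
    if np.any(s == 0):
        raise ValueError("dexterity undefined for zero pathlength")
    return features["J"].to_numpy(float) * features["t_task_s"].to_numpy(float) ** 5 / s**2


# ---------------------------------------------------------------------------
# Eq. 2 — decision making
# ---------------------------------------------------------------------------

def _dm_feature_matrix(features: pd.DataFrame, normalize: bool = True) -> np.ndarray:
    """(n, 4) matrix of DM inputs, optionally cohort min–max normalized.

    A feature that is constant across the cohort carries no information and
    normalizes to 0.
    """
    st = features["ST"].to_numpy(float)
    if np.any(st <= 0):
        raise ValueError("ST must be positive to form 1/ST")
    cols = np.column_stack([
        features["n_J_extr"].to_numpy(float),
        features["HE"].to_numpy(float),
        1.0 / st,
        features["t_firefly_s"].to_numpy(float),
    ])
    if not normalize:
        return cols
    if len(features) < 2:
        raise ValueError("cohort normalization needs at least 2 exercises")
    lo = cols.min(axis=0)
    span = cols.max(axis=0) - lo
    out = np.zeros_like(cols)
    nz = span > 0
    out[:, nz] = (cols[:, nz] - lo[nz]) / span[nz]
    return out


def decision_making_index(
    features: pd.DataFrame,
    wf: WeightFactors,
    normalize: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """DM index and fluency sub-score F per exercise.

    Returns ``(DM, F)`` arrays; see the module docstring for the formulas.
    """
    x = _dm_feature_matrix(features, normalize=normalize)
    w = wf.dm_weights
    dm = x @ w
    f = x[:, 2] * w[2] + x[:, 3] * w[3]
    return dm, f


def weight_grid(step: float = WEIGHT_GRID_STEP) -> np.ndarray:
    """All (wf1..wf4) on the simplex grid of the given step, lexicographic.

    With the default 0.02 step there are C(53, 3) = 23 426 grid points.
    """
    n = int(round(1.0 / step))
    pts = [
        (i, j, k, n - i - j - k)
        for i, j, k in itertools.product(range(n + 1), repeat=3)
        if i + j + k <= n
    ]
    return np.array(pts, dtype=float) * step


def optimize_weight_factors(
    features: pd.DataFrame,
    step: float = WEIGHT_GRID_STEP,
    normalize: bool = True,
) -> tuple[WeightFactors, float]:
    """Exhaustively search the weight simplex for the best DM composition.

    The objective is the R² of the univariate linear fit of total pathlength
    on the composite DM; the exhaustive grid search *is* the definition of
    the optimum, so the returned weights attain the global grid maximum.
    Ties go to the lexicographically smallest (wf1, wf2, wf3, wf4).

    Returns ``(weights, r_squared)``.
    """
    if len(features) < 5:
        raise ValueError("weight optimization needs at least 5 exercises")
    s = features["s_m"].to_numpy(float)
    if np.ptp(s) == 0:
        raise ValueError("pathlength has no variation; objective undefined")
    x = _dm_feature_matrix(features, normalize=normalize)
    grid = weight_grid(step)
    dm = x @ grid.T  # (n, G)
    dm_c = dm - dm.mean(axis=0)
    s_c = s - s.mean()
    denom = np.sqrt(np.sum(dm_c**2, axis=0) * np.sum(s_c**2))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, (dm_c.T @ s_c) / np.where(denom > 0, denom, 1.0), np.nan)
    r2 = r**2
    if np.all(np.isnan(r2)):
        raise ValueError("all candidate composites are constant; features carry no signal")
    best_r2 = np.nanmax(r2)
    # grid rows are lexicographically ordered, so the first within-tolerance
    # hit is the tie-break winner
    idx = int(np.argmax(r2 >= best_r2 - 1e-12))
    w = grid[idx]
    wf = WeightFactors(wf1=w[0], wf2=w[1], wf3=w[2], wf4=w[3])
    return wf, float(r2[idx])


# ---------------------------------------------------------------------------
# Anchored linear transform and Eq. 3
# ---------------------------------------------------------------------------

@dataclass
class AnchoredTransform:
    """Linear map fixed by two group-median anchor points.

    The cohort median of the index among exercises *with* handling errors
    maps to 0.6 and the median among error-free exercises to 0.9; values are
    clamped to [0, 1].  Since error-free exercises typically have the lower
    index, the map is decreasing in the raw index.
    """

    median_with_errors: float
    median_no_errors: float

    def __post_init__(self) -> None:
        if self.median_with_errors == self.median_no_errors:
            raise ValueError("group medians are equal; anchored transform undefined")

    def __call__(self, values) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        slope = (ANCHOR_NO_ERRORS - ANCHOR_WITH_ERRORS) / (
            self.median_no_errors - self.median_with_errors
        )
        out = ANCHOR_WITH_ERRORS + slope * (values - self.median_with_errors)
        return np.clip(out, 0.0, 1.0)


def fit_anchored_transform(values, has_error) -> AnchoredTransform:
    """Fit the anchored transform from cohort index values and error labels."""
    values = np.asarray(values, dtype=float)
    has_error = np.asarray(has_error, dtype=bool)
    if not np.any(has_error):
        raise ValueError("no exercises with handling errors; anchor undefined")
    if not np.any(~has_error):
        raise ValueError("no error-free exercises; anchor undefined")
    return AnchoredTransform(
        median_with_errors=float(np.median(values[has_error])),
        median_no_errors=float(np.median(values[~has_error])),
    )


def transform_components(
    dx_values, dm_values, has_error
) -> tuple[np.ndarray, np.ndarray, AnchoredTransform, AnchoredTransform]:
    """Map Dx and DM to performance components P_Dx and P_DM in [0, 1].

    Each index gets its own anchored transform fitted from its own group
    medians.  Returns ``(P_Dx, P_DM, dx_transform, dm_transform)``.
    """
    tx = fit_anchored_transform(dx_values, has_error)
    tm = fit_anchored_transform(dm_values, has_error)
    return tx(dx_values), tm(dm_values), tx, tm


def pca_weights(p_dx, p_dm, method: str = "correlation") -> tuple[float, float]:
    """PS composition weights from a principal component analysis.

    The first-principal-component loadings of the (by default standardized)
    component pair, taken in absolute value and normalized to sum 1.  For two
    standardized variables the leading eigenvector of the correlation matrix
    is (1, 1)/√2, so the weights are exactly (0.5, 0.5); the covariance-based
    variant (``method='covariance'``) lets unequal variances tilt them.
    """
    p_dx = np.asarray(p_dx, dtype=float)
    p_dm = np.asarray(p_dm, dtype=float)
    if len(p_dx) < 3:
        raise ValueError("PCA weighting needs at least 3 exercises")
    if np.std(p_dx) == 0 or np.std(p_dm) == 0:
        raise ValueError("zero variance in a performance component")
    if method == "correlation":
        x = np.column_stack([
            (p_dx - p_dx.mean()) / p_dx.std(),
            (p_dm - p_dm.mean()) / p_dm.std(),
        ])
    elif method == "covariance":
        x = np.column_stack([p_dx - p_dx.mean(), p_dm - p_dm.mean()])
    else:
        raise ValueError(f"unknown PCA method {method!r}")
    cov = np.cov(x, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(cov)
    loading = np.abs(eigvecs[:, np.argmax(eigvals)])
    loading = loading / loading.sum()
    return float(loading[0]), float(loading[1])


def performance_score(p_dx, p_dm, wf_dx: float, wf_dm: float) -> np.ndarray:
    """PS = wf_Dx·P_Dx + wf_DM·P_DM (convex combination, stays in [0, 1])."""
    if abs(wf_dx + wf_dm - 1.0) > 1e-9:
        raise ValueError("wf_dx + wf_dm must equal 1")
    return wf_dx * np.asarray(p_dx, float) + wf_dm * np.asarray(p_dm, float)


def proficiency_cutoff(
    ps_values, has_error, z: float = Z_MULTIPLIER
) -> tuple[float, np.ndarray]:
    """Proficiency cutoff and per-exercise flags via the Z-score method.

    The cutoff is mean − z·SD of the PS values of error-free exercises only
    (including error-laden exercises would underestimate proficiency).  Only
    the lower Z bound is applied: an upper bound would disqualify the best
    performers.  Every exercise with PS ≥ cutoff is flagged proficient.
    """
    ps_values = np.asarray(ps_values, dtype=float)
    has_error = np.asarray(has_error, dtype=bool)
    ref = ps_values[~has_error]
    if len(ref) < 3:
        raise ValueError("need at least 3 error-free exercises for the Z-score cutoff")
    sd = float(np.std(ref, ddof=1))
    mean = float(np.mean(ref))
    if sd == 0:
        warnings.warn("zero spread in the reference sample; cutoff equals its mean",
                      stacklevel=2)
    cutoff = mean - z * sd
    return cutoff, ps_values >= cutoff


# ---------------------------------------------------------------------------
# Full stack
# ---------------------------------------------------------------------------

def score_cohort(
    features: pd.DataFrame,
    step: float = WEIGHT_GRID_STEP,
    normalize_dm: bool = True,
    pca_method: str = "correlation",
    z: float = Z_MULTIPLIER,
) -> tuple[pd.DataFrame, dict]:
    """Run the whole scoring stack on a cohort feature table.

    Returns the scores table (``exercise_id, Dx, DM, F, P_Dx, P_DM, PS,
    proficient``) and a metadata dict with the fitted weights, anchors and
    cutoff.
    """
    dx = dexterity_from_frame(features)
    wf, r2 = optimize_weight_factors(features, step=step, normalize=normalize_dm)
    dm, f = decision_making_index(features, wf, normalize=normalize_dm)
    has_error = features["HE"].to_numpy() > 0
    p_dx, p_dm, tx, tm = transform_components(dx, dm, has_error)
    wf_dx, wf_dm = pca_weights(p_dx, p_dm, method=pca_method)
    ps = performance_score(p_dx, p_dm, wf_dx, wf_dm)
    cutoff, proficient = proficiency_cutoff(ps, has_error, z=z)
    scores = pd.DataFrame({
        "exercise_id": features["exercise_id"],
        "Dx": dx, "DM": dm, "F": f,
        "P_Dx": p_dx, "P_DM": p_dm, "PS": ps,
        "proficient": proficient,
    })
    metadata = {
        "dm_weights": {"wf1": wf.wf1, "wf2": wf.wf2, "wf3": wf.wf3, "wf4": wf.wf4},
        "dm_fit_r2": r2,
        "dx_anchors": {"median_with_errors": tx.median_with_errors,
                       "median_no_errors": tx.median_no_errors},
        "dm_anchors": {"median_with_errors": tm.median_with_errors,
                       "median_no_errors": tm.median_no_errors},
        "ps_weights": {"wf_dx": wf_dx, "wf_dm": wf_dm},
        "proficiency_cutoff": cutoff,
        "z_multiplier": z,
        "normalize_dm": normalize_dm,
        "pca_method": pca_method,
        "weight_grid_step": step,
    }
    return scores, metadata
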