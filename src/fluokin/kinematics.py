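"""Kinematic metric extraction from digitized instrument-tip tracks.

A :class:`Track` is a time-ordered sequence of 3D instrument-tip positions
(millimetres) with a per-sample imaging-mode flag (white light vs. fluorescence)
and optional lid-opening event labels.  From a track this module derives the
standard motion metrics used for surgical skill assessment:

* pathlength ``s`` and straightness index ``ST`` (net displacement / pathlength),
* mean speed ``v`` and mean acceleration magnitude ``a``,
* integrated squared jerk ``J`` and its dimensionless, scale-invariant core
  ``J * dt^5 / s^2`` (the dexterity index),
* the count of extreme jerk peaks (local maxima of the jerk-magnitude above a
  threshold, default 100 000 m/s^3),
* mean discrete (Menger) curvature ``Cr`` and angular dispersion ``AD``
  (1 minus the mean resultant length of step-direction unit vectors),
* task and fluorescence-mode times, and
* the 2D position-density map (% of time per spatial bin).

Positions are stored in mm but every derivative-based quantity is computed in
SI units (metres, seconds) so that the extreme-jerk threshold in m/s^3 applies
literally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import savgol_filter

MM_PER_M = 1000.0

#: Imaging-mode flags used throughout the package.
MODE_WHITE_LIGHT = 0
MODE_FIREFLY = 1

#: Recognised per-sample event labels.
EVENT_LABELS = ("none", "open_correct", "open_wrong")

#: Default extreme-jerk threshold in m/s^3.
EXTREME_JERK_THRESHOLD = 100_000.0


# ---------------------------------------------------------------------------
# Track container
# ---------------------------------------------------------------------------

@dataclass
class Track:
    """Time-stamped 3D instrument-tip positions with mode flags and events.

    Parameters
    ----------
    t_s : array of float
        Sample timestamps in seconds, strictly increasing.
    x_mm, y_mm, z_mm : arrays of float
        Tip coordinates in millimetres (image-plane x/y, depth z).
    mode : array of int
        Per-sample imaging mode, 0 = white light, 1 = fluorescence ("Firefly").
    event : array of str
        Per-sample event label: ``none``, ``open_correct`` or ``open_wrong``.
    """

    t_s: np.ndarray
    x_mm: np.ndarray
    y_mm: np.ndarray
    z_mm: np.ndarray
    mode: np.ndarray
    event: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.x_mm = np.asarray(self.x_mm, dtype=float)
        self.y_mm = np.asarray(self.y_mm, dtype=float)
        self.z_mm = np.asarray(self.z_mm, dtype=float)
        self.mode = np.asarray(self.mode, dtype=int)
        if self.event is None:
            self.event = np.full(self.t_s.shape, "none", dtype=object)
        else:
            self.event = np.asarray(self.event, dtype=object)
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        n = len(self.t_s)
        for name in ("x_mm", "y_mm", "z_mm", "mode", "event"):
            if len(getattr(self, name)) != n:
                raise ValueError(
                    f"track column '{name}' has length {len(getattr(self, name))}, "
                    f"expected {n}"
                )
        if n == 0:
            raise ValueError("empty track")
        if not np.all(np.isfinite(self.t_s)):
            raise ValueError("non-finite timestamps")
        if np.any(np.diff(self.t_s) <= 0):
            bad = int(np.argmax(np.diff(self.t_s) <= 0)) + 1
            raise ValueError(
                f"timestamps must be strictly increasing (violation at sample {bad})"
            )
        for name in ("x_mm", "y_mm", "z_mm"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"non-finite coordinates in '{name}'")
        if not np.all(np.isin(self.mode, (MODE_WHITE_LIGHT, MODE_FIREFLY))):
            raise ValueError("mode flags must be 0 (white light) or 1 (firefly)")
        bad_events = set(self.event) - set(EVENT_LABELS)
        if bad_events:
            raise ValueError(f"unknown event labels: {sorted(bad_events)}")

    # -- convenience --------------------------------------------------------
    def __len__(self) -> int:
        return len(self.t_s)

    @property
    def positions_mm(self) -> np.ndarray:
        """(n, 3) position array in millimetres."""
        return np.column_stack([self.x_mm, self.y_mm, self.z_mm])

    @property
    def positions_m(self) -> np.ndarray:
        """(n, 3) position array in metres (SI), used for all derivatives."""
        return self.positions_mm / MM_PER_M

    @property
    def dt_nominal(self) -> float:
        """Median sampling interval in seconds."""
        return float(np.median(np.diff(self.t_s)))


# ---------------------------------------------------------------------------
# Derivatives
# ---------------------------------------------------------------------------

def differentiate(
    track: Track,
    order: int,
    window: int = 7,
    polyorder: int = 3,
) -> np.ndarray:
    """Smoothed time-derivative of the tip position.

    Uses a local-polynomial (Savitzky-Golay) differentiator: within each
    sliding window of ``window`` samples a polynomial of degree ``polyorder``
    is fitted and its ``order``-th derivative evaluated at the window centre.
    Near the track ends the derivative is taken from the polynomial fitted to
    the first/last window, so no samples are discarded.  Third derivatives
    amplify measurement noise steeply, hence the smoothing window is exposed.

    Parameters
    ----------
    track : Track
    order : int
        Derivative order, 1 (velocity), 2 (acceleration) or 3 (jerk).
    window : int
        Window length in samples (odd, > polyorder).
    polyorder : int
        Local polynomial degree; must be >= ``order``.

    Returns
    -------
    (n, 3) array of the derivative in SI units (m/s^order).
    """
    if order not in (1, 2, 3):
        raise ValueError(f"order must be 1, 2 or 3, got {order}")
    if polyorder < order:
        raise ValueError(f"polyorder {polyorder} cannot support derivative order {order}")
    n = len(track)
    if window > n:
        raise ValueError(f"smoothing window ({window}) larger than track ({n} samples)")
    if window % 2 == 0:
        raise ValueError("window must be odd")
    dts = np.diff(track.t_s)
    dt = float(np.mean(dts))
    if np.max(np.abs(dts - dt)) > 1e-6 + 1e-3 * dt:
        raise ValueError("differentiate requires (near-)uniform sampling")
    pos = track.positions_m
    return savgol_filter(
        pos, window_length=window, polyorder=polyorder, deriv=order,
        delta=dt, axis=0, mode="interp",
    )


# ---------------------------------------------------------------------------
# Spatial metrics
# ---------------------------------------------------------------------------

def pathlength(track: Track) -> float:
    """Total traveled pathlength in metres (sum of Euclidean segment lengths)."""
    if len(track) < 2:
        warnings.warn("pathlength of a single-sample track is 0", stacklevel=2)
        return 0.0
    steps = np.diff(track.positions_m, axis=0)
    return float(np.sum(np.linalg.norm(steps, axis=1)))


def straightness_index(track: Track) -> float:
    """Straightness index ST = net displacement / pathlength, in (0, 1].

    Returns NaN (with a warning) for a degenerate zero-pathlength track.
    """
    s = pathlength(track)
    if s == 0.0:
        warnings.warn("straightness index undefined for zero pathlength", stacklevel=2)
        return float("nan")
    pos = track.positions_m
    net = float(np.linalg.norm(pos[-1] - pos[0]))
    return net / s


def curvature_and_dispersion(track: Track) -> tuple[float, float]:
    """Mean Menger curvature (1/m) and angular dispersion of a track.

    Curvature of each consecutive point triple is the reciprocal radius of its
    circumscribed circle, ``4 * area / (|ab| |bc| |ca|)``; collinear or
    degenerate triples contribute 0.  Angular dispersion is ``1 - R`` where
    ``R`` is the mean resultant length of the unit step-direction vectors:
    0 for a straight path, -> 1 for isotropic random steps.
    """
    if len(track) < 3:
        raise ValueError("curvature requires at least 3 samples")
    p = track.positions_m
    a, b, c = p[:-2], p[1:-1], p[2:]
    ab = np.linalg.norm(b - a, axis=1)
    bc = np.linalg.norm(c - b, axis=1)
    ca = np.linalg.norm(a - c, axis=1)
    cross = np.cross(b - a, c - a)
    area = 0.5 * np.linalg.norm(cross, axis=1)
    denom = ab * bc * ca
    with np.errstate(divide="ignore", invalid="ignore"):
        curv = np.where(denom > 0, 4.0 * area / np.where(denom > 0, denom, 1.0), 0.0)
    cr = float(np.mean(curv))

    steps = np.diff(p, axis=0)
    norms = np.linalg.norm(steps, axis=1)
    units = steps[norms > 0] / norms[norms > 0, None]
    if len(units) == 0:
        return cr, 0.0
    resultant = float(np.linalg.norm(np.mean(units, axis=0)))
    return cr, 1.0 - resultant


# ---------------------------------------------------------------------------
# Jerk metrics
# ---------------------------------------------------------------------------

def jerk_integral(
    track: Track,
    window: int = 7,
    polyorder: int = 3,
    endpoint_trim: int = 0,
) -> tuple[float, float]:
    """Integrated squared jerk and its dimensionless (dexterity) core.

    Computes ``J = integral of |jerk|^2 dt`` by trapezoidal rule over the
    smoothed third derivative, and the scale-invariant core
    ``J * dt^5 / s^2`` with ``dt`` the task duration and ``s`` the pathlength.
    The squared jerk magnitude equals the sum of the squared per-axis third
    derivatives.  All quantities SI.

    ``endpoint_trim`` optionally discards that many derivative samples at each
    end before integrating; the default keeps them, since the edge estimates
    come from full-window polynomial fits and a minimum-jerk reach has its
    largest jerk exactly at the endpoints.

    Returns
    -------
    (J, core) : tuple of float
        ``J`` in m^2 s^-5 and the dimensionless core.  ``(nan, nan)`` with a
        warning when the pathlength is zero.
    """
    s = pathlength(track)
    if s == 0.0:
        warnings.warn("jerk core undefined for zero pathlength", stacklevel=2)
        return float("nan"), float("nan")
    jerk = differentiate(track, order=3, window=window, polyorder=polyorder)
    sq = np.sum(jerk**2, axis=1)
    t = track.t_s
    if endpoint_trim > 0:
        sq = sq[endpoint_trim:-endpoint_trim]
        t = t[endpoint_trim:-endpoint_trim]
    j_int = float(np.trapezoid(sq, t))
    delta_t = float(track.t_s[-1] - track.t_s[0])
    return j_int, j_int * delta_t**5 / s**2


def count_extreme_jerk_peaks(
    track: Track,
    threshold: float = EXTREME_JERK_THRESHOLD,
    window: int = 7,
    polyorder: int = 3,
) -> int:
    """Number of extreme jerk peaks.

    A peak is a strict local maximum of the jerk-magnitude series (greater
    than both neighbours beyond floating-point jitter) that exceeds
    ``threshold`` (m/s^3).  A flat super-threshold plateau therefore contains
    no strict local maximum and counts zero.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    jerk = differentiate(track, order=3, window=window, polyorder=polyorder)
    mag = np.linalg.norm(jerk, axis=1)
    if len(mag) < 3:
        return 0
    interior = mag[1:-1]
    eps = 1e-9 * float(np.max(mag))  # exact plateaus carry float jitter
    peaks = (interior > mag[:-2] + eps) & (interior > mag[2:] + eps) & (interior > threshold)
    return int(np.sum(peaks))


# ---------------------------------------------------------------------------
# Temporal metrics
# ---------------------------------------------------------------------------

def mode_times(track: Track) -> tuple[float, float]:
    """Task time and fluorescence-mode time, both in seconds.

    ``t_task`` is the full span from first to last sample; ``t_firefly``
    attributes each inter-sample interval to the mode of its leading sample.
    """
    t_task = float(track.t_s[-1] - track.t_s[0])
    if len(track) < 2:
        return 0.0, 0.0
    dts = np.diff(track.t_s)
    t_firefly = float(np.sum(dts[track.mode[:-1] == MODE_FIREFLY]))
    return t_task, t_firefly


def position_density(
    track: Track,
    bin_size_mm: float = 10.0,
    extent_mm: tuple[float, float, float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Percentage of time spent per spatial bin in the XY (image) plane.

    Each inter-sample interval is assigned to the bin of its leading sample.
    With the 10 mm default the map reads as % of time per square centimetre.

    Parameters
    ----------
    track : Track
    bin_size_mm : float
        Square bin edge length.
    extent_mm : (xmin, xmax, ymin, ymax), optional
        Fixed map extent; defaults to the track's bounding box.

    Returns
    -------
    (density, x_edges, y_edges)
        ``density[i, j]`` is the percentage of total time in x-bin i, y-bin j;
        the bins sum to 100.
    """
    if bin_size_mm <= 0:
        raise ValueError("bin_size_mm must be positive")
    if len(track) < 2:
        # degenerate: all mass in one bin
        return np.array([[100.0]]), \
            np.array([track.x_mm[0] - bin_size_mm / 2, track.x_mm[0] + bin_size_mm / 2]), \
            np.array([track.y_mm[0] - bin_size_mm / 2, track.y_mm[0] + bin_size_mm / 2])
    x = track.x_mm[:-1]
    y = track.y_mm[:-1]
    weights = np.diff(track.t_s)
    if extent_mm is None:
        xmin, xmax = float(np.min(track.x_mm)), float(np.max(track.x_mm))
        ymin, ymax = float(np.min(track.y_mm)), float(np.max(track.y_mm))
    else:
        xmin, xmax, ymin, ymax = extent_mm
    # edges cover the extent with whole bins
    nx = max(1, int(np.ceil((xmax - xmin) / bin_size_mm)))
    ny = max(1, int(np.ceil((ymax - ymin) / bin_size_mm)))
    x_edges = xmin + bin_size_mm * np.arange(nx + 1)
    y_edges = ymin + bin_size_mm * np.arange(ny + 1)
    # keep boundary samples inside the outermost bins
    xc = np.clip(x, x_edges[0], np.nextafter(x_edges[-1], -np.inf))
    yc = np.clip(y, y_edges[0], np.nextafter(y_edges[-1], -np.inf))
    hist, _, _ = np.histogram2d(xc, yc, bins=[x_edges, y_edges], weights=weights)
    total = float(np.sum(weights))
    return hist / total * 100.0, x_edges, y_edges


def plot_position_density(
    density: np.ndarray,
    x_edges: np.ndarray,
    y_edges: np.ndarray,
    path: str,
) -> None:
    """Render a position-density map to a PNG heatmap."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    mesh = ax.pcolormesh(x_edges, y_edges, density.T, cmap="inferno")
    fig.colorbar(mesh, ax=ax, label="% time / bin")
    ax.set_xlabel("x [mm]")
    ax.set_ylabel("y [mm]")
    ax.set_aspect("equal")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Feature record
# ---------------------------------------------------------------------------

@dataclass
class KinematicFeatures:
    """Per-exercise kinematic metric record."""

    exercise_id: str
    s_m: float            # total pathlength [m]
    t_task_s: float       # task completion time [s]
    t_firefly_s: float    # time in fluorescence mode [s]
    v_mps: float          # mean speed [m/s]
    a_mps2: float         # mean |acceleration| [m/s^2]
    J: float              # integrated squared jerk [m^2 s^-5]
    n_J_extr: int         # extreme jerk peak count
    ST: float             # straightness index (0, 1]
    Cr: float             # mean Menger curvature [1/m]
    AD: float             # angular dispersion [0, 1]
    HE: int               # handling-error count
    sbr_min: float        # lowest target SBR in the exercise


def extract_features(
    track: Track,
    exercise_id: str = "",
    handling_errors: int | None = None,
    sbr_min: float = float("nan"),
    window: int = 7,
    polyorder: int = 3,
    jerk_threshold: float = EXTREME_JERK_THRESHOLD,
) -> KinematicFeatures:
    """Digitize one track into the full kinematic feature record.

    ``handling_errors`` defaults to the number of ``open_wrong`` events
    recorded on the track itself.
    """
    if handling_errors is None:
        handling_errors = int(np.sum(track.event == "open_wrong"))
    s = pathlength(track)
    t_task, t_firefly = mode_times(track)
    vel = differentiate(track, 1, window=window, polyorder=polyorder)
    acc = differentiate(track, 2, window=window, polyorder=polyorder)
    j_int, _ = jerk_integral(track, window=window, polyorder=polyorder)
    cr, ad = curvature_and_dispersion(track)
    return KinematicFeatures(
        exercise_id=exercise_id,
        s_m=s,
        t_task_s=t_task,
        t_firefly_s=t_firefly,
        v_mps=float(np.mean(np.linalg.norm(vel, axis=1))),
        a_mps2=float(np.mean(np.linalg.norm(acc, axis=1))),
        J=j_int,
        n_J_extr=count_extreme_jerk_peaks(
            track, threshold=jerk_threshold, window=window, polyorder=polyorder
        ),
        ST=straightness_index(track),
        Cr=cr,
        AD=ad,
        HE=handling_errors,
        sbr_min=sbr_min,
    )


def features_to_frame(features: Sequence[KinematicFeatures]):
    """Stack feature records into the canonical feature table (DataFrame)."""
    import pandas as pd

    return pd.DataFrame([vars(f) for f in features])
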