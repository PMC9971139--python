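"""Synthetic fluorescence-guided target-search exercises.

Emulates the structure of a grid-phantom exercise: a 4 x 7 silicone phantom
with 28 lidded locations hides a few fluorescent targets of varying intensity;
the operator scans in fluorescence ("Firefly") mode, and either sees a target
(high signal-to-background ratio, SBR) and reaches straight for its lid, or —
when the contrast is too low — falls back to opening candidate lids at random,
each wrong opening counting as a handling error.

Detection is psychometric: a target of contrast SBR is spotted with
probability Phi((SBR - theta) / sigma), a Gaussian-CDF curve centred on the
detection threshold ``theta``.  Reaches are minimum-jerk point-to-point
segments (the standard motor-control model, position profile
``10 tau^3 - 15 tau^4 + 6 tau^5``), which gives every downstream smoothness
metric a closed-form oracle.  Tracking noise is additive low-pass-filtered
Gaussian position noise.

The module also renders phantom frames (white-light and fluorescence mode) so
that the imaging stage can be exercised end-to-end without any recorded video.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.signal import butter, filtfilt
from scipy.stats import norm

from .kinematics import MODE_FIREFLY, MODE_WHITE_LIGHT, Track

N_ROWS_DEFAULT = 4
N_COLS_DEFAULT = 7


# ---------------------------------------------------------------------------
# Phantom layout
# ---------------------------------------------------------------------------

@dataclass
class PhantomLayout:
    """Grid-phantom geometry and hidden-target placement.

    ``target_slots`` holds ``(row, col, intensity)`` triples; ``intensity`` is
    the target's relative fluorescence level, calibrated so that the rendered
    and re-measured SBR approximately equals it (background = 1).
    """

    n_rows: int = N_ROWS_DEFAULT
    n_cols: int = N_COLS_DEFAULT
    pitch_mm: float = 25.0
    lid_radius_mm: float = 8.0
    target_slots: list[tuple[int, int, float]] = field(default_factory=list)
    origin_mm: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid dimensions must be positive")
        if self.pitch_mm <= 0 or self.lid_radius_mm <= 0:
            raise ValueError("pitch and lid radius must be positive")
        if not 0 <= len(self.target_slots) <= self.n_locations:
            raise ValueError(
                f"cannot place {len(self.target_slots)} targets on "
                f"{self.n_locations} locations"
            )
        seen = set()
        for row, col, intensity in self.target_slots:
            if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
                raise ValueError(f"target slot ({row}, {col}) outside the grid")
            if (row, col) in seen:
                raise ValueError(f"duplicate target slot ({row}, {col})")
            if intensity <= 0:
                raise ValueError("target intensity must be positive")
            seen.add((row, col))

    @property
    def n_locations(self) -> int:
        return self.n_rows * self.n_cols

    def lid_center_mm(self, row: int, col: int) -> np.ndarray:
        """Lid-centre coordinates (x, y) in mm, origin at the corner lid."""
        ox, oy = self.origin_mm
        return np.array([ox + col * self.pitch_mm, oy + row * self.pitch_mm])

    @property
    def all_slots(self) -> list[tuple[int, int]]:
        return [(r, c) for r in range(self.n_rows) for c in range(self.n_cols)]

    @property
    def target_positions(self) -> list[tuple[int, int]]:
        return [(r, c) for r, c, _ in self.target_slots]


def generate_phantom(
    n_targets: int = 3,
    intensity_range: tuple[float, float] = (1.0, 3.5),
    seed: int | np.random.Generator = 0,
    n_rows: int = N_ROWS_DEFAULT,
    n_cols: int = N_COLS_DEFAULT,
    pitch_mm: float = 25.0,
    lid_radius_mm: float = 8.0,
) -> PhantomLayout:
    """Place ``n_targets`` fluorescent targets uniformly at random on the grid.

    Intensities are drawn uniformly from ``intensity_range`` (relative units
    calibrated to rendered SBR, spanning roughly the 1.0-3.5 range observed
    with ICG dilution series).
    """
    lo, hi = intensity_range
    if not (0 < lo < hi):
        raise ValueError("intensity_range must be positive with low < high")
    n_locations = n_rows * n_cols
    if n_targets > n_locations:
        raise ValueError(
            f"cannot place {n_targets} targets on a grid with only "
            f"{n_locations} locations"
        )
    if n_targets < 1:
        raise ValueError("need at least one target")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    flat = rng.choice(n_locations, size=n_targets, replace=False)
    intensities = rng.uniform(lo, hi, size=n_targets)
    slots = [
        (int(f // n_cols), int(f % n_cols), float(i))
        for f, i in zip(flat, intensities)
    ]
    return PhantomLayout(
        n_rows=n_rows, n_cols=n_cols, pitch_mm=pitch_mm,
        lid_radius_mm=lid_radius_mm, target_slots=slots,
    )


# ---------------------------------------------------------------------------
# Trial configuration
# ---------------------------------------------------------------------------

@dataclass
class TrialConfig:
    """Parameters of one simulated exercise.

    theta : detection-threshold SBR of the psychometric curve (> 1; an SBR of
        1 is no contrast at all).
    sigma_psy : psychometric slope; detection probability is
        Phi((SBR - theta) / sigma_psy).
    reach_duration_s : duration of one minimum-jerk reach between lids.
    scan_time_s : fluorescence-mode dwell per detection attempt.
    lid_open_time_s : white-light dwell while opening a lid.
    motor_noise_sd_mm : s.d. of the additive position noise (tracking +
        tremor), low-pass filtered at ``noise_cutoff_hz``.
    refirefly_during_search : when True the operator re-enters fluorescence
        mode before every candidate opening during random search, accumulating
        additional Firefly time on hard targets.
    """

    n_targets: int = 3
    theta: float = 1.5
    sigma_psy: float = 0.1
    reach_duration_s: float = 1.0
    scan_time_s: float = 2.0
    lid_open_time_s: float = 0.5
    motor_noise_sd_mm: float = 0.5
    noise_cutoff_hz: float = 6.0
    sample_rate_hz: float = 30.0
    refirefly_during_search: bool = True
    hover_height_mm: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.theta <= 1:
            raise ValueError("theta must exceed 1 (SBR of 1 is no contrast)")
        if self.sigma_psy < 0:
            raise ValueError("sigma_psy must be non-negative")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if self.n_targets < 1:
            raise ValueError("n_targets must be >= 1")
        if min(self.reach_duration_s, self.scan_time_s, self.lid_open_time_s) <= 0:
            raise ValueError("durations must be positive")
        if self.motor_noise_sd_mm < 0:
            raise ValueError("motor_noise_sd_mm must be non-negative")


def detection_probability(sbr, theta: float, sigma_psy: float):
    """Psychometric detection probability Phi((SBR - theta) / sigma).

    Monotone non-decreasing in SBR; degenerates to a step at ``theta`` as
    sigma -> 0.
    """
    sbr = np.asarray(sbr, dtype=float)
    if sigma_psy == 0:
        return (sbr > theta).astype(float)
    return norm.cdf((sbr - theta) / sigma_psy)


# ---------------------------------------------------------------------------
# Trial simulation
# ---------------------------------------------------------------------------

@dataclass
class ExerciseRecord:
    """One simulated exercise: track, per-target SBRs and error bookkeeping."""

    exercise_id: str
    track: Track
    target_sbrs: list[float]
    handling_errors: int
    detected_in_firefly: list[bool]
    per_target_errors: list[int]
    layout: PhantomLayout
    seed: int


def _min_jerk_profile(tau: np.ndarray) -> np.ndarray:
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


class _TrackBuilder:
    """Accumulates trajectory segments sampled on a global uniform clock."""

    def __init__(self, start_pos: np.ndarray, rate_hz: float):
        self.dt = 1.0 / rate_hz
        self.pos: list[np.ndarray] = [np.asarray(start_pos, dtype=float)]
        self.mode: list[int] = [MODE_WHITE_LIGHT]
        self.event: list[str] = ["none"]

    @property
    def current(self) -> np.ndarray:
        return self.pos[-1]

    def dwell(self, duration_s: float, mode: int, event: str = "none") -> None:
        n = max(1, round(duration_s / self.dt))
        self.pos.extend([self.current.copy() for _ in range(n)])
        self.mode.extend([mode] * n)
        ev = ["none"] * n
        ev[0] = event
        self.event.extend(ev)

    def reach(self, target: np.ndarray, duration_s: float, mode: int) -> None:
        n = max(2, round(duration_s / self.dt))
        tau = np.arange(1, n + 1) / n
        prof = _min_jerk_profile(tau)
        seg = self.current + prof[:, None] * (np.asarray(target, float) - self.current)
        self.pos.extend(list(seg))
        self.mode.extend([mode] * n)
        self.event.extend(["none"] * n)

    def build(self, rng: np.random.Generator, noise_sd_mm: float,
              cutoff_hz: float) -> Track:
        pos = np.array(self.pos)
        n = len(pos)
        if noise_sd_mm > 0 and n > 18:  # filtfilt needs padding room
            noise = rng.standard_normal((n, 3))
            b, a = butter(4, cutoff_hz, fs=1.0 / self.dt)
            noise = filtfilt(b, a, noise, axis=0)
            sd = noise.std(axis=0, keepdims=True)
            sd[sd == 0] = 1.0
            pos = pos + noise / sd * noise_sd_mm
        t = np.arange(n) * self.dt
        return Track(
            t_s=t, x_mm=pos[:, 0], y_mm=pos[:, 1], z_mm=pos[:, 2],
            mode=np.array(self.mode), event=np.array(self.event, dtype=object),
        )


def simulate_trial(
    layout: PhantomLayout,
    config: TrialConfig,
    rng: np.random.Generator | None = None,
    exercise_id: str = "ex",
) -> ExerciseRecord:
    """Simulate one exercise on a given phantom layout.

    For each hidden target in turn the operator scans in fluorescence mode
    (``scan_time_s``); with probability Phi((SBR - theta)/sigma) the target is
    seen and a single minimum-jerk reach opens the correct lid.  Otherwise the
    operator searches: uniformly random still-closed lids are opened one by
    one (each preceded by another fluorescence scan when
    ``refirefly_during_search``) until the target's lid turns up; every
    non-target opening is logged as a handling error.

    The track starts hovering over the grid centre and is sampled at
    ``sample_rate_hz`` with additive low-pass-filtered Gaussian noise.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    targets = layout.target_positions
    if len(targets) == 0:
        raise ValueError("layout has no targets")
    sbrs = [i for _, _, i in layout.target_slots]

    center = layout.lid_center_mm(
        (layout.n_rows - 1) / 2, (layout.n_cols - 1) / 2  # type: ignore[arg-type]
    )
    home = np.array([center[0], center[1], config.hover_height_mm])
    builder = _TrackBuilder(home, config.sample_rate_hz)

    def lid_pos(slot: tuple[int, int]) -> np.ndarray:
        xy = layout.lid_center_mm(*slot)
        return np.array([xy[0], xy[1], 0.0])

    opened: set[tuple[int, int]] = set()
    detected_flags: list[bool] = []
    per_target_errors: list[int] = []
    handling_errors = 0

    for idx, slot in enumerate(targets):
        sbr = sbrs[idx]
        p = float(detection_probability(sbr, config.theta, config.sigma_psy))
        detected = bool(rng.random() < p)
        detected_flags.append(detected)
        errors_this_target = 0
        builder.dwell(config.scan_time_s, MODE_FIREFLY)
        if detected:
            builder.reach(lid_pos(slot), config.reach_duration_s, MODE_WHITE_LIGHT)
            builder.dwell(config.lid_open_time_s, MODE_WHITE_LIGHT, "open_correct")
            opened.add(slot)
        else:
            remaining_targets = set(targets[idx + 1:])
            while slot not in opened:
                candidates = [
                    s for s in layout.all_slots
                    if s not in opened and s not in remaining_targets
                ]
                choice = candidates[int(rng.integers(len(candidates)))]
                if config.refirefly_during_search:
                    builder.dwell(config.scan_time_s, MODE_FIREFLY)
                builder.reach(lid_pos(choice), config.reach_duration_s, MODE_WHITE_LIGHT)
                if choice == slot:
                    builder.dwell(config.lid_open_time_s, MODE_WHITE_LIGHT, "open_correct")
                else:
                    builder.dwell(config.lid_open_time_s, MODE_WHITE_LIGHT, "open_wrong")
                    errors_this_target += 1
                    handling_errors += 1
                opened.add(choice)
        per_target_errors.append(errors_this_target)

    track = builder.build(rng, config.motor_noise_sd_mm, config.noise_cutoff_hz)
    return ExerciseRecord(
        exercise_id=exercise_id,
        track=track,
        target_sbrs=[float(s) for s in sbrs],
        handling_errors=handling_errors,
        detected_in_firefly=detected_flags,
        per_target_errors=per_target_errors,
        layout=layout,
        seed=int(config.seed),
    )


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def derive_seeds(master_seed: int, n: int, stream: str = "cohort") -> list[int]:
    """Reproducible per-exercise seeds below 2**31, derived from one master."""
    import zlib

    ss = np.random.SeedSequence([int(master_seed), zlib.crc32(stream.encode())])
    return [int(s) % 2**31 for s in ss.generate_state(n, dtype=np.uint64)]


def generate_cohort(
    n_exercises: int,
    config: TrialConfig | None = None,
    intensity_range: tuple[float, float] = (1.0, 3.5),
    out_dir: str | Path | None = None,
    master_seed: int | None = None,
) -> list[ExerciseRecord]:
    """Generate a cohort of exercises; optionally write track CSVs + manifest.

    Every exercise gets a freshly randomized phantom (target placement and
    intensities) and its own seed derived from the master, so target SBRs
    across the cohort span the configured intensity range.
    """
    if n_exercises < 1:
        raise ValueError("n_exercises must be >= 1")
    config = config or TrialConfig()
    if master_seed is None:
        master_seed = config.seed
    seeds = derive_seeds(master_seed, n_exercises)
    records = []
    for i, seed in enumerate(seeds):
        rng = np.random.default_rng(seed)
        layout = generate_phantom(
            n_targets=config.n_targets, intensity_range=intensity_range, seed=rng,
        )
        cfg = replace(config, seed=seed)
        rec = simulate_trial(layout, cfg, rng=rng, exercise_id=f"ex{i:04d}")
        records.append(rec)
    if out_dir is not None:
        _write_cohort(records, Path(out_dir))
    return records


def _write_cohort(records: list[ExerciseRecord], out_dir: Path) -> None:
    import pandas as pd

    from .io import write_track

    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create cohort directory {out_dir}: {exc}") from exc
    rows = []
    n_targets = max(len(r.target_sbrs) for r in records)
    for rec in records:
        track_path = out_dir / f"{rec.exercise_id}_track.csv"
        write_track(rec.track, track_path)
        row = {"exercise_id": rec.exercise_id, "track_path": track_path.name}
        for j in range(n_targets):
            row[f"sbr_{j + 1}"] = (
                round(rec.target_sbrs[j], 6) if j < len(rec.target_sbrs) else ""
            )
        row["handling_errors"] = rec.handling_errors
        row["seed"] = rec.seed
        rows.append(row)
    pd.DataFrame(rows).to_csv(out_dir / "manifest.csv", index=False)


# ---------------------------------------------------------------------------
# Frame rendering
# ---------------------------------------------------------------------------

@dataclass
class OpticsParams:
    """Rendering parameters for synthetic phantom frames."""

    px_per_mm: float = 2.0
    margin_mm: float = 15.0
    background_green: float = 40.0     # fluorescence-mode background level
    blob_core_frac: float = 0.5        # flat-top core radius / lid radius
    blob_skirt_frac: float = 0.5       # Gaussian skirt sigma / lid radius
    white_light_bg: float = 200.0
    lid_gray: float = 120.0
    specular_spots: list[tuple[float, float, float]] = field(default_factory=list)
    # each spot: (x_mm, y_mm, radius_mm), rendered saturated white


def render_frame(
    layout: PhantomLayout,
    mode: str,
    optics: OpticsParams | None = None,
) -> np.ndarray:
    """Render an RGB frame of the phantom (uint8, H x W x 3).

    ``firefly`` mode shows each target as a green blob on a dark background:
    a flat-top core of radius ``blob_core_frac * lid_radius`` at peak level
    ``background_green * intensity`` with a Gaussian skirt, so that a small
    ROI at the lid centre measures SBR equal to the target intensity.
    ``white_light`` shows the grid lids with no fluorescence.  Optional
    saturated white specular spots emulate reflections of the excitation
    light.
    """
    if mode not in ("white_light", "firefly"):
        raise ValueError(f"mode must be 'white_light' or 'firefly', got {mode!r}")
    optics = optics or OpticsParams()
    if optics.px_per_mm <= 0:
        raise ValueError("px_per_mm must be positive")
    width_mm = (layout.n_cols - 1) * layout.pitch_mm + 2 * optics.margin_mm
    height_mm = (layout.n_rows - 1) * layout.pitch_mm + 2 * optics.margin_mm
    w = int(round(width_mm * optics.px_per_mm))
    h = int(round(height_mm * optics.px_per_mm))
    if w < 1 or h < 1:
        raise ValueError("non-positive image dimensions")

    yy, xx = np.mgrid[0:h, 0:w]
    # mm coordinates of each pixel (origin at corner lid centre)
    x_mm = xx / optics.px_per_mm - optics.margin_mm
    y_mm = yy / optics.px_per_mm - optics.margin_mm

    img = np.zeros((h, w, 3), dtype=float)
    if mode == "white_light":
        img[:] = optics.white_light_bg
        for r, c in layout.all_slots:
            cx, cy = layout.lid_center_mm(r, c)
            d2 = (x_mm - cx) ** 2 + (y_mm - cy) ** 2
            img[d2 <= layout.lid_radius_mm**2] = optics.lid_gray
    else:
        bg = optics.background_green
        green = np.full((h, w), bg)
        core = optics.blob_core_frac * layout.lid_radius_mm
        sigma = optics.blob_skirt_frac * layout.lid_radius_mm
        for r, c, intensity in layout.target_slots:
            cx, cy = layout.lid_center_mm(r, c)
            d = np.hypot(x_mm - cx, y_mm - cy)
            excess = np.maximum(0.0, d - core)
            green += bg * (intensity - 1.0) * np.exp(-(excess**2) / (2 * sigma**2))
        img[:, :, 1] = green
        img[:, :, 0] = 0.1 * green
        img[:, :, 2] = 0.1 * green

    for sx, sy, sr in optics.specular_spots:
        d2 = (x_mm - sx) ** 2 + (y_mm - sy) ** 2
        img[d2 <= sr**2] = 255.0

    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def lid_center_px(
    layout: PhantomLayout, row: int, col: int, optics: OpticsParams | None = None
) -> tuple[float, float]:
    """Pixel coordinates (x, y) of a lid centre in a rendered frame."""
    optics = optics or OpticsParams()
    cx, cy = layout.lid_center_mm(row, col)
    return (
        (cx + optics.margin_mm) * optics.px_per_mm,
        (cy + optics.margin_mm) * optics.px_per_mm,
    )
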