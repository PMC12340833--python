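"""Synthetic timelapse and FRAP generators with known ground truth.

Focal adhesions appear in fluorescence timelapses as diffraction-limited
punctae whose intensity rises as the adhesion assembles and falls as it
disassembles. The generator renders each puncta as an isotropic 2-D Gaussian
whose peak follows a logistic rise multiplied, past its peak time, by an
exponential decay — the same two functional forms the analysis fits — on top
of a smoothed, translating disk standing in for the cell body. Because every
generative parameter is recorded, the detection, tracking, kinetics,
colocalization and FRAP stages can all be validated by parameter recovery.

Noise model: Poisson shot noise on the clean image plus additive Gaussian
read noise of standard deviation ``noise_sd``. Setting ``noise_sd = 0``
switches off all stochastic noise (shot noise included) so the rendered frame
is an exact evaluation of the model, which the oracle tests rely on.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .stack import ImageStack

__all__ = [
    "SimConfig",
    "FrapSimConfig",
    "GroundTruthTable",
    "FrapTrace",
    "kinetic_curve",
    "half_max_crossings",
    "simulate_timelapse",
    "simulate_frap_trace",
]


# --------------------------------------------------------------------------
# configuration


@dataclass
class SimConfig:
    """Parameters of one synthetic two-channel adhesion timelapse.

    Defaults follow the acquisition the analysis targets: 750 ms frame
    interval for 3 minutes (240 frames), ~0.1 µm pixels, punctae of ~2.5 px
    Gaussian width. Kinetic-rate and amplitude ranges are sampled uniformly
    per puncta.
    """

    image_shape: tuple[int, int] = (160, 160)
    n_frames: int = 240
    frame_interval_s: float = 0.75
    pixel_size_um: float = 0.1
    n_punctae: int = 30
    puncta_sigma_px: float = 2.5
    assembly_rate_range: tuple[float, float] = (0.2, 0.8)
    disassembly_rate_range: tuple[float, float] = (0.05, 0.15)
    peak_amplitude_range: tuple[float, float] = (80.0, 150.0)
    coloc_fraction: float = 0.5
    cell_speed_um_s: float = 0.05
    background_level: float = 20.0
    cell_body_intensity: float = 15.0
    noise_sd: float = 10.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 10:
            raise ValueError("n_frames must be >= 10")
        if not 0.0 <= self.coloc_fraction <= 1.0:
            raise ValueError("coloc_fraction must lie in [0, 1]")
        for name in ("assembly_rate_range", "disassembly_rate_range", "peak_amplitude_range"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"{name} must be strictly positive with lo <= hi")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        if self.n_punctae < 0:
            raise ValueError("n_punctae must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        # Density guard: tracking is ill-posed when punctae crowd closer than
        # ~4 Gaussian widths. Expected nearest-neighbour distance for n uniform
        # points in area A is 0.5 * sqrt(A / n).
        if self.n_punctae > 1:
            margin = 0.15
            rows = self.image_shape[0] * (1 - 2 * margin)
            cols = self.image_shape[1] * (1 - 2 * margin)
            mean_nn = 0.5 * np.sqrt(rows * cols / self.n_punctae)
            if mean_nn < 4 * self.puncta_sigma_px:
                raise ValueError(
                    f"puncta density too high: expected nearest-neighbour spacing "
                    f"{mean_nn:.1f} px < 4*sigma = {4 * self.puncta_sigma_px:.1f} px"
                )

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        d = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        import yaml

        with open(path) as fh:
            d = yaml.safe_load(fh)
        for key in ("image_shape", "assembly_rate_range", "disassembly_rate_range", "peak_amplitude_range"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class FrapSimConfig:
    """Parameters of one synthetic FRAP trace.

    Defaults follow the target acquisition: 3 prebleach frames, 500 ms frame
    interval, 45 s of postbleach imaging. ``k_true`` is the recovery rate
    constant (1/s) and ``immobile_fraction_true`` the fraction of fluorescence
    that does not return within the trace.
    """

    n_prebleach: int = 3
    frame_interval_s: float = 0.5
    total_postbleach_s: float = 45.0
    k_true: float = 0.35
    immobile_fraction_true: float = 0.5
    bleach_depth: float = 0.8
    background_level: float = 100.0
    noise_sd: float = 0.02
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.immobile_fraction_true <= 1.0:
            raise ValueError("immobile_fraction_true must lie in [0, 1]")
        if self.k_true <= 0:
            raise ValueError("k_true must be positive")
        if not 0.0 < self.bleach_depth <= 1.0:
            raise ValueError("bleach_depth must lie in (0, 1]")
        if self.n_prebleach < 1:
            raise ValueError("n_prebleach must be >= 1")
        if self.frame_interval_s <= 0 or self.total_postbleach_s <= 0:
            raise ValueError("time parameters must be positive")


# --------------------------------------------------------------------------
# ground truth containers


@dataclass
class GroundTruthTable:
    """Per-object generative parameters plus per-frame true centroids.

    ``objects`` has one row per puncta (kinetic parameters, half-max times,
    colocalization label); ``positions`` is long-format with one row per
    (object, frame) while the object's true intensity is nonzero.
    """

    objects: pd.DataFrame
    positions: pd.DataFrame

    OBJECT_COLUMNS = (
        "object_id",
        "birth_time_s",
        "peak_amplitude",
        "assembly_rate",
        "disassembly_rate",
        "t_mid_s",
        "t_peak_s",
        "half_max_entry_time_s",
        "half_max_exit_time_s",
        "true_lifetime_s",
        "channel2_positive",
        "row",
        "col",
    )

    def __post_init__(self) -> None:
        if len(self.objects):
            life = self.objects["true_lifetime_s"]
            if (life <= 0).any():
                raise ValueError("true_lifetime_s must be positive")
            bad = (
                self.objects["half_max_entry_time_s"]
                >= self.objects["half_max_exit_time_s"]
            )
            if bad.any():
                raise ValueError("half-max entry must precede exit")

    def __len__(self) -> int:
        return len(self.objects)

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        self.objects.to_csv(path, index=False)
        self.positions.to_csv(
            path.with_name(path.stem + "_positions" + path.suffix), index=False
        )


@dataclass
class FrapTrace:
    """One bleach-spot intensity time course with its background control.

    Times are in seconds with the first postbleach frame at t = 0 and
    prebleach frames at negative times. Intensities are raw (integrated
    density) units; normalization happens downstream.
    """

    times_s: np.ndarray
    bleach_intensity: np.ndarray
    background_intensity: np.ndarray
    n_prebleach: int

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.bleach_intensity = np.asarray(self.bleach_intensity, dtype=float)
        self.background_intensity = np.asarray(self.background_intensity, dtype=float)
        n = len(self.times_s)
        if len(self.bleach_intensity) != n or len(self.background_intensity) != n:
            raise ValueError("trace arrays must share a length")
        if self.n_prebleach < 1:
            raise ValueError("n_prebleach must be >= 1")
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.i_pre - self.i_bg_pre <= 0:
            raise ValueError("prebleach signal must exceed background")

    @property
    def i_pre(self) -> float:
        """Bleach-ROI intensity at the initial prebleach frame."""
        return float(self.bleach_intensity[0])

    @property
    def i_bg_pre(self) -> float:
        """Background-ROI intensity at the initial prebleach frame."""
        return float(self.background_intensity[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.times_s,
                "bleach_intensity": self.bleach_intensity,
                "background_intensity": self.background_intensity,
                "prebleach": np.arange(len(self.times_s)) < self.n_prebleach,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FrapTrace":
        n_pre = int(df["prebleach"].sum()) if "prebleach" in df else int((df["time_s"] < 0).sum())
        return cls(
            times_s=df["time_s"].to_numpy(),
            bleach_intensity=df["bleach_intensity"].to_numpy(),
            background_intensity=df["background_intensity"].to_numpy(),
            n_prebleach=n_pre,
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "FrapTrace":
        return cls.from_frame(pd.read_csv(path))


# --------------------------------------------------------------------------
# kinetic model


def kinetic_curve(
    t: np.ndarray | float,
    peak_amplitude: float,
    assembly_rate: float,
    t_mid: float,
    disassembly_rate: float,
    t_peak: float,
) -> np.ndarray:
    """Generative adhesion intensity: logistic rise times exponential fall.

    ``A / (1 + exp(-r_a (t - t_mid)))`` throughout, multiplied by
    ``exp(-r_d (t - t_peak))`` for ``t > t_peak``. The curve is continuous at
    ``t_peak`` and attains its maximum there.
    """
    t = np.asarray(t, dtype=float)
    rise = peak_amplitude / (1.0 + np.exp(-assembly_rate * (t - t_mid)))
    fall = np.where(t > t_peak, np.exp(-disassembly_rate * (t - t_peak)), 1.0)
    return rise * fall


def half_max_crossings(
    curve: np.ndarray, times: np.ndarray
) -> tuple[float, float]:
    """First/last times a sampled curve is at or above half its maximum.

    Linear interpolation between bracketing samples; this brute-force scan is
    the oracle the fitted lifetime is checked against.
    """
    curve = np.asarray(curve, dtype=float)
    times = np.asarray(times, dtype=float)
    half = curve.max() / 2.0
    above = curve >= half
    if not above.any():
        raise ValueError("curve never reaches half max")
    idx = np.nonzero(above)[0]
    i0, i1 = idx[0], idx[-1]
    if i0 == 0:
        entry = times[0]
    else:
        f = (half - curve[i0 - 1]) / (curve[i0] - curve[i0 - 1])
        entry = times[i0 - 1] + f * (times[i0] - times[i0 - 1])
    if i1 == len(curve) - 1:
        exit_ = times[-1]
    else:
        f = (curve[i1] - half) / (curve[i1] - curve[i1 + 1])
        exit_ = times[i1] + f * (times[i1 + 1] - times[i1])
    return float(entry), float(exit_)


# --------------------------------------------------------------------------
# timelapse simulation


def _sample_positions(
    rng: np.random.Generator,
    shape: tuple[int, int],
    n: int,
    min_dist: float,
    margin_frac: float = 0.15,
) -> np.ndarray:
    """Uniform positions in the central region with a minimum pairwise distance."""
    lo_r, hi_r = shape[0] * margin_frac, shape[0] * (1 - margin_frac)
    lo_c, hi_c = shape[1] * margin_frac, shape[1] * (1 - margin_frac)
    positions: list[np.ndarray] = []
    attempts = 0
    while len(positions) < n:
        cand = np.array([rng.uniform(lo_r, hi_r), rng.uniform(lo_c, hi_c)])
        if all(np.hypot(*(cand - p)) >= min_dist for p in positions):
            positions.append(cand)
        attempts += 1
        if attempts > 20000:
            raise RuntimeError("could not place punctae at the requested density")
    return np.array(positions).reshape(n, 2)


def _render_gaussian(frame: np.ndarray, row: float, col: float, amp: float, sigma: float) -> None:
    """Add an isotropic Gaussian spot in place, over a ±4σ window."""
    if amp <= 0:
        return
    half = int(np.ceil(4 * sigma))
    r0, r1 = int(np.floor(row)) - half, int(np.floor(row)) + half + 1
    c0, c1 = int(np.floor(col)) - half, int(np.floor(col)) + half + 1
    r0, r1 = max(r0, 0), min(r1, frame.shape[0])
    c0, c1 = max(c0, 0), min(c1, frame.shape[1])
    if r0 >= r1 or c0 >= c1:
        return
    rr = np.arange(r0, r1)[:, None] - row
    cc = np.arange(c0, c1)[None, :] - col
    frame[r0:r1, c0:c1] += amp * np.exp(-(rr**2 + cc**2) / (2 * sigma**2))


def _cell_body_path(
    rng: np.random.Generator, config: SimConfig
) -> np.ndarray:
    """Per-frame (row, col) centre of the translating cell body.

    Constant drift at ``cell_speed_um_s`` along a random heading plus small
    Gaussian jitter; the path is reflected at a margin so the body stays in
    the field of view.
    """
    shape = np.array(config.image_shape, dtype=float)
    speed_px = config.cell_speed_um_s * config.frame_interval_s / config.pixel_size_um
    heading = rng.uniform(0, 2 * np.pi)
    step = speed_px * np.array([np.sin(heading), np.cos(heading)])
    jitter = rng.normal(0.0, 0.15 * max(speed_px, 0.05), size=(config.n_frames, 2))
    pos = shape / 2.0
    lo = shape * 0.25
    hi = shape * 0.75
    path = np.empty((config.n_frames, 2))
    for f in range(config.n_frames):
        path[f] = pos
        pos = pos + step + jitter[f]
        for ax in range(2):
            if pos[ax] < lo[ax]:
                pos[ax] = 2 * lo[ax] - pos[ax]
                step[ax] = -step[ax]
            elif pos[ax] > hi[ax]:
                pos[ax] = 2 * hi[ax] - pos[ax]
                step[ax] = -step[ax]
    return path


def _render_cell_body(frame: np.ndarray, centre: np.ndarray, radius: float, amp: float) -> None:
    """Add a smooth-edged disk (the cell body) in place."""
    rr = np.arange(frame.shape[0])[:, None] - centre[0]
    cc = np.arange(frame.shape[1])[None, :] - centre[1]
    dist = np.sqrt(rr**2 + cc**2)
    edge = radius * 0.15
    frame += amp / (1.0 + np.exp((dist - radius) / edge))


def simulate_timelapse(config: SimConfig) -> tuple[ImageStack, GroundTruthTable]:
    """Render a two-channel adhesion timelapse with full ground truth.

    Channel 0 carries every puncta; channel 1 mirrors channel 0 on exactly
    ``round(coloc_fraction * n_punctae)`` punctae (the channel2-positive
    class). Both channels share the cell-body background. Identical seeds give
    bit-identical output.
    """
    rng = np.random.default_rng(config.rng_seed)
    n = config.n_punctae
    dt = config.frame_interval_s
    times = np.arange(config.n_frames) * dt

    positions = (
        _sample_positions(rng, config.image_shape, n, 4 * config.puncta_sigma_px)
        if n
        else np.empty((0, 2))
    )
    amps = rng.uniform(*config.peak_amplitude_range, size=n)
    r_a = rng.uniform(*config.assembly_rate_range, size=n)
    r_d = rng.uniform(*config.disassembly_rate_range, size=n)
    total_s = config.n_frames * dt
    t_mid = rng.uniform(0.2 * total_s, 0.45 * total_s, size=n)
    t_peak = t_mid + 6.0 / r_a  # logistic ~99.8% saturated before decay begins
    birth = t_mid - 6.0 / r_a

    n_pos = int(round(config.coloc_fraction * n))
    ch2_positive = np.zeros(n, dtype=bool)
    if n_pos:
        ch2_positive[rng.choice(n, size=n_pos, replace=False)] = True

    # ground-truth half-max times from a dense scan of the generative curve
    rows = []
    pos_rows = []
    fine_t = np.arange(0.0, total_s, dt / 50.0)
    for i in range(n):
        fine = kinetic_curve(fine_t, amps[i], r_a[i], t_mid[i], r_d[i], t_peak[i])
        entry, exit_ = half_max_crossings(fine, fine_t)
        rows.append(
            {
                "object_id": i,
                "birth_time_s": birth[i],
                "peak_amplitude": amps[i],
                "assembly_rate": r_a[i],
                "disassembly_rate": r_d[i],
                "t_mid_s": t_mid[i],
                "t_peak_s": t_peak[i],
                "half_max_entry_time_s": entry,
                "half_max_exit_time_s": exit_,
                "true_lifetime_s": exit_ - entry,
                "channel2_positive": bool(ch2_positive[i]),
                "row": positions[i, 0],
                "col": positions[i, 1],
            }
        )
        amp_t = kinetic_curve(times, amps[i], r_a[i], t_mid[i], r_d[i], t_peak[i])
        for f in np.nonzero(amp_t > 1e-3)[0]:
            pos_rows.append(
                {
                    "object_id": i,
                    "frame": int(f),
                    "row": positions[i, 0],
                    "col": positions[i, 1],
                    "true_intensity": amp_t[f],
                }
            )
    objects = pd.DataFrame(rows, columns=list(GroundTruthTable.OBJECT_COLUMNS))
    positions_df = pd.DataFrame(
        pos_rows, columns=["object_id", "frame", "row", "col", "true_intensity"]
    )
    truth = GroundTruthTable(objects=objects, positions=positions_df)

    body_path = _cell_body_path(rng, config)
    body_radius = 0.3 * min(config.image_shape)

    data = np.zeros((config.n_frames, *config.image_shape, 2), dtype=float)
    for f in range(config.n_frames):
        for c in range(2):
            frame = data[f, :, :, c]
            frame += config.background_level
            _render_cell_body(frame, body_path[f], body_radius, config.cell_body_intensity)
        amp_t = (
            kinetic_curve(times[f], amps, r_a, t_mid, r_d, t_peak) if n else np.empty(0)
        )
        for i in range(n):
            if amp_t[i] <= 1e-3:
                continue
            _render_gaussian(
                data[f, :, :, 0], positions[i, 0], positions[i, 1], amp_t[i], config.puncta_sigma_px
            )
            if ch2_positive[i]:
                _render_gaussian(
                    data[f, :, :, 1], positions[i, 0], positions[i, 1], amp_t[i], config.puncta_sigma_px
                )
    if config.noise_sd > 0:
        data = rng.poisson(np.clip(data, 0, None)).astype(float)
        data += rng.normal(0.0, config.noise_sd, size=data.shape)
        np.clip(data, 0.0, None, out=data)  # camera counts are nonnegative
    stack = ImageStack(data, config.frame_interval_s, config.pixel_size_um)
    return stack, truth


# --------------------------------------------------------------------------
# FRAP simulation


def simulate_frap_trace(config: FrapSimConfig) -> tuple[FrapTrace, dict]:
    """Generate one FRAP trace and the true parameters behind it.

    The noiseless relative fluorescence follows
    ``Y0 + (P - Y0)(1 - exp(-k t))`` postbleach, with floor
    ``Y0 = 1 - bleach_depth`` and plateau ``P`` chosen so that the
    immobile-fraction formula, evaluated on the noiseless curve at the final
    time point of the trace, returns ``immobile_fraction_true`` exactly.
    Raw intensities are background + RFI-scaled signal; Gaussian noise of sd
    ``noise_sd`` is added to the bleach-ROI signal.
    """
    rng = np.random.default_rng(config.rng_seed)
    dt = config.frame_interval_s
    pre_times = -dt * np.arange(config.n_prebleach, 0, -1)
    n_post = int(np.floor(config.total_postbleach_s / dt)) + 1
    post_times = dt * np.arange(n_post)
    times = np.concatenate([pre_times, post_times])

    y0 = 1.0 - config.bleach_depth
    t_final = post_times[-1]
    recovery_final = 1.0 - np.exp(-config.k_true * t_final)
    # plateau such that IMf( curve(t_final) ) == immobile_fraction_true
    plateau = y0 + (1.0 - config.immobile_fraction_true) * (1.0 - y0) / recovery_final
    rfi_true = np.concatenate(
        [
            np.ones_like(pre_times),
            y0 + (plateau - y0) * (1.0 - np.exp(-config.k_true * post_times)),
        ]
    )
    noise = (
        rng.normal(0.0, config.noise_sd, size=rfi_true.shape)
        if config.noise_sd > 0
        else 0.0
    )
    bleach = config.background_level + rfi_true + noise
    background = np.full_like(bleach, config.background_level)
    # normalization anchor: the initial prebleach frame is noise-free so that
    # RFI is defined relative to the true prebleach level
    bleach[0] = config.background_level + 1.0
    trace = FrapTrace(
        times_s=times,
        bleach_intensity=bleach,
        background_intensity=background,
        n_prebleach=config.n_prebleach,
    )
    true = {
        "k_true": config.k_true,
        "t_half_true": float(np.log(2.0) / config.k_true),
        "immobile_fraction_true": config.immobile_fraction_true,
        "y0_true": y0,
        "plateau_true": float(plateau),
        "t_final_s": float(t_final),
    }
    return trace, true


def write_truth_bundle(
    out_dir: str | Path, config: SimConfig, stack: ImageStack, truth: GroundTruthTable
) -> None:
    """Convenience writer: TIFF stack + truth CSVs + config JSON in one place."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stack.save_tiff(out_dir / "stack.tif")
    truth.to_csv(out_dir / "truth.csv")
    with open(out_dir / "config.json", "w") as fh:
        json.dump(dataclasses.asdict(config), fh, indent=2, default=list)
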