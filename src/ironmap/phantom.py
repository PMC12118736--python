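"""Digital left-ventricle phantom and synthetic data generators.

This module produces every synthetic input the analysis chain consumes:

* a ring-shaped short-axis LV myocardium partitioned into three contiguous
  angular coronary territories (LCX / LAD / RCA), with ground-truth tissue
  parameter maps (S0, T1, T2, R2*) and an optional MPIO-induced R2*
  increment confined to one territory;
* magnitude MR image series under multi-echo, inversion-recovery and
  T2-prepared acquisition schedules, with Rician noise;
* two-channel immunofluorescence image pairs with a controllable P-selectin
  coverage fraction;
* flow-chamber particle track tables with stationary (bound) and transient
  tracks;
* bright-field spot fields with dark MPIO-like particles on a textured
  background.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

__all__ = [
    "BACKGROUND",
    "TERRITORY_CODES",
    "TERRITORY_NAMES",
    "IN_VIVO_MULTI_ECHO_TES_MS",
    "EX_VIVO_MULTI_ECHO_TES_MS",
    "DEFAULT_IR_TIS_MS",
    "T2PREP_TIMES_MS",
    "AcquisitionSchedule",
    "PhantomTruth",
    "EchoSeries",
    "IFImagePair",
    "TrackTable",
    "SpotField",
    "make_phantom",
    "simulate_series",
    "make_if_pair",
    "make_tracks",
    "make_spot_field",
]

# Territory label codes used in every label volume.
BACKGROUND = 0
TERRITORY_CODES = {"LCX": 1, "LAD": 2, "RCA": 3}
TERRITORY_NAMES = {v: k for k, v in TERRITORY_CODES.items()}

# Acquisition time schedules of the study protocols (ms).
IN_VIVO_MULTI_ECHO_TES_MS = (2.4, 6.0, 9.5, 13.0)
EX_VIVO_MULTI_ECHO_TES_MS = (3.4, 9.8, 17.1)
DEFAULT_IR_TIS_MS = (100.0, 200.0, 400.0, 800.0, 1200.0, 1800.0, 2800.0, 4500.0)
T2PREP_TIMES_MS = (0.0, 30.0, 40.0)

_SCHEDULE_KINDS = ("multi_echo", "inversion_recovery", "t2_prep")


@dataclass(frozen=True)
class AcquisitionSchedule:
    """An ordered list of acquisition times with its signal model kind.

    Parameters
    ----------
    kind : {"multi_echo", "inversion_recovery", "t2_prep"}
        Which preparation the times refer to (TE, TI or T2-prep duration).
    times : tuple of float
        Acquisition times in milliseconds, strictly increasing, all >= 0.
        At least 2 times (3 for inversion recovery).
    noise_sigma : float
        Standard deviation of the complex Gaussian noise added per channel
        before the magnitude operation, in signal units.
    model_name : str
        Free-text label for provenance (e.g. "multi-echo FLASH").
    """

    kind: str
    times: tuple[float, ...]
    noise_sigma: float = 0.0
    model_name: str = ""

    def __post_init__(self) -> None:
        if self.kind not in _SCHEDULE_KINDS:
            raise ValueError(f"unknown schedule kind {self.kind!r}")
        times = tuple(float(t) for t in self.times)
        object.__setattr__(self, "times", times)
        min_len = 3 if self.kind == "inversion_recovery" else 2
        if len(times) < min_len:
            raise ValueError(
                f"{self.kind} schedule needs >= {min_len} times, got {len(times)}"
            )
        arr = np.asarray(times)
        if np.any(arr < 0) or np.any(np.diff(arr) <= 0):
            raise ValueError("schedule times must be >= 0 and strictly increasing")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    @property
    def times_ms(self) -> np.ndarray:
        return np.asarray(self.times, dtype=float)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "times_ms": list(self.times),
            "noise_sigma": self.noise_sigma,
            "model_name": self.model_name,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionSchedule":
        return cls(
            kind=d["kind"],
            times=tuple(d["times_ms"]),
            noise_sigma=float(d.get("noise_sigma", 0.0)),
            model_name=d.get("model_name", ""),
        )


@dataclass
class PhantomTruth:
    """Ground-truth parameter maps and territory geometry of one phantom.

    Maps are 2D (one short-axis slice) or 3D (slice stack / ex vivo volume),
    row-major with pixel-centered 0-based coordinates.  Units: T1/T2 in ms,
    R2* and field offsets in 1/s, pixel size in mm.
    """

    grid_shape: tuple[int, ...]
    pixel_size: float
    myocardium_mask: np.ndarray
    territory_labels: np.ndarray
    s0_map: np.ndarray
    t1_map: np.ndarray
    t2_map: np.ndarray
    r2star_map: np.ndarray
    mpio_delta_r2star: float
    lesion_territory: str
    field_offset_map: np.ndarray
    seed: int

    @property
    def t2star_map(self) -> np.ndarray:
        """Effective T2* in ms (1000 / R2*[1/s]); inf outside the tissue."""
        with np.errstate(divide="ignore"):
            return np.where(self.r2star_map > 0, 1000.0 / self.r2star_map, np.inf)

    def territory_mask(self, territory: str) -> np.ndarray:
        return self.territory_labels == TERRITORY_CODES[territory]


@dataclass
class EchoSeries:
    """A stack of magnitude images, one per acquisition time."""

    images: np.ndarray  # shape (n_times, *grid_shape), all >= 0
    schedule: AcquisitionSchedule
    pixel_size: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=float)
        if self.images.shape[0] != len(self.schedule.times):
            raise ValueError("number of images must equal number of schedule times")
        if np.any(self.images < 0):
            raise ValueError("magnitude images must be non-negative")

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.images.shape[1:]


@dataclass
class IFImagePair:
    """Two-channel immunofluorescence image: red = P-selectin stain,
    green = tissue autofluorescence."""

    red_channel: np.ndarray
    green_channel: np.ndarray
    is_remote: bool
    true_coverage: float
    true_tissue_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.red_channel.shape != self.green_channel.shape:
            raise ValueError("channels must share shape")
        if not 0.0 <= self.true_coverage <= 1.0:
            raise ValueError("true_coverage must be in [0, 1]")


@dataclass
class TrackTable:
    """Particle tracks from a flow-chamber recording.

    ``frame`` holds one row per observation (track_id, t_s, x_um, y_um);
    ``true_labels`` maps track_id -> bound ground truth (synthetic only).
    """

    frame: pd.DataFrame
    field_extent: tuple[float, float]  # um
    duration: float  # s
    true_labels: dict[int, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = ["track_id", "t_s", "x_um", "y_um"]
        if list(self.frame.columns[:4]) != required:
            raise ValueError(f"track table must have columns {required}")


@dataclass
class SpotField:
    """A bright-field image with dark particle spots and their true centers."""

    image: np.ndarray
    centers: np.ndarray  # (n, 2) array of (row, col)
    spot_radius_px: float


def _smooth_unit_field(shape: tuple[int, ...], rng: np.random.Generator,
                       smoothness: float = 6.0) -> np.ndarray:
    """Zero-mean, unit-std smooth random field (for within-tissue variation)."""
    raw = gaussian_filter(rng.standard_normal(shape), sigma=smoothness)
    sd = raw.std()
    if sd == 0:
        return np.zeros(shape)
    return (raw - raw.mean()) / sd


def make_phantom(
    grid_shape: Sequence[int] = (64, 64),
    pixel_size: float = 1.0,
    *,
    inner_radius_frac: float = 0.22,
    outer_radius_frac: float = 0.42,
    territory_start_deg: float = 90.0,
    territory_extents_deg: Sequence[float] = (120.0, 120.0, 120.0),
    s0: float = 100.0,
    t1_ms: float = 1200.0,
    t2_ms: float = 45.0,
    t2star_ms: float = 30.0,
    tissue_variation: float = 0.0,
    field_offset_amplitude: float = 0.0,
    lesion: str = "none",
    mpio_delta_r2star: float = 0.0,
    seed: int = 0,
) -> PhantomTruth:
    """Build a ring-shaped LV phantom with three angular coronary territories.

    The myocardium is an annulus centered in the in-plane grid, split into
    three contiguous angular sectors labelled LCX, LAD and RCA (120 deg each
    by default, starting at ``territory_start_deg`` and proceeding
    counter-clockwise).  Tissue parameters are piecewise constant at the
    stated base values, optionally modulated by a smooth within-tissue
    variation of fractional standard deviation ``tissue_variation``.  When
    ``lesion`` names a territory, ``mpio_delta_r2star`` (1/s) is added to
    R2* inside it, emulating bound iron-oxide contrast.

    ``field_offset_amplitude`` scales a smooth macroscopic field-inhomogeneity
    map (R2' contribution, 1/s) that adds to the decay rate seen by the
    multi-echo signal but is not part of the tissue R2*.

    For 3D shapes the annulus geometry is replicated along the last axis
    (short-axis slice stack).
    """
    grid_shape = tuple(int(n) for n in grid_shape)
    if len(grid_shape) not in (2, 3):
        raise ValueError("grid_shape must be 2D or 3D")
    if grid_shape[0] < 32 or grid_shape[1] < 32:
        raise ValueError("in-plane grid must be at least 32x32 to contain the ring")
    if lesion != "none" and lesion not in TERRITORY_CODES:
        raise ValueError(f"unknown territory name {lesion!r}")
    if mpio_delta_r2star < 0:
        raise ValueError("mpio_delta_r2star must be >= 0")
    extents = tuple(float(e) for e in territory_extents_deg)
    if len(extents) != 3 or not np.isclose(sum(extents), 360.0):
        raise ValueError("territory_extents_deg must be three angles summing to 360")
    if not 0 < inner_radius_frac < outer_radius_frac <= 0.5:
        raise ValueError("need 0 < inner_radius_frac < outer_radius_frac <= 0.5")

    ny, nx = grid_shape[0], grid_shape[1]
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    yy, xx = np.mgrid[0:ny, 0:nx]
    r = np.hypot(yy - cy, xx - cx)
    half = min(ny, nx) / 2.0
    ring2d = (r >= inner_radius_frac * 2 * half) & (r <= outer_radius_frac * 2 * half)
    # guard: the annulus must contain at least a few pixels per territory
    if ring2d.sum() < 60:
        raise ValueError("grid too small to contain the myocardial ring")

    theta = np.degrees(np.arctan2(-(yy - cy), xx - cx))  # ccw, 0 deg = +x
    rel = np.mod(theta - territory_start_deg, 360.0)
    labels2d = np.zeros((ny, nx), dtype=np.int16)
    bounds = np.cumsum((0.0,) + extents)
    for code, (lo, hi) in zip(
        (TERRITORY_CODES["LCX"], TERRITORY_CODES["LAD"], TERRITORY_CODES["RCA"]),
        zip(bounds[:-1], bounds[1:]),
    ):
        labels2d[ring2d & (rel >= lo) & (rel < hi)] = code

    if len(grid_shape) == 3:
        mask = np.repeat(ring2d[:, :, None], grid_shape[2], axis=2)
        labels = np.repeat(labels2d[:, :, None], grid_shape[2], axis=2)
    else:
        mask = ring2d
        labels = labels2d

    rng = np.random.default_rng(seed)
    base_r2star = 1000.0 / t2star_ms

    def vary(base: float) -> np.ndarray:
        out = np.full(grid_shape, float(base))
        if tissue_variation > 0:
            out = out * (1.0 + tissue_variation * _smooth_unit_field(grid_shape, rng))
            out = np.clip(out, base * 0.05, None)
        return np.where(mask, out, 0.0)

    s0_map = vary(s0)
    t1_map = vary(t1_ms)
    t2_map = vary(t2_ms)
    r2star_map = vary(base_r2star)
    if lesion != "none" and mpio_delta_r2star > 0:
        r2star_map = np.where(
            labels == TERRITORY_CODES[lesion], r2star_map + mpio_delta_r2star, r2star_map
        )

    field_offset_map = np.zeros(grid_shape)
    if field_offset_amplitude > 0:
        field_offset_map = field_offset_amplitude * _smooth_unit_field(
            grid_shape, rng, smoothness=max(8.0, min(ny, nx) / 8.0)
        )

    return PhantomTruth(
        grid_shape=grid_shape,
        pixel_size=float(pixel_size),
        myocardium_mask=mask,
        territory_labels=labels,
        s0_map=s0_map,
        t1_map=t1_map,
        t2_map=t2_map,
        r2star_map=r2star_map,
        mpio_delta_r2star=float(mpio_delta_r2star),
        lesion_territory=lesion,
        field_offset_map=field_offset_map,
        seed=int(seed),
    )


def noiseless_signal(truth: PhantomTruth, schedule: AcquisitionSchedule) -> np.ndarray:
    """Exact per-pixel model signal for each schedule time (no noise).

    multi_echo          S(TE) = S0 * exp(-TE * (R2* + field_offset))
    inversion_recovery  S(TI) = |S0 * (1 - 2 * exp(-TI / T1))|
    t2_prep             S(tau) = S0 * exp(-tau / T2)
    """
    times = schedule.times_ms[(...,) + (None,) * len(truth.grid_shape)]
    s0 = truth.s0_map[None]
    with np.errstate(divide="ignore", invalid="ignore"):
        if schedule.kind == "multi_echo":
            rate_per_ms = (truth.r2star_map + truth.field_offset_map)[None] / 1000.0
            sig = s0 * np.exp(-times * rate_per_ms)
        elif schedule.kind == "inversion_recovery":
            t1 = np.where(truth.t1_map > 0, truth.t1_map, np.inf)[None]
            sig = np.abs(s0 * (1.0 - 2.0 * np.exp(-times / t1)))
        else:  # t2_prep
            t2 = np.where(truth.t2_map > 0, truth.t2_map, np.inf)[None]
            sig = s0 * np.exp(-times / t2)
    return np.nan_to_num(sig, nan=0.0, posinf=0.0)


def simulate_series(
    truth: PhantomTruth, schedule: AcquisitionSchedule, seed: int = 0
) -> EchoSeries:
    """Simulate a magnitude image series under ``schedule`` with Rician noise.

    Independent complex Gaussian noise of per-channel standard deviation
    ``schedule.noise_sigma`` is added to the noiseless model signal (taken as
    the real channel) and the modulus is returned, yielding Rician magnitude
    statistics; ``noise_sigma=0`` returns the exact model values.
    """
    for m in (truth.s0_map, truth.t1_map, truth.t2_map, truth.r2star_map,
              truth.field_offset_map):
        if not np.all(np.isfinite(m)):
            raise ValueError("phantom maps must be finite")
    sig = noiseless_signal(truth, schedule)
    sigma = schedule.noise_sigma
    if sigma > 0:
        rng = np.random.default_rng(seed)
        re = sig + sigma * rng.standard_normal(sig.shape)
        im = sigma * rng.standard_normal(sig.shape)
        sig = np.hypot(re, im)
    return EchoSeries(
        images=sig,
        schedule=schedule,
        pixel_size=truth.pixel_size,
        provenance={"phantom_seed": truth.seed, "noise_seed": int(seed)},
    )


def make_if_pair(
    shape: Sequence[int] = (256, 256),
    tissue_fraction: float = 0.6,
    coverage: float = 0.3,
    *,
    is_remote: bool = False,
    tissue_intensity: float = 120.0,
    tissue_sigma: float = 8.0,
    positive_intensity: float = 200.0,
    positive_sigma: float = 5.0,
    speckle_intensity: float = 20.0,
    speckle_sigma: float = 4.0,
    speckle_density: float = 0.10,
    seed: int = 0,
) -> IFImagePair:
    """Generate a two-channel IF image with a known P-selectin coverage.

    The green (autofluorescence) channel is bright on a single connected
    tissue region occupying approximately ``tissue_fraction`` of the image.
    In the red channel, a random subset of tissue pixels of size
    ``round(coverage * tissue_area)`` receives supra-threshold stain
    intensity (~``positive_intensity``); a sparse sub-threshold speckle
    (fraction ``speckle_density`` of all pixels, ~``speckle_intensity``)
    models unspecific background fluorescence, and the remaining pixels are
    exactly zero.  ``true_coverage`` records the realized marked fraction.
    """
    if not 0.0 <= coverage <= 1.0:
        raise ValueError("coverage must be in [0, 1]")
    if not 0.0 < tissue_fraction <= 1.0:
        raise ValueError("tissue_fraction must be in (0, 1]")
    shape = tuple(int(n) for n in shape)
    rng = np.random.default_rng(seed)
    ny, nx = shape
    n_pix = ny * nx

    # Connected tissue region: a centered disk with mildly irregular boundary.
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    yy, xx = np.mgrid[0:ny, 0:nx]
    r = np.hypot(yy - cy, xx - cx)
    base_radius = np.sqrt(tissue_fraction * n_pix / np.pi)
    ang = np.arctan2(yy - cy, xx - cx)
    wobble = sum(
        rng.uniform(-0.04, 0.04) * np.cos(k * ang + rng.uniform(0, 2 * np.pi))
        for k in (2, 3, 5)
    )
    tissue = r <= base_radius * (1.0 + wobble)
    tissue_area = int(tissue.sum())
    if tissue_area == 0:
        raise ValueError("tissue_fraction too small for this image size")

    green = np.zeros(shape)
    green[tissue] = np.clip(
        tissue_intensity + tissue_sigma * rng.standard_normal(tissue_area), 1.0, None
    )

    red = np.zeros(shape)
    speckle = rng.random(shape) < speckle_density
    n_speckle = int(speckle.sum())
    red[speckle] = np.clip(
        speckle_intensity + speckle_sigma * rng.standard_normal(n_speckle), 0.5, None
    )
    n_marked = int(round(coverage * tissue_area))
    tissue_idx = np.flatnonzero(tissue.ravel())
    marked = rng.choice(tissue_idx, size=n_marked, replace=False)
    red.ravel()[marked] = np.clip(
        positive_intensity + positive_sigma * rng.standard_normal(n_marked), 1.0, None
    )

    return IFImagePair(
        red_channel=red,
        green_channel=green,
        is_remote=is_remote,
        true_coverage=n_marked / tissue_area,
        true_tissue_mask=tissue,
    )


def make_tracks(
    n_bound: int,
    n_transient: int,
    dwell_range_s: tuple[float, float] = (11.0, 20.0),
    field_extent_um: tuple[float, float] = (450.0, 350.0),
    frame_interval_s: float = 0.1,
    *,
    duration_s: float = 60.0,
    jitter_um: float = 0.2,
    transient_dwell_range_s: tuple[float, float] = (1.0, 8.0),
    speed_um_s: tuple[float, float] = (20.0, 60.0),
    seed: int = 0,
) -> TrackTable:
    """Generate particle tracks over a flow-chamber field of view.

    Bound tracks are stationary (per-frame jitter within ``jitter_um`` of an
    anchor point) for a dwell drawn from ``dwell_range_s`` (>= 10 s for the
    defaults) fully inside the observation window.  Transient tracks either
    translate continuously at a flow speed from ``speed_um_s`` or stick for a
    short dwell drawn from ``transient_dwell_range_s`` (< 10 s) before being
    lost.  Ground-truth bound labels are stored on the table.
    """
    if dwell_range_s[0] <= 0 or transient_dwell_range_s[0] <= 0:
        raise ValueError("dwell ranges must be positive")
    if frame_interval_s <= 0:
        raise ValueError("frame_interval_s must be > 0")
    rng = np.random.default_rng(seed)
    fx, fy = field_extent_um
    rows: list[tuple[int, float, float, float]] = []
    labels: dict[int, bool] = {}
    tid = 0

    def stationary_track(tid: int, dwell: float) -> None:
        start = rng.uniform(0.0, max(duration_s - dwell, 0.0))
        n_frames = int(round(dwell / frame_interval_s)) + 1
        ax = rng.uniform(5.0, fx - 5.0)
        ay = rng.uniform(5.0, fy - 5.0)
        for k in range(n_frames):
            ang = rng.uniform(0, 2 * np.pi)
            rad = rng.uniform(0, jitter_um)
            rows.append(
                (tid, start + k * frame_interval_s,
                 float(np.clip(ax + rad * np.cos(ang), 0, fx)),
                 float(np.clip(ay + rad * np.sin(ang), 0, fy)))
            )

    for _ in range(n_bound):
        stationary_track(tid, rng.uniform(*dwell_range_s))
        labels[tid] = True
        tid += 1

    for j in range(n_transient):
        if j % 2 == 0:  # mover: crosses the field with the flow
            speed = rng.uniform(*speed_um_s)
            y0 = rng.uniform(5.0, fy - 5.0)
            start = rng.uniform(0.0, duration_s * 0.8)
            t = start
            x = 0.0
            while x <= fx and t <= duration_s:
                rows.append((tid, t, x, float(np.clip(
                    y0 + rng.uniform(-0.5, 0.5), 0, fy))))
                x += speed * frame_interval_s
                t += frame_interval_s
        else:  # short-stick: stationary below the dwell rule, then lost
            stationary_track(tid, rng.uniform(*transient_dwell_range_s))
        labels[tid] = False
        tid += 1

    frame = pd.DataFrame(rows, columns=["track_id", "t_s", "x_um", "y_um"])
    frame = frame.sort_values(["track_id", "t_s"], kind="stable").reset_index(drop=True)
    return TrackTable(
        frame=frame,
        field_extent=tuple(float(v) for v in field_extent_um),
        duration=float(duration_s),
        true_labels=labels,
    )


def make_spot_field(
    shape: Sequence[int] = (256, 256),
    n_spots: int = 30,
    spot_radius_px: float = 3.0,
    *,
    background_level: float = 200.0,
    texture_amplitude: float = 6.0,
    pixel_noise: float = 1.5,
    spot_depth: float = 120.0,
    min_separation_factor: float = 2.5,
    max_tries: int = 20000,
    seed: int = 0,
) -> SpotField:
    """Render dark circular spots on a brighter textured background.

    Spots are placed by rejection sampling so that center-to-center distances
    exceed ``min_separation_factor * 2 * spot_radius_px`` (non-overlapping
    with margin); raises if placement fails within ``max_tries`` attempts.
    """
    if n_spots < 0:
        raise ValueError("n_spots must be >= 0")
    shape = tuple(int(n) for n in shape)
    rng = np.random.default_rng(seed)
    ny, nx = shape
    img = (
        background_level
        + texture_amplitude * _smooth_unit_field(shape, rng, smoothness=10.0)
        + pixel_noise * rng.standard_normal(shape)
    )

    margin = spot_radius_px + 3.0
    min_d = min_separation_factor * 2.0 * spot_radius_px
    centers: list[tuple[float, float]] = []
    tries = 0
    while len(centers) < n_spots:
        if tries >= max_tries:
            raise RuntimeError(
                f"could not place {n_spots} non-overlapping spots in {max_tries} tries"
            )
        tries += 1
        cy = rng.uniform(margin, ny - 1 - margin)
        cx = rng.uniform(margin, nx - 1 - margin)
        if all(np.hypot(cy - a, cx - b) >= min_d for a, b in centers):
            centers.append((cy, cx))

    yy, xx = np.mgrid[0:ny, 0:nx]
    for cy, cx in centers:
        d = np.hypot(yy - cy, xx - cx)
        # soft-edged disk: flat core, ~1 px anti-aliased rim
        profile = np.clip(spot_radius_px + 0.5 - d, 0.0, 1.0)
        img -= spot_depth * profile
    img = np.clip(img, 0.0, None)

    return SpotField(
        image=img,
        centers=np.asarray(centers, dtype=float).reshape(-1, 2),
        spot_radius_px=float(spot_radius_px),
    )


def apply_mpio(truth: PhantomTruth, delta_r2star: float, lesion: str) -> PhantomTruth:
    """Return a copy of ``truth`` with an MPIO R2* increment in ``lesion``."""
    if lesion not in TERRITORY_CODES:
        raise ValueError(f"unknown territory name {lesion!r}")
    if delta_r2star < 0:
        raise ValueError("delta_r2star must be >= 0")
    new_r2star = np.where(
        truth.territory_labels == TERRITORY_CODES[lesion],
        truth.r2star_map + delta_r2star,
        truth.r2star_map,
    )
    return replace(
        truth,
        r2star_map=new_r2star,
        mpio_delta_r2star=float(delta_r2star),
        lesion_territory=lesion,
    )
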