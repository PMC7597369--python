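"""Spot localization, diffusion-gated track linking, and nuclear filtering.

Positions are continuous, in nanometers, with the origin at the field corner;
a pixel's integer index is its coordinate (column j sits at x = j * pixel
size). Track durations follow the spanned-frames convention
``(last_frame - first_frame + 1) * frame_interval`` so the shortest
observable binding event lasts exactly one frame interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit, linear_sum_assignment
from shapely.geometry import Point, Polygon
from shapely.prepared import prep
from skimage.feature import peak_local_max

from .config import ConfigError


@dataclass
class Localization:
    """One fitted spot."""

    channel: str
    frame: int
    t: float  # s
    x: float  # nm
    y: float  # nm
    intensity: float
    sigma: float = np.nan  # fitted PSF width, nm


@dataclass
class Track:
    """A genomic binding event: ordered localizations of one molecule."""

    id: int
    channel: str
    localizations: list[Localization]
    frame_interval: float
    censored_start: bool = False
    censored_end: bool = False

    @property
    def start_t(self) -> float:
        return self.localizations[0].t

    @property
    def end_t(self) -> float:
        return self.localizations[-1].t

    @property
    def first_frame(self) -> int:
        return self.localizations[0].frame

    @property
    def last_frame(self) -> int:
        return self.localizations[-1].frame

    @property
    def duration(self) -> float:
        return (self.last_frame - self.first_frame + 1) * self.frame_interval

    @property
    def mean_x(self) -> float:
        return float(np.mean([l.x for l in self.localizations]))

    @property
    def mean_y(self) -> float:
        return float(np.mean([l.y for l in self.localizations]))

    def mean_position(self, t0: float | None = None, t1: float | None = None):
        """Time-averaged position, optionally over a closed time window.

        Falls back to the whole-track mean if no localization falls in the
        window (possible across blink gaps).
        """
        if t0 is None and t1 is None:
            return self.mean_x, self.mean_y
        xs = [l for l in self.localizations
              if (t0 is None or l.t >= t0 - 1e-9) and (t1 is None or l.t <= t1 + 1e-9)]
        if not xs:
            return self.mean_x, self.mean_y
        return (float(np.mean([l.x for l in xs])), float(np.mean([l.y for l in xs])))


@dataclass
class NucleusROI:
    """Nuclear boundary as a closed polygon in nm."""

    polygon: Polygon

    def __post_init__(self) -> None:
        if not self.polygon.is_valid or self.polygon.area <= 0:
            raise ConfigError("ROI polygon must be valid with nonzero area")
        self._prepared = prep(self.polygon)

    @classmethod
    def from_vertices(cls, vertices) -> "NucleusROI":
        return cls(Polygon(vertices))

    @classmethod
    def ellipse(cls, cx: float, cy: float, a: float, b: float, n: int = 128):
        th = np.linspace(0, 2 * np.pi, n, endpoint=False)
        return cls(Polygon(np.column_stack([cx + a * np.cos(th), cy + b * np.sin(th)])))

    @property
    def area(self) -> float:
        return float(self.polygon.area)

    def contains(self, x: float, y: float) -> bool:
        """Inside-or-on-boundary test."""
        return bool(self._prepared.covers(Point(x, y)))

    def sample_uniform(self, n: int, rng: np.random.Generator):
        """Uniform points inside the polygon via bounding-box rejection."""
        minx, miny, maxx, maxy = self.polygon.bounds
        xs = np.empty(n)
        ys = np.empty(n)
        filled = 0
        while filled < n:
            m = max(2 * (n - filled), 16)
            cx = minx + rng.random(m) * (maxx - minx)
            cy = miny + rng.random(m) * (maxy - miny)
            for xi, yi in zip(cx, cy):
                if filled < n and self._prepared.covers(Point(xi, yi)):
                    xs[filled] = xi
                    ys[filled] = yi
                    filled += 1
        return xs, ys


# ---------------------------------------------------------------------------
# Localization
# ---------------------------------------------------------------------------

def _gauss2d(coords, amp, x0, y0, sigma, offset):
    x, y = coords
    return (amp * np.exp(-((x - x0) ** 2 + (y - y0) ** 2) / (2 * sigma**2)) + offset).ravel()


def localize_frame(
    image: np.ndarray,
    detect_threshold: float,
    *,
    psf_sigma_px: float = 1.5,
    sigma_bounds_px: tuple[float, float] = (0.5, 3.0),
    window_half: int = 4,
    min_distance: int = 3,
) -> list[tuple[float, float, float, float]]:
    """Detect and fit single-molecule spots in one background-subtracted frame.

    Candidate peaks above ``detect_threshold`` (over the frame median) are
    refined by least-squares 2D Gaussian fits in a local window; fits that do
    not converge, drift out of the window, or have widths outside
    ``sigma_bounds_px`` are rejected.

    Returns a list of ``(x_px, y_px, intensity, sigma_px)`` tuples; the caller
    attaches channel/frame metadata and converts to nm.
    """
    image = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite pixels")
    bg = float(np.median(image))
    peaks = peak_local_max(
        image, min_distance=min_distance, threshold_abs=bg + detect_threshold,
        exclude_border=False,
    )
    out = []
    ny, nx = image.shape
    for py, px in peaks:
        x0, x1 = max(px - window_half, 0), min(px + window_half + 1, nx)
        y0, y1 = max(py - window_half, 0), min(py + window_half + 1, ny)
        win = image[y0:y1, x0:x1]
        yy, xx = np.mgrid[y0:y1, x0:x1]
        p0 = (image[py, px] - bg, float(px), float(py), psf_sigma_px, bg)
        try:
            popt, _ = curve_fit(
                _gauss2d, (xx, yy), win.ravel(), p0=p0,
                bounds=(
                    (0.0, x0 - 1, y0 - 1, sigma_bounds_px[0] * 0.5, -np.inf),
                    (np.inf, x1, y1, sigma_bounds_px[1] * 2.0, np.inf),
                ),
                maxfev=300,
            )
        except (RuntimeError, ValueError):
            continue
        amp, xf, yf, sig, off = popt
        if not (sigma_bounds_px[0] <= sig <= sigma_bounds_px[1]):
            continue
        if not (x0 - 0.5 <= xf <= x1 - 0.5 and y0 - 0.5 <= yf <= y1 - 0.5):
            continue
        out.append((float(xf), float(yf), float(amp * 2 * np.pi * sig**2), float(sig)))
    return out


def localize_stack(
    stack: np.ndarray,
    frame_times: np.ndarray,
    channel: str,
    pixel_size: float,
    detect_threshold: float,
    **kwargs,
) -> list[Localization]:
    """Run :func:`localize_frame` over a stack, returning nm-scale records."""
    locs: list[Localization] = []
    for k, frame in enumerate(stack):
        for x_px, y_px, inten, sig in localize_frame(frame, detect_threshold, **kwargs):
            locs.append(
                Localization(
                    channel=channel, frame=k, t=float(frame_times[k]),
                    x=x_px * pixel_size, y=y_px * pixel_size,
                    intensity=inten, sigma=sig * pixel_size,
                )
            )
    return locs


def subtract_background(image: np.ndarray, radius: int = 50) -> np.ndarray:
    """Rolling-ball background subtraction (for raw, unsubtracted movies)."""
    from skimage.restoration import rolling_ball

    return image - rolling_ball(image, radius=radius)


# ---------------------------------------------------------------------------
# Linking
# ---------------------------------------------------------------------------

_BIG = 1e18


def link_tracks(
    locs: list[Localization],
    *,
    d_max_um2_s: float = 0.05,
    max_gap_s: float = 5.0,
    frame_interval: float = 1.34,
    n_frames: int | None = None,
) -> list[Track]:
    """Link localizations of one channel into tracks.

    Frame-to-frame assignment minimizes total squared displacement (optimal
    bipartite assignment, not greedy) under the diffusion gating radius
    ``r_max(dt) = sqrt(4 * D * dt)``; a track may bridge missing frames whose
    total elapsed blind time is at most ``max_gap_s``. Tracks touching the
    first (last) movie frame are flagged censored.
    """
    if not locs:
        return []
    d_nm2_s = d_max_um2_s * 1e6
    by_frame: dict[int, list[Localization]] = {}
    for l in locs:
        by_frame.setdefault(l.frame, []).append(l)
    frames = sorted(by_frame)
    first_frame = 0
    last_frame = (n_frames - 1) if n_frames is not None else frames[-1]

    active: list[list[Localization]] = []
    closed: list[list[Localization]] = []
    for f in frames:
        new = by_frame[f]
        t_new = new[0].t
        # retire tracks whose blind gap already exceeds the allowance
        still = []
        for tr in active:
            gap = t_new - tr[-1].t - frame_interval
            if gap > max_gap_s + 1e-9:
                closed.append(tr)
            else:
                still.append(tr)
        active = still
        if active and new:
            cost = np.full((len(active), len(new)), _BIG)
            for i, tr in enumerate(active):
                dt = t_new - tr[-1].t
                r2 = 4.0 * d_nm2_s * dt
                for j, l in enumerate(new):
                    d2 = (l.x - tr[-1].x) ** 2 + (l.y - tr[-1].y) ** 2
                    if d2 <= r2:
                        cost[i, j] = d2
            rows, cols = linear_sum_assignment(cost)
            matched_new = set()
            for i, j in zip(rows, cols):
                if cost[i, j] < _BIG:
                    active[i].append(new[j])
                    matched_new.add(j)
            for j, l in enumerate(new):
                if j not in matched_new:
                    active.append([l])
        else:
            active.extend([l] for l in new)
    closed.extend(active)

    tracks = []
    for i, tr in enumerate(sorted(closed, key=lambda t: (t[0].frame, t[0].x, t[0].y))):
        tracks.append(
            Track(
                id=i, channel=tr[0].channel, localizations=tr,
                frame_interval=frame_interval,
                censored_start=tr[0].frame == first_frame,
                censored_end=tr[-1].frame == last_frame,
            )
        )
    return tracks


# ---------------------------------------------------------------------------
# Track tables <-> Track objects
# ---------------------------------------------------------------------------

def table_to_tracks(
    df: pd.DataFrame,
    *,
    frame_interval: float = 1.34,
    n_frames: int | None = None,
) -> dict[str, list[Track]]:
    """Build per-channel Track lists from a pre-linked track table.

    Expects the columns ``track_id, channel, frame, t_s, x_nm, y_nm,
    intensity``. Censoring is flagged against frame 0 and ``n_frames - 1``
    (or the table's maximum frame when ``n_frames`` is omitted).
    """
    last = (n_frames - 1) if n_frames is not None else int(df["frame"].max())
    out: dict[str, list[Track]] = {}
    for (channel, tid), g in df.sort_values("frame").groupby(["channel", "track_id"]):
        locs = [
            Localization(channel=channel, frame=int(r.frame), t=float(r.t_s),
                         x=float(r.x_nm), y=float(r.y_nm), intensity=float(r.intensity))
            for r in g.itertuples(index=False)
        ]
        out.setdefault(channel, []).append(
            Track(
                id=int(tid), channel=channel, localizations=locs,
                frame_interval=frame_interval,
                censored_start=locs[0].frame == 0,
                censored_end=locs[-1].frame == last,
            )
        )
    return out


def tracks_to_table(tracks: list[Track]) -> pd.DataFrame:
    rows = [
        (t.id, t.channel, l.frame, l.t, l.x, l.y, l.intensity)
        for t in tracks
        for l in t.localizations
    ]
    return pd.DataFrame(
        rows, columns=["track_id", "channel", "frame", "t_s", "x_nm", "y_nm", "intensity"]
    )


def events_table(tracks: list[Track]) -> pd.DataFrame:
    """Summarize tracks as binding events (one row per track)."""
    return pd.DataFrame(
        {
            "track_id": [t.id for t in tracks],
            "channel": [t.channel for t in tracks],
            "x_nm": [t.mean_x for t in tracks],
            "y_nm": [t.mean_y for t in tracks],
            "start_s": [t.start_t for t in tracks],
            "end_s": [t.end_t for t in tracks],
            "duration_s": [t.duration for t in tracks],
            "censored": [t.censored_start or t.censored_end for t in tracks],
        }
    )


# ---------------------------------------------------------------------------
# Nuclear filtering, projection maps, photobleaching
# ---------------------------------------------------------------------------

def filter_nuclear_tracks(tracks: list[Track], roi: NucleusROI) -> list[Track]:
    """Keep tracks whose mean position lies inside (or on) the nuclear ROI."""
    return [t for t in tracks if roi.contains(t.mean_x, t.mean_y)]


def build_projection_map(
    tracks: list[Track], field_size: tuple[int, int], pixel_size: float
) -> np.ndarray:
    """Histogram of track mean positions on the native pixel grid."""
    ny, nx = field_size
    counts = np.zeros((ny, nx), dtype=np.int64)
    for t in tracks:
        j = min(max(int(t.mean_x // pixel_size), 0), nx - 1)
        i = min(max(int(t.mean_y // pixel_size), 0), ny - 1)
        counts[i, j] += 1
    return counts


@dataclass
class PhotobleachFit:
    tau_s: float
    amplitude: float
    offset: float
    decaying: bool
    rss: float


def estimate_photobleach(
    bound_signal: np.ndarray, frame_interval: float = 1.34
) -> PhotobleachFit:
    """Fit ``A * exp(-t / tau) + c`` to a global bound-fluorescence series.

    The exponential decay of the summed bound signal estimates the dye's
    photobleaching time constant. Non-decaying series are flagged
    (``decaying=False``, ``tau_s=inf``) rather than raising.
    """
    y = np.asarray(bound_signal, dtype=float)
    if y.size < 10:
        raise ValueError("need at least 10 frames to estimate photobleaching")
    if np.any(y < 0) or not np.all(np.isfinite(y)):
        raise ValueError("signal must be finite and non-negative")
    if np.all(y == 0):
        raise ValueError("all-zero signal")
    t = frame_interval * np.arange(y.size)
    head = y[: max(y.size // 10, 3)].mean()
    tail = y[-max(y.size // 10, 3):].mean()
    if head <= tail * (1 + 1e-6):
        return PhotobleachFit(np.inf, 0.0, float(y.mean()), False, float(np.var(y) * y.size))
    p0 = (head - tail, max(t[-1] / 3.0, frame_interval), tail)

    def model(t, a, tau, c):
        return a * np.exp(-t / tau) + c

    try:
        popt, _ = curve_fit(
            model, t, y, p0=p0,
            bounds=((0, frame_interval * 1e-3, -np.inf), (np.inf, np.inf, np.inf)),
            maxfev=2000,
        )
    except RuntimeError:
        return PhotobleachFit(np.inf, 0.0, float(y.mean()), False, float(np.inf))
    rss = float(np.sum((model(t, *popt) - y) ** 2))
    return PhotobleachFit(float(popt[1]), float(popt[0]), float(popt[2]), True, rss)
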