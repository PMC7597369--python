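"""Two-color colocalization detection, binding-order classification and nulls.

A Pol delta track qualifies if it lasts longer than one frame interval
(> 1.34 s). It colocalizes with a PCNA track when their bound intervals
overlap in time on the interleaved clock (closed intervals; touching counts)
and their time-averaged positions over the overlap window lie within 47 nm.
Pairing is Pol delta-centric and one-to-one: candidate pairs are accepted in
order of increasing separation (ties broken by longer temporal overlap).

Because the two channels are never sampled at the same instant, arrivals and
departures closer than one frame interval are classified as simultaneous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import ARRIVAL_CLASSES, DEPARTURE_CLASSES
from .tracking import NucleusROI, Track

DEFAULT_RADIUS_NM = 47.0
DEFAULT_MIN_POLD_S = 1.34
DEFAULT_TOL_S = 1.34


@dataclass
class ColocEvent:
    """A paired Pol delta / PCNA binding-event couple."""

    pold_track_id: int
    pcna_track_id: int
    separation_nm: float
    coloc_start_t: float
    coloc_end_t: float
    arrival_class: str
    departure_class: str
    pre_interval_s: float
    post_interval_s: float
    coloc_duration_s: float
    pold_start_t: float = np.nan
    pold_end_t: float = np.nan
    pcna_start_t: float = np.nan
    pcna_end_t: float = np.nan


def classify_order(
    pold_start: float,
    pold_end: float,
    pcna_start: float,
    pcna_end: float,
    tol_s: float = DEFAULT_TOL_S,
) -> tuple[str, str]:
    """Arrival and departure classes from signed start/end time differences.

    ``|dt| <= tol`` means simultaneous; otherwise the sign decides, applied
    independently to arrivals and departures.
    """
    d_arr = pold_start - pcna_start
    if abs(d_arr) <= tol_s + 1e-9:
        arrival = "simultaneous"
    elif d_arr > 0:
        arrival = "pcna_first"
    else:
        arrival = "pold_first"
    d_dep = pcna_end - pold_end
    if abs(d_dep) <= tol_s + 1e-9:
        departure = "simultaneous"
    elif d_dep > 0:
        departure = "pold_first"
    else:
        departure = "pcna_first"
    return arrival, departure


def _pair_geometry(pold: Track, pcna: Track, per_frame: bool):
    """Overlap window and separation for a candidate pair, or None."""
    ov0 = max(pold.start_t, pcna.start_t)
    ov1 = min(pold.end_t, pcna.end_t)
    if ov1 < ov0 - 1e-9:
        return None
    if per_frame:
        # minimum distance between any Pol delta and PCNA localization in the
        # overlap window (optional mode; noisier than averaged positions)
        pl = [l for l in pold.localizations if ov0 - 1e-9 <= l.t <= ov1 + 1e-9]
        cl = [l for l in pcna.localizations if ov0 - 1e-9 <= l.t <= ov1 + 1e-9]
        if not pl or not cl:
            px, py = pold.mean_position(ov0, ov1)
            cx, cy = pcna.mean_position(ov0, ov1)
            sep = float(np.hypot(px - cx, py - cy))
        else:
            sep = min(
                float(np.hypot(a.x - b.x, a.y - b.y)) for a in pl for b in cl
            )
    else:
        px, py = pold.mean_position(ov0, ov1)
        cx, cy = pcna.mean_position(ov0, ov1)
        sep = float(np.hypot(px - cx, py - cy))
    return ov0, ov1, sep


def detect_colocalizations(
    pold_tracks: list[Track],
    pcna_tracks: list[Track],
    *,
    radius_nm: float = DEFAULT_RADIUS_NM,
    min_pold_s: float = DEFAULT_MIN_POLD_S,
    tol_s: float = DEFAULT_TOL_S,
    per_frame: bool = False,
) -> list[ColocEvent]:
    """Detect Pol delta-centric colocalization events.

    Returns one event per paired Pol delta track. ``per_frame=True`` switches
    the distance criterion from time-averaged positions over the overlap to
    the per-frame minimum distance.
    """
    qualifying = [t for t in pold_tracks if t.duration > min_pold_s + 1e-9]
    if not qualifying or not pcna_tracks:
        return []
    # vectorized prefilter on temporal overlap
    p_start = np.array([t.start_t for t in qualifying])
    p_end = np.array([t.end_t for t in qualifying])
    c_start = np.array([t.start_t for t in pcna_tracks])
    c_end = np.array([t.end_t for t in pcna_tracks])
    overlap = (p_start[:, None] <= c_end[None, :] + 1e-9) & (
        c_start[None, :] <= p_end[:, None] + 1e-9
    )
    candidates = []
    for i, j in zip(*np.nonzero(overlap)):
        geom = _pair_geometry(qualifying[i], pcna_tracks[j], per_frame)
        if geom is None:
            continue
        ov0, ov1, sep = geom
        if sep < radius_nm:
            candidates.append((sep, -(ov1 - ov0), i, j, ov0, ov1))
    candidates.sort()
    used_p: set[int] = set()
    used_c: set[int] = set()
    events = []
    for sep, neg_ov, i, j, ov0, ov1 in candidates:
        if i in used_p or j in used_c:
            continue
        used_p.add(i)
        used_c.add(j)
        pold, pcna = qualifying[i], pcna_tracks[j]
        arrival, departure = classify_order(
            pold.start_t, pold.end_t, pcna.start_t, pcna.end_t, tol_s
        )
        events.append(
            ColocEvent(
                pold_track_id=pold.id,
                pcna_track_id=pcna.id,
                separation_nm=sep,
                coloc_start_t=ov0,
                coloc_end_t=ov1,
                arrival_class=arrival,
                departure_class=departure,
                pre_interval_s=ov0 - min(pold.start_t, pcna.start_t),
                post_interval_s=max(pold.end_t, pcna.end_t) - ov1,
                coloc_duration_s=ov1 - ov0,
                pold_start_t=pold.start_t,
                pold_end_t=pold.end_t,
                pcna_start_t=pcna.start_t,
                pcna_end_t=pcna.end_t,
            )
        )
    events.sort(key=lambda e: (e.coloc_start_t, e.pold_track_id))
    return events


def colocalization_frequency(events: list[ColocEvent], n_pold_tracks: int) -> float:
    """Percentage of qualifying Pol delta tracks that colocalized."""
    if n_pold_tracks <= 0:
        raise ValueError("n_pold_tracks must be positive")
    return 100.0 * len(events) / n_pold_tracks


def n_qualifying(pold_tracks: list[Track], min_pold_s: float = DEFAULT_MIN_POLD_S) -> int:
    return sum(1 for t in pold_tracks if t.duration > min_pold_s + 1e-9)


def randomize_positions(
    tracks: list[Track], roi: NucleusROI, seed: int
) -> list[Track]:
    """Positional-randomization null: redraw each track's mean position
    uniformly over the nuclear ROI, preserving durations, frames and channel.

    Per-localization scatter around the mean is preserved by translating the
    whole track.
    """
    if roi.area <= 0:
        raise ValueError("degenerate ROI")
    rng = np.random.default_rng(seed)
    xs, ys = roi.sample_uniform(len(tracks), rng)
    out = []
    for t, nx, ny in zip(tracks, xs, ys):
        dx, dy = nx - t.mean_x, ny - t.mean_y
        locs = [
            type(l)(channel=l.channel, frame=l.frame, t=l.t, x=l.x + dx,
                    y=l.y + dy, intensity=l.intensity, sigma=l.sigma)
            for l in t.localizations
        ]
        out.append(
            Track(id=t.id, channel=t.channel, localizations=locs,
                  frame_interval=t.frame_interval,
                  censored_start=t.censored_start, censored_end=t.censored_end)
        )
    return out


@dataclass
class OrderSummary:
    """Arrival/departure class counts, fractions and bootstrap SDs."""

    n_events: int
    arrival_counts: dict[str, int]
    arrival_fractions: dict[str, float]
    arrival_sd: dict[str, float]
    departure_counts: dict[str, int]
    departure_fractions: dict[str, float]
    departure_sd: dict[str, float]
    quadrants: dict[str, dict] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_events": self.n_events,
            "arrival": {
                c: {
                    "count": self.arrival_counts[c],
                    "fraction": self.arrival_fractions[c],
                    "bootstrap_sd": self.arrival_sd[c],
                }
                for c in ARRIVAL_CLASSES
            },
            "departure": {
                c: {
                    "count": self.departure_counts[c],
                    "fraction": self.departure_fractions[c],
                    "bootstrap_sd": self.departure_sd[c],
                }
                for c in DEPARTURE_CLASSES
            },
            "quadrants": self.quadrants,
        }


def bootstrap_order_fractions(
    events: list[ColocEvent], n_boot: int = 1000, seed: int = 0
) -> OrderSummary:
    """Class fractions with SDs from bootstrap resampling of events."""
    if not events:
        raise ValueError("need at least one event")
    rng = np.random.default_rng(seed)
    arr = np.array([ARRIVAL_CLASSES.index(e.arrival_class) for e in events])
    dep = np.array([DEPARTURE_CLASSES.index(e.departure_class) for e in events])
    n = len(events)
    idx = rng.integers(0, n, size=(n_boot, n))
    arr_frac = np.stack([(arr[idx] == k).mean(axis=1) for k in range(3)], axis=1)
    dep_frac = np.stack([(dep[idx] == k).mean(axis=1) for k in range(3)], axis=1)
    return OrderSummary(
        n_events=n,
        arrival_counts={c: int((arr == k).sum()) for k, c in enumerate(ARRIVAL_CLASSES)},
        arrival_fractions={c: float((arr == k).mean()) for k, c in enumerate(ARRIVAL_CLASSES)},
        arrival_sd={c: float(arr_frac[:, k].std(ddof=0)) for k, c in enumerate(ARRIVAL_CLASSES)},
        departure_counts={c: int((dep == k).sum()) for k, c in enumerate(DEPARTURE_CLASSES)},
        departure_fractions={c: float((dep == k).mean()) for k, c in enumerate(DEPARTURE_CLASSES)},
        departure_sd={c: float(dep_frac[:, k].std(ddof=0)) for k, c in enumerate(DEPARTURE_CLASSES)},
    )


def _median_ci(values: np.ndarray, n_boot: int, rng: np.random.Generator):
    if values.size == 0:
        return (np.nan, np.nan, np.nan)
    med = float(np.median(values))
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    boot = np.median(values[idx], axis=1)
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return med, float(lo), float(hi)


def quadrant_analysis(
    events: list[ColocEvent], n_boot: int = 1000, seed: int = 0
) -> dict[str, dict]:
    """Assembly/disassembly pathway table.

    Quadrants cross non-simultaneous arrival classes with non-simultaneous
    departure classes; each carries its share of all colocalizations and the
    median (with bootstrap 95% CI) of the partner-alone intervals before and
    after joint binding and of the colocalized time. Events with a
    simultaneous arrival or departure are tallied separately.
    """
    rng = np.random.default_rng(seed)
    n = len(events)
    out: dict[str, dict] = {}
    for arr in ("pcna_first", "pold_first"):
        for dep in ("pold_first", "pcna_first"):
            sel = [e for e in events if e.arrival_class == arr and e.departure_class == dep]
            entry: dict = {
                "n": len(sel),
                "fraction": len(sel) / n if n else np.nan,
            }
            for name, getter in (
                ("pre_s", lambda e: e.pre_interval_s),
                ("coloc_s", lambda e: e.coloc_duration_s),
                ("post_s", lambda e: e.post_interval_s),
            ):
                med, lo, hi = _median_ci(
                    np.array([getter(e) for e in sel]), n_boot, rng
                )
                entry[f"median_{name}"] = med
                entry[f"median_{name}_ci95"] = [lo, hi]
            out[f"arrival_{arr}/departure_{dep}"] = entry
    n_sim = sum(
        1 for e in events
        if e.arrival_class == "simultaneous" or e.departure_class == "simultaneous"
    )
    out["any_simultaneous"] = {"n": n_sim, "fraction": n_sim / n if n else np.nan}
    return out
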