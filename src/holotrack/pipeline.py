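"""End-to-end orchestration: simulate -> track -> colocalize -> fit -> hubs.

``run_pipeline`` produces a single machine-readable report (JSON) plus CSV
tables; ``make_figures`` renders deterministic SVG figures from a report
without recomputing anything.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint

from . import colocalization as coloc
from . import hubs as hubmod
from . import kinetics
from .config import CH_PCNA, CH_POLD, ConfigError, SimConfig
from .io import write_tracks
from .simulate import emit_tracks, generate_truth
from .tracking import NucleusROI, Track, events_table, table_to_tracks


@dataclass
class AnalysisParams:
    """Analysis-stage constants; defaults equal the published protocol."""

    radius_nm: float = 47.0
    min_pold_s: float = 1.34
    tol_s: float = 1.34
    long_threshold_s: float = 1.7
    frame_interval: float = 1.34
    d_max_um2_s: float = 0.05
    max_gap_s: float = 5.0
    hub_diameter_nm: float = 168.0
    hub_min_events: int = 3
    expand_factor: int = 10
    n_boot: int = 1000
    field_size: tuple[int, int] = (512, 512)
    pixel_size_nm: float = 84.0
    n_frames: int = 1000
    n_randomizations: int = 0


@dataclass
class RunConfig:
    """Pipeline run settings; every run writes its resolved config."""

    mode: str = "full"  # simulate | analyze | full
    sim: SimConfig = field(default_factory=SimConfig)
    params: AnalysisParams = field(default_factory=AnalysisParams)
    n_cells: int = 5
    seed: int = 0
    input_tables: list[str] = field(default_factory=list)
    outdir: str = "holotrack_out"

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "analyze", "full"):
            raise ConfigError(f"unknown mode {self.mode!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"] = self.sim.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if isinstance(d.get("sim"), dict):
            d["sim"] = SimConfig.from_dict(d["sim"])
        if isinstance(d.get("params"), dict):
            p = dict(d["params"])
            if "field_size" in p:
                p["field_size"] = tuple(p["field_size"])
            d["params"] = AnalysisParams(**p)
        return cls(**d)


def _roi_from_tracks(tracks: list[Track]) -> NucleusROI:
    pts = MultiPoint([(t.mean_x, t.mean_y) for t in tracks])
    return NucleusROI(pts.convex_hull.buffer(1.0))


def analyze_cell(
    tracks_df: pd.DataFrame,
    params: AnalysisParams,
    roi: NucleusROI | None = None,
    seed: int = 0,
) -> dict:
    """Single-nucleus analysis of a pre-linked two-channel track table."""
    per_channel = table_to_tracks(
        tracks_df, frame_interval=params.frame_interval, n_frames=params.n_frames
    )
    pold = per_channel.get(CH_POLD, [])
    pcna = per_channel.get(CH_PCNA, [])
    events = coloc.detect_colocalizations(
        pold, pcna, radius_nm=params.radius_nm,
        min_pold_s=params.min_pold_s, tol_s=params.tol_s,
    )
    n_qual = coloc.n_qualifying(pold, params.min_pold_s)
    out: dict = {
        "n_tracks": {CH_POLD: len(pold), CH_PCNA: len(pcna)},
        "n_qualifying_pold": n_qual,
        "events": events,
        "coloc_frequency_percent": (
            coloc.colocalization_frequency(events, n_qual) if n_qual else np.nan
        ),
        "durations": {
            ch: np.array(
                [t.duration for t in trs if not (t.censored_start or t.censored_end)]
            )
            for ch, trs in ((CH_POLD, pold), (CH_PCNA, pcna))
        },
    }
    # randomization null on the same observed tracks
    if params.n_randomizations > 0:
        roi = roi or _roi_from_tracks(pold + pcna)
        freqs = []
        for r in range(params.n_randomizations):
            rp = coloc.randomize_positions(pold, roi, seed=seed * 10007 + 2 * r)
            rc = coloc.randomize_positions(pcna, roi, seed=seed * 10007 + 2 * r + 1)
            ev = coloc.detect_colocalizations(
                rp, rc, radius_nm=params.radius_nm,
                min_pold_s=params.min_pold_s, tol_s=params.tol_s,
            )
            freqs.append(coloc.colocalization_frequency(ev, n_qual) if n_qual else np.nan)
        out["randomized_frequency_percent"] = freqs
    # hubs on long-lived Pol delta events
    ev_table = events_table(pold)
    hub_list, _ = hubmod.find_hubs(
        ev_table.rename(columns={"x_nm": "x_nm", "y_nm": "y_nm"}),
        field_size=params.field_size, pixel_size_nm=params.pixel_size_nm,
        factor=params.expand_factor, min_duration_s=params.long_threshold_s,
        diameter_nm=params.hub_diameter_nm, min_events=params.hub_min_events,
    )
    n_map_events = int((ev_table["duration_s"] > params.long_threshold_s).sum())
    out["hubs"] = hub_list
    out["n_hub_map_events"] = n_map_events
    out["hubs_per_1000"] = (
        hubmod.hubs_per_1000(len(hub_list), n_map_events) if n_map_events else np.nan
    )
    out["latencies"] = (
        np.concatenate([h.latencies_s for h in hub_list])
        if hub_list else np.array([])
    )
    return out


def _fit_residences(durations: np.ndarray, seed: int) -> dict:
    if durations.size < 20:
        return {"error": "too few durations"}
    fits = [
        kinetics.fit_exponential_mixture(durations, k=k, seed=seed) for k in (1, 2)
    ]
    best = kinetics.select_model(fits)
    two = fits[1]
    return {
        "selected_k": best.k,
        "fits": {f.k: f.to_dict() for f in fits},
        "T1_s": two.T1,
        "T2_s": two.T2,
        "percent_T1": float(two.population_percent[0]),
        "percent_T2": float(two.population_percent[-1]),
    }


def run_pipeline(config: RunConfig, write: bool = True) -> dict:
    """Run the configured pipeline stages and assemble the report bundle."""
    outdir = Path(config.outdir)
    if write:
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "run_config.json", "w") as fh:
            json.dump(config.to_dict(), fh, indent=2)

    cell_tables: list[pd.DataFrame] = []
    if config.mode in ("simulate", "full"):
        for c in range(config.n_cells):
            sim = dataclasses.replace(config.sim, seed=config.seed + 1000 * c)
            truth = generate_truth(sim)
            table = emit_tracks(truth, sim)
            cell_tables.append(table)
            if write:
                write_tracks(table, outdir / f"tracks_cell{c:03d}.csv")
    else:
        from .io import read_tracks

        for p in config.input_tables:
            cell_tables.append(read_tracks(p))
    if config.mode == "simulate":
        return {"mode": "simulate", "n_cells": len(cell_tables)}

    params = config.params
    roi = None
    if config.mode == "full":
        a, b = config.sim.nucleus_semiaxes
        cx, cy = config.sim.nucleus_center
        roi = NucleusROI.ellipse(cx, cy, a * 1.02, b * 1.02)

    cells = [
        analyze_cell(t, params, roi=roi, seed=config.seed + i)
        for i, t in enumerate(cell_tables)
    ]
    all_events = [e for c in cells for e in c["events"]]

    report: dict = {
        "mode": config.mode,
        "n_cells": len(cells),
        "colocalization": {
            "per_cell_frequency_percent": [c["coloc_frequency_percent"] for c in cells],
            "pooled_frequency_percent": (
                100.0 * len(all_events) / max(sum(c["n_qualifying_pold"] for c in cells), 1)
            ),
            "n_events": len(all_events),
            "n_qualifying_pold": int(sum(c["n_qualifying_pold"] for c in cells)),
        },
    }
    if params.n_randomizations > 0:
        rand = [f for c in cells for f in c.get("randomized_frequency_percent", [])]
        report["colocalization"]["randomized_frequency_percent_mean"] = float(
            np.nanmean(rand)
        )
    if all_events:
        summary = coloc.bootstrap_order_fractions(
            all_events, n_boot=params.n_boot, seed=config.seed
        )
        summary.quadrants = coloc.quadrant_analysis(
            all_events, n_boot=params.n_boot, seed=config.seed
        )
        report["order"] = summary.to_dict()
        report["median_coloc_s"] = float(
            np.median([e.coloc_duration_s for e in all_events])
        )

    residence: dict = {}
    for ch in (CH_POLD, CH_PCNA):
        per_cell = [
            _fit_residences(c["durations"][ch], seed=config.seed + i)
            for i, c in enumerate(cells)
        ]
        ok = [r for r in per_cell if "error" not in r]
        residence[ch] = {
            "per_cell": per_cell,
            "median_T1_s": float(np.median([r["T1_s"] for r in ok])) if ok else np.nan,
            "median_T2_s": float(np.median([r["T2_s"] for r in ok])) if ok else np.nan,
            "median_percent_T2": (
                float(np.median([r["percent_T2"] for r in ok])) if ok else np.nan
            ),
        }
        # an example survival curve for plotting (first cell)
        d = cells[0]["durations"][ch]
        if d.size:
            curve = kinetics.survival_curve(d)
            residence[ch]["example_curve"] = {
                "t_s": curve.t[:: max(1, curve.t.size // 200)].tolist(),
                "s": curve.s[:: max(1, curve.t.size // 200)].tolist(),
            }
    report["residence"] = residence

    report["hubs"] = {
        "per_cell_hubs_per_1000": [c["hubs_per_1000"] for c in cells],
        "median_hubs_per_1000": float(
            np.nanmedian([c["hubs_per_1000"] for c in cells])
        ),
        "per_cell_n_hubs": [len(c["hubs"]) for c in cells],
        "mean_events_per_hub": (
            float(np.mean([h.n_events for c in cells for h in c["hubs"]]))
            if any(c["hubs"] for c in cells) else np.nan
        ),
    }
    pooled_lat = (
        np.concatenate([c["latencies"] for c in cells])
        if cells else np.array([])
    )
    # gaps below two frame intervals are at the interleaved-clock resolution
    # limit (aliased by start/end phase); exclude them and fit left-truncated
    pooled_lat = pooled_lat[pooled_lat >= 2 * params.frame_interval - 1e-9]
    if pooled_lat.size >= 30:
        fits = [
            kinetics.fit_exponential_mixture(pooled_lat, k=k, seed=config.seed)
            for k in (1, 2, 3)
        ]
        best = kinetics.select_model(fits)
        report["latency"] = {
            "n": int(pooled_lat.size),
            "selected_k": best.k,
            "fits": {f.k: f.to_dict() for f in fits},
        }
    if write:
        with open(outdir / "report.json", "w") as fh:
            json.dump(_jsonable(report), fh, indent=2)
        hub_rows = [
            {
                "hub_id": h.id, "cell_id": c_i,
                "centroid_x_nm": h.centroid_nm[0],
                "centroid_y_nm": h.centroid_nm[1],
                "n_events": h.n_events,
            }
            for c_i, c in enumerate(cells)
            for h in c["hubs"]
        ]
        pd.DataFrame(
            hub_rows,
            columns=["hub_id", "cell_id", "centroid_x_nm", "centroid_y_nm", "n_events"],
        ).to_csv(outdir / "hubs.csv", index=False)
        pd.DataFrame(
            [
                {"cell_id": c_i, "hub_id": h.id, "latency_s": l}
                for c_i, c in enumerate(cells)
                for h in c["hubs"]
                for l in h.latencies_s
            ],
            columns=["cell_id", "hub_id", "latency_s"],
        ).to_csv(outdir / "hub_latencies.csv", index=False)
        kin_rows = []
        for ch in (CH_POLD, CH_PCNA):
            for c_i, r in enumerate(residence[ch]["per_cell"]):
                if "error" in r:
                    continue
                kin_rows.append(
                    {
                        "cell_id": c_i, "channel": ch, "T1_s": r["T1_s"],
                        "T2_s": r["T2_s"], "percent_T1": r["percent_T1"],
                        "percent_T2": r["percent_T2"],
                    }
                )
        pd.DataFrame(
            kin_rows,
            columns=["cell_id", "channel", "T1_s", "T2_s", "percent_T1", "percent_T2"],
        ).to_csv(outdir / "residence_per_cell.csv", index=False)
        if all_events:
            pd.DataFrame(
                [
                    {
                        "event_id": i,
                        "pold_track": e.pold_track_id,
                        "pcna_track": e.pcna_track_id,
                        "sep_nm": e.separation_nm,
                        "t0": e.coloc_start_t,
                        "t1": e.coloc_end_t,
                        "arrival": e.arrival_class,
                        "departure": e.departure_class,
                        "pre_s": e.pre_interval_s,
                        "coloc_s": e.coloc_duration_s,
                        "post_s": e.post_interval_s,
                    }
                    for i, e in enumerate(all_events)
                ]
            ).to_csv(outdir / "coloc_events.csv", index=False)
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if np.isnan(f) else f
    if isinstance(obj, np.integer):
        return int(obj)
    if hasattr(obj, "to_dict"):
        return _jsonable(obj.to_dict())
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    return obj


# ---------------------------------------------------------------------------
# Figures
# ---------------------------------------------------------------------------

def make_figures(report: dict, outdir) -> list[str]:
    """Render deterministic SVG figures from a report bundle.

    Missing report sections are skipped with a warning; no computation
    happens here.
    """
    import warnings

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plt.rcParams["svg.hashsalt"] = "holotrack"
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    def _save(fig, name):
        p = outdir / name
        fig.savefig(p, format="svg", metadata={"Date": None})
        plt.close(fig)
        written.append(str(p))

    cl = report.get("colocalization")
    if cl:
        fig, ax = plt.subplots(figsize=(4, 3))
        vals = [cl["pooled_frequency_percent"]]
        labels = ["observed"]
        if "randomized_frequency_percent_mean" in cl:
            vals.append(cl["randomized_frequency_percent_mean"])
            labels.append("randomized")
        ax.bar(labels, vals, color=["tab:blue", "tab:gray"][: len(vals)])
        ax.set_ylabel("colocalization frequency (%)")
        fig.tight_layout()
        _save(fig, "fig_coloc_frequency.svg")
    else:
        warnings.warn("report lacks colocalization section; figure skipped")

    order = report.get("order")
    if order:
        fig, axes = plt.subplots(1, 2, figsize=(7, 3), sharey=True)
        for ax, margin in zip(axes, ("arrival", "departure")):
            classes = list(order[margin])
            fr = [100 * order[margin][c]["fraction"] for c in classes]
            sd = [100 * order[margin][c]["bootstrap_sd"] for c in classes]
            ax.bar(range(len(classes)), fr, yerr=sd, capsize=3)
            ax.set_xticks(range(len(classes)))
            ax.set_xticklabels(classes, rotation=30, ha="right", fontsize=8)
            ax.set_title(margin)
        axes[0].set_ylabel("% of colocalizations")
        fig.tight_layout()
        _save(fig, "fig_order.svg")

        quads = order.get("quadrants")
        if quads:
            keys = [k for k in quads if k.startswith("arrival_")]
            fig, ax = plt.subplots(figsize=(5, 3))
            ax.bar(range(len(keys)), [100 * quads[k]["fraction"] for k in keys])
            ax.set_xticks(range(len(keys)))
            ax.set_xticklabels(
                [k.replace("arrival_", "a:").replace("/departure_", "\nd:") for k in keys],
                fontsize=7,
            )
            ax.set_ylabel("% of colocalizations")
            fig.tight_layout()
            _save(fig, "fig_quadrants.svg")
    else:
        warnings.warn("report lacks order section; figures skipped")

    res = report.get("residence")
    if res:
        fig, ax = plt.subplots(figsize=(4.5, 3.5))
        for ch, color in ((CH_POLD, "tab:orange"), (CH_PCNA, "tab:blue")):
            ex = res.get(ch, {}).get("example_curve")
            if ex:
                ax.semilogy(ex["t_s"], ex["s"], ".", ms=3, color=color, label=ch)
        ax.set_xlabel("residence time (s)")
        ax.set_ylabel("1 - CDF")
        ax.legend()
        fig.tight_layout()
        _save(fig, "fig_survival.svg")
    else:
        warnings.warn("report lacks residence section; figure skipped")

    hb = report.get("hubs")
    if hb and hb.get("per_cell_hubs_per_1000"):
        fig, ax = plt.subplots(figsize=(3, 3))
        vals = [v for v in hb["per_cell_hubs_per_1000"] if v is not None]
        ax.boxplot([vals], tick_labels=["cells"])
        ax.set_ylabel("hubs per 1,000 events")
        fig.tight_layout()
        _save(fig, "fig_hubs.svg")
    else:
        warnings.warn("report lacks hubs section; figure skipped")

    lat = report.get("latency")
    if lat:
        fig, ax = plt.subplots(figsize=(4, 3))
        ks = sorted(lat["fits"])
        ax.bar(
            [str(k) for k in ks],
            [lat["fits"][k]["aicc"] - min(f["aicc"] for f in lat["fits"].values())
             for k in ks],
        )
        ax.set_xlabel("components")
        ax.set_ylabel("delta AICc")
        ax.set_title(f"latency model selection (k={lat['selected_k']})")
        fig.tight_layout()
        _save(fig, "fig_latency.svg")
    else:
        warnings.warn("report lacks latency section; figure skipped")
    return written
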