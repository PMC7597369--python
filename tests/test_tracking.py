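"""Localization, linking, nuclear filtering and photobleach tests."""

import dataclasses
import itertools

import numpy as np
import pytest

from holotrack import (
    CH_POLD,
    Localization,
    NucleusROI,
    SimConfig,
    build_projection_map,
    emit_tracks,
    estimate_photobleach,
    generate_truth,
    link_tracks,
    localize_frame,
    localize_stack,
    render_movie,
    table_to_tracks,
)

from conftest import make_track


def gaussian_frame(shape, x0, y0, amp=500.0, sigma=1.5, bg=100.0):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return bg + amp * np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2) / (2 * sigma**2))


class TestLocalize:
    def test_noiseless_subpixel_accuracy(self):
        img = gaussian_frame((256, 256), 100.3, 200.7)
        locs = localize_frame(img, detect_threshold=100.0)
        assert len(locs) == 1
        x, y, inten, sig = locs[0]
        assert abs(x - 100.3) < 0.02 and abs(y - 200.7) < 0.02

    def test_flat_frame_empty(self):
        assert localize_frame(np.full((64, 64), 100.0), 50.0) == []

    def test_nonfinite_pixels_rejected(self):
        img = np.full((32, 32), 10.0)
        img[3, 3] = np.nan
        with pytest.raises(ValueError):
            localize_frame(img, 5.0)

    def test_noisy_rmse_matches_single_spot_oracle(self):
        """Multi-spot localization precision should match a Monte-Carlo
        oracle built from repeated isolated-spot fits at the same SNR."""
        rng = np.random.default_rng(42)
        amp, sigma, bg = 600.0, 1.5, 100.0
        # oracle: isolated spots, one per frame
        errs = []
        for _ in range(150):
            x0 = 10 + rng.random() * 4
            y0 = 10 + rng.random() * 4
            img = rng.poisson(gaussian_frame((24, 24), x0, y0, amp, sigma, bg))
            locs = localize_frame(img.astype(float), 150.0)
            if len(locs) == 1:
                errs.append((locs[0][0] - x0) ** 2 + (locs[0][1] - y0) ** 2)
        oracle_rmse = np.sqrt(np.mean(errs))
        # many spots in one large frame, well separated
        n = 100
        xs = rng.permutation(n) * 12 + 6 + rng.random(n) * 2
        ys = rng.integers(6, 1190, n) + rng.random(n)
        img = np.full((1200, 1200), bg)
        for x0, y0 in zip(xs, ys):
            img += gaussian_frame((1200, 1200), x0, y0, amp, sigma, 0.0)
        img = rng.poisson(img).astype(float)
        locs = localize_frame(img, 150.0)
        found = 0
        errs2 = []
        for x0, y0 in zip(xs, ys):
            d2 = [(l[0] - x0) ** 2 + (l[1] - y0) ** 2 for l in locs]
            if d2 and min(d2) < 1.0:
                found += 1
                errs2.append(min(d2))
        assert found >= 95
        rmse = np.sqrt(np.mean(errs2))
        assert rmse < 1.5 * oracle_rmse


class TestLink:
    def test_stationary_spot_single_track(self):
        locs = [
            Localization(CH_POLD, k, k * 1.34, 100.0, 200.0, 1.0) for k in range(5)
        ]
        tracks = link_tracks(locs, frame_interval=1.34, n_frames=10)
        assert len(tracks) == 1
        assert len(tracks[0].localizations) == 5
        assert tracks[0].duration == pytest.approx(5 * 1.34)
        assert tracks[0].censored_start and not tracks[0].censored_end

    @pytest.mark.parametrize("gap_frames,expected_tracks", [(2, 1), (4, 2)])
    def test_gap_bridging_threshold(self, gap_frames, expected_tracks):
        # 2 missing frames = 2.68 s <= 5 s bridges; 4 missing = 5.36 s splits
        frames = list(range(3)) + list(range(3 + gap_frames, 6 + gap_frames))
        locs = [
            Localization(CH_POLD, k, k * 1.34, 500.0, 500.0, 1.0) for k in frames
        ]
        tracks = link_tracks(locs, frame_interval=1.34, n_frames=20)
        assert len(tracks) == expected_tracks

    def test_empty_input(self):
        assert link_tracks([]) == []

    def test_no_shared_localizations(self):
        rng = np.random.default_rng(0)
        locs = [
            Localization(CH_POLD, k, k * 1.34, rng.random() * 5000,
                         rng.random() * 5000, 1.0)
            for k in range(30)
            for _ in range(rng.integers(0, 4))
        ]
        tracks = link_tracks(locs, frame_interval=1.34)
        seen = set()
        for t in tracks:
            for l in t.localizations:
                assert id(l) not in seen
                seen.add(id(l))
        assert len(seen) == len(locs)

    def test_translation_invariance(self):
        rng = np.random.default_rng(3)
        locs = [
            Localization(CH_POLD, k, k * 1.34, rng.random() * 3000,
                         rng.random() * 3000, 1.0)
            for k in range(20)
            for _ in range(2)
        ]
        shifted = [
            Localization(l.channel, l.frame, l.t, l.x + 1e5, l.y + 2e5, l.intensity)
            for l in locs
        ]
        t1 = link_tracks(locs, frame_interval=1.34)
        t2 = link_tracks(shifted, frame_interval=1.34)
        sig1 = sorted(tuple(l.frame for l in t.localizations) for t in t1)
        sig2 = sorted(tuple(l.frame for l in t.localizations) for t in t2)
        assert sig1 == sig2

    def test_matches_exhaustive_assignment_oracle(self):
        """Per-frame linking equals a brute-force matcher that maximizes the
        number of gated links, then minimizes the total squared displacement."""
        rng = np.random.default_rng(7)
        dt, d_nm2 = 1.34, 0.05 * 1e6
        r2 = 4 * d_nm2 * dt

        def best_matching(prev, new):
            # recursive enumeration of all injective partial matchings
            best = {"n": -1, "cost": np.inf, "pairs": []}

            def rec(i, used, cost, pairs):
                if i == len(prev):
                    n = len(pairs)
                    if (n, cost) > (best["n"], -1) and (
                        n > best["n"] or cost < best["cost"] - 1e-12
                    ):
                        best.update(n=n, cost=cost, pairs=list(pairs))
                    return
                rec(i + 1, used, cost, pairs)  # leave chain i unmatched
                for j, l in enumerate(new):
                    if j in used:
                        continue
                    d2 = (prev[i][-1].x - l.x) ** 2 + (prev[i][-1].y - l.y) ** 2
                    if d2 <= r2:
                        rec(i + 1, used | {j}, cost + d2, pairs + [(i, j)])

            rec(0, frozenset(), 0.0, [])
            return best["pairs"]

        for trial in range(15):
            locs = [
                Localization(CH_POLD, f, f * dt, rng.random() * 2500,
                             rng.random() * 2500, 1.0)
                for f in range(4)
                for _ in range(rng.integers(1, 6))
            ]
            tracks = link_tracks(locs, frame_interval=dt, max_gap_s=0.0)
            by_frame: dict[int, list[Localization]] = {}
            for l in locs:
                by_frame.setdefault(l.frame, []).append(l)
            chains: list[list[Localization]] = []
            for f in sorted(by_frame):
                new = by_frame[f]
                open_chains = [c for c in chains if c[-1].frame == f - 1]
                matched_new = set()
                for i, j in best_matching(open_chains, new):
                    open_chains[i].append(new[j])
                    matched_new.add(j)
                chains.extend([l] for j, l in enumerate(new) if j not in matched_new)
            sig_impl = sorted(
                tuple((l.frame, round(l.x, 6)) for l in t.localizations)
                for t in tracks
            )
            sig_oracle = sorted(
                tuple((l.frame, round(l.x, 6)) for l in c) for c in chains
            )
            assert sig_impl == sig_oracle

    def test_ground_truth_track_recovery(self):
        """Relinking emitted localizations recovers the true partition."""
        cfg = SimConfig(
            n_events_per_channel=50, hub_count=0, coloc_fraction=0.0,
            residence_mix=dataclasses.replace(
                SimConfig().residence_mix, weights=(0.2, 0.8), taus=(2.0, 15.0)
            ),
            bleach_tau_per_channel=(1e12, 1e12), blink_gap_prob=0.0, seed=31,
        )
        table = emit_tracks(generate_truth(cfg))
        sub = table[table["channel"] == CH_POLD]
        locs = [
            Localization(CH_POLD, int(r.frame), float(r.t_s), float(r.x_nm),
                         float(r.y_nm), float(r.intensity))
            for r in sub.itertuples(index=False)
        ]
        tracks = link_tracks(
            locs, frame_interval=cfg.frame_interval, n_frames=cfg.movie_length
        )
        # pairwise Jaccard between recovered and true co-track relations
        key = {(round(r.t_s, 6), round(r.x_nm, 4)): r.track_id
               for r in sub.itertuples(index=False)}
        true_pairs, rec_pairs = set(), set()
        by_true = {}
        for r in sub.itertuples(index=False):
            by_true.setdefault(r.track_id, []).append((round(r.t_s, 6), round(r.x_nm, 4)))
        for members in by_true.values():
            true_pairs.update(itertools.combinations(sorted(members), 2))
        for t in tracks:
            members = sorted((round(l.t, 6), round(l.x, 4)) for l in t.localizations)
            rec_pairs.update(itertools.combinations(members, 2))
        jacc = len(true_pairs & rec_pairs) / len(true_pairs | rec_pairs)
        assert jacc >= 0.95


class TestNuclearFilter:
    def test_outside_removed_boundary_kept(self):
        roi = NucleusROI.from_vertices([(0, 0), (100, 0), (100, 100), (0, 100)])
        inside = make_track(0, CH_POLD, [0, 1], 50, 50)
        outside = make_track(1, CH_POLD, [0, 1], 150, 50)
        on_vertex = make_track(2, CH_POLD, [0, 1], 100, 100)
        from holotrack import filter_nuclear_tracks

        kept = filter_nuclear_tracks([inside, outside, on_vertex], roi)
        assert [t.id for t in kept] == [0, 2]

    def test_matches_ray_casting_oracle(self, rng):
        verts = [(0, 0), (200, 20), (260, 150), (120, 260), (-30, 140)]
        roi = NucleusROI.from_vertices(verts)

        def ray_cast(px, py):
            # standard even-odd rule
            inside = False
            n = len(verts)
            for i in range(n):
                x1, y1 = verts[i]
                x2, y2 = verts[(i + 1) % n]
                if (y1 > py) != (y2 > py):
                    xint = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
                    if px < xint:
                        inside = not inside
            return inside

        from holotrack import filter_nuclear_tracks

        tracks = [
            make_track(i, CH_POLD, [0, 1], rng.random() * 320 - 40,
                       rng.random() * 320 - 40)
            for i in range(100)
        ]
        kept = {t.id for t in filter_nuclear_tracks(tracks, roi)}
        oracle = {t.id for t in tracks if ray_cast(t.mean_x, t.mean_y)}
        # boundary-exact points are the only allowed discrepancy; none here
        assert kept == oracle


class TestProjectionMap:
    def test_three_distinct_pixels(self):
        tracks = [
            make_track(i, CH_POLD, [0], (i * 10 + 0.5) * 84.0, 84.0 * 2.5)
            for i in range(3)
        ]
        m = build_projection_map(tracks, (64, 64), 84.0)
        assert m.sum() == 3
        assert (m[2, [0, 10, 20]] == 1).all()

    def test_empty(self):
        assert build_projection_map([], (16, 16), 84.0).sum() == 0

    def test_matches_histogram_oracle(self, rng):
        tracks = [
            make_track(i, CH_POLD, [0], rng.random() * 64 * 84, rng.random() * 64 * 84)
            for i in range(500)
        ]
        m = build_projection_map(tracks, (64, 64), 84.0)
        edges = np.arange(65) * 84.0
        oracle, _, _ = np.histogram2d(
            [t.mean_y for t in tracks], [t.mean_x for t in tracks], bins=(edges, edges)
        )
        assert (m == oracle.astype(int)).all()


class TestPhotobleach:
    def test_noiseless_decay(self):
        t = np.arange(200) * 1.34
        fit = estimate_photobleach(1000 * np.exp(-t / 100.0) + 50, 1.34)
        assert fit.decaying
        assert fit.tau_s == pytest.approx(100.0, abs=0.1)

    def test_constant_series_flagged(self):
        fit = estimate_photobleach(np.full(50, 500.0), 1.34)
        assert not fit.decaying and np.isinf(fit.tau_s)

    def test_all_zero_raises(self):
        with pytest.raises(ValueError):
            estimate_photobleach(np.zeros(50), 1.34)

    def test_noisy_recovery_within_5_percent(self):
        rng = np.random.default_rng(8)
        t = np.arange(200) * 1.34
        taus = []
        for _ in range(40):
            y = rng.poisson(2000 * np.exp(-t / 100.0) + 100).astype(float)
            taus.append(estimate_photobleach(y, 1.34).tau_s)
        assert abs(np.mean(taus) - 100.0) / 100.0 < 0.05


class TestEndToEnd:
    def test_rendered_movie_duration_distribution_recovered(self):
        """Render -> localize -> link reproduces the emitted duration set."""
        from scipy import stats

        cfg = SimConfig(
            n_events_per_channel=800, hub_count=0, coloc_fraction=0.0,
            field_size=(256, 256), movie_length=300,
            residence_mix=dataclasses.replace(
                SimConfig().residence_mix, weights=(0.5, 0.5), taus=(3.0, 15.0)
            ),
            bleach_tau_per_channel=(1e12, 1e12), loc_noise_sigma=10.0,
            blink_gap_prob=0.0, seed=19,
        )
        table = emit_tracks(generate_truth(cfg))
        sub = table[table["channel"] == CH_POLD]
        stacks, sidecar = render_movie(sub, cfg, seed=20)
        times = np.asarray(sidecar["channels"][CH_POLD]["frame_times_s"])
        locs = localize_stack(stacks[CH_POLD], times, CH_POLD, 84.0, 150.0)
        tracks = link_tracks(
            locs, frame_interval=cfg.frame_interval, n_frames=cfg.movie_length
        )
        rec = np.array(
            [t.duration for t in tracks
             if not (t.censored_start or t.censored_end) and len(t.localizations) > 1]
        )
        true_tracks = table_to_tracks(
            sub, frame_interval=cfg.frame_interval, n_frames=cfg.movie_length
        )[CH_POLD]
        ref = np.array(
            [t.duration for t in true_tracks
             if not (t.censored_start or t.censored_end) and len(t.localizations) > 1]
        )
        assert rec.size > 0.8 * ref.size
        assert stats.ks_2samp(rec, ref).pvalue > 0.01


class TestBackgroundSubtraction:
    def test_rolling_ball_removes_flat_background(self):
        from holotrack.tracking import subtract_background

        img = gaussian_frame((64, 64), 30.0, 30.0, amp=400.0, bg=500.0)
        sub = subtract_background(img, radius=10)
        # background gone, peak preserved
        assert abs(np.median(sub)) < 5.0
        iy, ix = np.unravel_index(np.argmax(sub), sub.shape)
        assert (iy, ix) == (30, 30)
        assert sub[30, 30] > 300.0
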