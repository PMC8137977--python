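"""Synthetic network generator: determinism, geometry, treatment transform."""

import math

import numpy as np
import pytest

from mcnvquant.imaging import rasterize_contour
from mcnvquant.synthetic import (
    PATTERNS,
    RenderNoise,
    apply_anti_vegf,
    generate_cohort,
    generate_network,
    render_octa,
)


def has_cycle(truth):
    """Union-find over segment connectivity (parent links + anastomoses),
    plus closed-loop segments (first and last polyline point coincide)."""
    if any(np.allclose(s.points[0], s.points[-1]) and len(s.points) > 3
           for s in truth.segments):
        return True
    ids = [s.id for s in truth.segments]
    parent = {i: i for i in ids}

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    cyclic = False
    for s in truth.segments:
        if s.parent is not None and s.parent in parent:
            a, b = find(s.id), find(s.parent)
            if a == b:
                cyclic = True
            parent[a] = b
    for j in truth.junctions:
        mids = [sid for sid, kind in j.arms if kind == "mid" and sid in parent]
        ends = [sid for sid, kind in j.arms if kind == "end" and sid in parent]
        for m in mids:
            for e in ends:
                a, b = find(m), find(e)
                if a == b:
                    cyclic = True
                parent[a] = b
    return cyclic


class TestGeneration:
    @pytest.mark.parametrize("pattern", PATTERNS)
    def test_same_seed_regenerates_identical_network(self, pattern):
        t1 = generate_network(pattern, seed=7)
        t2 = generate_network(pattern, seed=7)
        assert len(t1.segments) == len(t2.segments)
        for a, b in zip(t1.segments, t2.segments):
            assert np.array_equal(a.points, b.points)
            assert a.caliber_px == b.caliber_px
        assert np.array_equal(t1.junction_points, t2.junction_points)

    def test_unknown_pattern_rejected(self):
        with pytest.raises(ValueError):
            generate_network("starburst", seed=0)

    def test_loops_pattern_contains_cycles(self):
        assert any(has_cycle(generate_network("disorganized_loops", seed=s))
                   for s in range(6))

    def test_sea_fan_origins_within_60_degree_sector(self):
        for seed in range(5):
            t = generate_network("sea_fan", seed=seed)
            center = np.array([t.shape[1] / 2, t.shape[0] / 2])
            roots = [s.points[0] for s in t.segments if s.parent is None]
            angles = np.array([math.atan2(p[1] - center[1], p[0] - center[0])
                               for p in roots])
            spread = np.angle(np.exp(1j * (angles - angles[0])))
            assert spread.max() - spread.min() <= math.radians(60) + 1e-6

    @pytest.mark.parametrize("pattern", PATTERNS)
    def test_centerlines_inside_lesion_polygon(self, pattern):
        t = generate_network(pattern, seed=3)
        if not t.segments:
            pytest.skip("degenerate empty network")
        lesion = rasterize_contour(t.lesion_polygon, t.shape)
        center = t.centerline_mask()
        assert (center & ~lesion.mask).sum() == 0

    def test_true_metric_internal_consistency(self):
        t = generate_network("medusa", seed=5)
        tm = t.true_metrics()
        assert tm.vessel_density == pytest.approx(
            tm.vessel_area_mm2 / tm.mcnv_area_mm2)
        assert tm.junction_density_per_mm == pytest.approx(
            tm.vessel_junctions / tm.vessel_length_mm)
        assert tm.vessel_tortuosity >= 1.0


class TestAntiVegf:
    def test_identity_transform(self):
        t = generate_network("medusa", seed=2)
        post = apply_anti_vegf(t, prune_caliber_px=0.0, trunk_dilation=1.0)
        assert len(post.segments) == len(t.segments)
        assert post.n_junctions == t.n_junctions
        assert post.true_metrics().vessel_length_mm == pytest.approx(
            t.true_metrics().vessel_length_mm)

    @pytest.mark.parametrize("seed", range(10))
    def test_median_prune_reduces_junctions_and_raises_caliber(self, seed):
        t = generate_network("medusa", seed=seed)
        med = float(np.median([s.caliber_px for s in t.segments]))
        post = apply_anti_vegf(t, prune_caliber_px=med, trunk_dilation=1.0)
        assert post.n_junctions < t.n_junctions
        assert (np.mean([s.caliber_px for s in post.segments])
                > np.mean([s.caliber_px for s in t.segments]))

    def test_prune_above_max_caliber_empties_network(self):
        t = generate_network("medusa", seed=1)
        post = apply_anti_vegf(t, prune_caliber_px=99.0)
        assert post.segments == []
        tm = post.true_metrics()
        assert tm.vessel_area_mm2 == 0.0 and tm.vessel_junctions == 0

    def test_orphaned_descendants_removed(self):
        t = generate_network("medusa", seed=4)
        post = apply_anti_vegf(t, prune_caliber_px=2.3)
        alive = {s.id for s in post.segments}
        for s in post.segments:
            assert s.parent is None or s.parent in alive


class TestRender:
    def test_noise_free_render_is_binary_like(self, medusa_clean):
        truth, img, lesion = medusa_clean
        assert set(np.unique(img.pixels)) <= {0.0, 1.0}
        assert np.array_equal(img.pixels == 1.0, truth.tube_mask())

    def test_same_seed_renders_identical_images(self, medusa_truth):
        i1, m1 = render_octa(medusa_truth, seed=11)
        i2, m2 = render_octa(medusa_truth, seed=11)
        assert np.array_equal(i1.pixels, i2.pixels)
        assert np.array_equal(m1.mask, m2.mask)

    def test_speckle_changes_with_seed(self, medusa_truth):
        i1, _ = render_octa(medusa_truth, seed=11)
        i2, _ = render_octa(medusa_truth, seed=12)
        assert not np.array_equal(i1.pixels, i2.pixels)


class TestParameterRecovery:
    """Panels computed from speckled renders track the ground truth: junction
    counts within +-15% in aggregate, length within +-10%, tortuosity within
    +-0.1 (the sparse loops phenotype is held to per-seed junction counts
    within +-1 and a wider tortuosity band, the loop-diameter chord being the
    most discretization-sensitive convention)."""

    N_SEEDS = 20

    @staticmethod
    def run_pattern(pattern):
        from mcnvquant.biomarkers import compute_panel

        rows = []
        for seed in range(TestParameterRecovery.N_SEEDS):
            truth = generate_network(pattern, seed=seed)
            img, lesion = render_octa(truth)
            panel = compute_panel(img, lesion)
            rows.append((truth.true_metrics(), panel))
        return rows

    @pytest.mark.parametrize("pattern", ["medusa", "sea_fan", "tree_in_bud"])
    def test_interlacing_phenotypes(self, pattern):
        rows = self.run_pattern(pattern)
        vj_true = sum(t.vessel_junctions for t, _ in rows)
        vj_est = sum(p.vessel_junctions for _, p in rows)
        assert abs(vj_est / vj_true - 1) <= 0.15
        vl_true = sum(t.vessel_length_mm for t, _ in rows)
        vl_est = sum(p.vessel_length_mm for _, p in rows)
        assert abs(vl_est / vl_true - 1) <= 0.10
        vt = [abs(p.vessel_tortuosity - t.vessel_tortuosity) for t, p in rows
              if not (math.isnan(p.vessel_tortuosity)
                      or math.isnan(t.vessel_tortuosity))]
        assert np.mean(vt) <= 0.1

    def test_sparse_loops_phenotype(self):
        rows = self.run_pattern("disorganized_loops")
        for t, p in rows:
            assert abs(p.vessel_junctions - t.vessel_junctions) <= 1
        vl_true = sum(t.vessel_length_mm for t, _ in rows)
        vl_est = sum(p.vessel_length_mm for _, p in rows)
        assert abs(vl_est / vl_true - 1) <= 0.10
        vt = [abs(p.vessel_tortuosity - t.vessel_tortuosity) for t, p in rows
              if not (math.isnan(p.vessel_tortuosity)
                      or math.isnan(t.vessel_tortuosity))]
        assert np.mean(vt) <= 0.25


class TestCohortSimulation:
    def test_cohort_is_deterministic_and_complete(self):
        c1 = generate_cohort(10, seed=3)
        c2 = generate_cohort(10, seed=3)
        assert len(c1) == 10
        for a, b in zip(c1, c2):
            assert a.baseline == b.baseline and a.post_ivi == b.post_ivi
            assert a.n_injections == b.n_injections

    def test_cohort_reproduces_sensitivity_ordering(self):
        """Population relative ratios mirror the clinical report: junction
        count drops the most, fractal dimension the least among decreasing
        markers, and mean vessel diameter does not decrease."""
        from mcnvquant.cohort import build_change_report

        report = build_change_report(generate_cohort(30, seed=1))
        rr = report.table.RR_pct
        decreasing = rr[["mCNV_area", "VA", "FD", "VL", "VJ", "JD"]]
        assert (decreasing < 100).all()
        assert decreasing.idxmin() == "VJ"
        assert decreasing.idxmax() == "FD"
        assert rr["VD"] > 100
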