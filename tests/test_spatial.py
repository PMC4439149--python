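"""Spatial statistics: weights geometry, Moran's I and Gi* against oracles.

The global Moran cross-check against an independent reference implementation
runs once through Rscript on a batch of random fixtures.
"""

import json
import shutil
import subprocess

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reefcpue.spatial import (build_weights, global_morans_i, local_gi_star,
                              morans_profile)


def _brute_moran(values, pts, band):
    """Direct double-sum transcription of the Moran formula."""
    x = np.asarray(values, float)
    n = len(x)
    z = x - x.mean()
    num = 0.0
    s0 = 0.0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = np.hypot(*(pts[i] - pts[j]))
            if d <= band:
                num += z[i] * z[j]
                s0 += 1.0
    return (n / s0) * num / np.sum(z * z)


def _brute_gi_star(values, pts, band):
    """Direct transcription of the Gi* z-form formula."""
    x = np.asarray(values, float)
    n = len(x)
    xbar = x.mean()
    s = np.sqrt(np.mean(x * x) - xbar ** 2)
    out = np.empty(n)
    for i in range(n):
        w = np.hypot(pts[:, 0] - pts[i, 0], pts[:, 1] - pts[i, 1]) <= band
        wi = w.sum()  # includes self (distance 0)
        num = x[w].sum() - xbar * wi
        den = s * np.sqrt((n * wi - wi * wi) / (n - 1))
        out[i] = num / den
    return out


class TestWeights:
    def test_band_100_gives_rook_neighbours(self, grid_10x10_centroids):
        w = build_weights(grid_10x10_centroids, 100.0)
        deg = w.degrees
        # corner 2, edge 3, interior 4
        assert deg.min() == 2 and deg.max() == 4
        assert w.s0 == 2 * (2 * 10 * 9)  # rook edge count on a 10x10 grid

    def test_band_150_gives_queen_neighbours(self, grid_10x10_centroids):
        w = build_weights(grid_10x10_centroids, 150.0)
        assert w.degrees.max() == 8  # interior cells include diagonals

    def test_matches_all_pairs_thresholding(self, rng):
        pts = rng.uniform(0, 1000, (60, 2))
        w = build_weights(pts, 220.0)
        have = set(zip(w.pairs_i.tolist(), w.pairs_j.tolist()))
        for i in range(60):
            for j in range(i + 1, 60):
                expected = np.hypot(*(pts[i] - pts[j])) <= 220.0
                assert ((i, j) in have) == expected

    def test_degenerate_inputs_rejected(self, rng):
        with pytest.raises(ValueError):
            build_weights(rng.uniform(0, 1, (1, 2)), 100.0)
        with pytest.raises(ValueError):
            build_weights(rng.uniform(0, 1, (5, 2)), -1.0)


class TestMoran:
    def test_checkerboard_is_minus_one(self, grid_10x10_centroids):
        vals = ((grid_10x10_centroids[:, 0] // 100
                 + grid_10x10_centroids[:, 1] // 100) % 2).astype(float)
        w = build_weights(grid_10x10_centroids, 100.0)
        r = global_morans_i(vals, w)
        assert r.I == pytest.approx(-1.0, abs=1e-12)

    def test_smooth_gradient_clusters(self, grid_10x10_centroids):
        vals = grid_10x10_centroids[:, 0] + 0.5 * grid_10x10_centroids[:, 1]
        w = build_weights(grid_10x10_centroids, 100.0)
        r = global_morans_i(vals, w)
        assert r.I > 0 and r.z > 1.65

    def test_matches_double_sum_oracle(self, rng):
        for _ in range(5):
            pts = rng.uniform(0, 800, (40, 2))
            vals = rng.normal(size=40)
            w = build_weights(pts, 250.0)
            if w.n_isolates:
                continue
            r = global_morans_i(vals, w)
            assert r.I == pytest.approx(_brute_moran(vals, pts, 250.0),
                                        abs=1e-12)

    def test_permutation_mean_matches_expected(self, rng, grid_10x10_centroids):
        vals = rng.normal(size=100)
        w = build_weights(grid_10x10_centroids, 100.0)
        sims = np.empty(2000)
        for k in range(2000):
            sims[k] = global_morans_i(rng.permutation(vals), w).I
        se = sims.std(ddof=1) / np.sqrt(len(sims))
        assert abs(sims.mean() - (-1.0 / 99.0)) <= 3 * se

    def test_constant_values_error(self, grid_10x10_centroids):
        w = build_weights(grid_10x10_centroids, 100.0)
        with pytest.raises(ValueError, match="variance"):
            global_morans_i(np.ones(100), w)

    def test_isolates_dropped_with_count(self, rng):
        pts = np.vstack([rng.uniform(0, 300, (30, 2)), [[5000.0, 5000.0]]])
        vals = rng.normal(size=31)
        w = build_weights(pts, 150.0)
        r = global_morans_i(vals, w)
        assert r.n_isolates == 1 and r.n == 30

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(a=st.floats(0.1, 50.0), b=st.floats(-100.0, 100.0),
           sign=st.sampled_from([-1.0, 1.0]))
    def test_affine_invariance(self, a, b, sign):
        xs, ys = np.meshgrid(np.arange(10) * 100.0 + 50.0,
                             np.arange(10) * 100.0 + 50.0)
        pts = np.column_stack([xs.ravel(), ys.ravel()])
        rng = np.random.default_rng(5)
        vals = rng.normal(size=100)
        w = build_weights(pts, 150.0)
        r1 = global_morans_i(vals, w)
        r2 = global_morans_i(sign * a * vals + b, w)
        assert r1.I == pytest.approx(r2.I, abs=1e-9)

    def test_profile_is_pure_and_matches_per_band(self, rng,
                                                  grid_10x10_centroids):
        vals = rng.normal(size=100)
        res1, err1 = morans_profile(vals, grid_10x10_centroids)
        res2, err2 = morans_profile(vals, grid_10x10_centroids)
        assert [r.I for r in res1] == [r.I for r in res2]
        for r in res1:
            w = build_weights(grid_10x10_centroids, r.band_m)
            direct = global_morans_i(vals, w)
            assert r.I == pytest.approx(direct.I, abs=0)
            assert r.z == pytest.approx(direct.z, abs=0)


@pytest.mark.skipif(shutil.which("Rscript") is None,
                    reason="Rscript not available")
def test_moran_matches_reference_implementation(rng, tmp_path):
    """Row-standardized I, E[I] and randomization SD vs an independent
    reference implementation, 20 random fixtures, 1e-8."""
    fixtures = []
    for _ in range(20):
        pts = rng.uniform(0, 900, (25, 2))
        vals = rng.normal(size=25)
        fixtures.append((pts, vals))
    payload = [{"pts": p.tolist(), "vals": v.tolist()} for p, v in fixtures]
    (tmp_path / "fixtures.json").write_text(json.dumps(payload))
    script = tmp_path / "oracle.R"
    script.write_text("""
suppressMessages(library(ape))
suppressMessages(library(jsonlite))
fx <- fromJSON(commandArgs(TRUE)[1], simplifyVector = FALSE)
out <- lapply(fx, function(f) {
  pts <- do.call(rbind, lapply(f$pts, unlist))
  x <- unlist(f$vals)
  d <- as.matrix(dist(pts))
  w <- (d > 0 & d <= 300) * 1.0
  if (any(rowSums(w) == 0)) return(NULL)
  r <- Moran.I(x, w)
  list(observed = r$observed, expected = r$expected, sd = r$sd)
})
cat(toJSON(out, auto_unbox = TRUE, digits = 15, null = "null"))
""")
    res = subprocess.run(["Rscript", str(script), str(tmp_path / "fixtures.json")],
                         capture_output=True, text=True, check=True)
    refs = json.loads(res.stdout)
    n_checked = 0
    for (pts, vals), ref in zip(fixtures, refs):
        if ref is None:
            continue
        w = build_weights(pts, 300.0)
        mine = global_morans_i(vals, w, style="W")
        assert mine.I == pytest.approx(ref["observed"], abs=1e-8)
        assert mine.expected == pytest.approx(ref["expected"], abs=1e-12)
        assert np.sqrt(mine.variance) == pytest.approx(ref["sd"], abs=1e-8)
        n_checked += 1
    assert n_checked >= 15


class TestGiStar:
    def test_single_spike_peaks_at_spike(self, grid_10x10_centroids):
        vals = np.ones(100)
        vals[44] = 50.0
        w = build_weights(grid_10x10_centroids, 250.0, include_self=True)
        g = local_gi_star(vals, w).gi_star
        # the spike cell attains the maximum, jointly with band neighbours
        # whose neighbourhood also contains the spike
        assert g[44] == pytest.approx(g.max(), rel=1e-12)
        d = np.hypot(grid_10x10_centroids[:, 0] - grid_10x10_centroids[44, 0],
                     grid_10x10_centroids[:, 1] - grid_10x10_centroids[44, 1])
        assert g[(d > 0) & (d <= 250.0)].min() > np.median(g)

    def test_matches_formula_transcription(self, rng):
        pts = rng.uniform(0, 600, (30, 2))
        vals = rng.lognormal(1.0, 0.5, 30)
        w = build_weights(pts, 200.0, include_self=True)
        g = local_gi_star(vals, w).gi_star
        expect = _brute_gi_star(vals, pts, 200.0)
        ok = np.isfinite(expect)
        np.testing.assert_allclose(g[ok], expect[ok], atol=1e-12)

    def test_neighbor_sum_bookkeeping_identity(self, rng,
                                               grid_10x10_centroids):
        vals = rng.normal(size=100)
        w = build_weights(grid_10x10_centroids, 250.0, include_self=True)
        nsum = w.neighbor_sum(vals) + vals       # self-inclusive sums
        deg_incl = w.degrees + 1
        assert nsum.sum() == pytest.approx(np.sum(vals * deg_incl), rel=1e-12)

    def test_shift_and_scale_invariance(self, rng, grid_10x10_centroids):
        vals = rng.normal(size=100)
        w = build_weights(grid_10x10_centroids, 250.0, include_self=True)
        g0 = local_gi_star(vals, w).gi_star
        g1 = local_gi_star(vals + 123.0, w).gi_star
        g2 = local_gi_star(vals * 4.5, w).gi_star
        np.testing.assert_allclose(g0, g1, atol=1e-9)
        np.testing.assert_allclose(g0, g2, atol=1e-9)

    def test_requires_self_inclusive_weights(self, rng, grid_10x10_centroids):
        w = build_weights(grid_10x10_centroids, 250.0, include_self=False)
        with pytest.raises(ValueError, match="include_self"):
            local_gi_star(rng.normal(size=100), w)

    def test_constant_values_error(self, grid_10x10_centroids):
        w = build_weights(grid_10x10_centroids, 250.0, include_self=True)
        with pytest.raises(ValueError, match="variance"):
            local_gi_star(np.full(100, 3.0), w)
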