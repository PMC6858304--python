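"""Synthetic-generator contracts: determinism, morphology, point
processes, difficulty dial, dose-law simulation."""

import numpy as np
import pytest
from skimage import feature, measure

import netquant as nq
from netquant.baseline import shape_features
from netquant.errors import PlacementError, ValidationError
from netquant.spatial import annd, clark_evans_expectation
from netquant.synth import (DEFAULT_BACKGROUND, sample_hardcore_points,
                            sample_thomas_points)


class TestRenderField:
    def test_empty_field_has_background_only(self):
        spec = nq.FieldSpec(height=96, width=96, n_nuclei=0,
                            phenotype_fractions=(1.0, 0.0, 0.0), seed=1)
        field = nq.render_field(spec)
        assert len(field.annotations) == 0
        assert abs(field.image.mean() - DEFAULT_BACKGROUND[0]) < 15

    def test_fraction_rounding_is_deterministic(self):
        spec = nq.FieldSpec(height=512, width=672, n_nuclei=50,
                            phenotype_fractions=(0.5, 0.5, 0.0), seed=2)
        counts = nq.render_field(spec).counts()
        assert counts == {1: 25, 2: 25}

    def test_hardcore_minimum_distance_brute_force(self, rng):
        pts = sample_hardcore_points(40, 400, 500, margin=10.0,
                                     min_distance=20.0, rng=rng)
        d = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 20.0

    def test_unsatisfiable_hardcore_raises_placement_error(self, rng):
        with pytest.raises(PlacementError, match="hard-core"):
            sample_hardcore_points(50, 60, 60, margin=5.0,
                                   min_distance=30.0, rng=rng)

    def test_identical_spec_renders_bit_identical(self):
        spec = nq.FieldSpec(height=128, width=160, n_nuclei=8, seed=7)
        a, b = nq.render_field(spec), nq.render_field(spec)
        assert np.array_equal(a.image, b.image)
        assert a.annotations.equals(b.annotations)

    def test_margin_keeps_nuclei_inside(self):
        field = nq.render_field(nq.FieldSpec(height=128, width=160,
                                             n_nuclei=10, seed=3))
        ann = field.annotations
        assert (ann.x >= 5).all() and (ann.x < 160 - 5).all()
        assert (ann.y >= 5).all() and (ann.y < 128 - 5).all()


class TestRenderPatch:
    def test_netotic_patch_is_one_connected_region(self, rng):
        nuc = nq.sample_nucleus("netotic", 0.0, rng)
        patch = nq.render_patch(nuc, 32, noise=False)
        offset, sd = DEFAULT_BACKGROUND
        binary = patch.astype(float) > offset + 3 * sd
        assert binary.any()
        assert measure.label(binary, connectivity=2).max() == 1

    def test_sharp_trilobed_nucleus_has_three_maxima(self):
        nuc = nq.NucleusSpec(phenotype="non_netotic", lobe_count=3,
                             radius=6.5, peak_intensity=30000,
                             blur_sigma=0.05, rng_key=9)
        patch = nq.render_patch(nuc, 32, noise=False).astype(float)
        peaks = feature.peak_local_max(patch, min_distance=2,
                                       threshold_abs=3000)
        assert len(peaks) == 3

    def test_zero_peak_equals_pure_background(self):
        a = nq.NucleusSpec(phenotype="netotic", lobe_count=1, radius=10,
                           peak_intensity=0, blur_sigma=3.0, rng_key=1)
        b = nq.NucleusSpec(phenotype="non_netotic", lobe_count=2, radius=6,
                           peak_intensity=0, blur_sigma=1.0, rng_key=2)
        pa = nq.render_patch(a, 32, seed=5)
        pb = nq.render_patch(b, 32, seed=5)
        assert np.array_equal(pa, pb)  # both are background-only draws

    def test_oversized_nucleus_rejected(self):
        nuc = nq.NucleusSpec(phenotype="netotic", lobe_count=1, radius=20,
                             peak_intensity=20000, blur_sigma=3.0)
        with pytest.raises(ValidationError, match="does not fit"):
            nq.render_patch(nuc, 32)

    def test_spec_invariants_enforced(self):
        with pytest.raises(ValidationError):
            nq.NucleusSpec(phenotype="non_netotic", lobe_count=1, radius=6,
                           peak_intensity=30000, blur_sigma=1.0)
        with pytest.raises(ValidationError):
            nq.NucleusSpec(phenotype="netotic", lobe_count=1, radius=10,
                           peak_intensity=70000, blur_sigma=3.0)


class TestDifficultyDial:
    def test_difficulty_zero_is_linearly_separable_on_shape_features(self):
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler
        from sklearn.svm import LinearSVC
        rng = np.random.default_rng(1)
        feats, labs = [], []
        for ci, cls in enumerate(["non_netotic", "netotic", "necrotic"]):
            for _ in range(60):
                nuc = nq.sample_nucleus(cls, 0.0, rng)
                patch = nq.render_patch(nuc, 48,
                                        seed=int(rng.integers(2**31)))
                f = shape_features(patch)
                assert f is not None
                feats.append(f)
                labs.append(ci)
        clf = make_pipeline(StandardScaler(),
                            LinearSVC(C=50.0, max_iter=50000))
        clf.fit(feats, labs)
        assert clf.score(feats, labs) == 1.0

    def test_difficulty_one_collapses_morphologies(self):
        """At difficulty 1 the class parameter ranges coincide, so the
        shape features must overlap heavily (no linear separation)."""
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler
        from sklearn.svm import LinearSVC
        rng = np.random.default_rng(2)
        feats, labs = [], []
        for ci, cls in enumerate(["non_netotic", "netotic"]):
            for _ in range(50):
                nuc = nq.sample_nucleus(cls, 1.0, rng)
                patch = nq.render_patch(nuc, 48,
                                        seed=int(rng.integers(2**31)))
                f = shape_features(patch)
                if f is not None:
                    feats.append(f)
                    labs.append(ci)
        clf = make_pipeline(StandardScaler(),
                            LinearSVC(C=50.0, max_iter=50000))
        clf.fit(feats, labs)
        assert clf.score(feats, labs) < 0.9


class TestPointProcessStatistics:
    def test_csr_annd_matches_clark_evans(self):
        """Hard-core process with distance 0 is CSR: mean ANND over 100
        replicates within 10% of 1/(2 sqrt(lambda))."""
        h, w, n = 512, 672, 250
        rng = np.random.default_rng(3)
        vals = []
        for _ in range(100):
            pts = np.column_stack([rng.uniform(1, h - 1, n),
                                   rng.uniform(1, w - 1, n)])
            vals.append(annd(pts))
        expected = clark_evans_expectation(n, h * w)
        assert abs(np.mean(vals) - expected) / expected < 0.10

    def test_thomas_clusters_tighter_than_hardcore(self):
        """Paired over 50 seeds: clustered fields have smaller ANND than
        dispersed fields at equal point count."""
        h, w, n = 400, 500, 60
        t_vals, hc_vals = [], []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            t = sample_thomas_points(n, h, w, 5.0, parent_rate=6.0,
                                     cluster_sigma=18.0, rng=rng)
            hc = sample_hardcore_points(n, h, w, 5.0, 20.0, rng)
            t_vals.append(annd(t))
            hc_vals.append(annd(hc))
        assert np.mean(t_vals) < np.mean(hc_vals)
        assert np.mean(np.array(t_vals) < np.array(hc_vals)) > 0.9


class TestDoseSeries:
    def test_midpoint_at_ec50_in_infinite_cell_limit(self):
        spec = nq.DoseSeriesSpec(ec50=2.1, hill=1.0, bottom=10, top=90,
                                 concentrations=(0.1, 2.1, 100.0),
                                 cells_per_well=None, n_replicates=1)
        df = nq.simulate_dose_series(spec)
        mid = df[df.concentration == 2.1].response.iloc[0]
        assert mid == pytest.approx((10 + 90) / 2)

    def test_high_dose_approaches_top(self):
        spec = nq.DoseSeriesSpec(ec50=1.0, hill=1.0,
                                 concentrations=(0.5, 1e6),
                                 cells_per_well=None, n_replicates=1)
        df = nq.simulate_dose_series(spec)
        assert df.response.iloc[-1] == pytest.approx(100.0, abs=1e-3)

    def test_binomial_sampling_unbiased_at_ec50(self):
        """At x = EC50 the mean over wells of 10,000 cells sits within 3
        binomial standard errors of 50%."""
        reps = 20
        spec = nq.DoseSeriesSpec(ec50=2.1, hill=1.0, concentrations=(2.1,),
                                 cells_per_well=10_000, n_replicates=reps,
                                 seed=4)
        df = nq.simulate_dose_series(spec)
        se = 100 * np.sqrt(0.25 / (10_000 * reps))
        assert abs(df.response.mean() - 50.0) <= 3 * se

    def test_spec_validation(self):
        with pytest.raises(ValidationError):
            nq.DoseSeriesSpec(ec50=-1, concentrations=(1.0, 2.0))
        with pytest.raises(ValidationError):
            nq.DoseSeriesSpec(ec50=1, concentrations=(2.0, 1.0))
        with pytest.raises(ValidationError):
            nq.DoseSeriesSpec(ec50=1, bottom=50, top=40,
                              concentrations=(1.0, 2.0))
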