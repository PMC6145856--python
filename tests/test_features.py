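"""Feature construction: round-trips, closed forms, invariances."""

import numpy as np
import pytest

from docprog._utils import R_CLIP
from docprog.exceptions import ConfigurationError, PipelineError
from docprog.features import (
    ConnectivityProfile,
    assemble_feature_vector,
    build_network_templates,
    extract_roi_timeseries,
    pairwise_fc,
    resemblance_features,
    seed_zmap,
)
from docprog.roi import N_FC_FEATURES, N_IMAGING_FEATURES, Roi, RoiSet, example_roiset
from docprog.synthetic import SubjectRecord, gen_bold_nifti

from conftest import make_run


class TestExtractRoiTimeseries:
    def test_one_voxel_roi_equals_voxel_series(self, rng):
        data = rng.standard_normal((10, 10, 8, 15))
        affine = np.eye(4)  # voxel size 1 mm, mm == voxel index
        run = make_run(data, affine=affine)
        rois = RoiSet((Roi("pt", "visual", (4.0, 5.0, 3.0), radius=0.4),))
        ts = extract_roi_timeseries(run, rois)
        np.testing.assert_allclose(ts[0], data[4, 5, 3, :])

    def test_disjoint_rois_with_equal_series_give_identical_rows(self, rng):
        data = np.zeros((12, 8, 8, 10))
        series = rng.standard_normal(10)
        data[2, 4, 4, :] = series
        data[9, 4, 4, :] = series
        run = make_run(data)
        rois = RoiSet(
            (
                Roi("a", "visual", (2.0, 4.0, 4.0), 0.4),
                Roi("b", "auditory", (9.0, 4.0, 4.0), 0.4),
            )
        )
        ts = extract_roi_timeseries(run, rois)
        np.testing.assert_allclose(ts[0], ts[1])

    def test_out_of_mask_roi_rejected(self, rng):
        data = rng.standard_normal((8, 8, 8, 5))
        mask = np.zeros((8, 8, 8), dtype=bool)
        mask[:4] = True
        run = make_run(data, mask=mask)
        rois = RoiSet((Roi("far", "visual", (7.0, 4.0, 4.0), 0.4),))
        with pytest.raises(PipelineError, match="far"):
            extract_roi_timeseries(run, rois)


class TestPairwiseFc:
    def test_canonical_length_for_22_rois(self, rng):
        ts = rng.standard_normal((22, 50))
        assert len(pairwise_fc(ts)) == N_FC_FEATURES == 231

    def test_duplicated_rows_are_clipped_finite(self, rng):
        ts = rng.standard_normal((3, 30))
        ts[1] = ts[0]
        z = pairwise_fc(ts)
        assert np.isfinite(z).all()
        assert np.isclose(z[0], np.arctanh(R_CLIP))

    def test_null_correlations_are_small(self, rng):
        ts = rng.standard_normal((6, 5000))
        z = pairwise_fc(ts)
        assert np.all(np.abs(z) < 0.05)

    def test_constant_row_rejected(self, rng):
        ts = rng.standard_normal((4, 20))
        ts[2] = 3.0
        with pytest.raises(PipelineError, match="2"):
            pairwise_fc(ts)

    def test_permutation_symmetry(self, rng):
        """Permuting ROI order and un-permuting the output recovers the
        same pairwise values."""
        n = 7
        ts = rng.standard_normal((n, 60))
        perm = rng.permutation(n)
        z = pairwise_fc(ts)
        zp = pairwise_fc(ts[perm])

        def pos(i, j, n):
            i, j = min(i, j), max(i, j)
            return i * n - i * (i + 1) // 2 + (j - i) - 1

        for a in range(n):
            for b in range(a + 1, n):
                ia, ib = list(perm).index(a), list(perm).index(b)
                assert np.isclose(z[pos(a, b, n)], zp[pos(ia, ib, n)])


class TestSeedZmap:
    def test_self_correlation_hits_clip_maximum(self, rng):
        data = rng.standard_normal((6, 6, 4, 25))
        run = make_run(data)
        z = seed_zmap(run, data[2, 3, 1, :])
        assert np.isclose(z[2, 3, 1], np.arctanh(R_CLIP))

    def test_anticorrelated_voxel_hits_clip_minimum(self, rng):
        data = rng.standard_normal((6, 6, 4, 25))
        data[0, 0, 0, :] = -data[2, 3, 1, :]
        run = make_run(data)
        z = seed_zmap(run, data[2, 3, 1, :])
        assert np.isclose(z[0, 0, 0], -np.arctanh(R_CLIP))

    def test_matches_hand_computed_correlation(self, rng):
        data = rng.standard_normal((4, 4, 3, 30))
        run = make_run(data)
        seed = rng.standard_normal(30)
        z = seed_zmap(run, seed)
        r = np.corrcoef(data[1, 2, 0, :], seed)[0, 1]
        assert abs(z[1, 2, 0] - np.arctanh(r)) < 1e-12

    def test_zero_variance_seed_rejected(self, rng):
        run = make_run(rng.standard_normal((4, 4, 3, 10)))
        with pytest.raises(PipelineError):
            seed_zmap(run, np.ones(10))


class TestNetworkTemplates:
    def test_hand_computed_three_control_voxel(self):
        maps = [np.full((2, 2, 2), v) for v in (0.1, 0.2, 0.3)]
        tm = build_network_templates({"visual": maps})["visual"]
        expected = 0.2 / (0.1 / np.sqrt(3))
        np.testing.assert_allclose(tm.tmap, expected)

    def test_identical_nonzero_maps_capped(self):
        maps = [np.full((3, 3, 3), 0.4)] * 4
        tm = build_network_templates({"auditory": maps})["auditory"]
        assert np.all(tm.tmap == 100.0)

    def test_null_maps_false_positive_rate(self, rng):
        from scipy import stats

        n = 20
        maps = [rng.standard_normal((20, 20, 10)) for _ in range(n)]
        tm = build_network_templates({"salience": maps})["salience"]
        tcrit = stats.t.ppf(0.975, df=n - 1)
        frac = (np.abs(tm.tmap) > tcrit).mean()
        assert abs(frac - 0.05) < 0.01

    def test_too_few_controls_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            build_network_templates({"visual": [rng.standard_normal((2, 2, 2))] * 2})


class TestResemblance:
    def _templates(self, rng, roiset):
        maps = {}
        for net in set(roiset.networks):
            maps[net] = [rng.standard_normal((8, 8, 6)) for _ in range(4)]
        return build_network_templates(maps)

    def test_identical_map_gives_one(self, rng, tiny_roiset):
        templates = self._templates(rng, tiny_roiset)
        zmaps = [templates[r.network].tmap.copy() for r in tiny_roiset]
        res = resemblance_features(zmaps, templates, tiny_roiset)
        np.testing.assert_allclose(res, 1.0)

    def test_negated_map_gives_minus_one(self, rng, tiny_roiset):
        templates = self._templates(rng, tiny_roiset)
        zmaps = [-templates[r.network].tmap for r in tiny_roiset]
        res = resemblance_features(zmaps, templates, tiny_roiset)
        np.testing.assert_allclose(res, -1.0)

    def test_affine_rescaling_invariance(self, rng, tiny_roiset):
        templates = self._templates(rng, tiny_roiset)
        zmaps = [
            0.3 * templates[r.network].tmap + rng.standard_normal((8, 8, 6))
            for r in tiny_roiset
        ]
        base = resemblance_features(zmaps, templates, tiny_roiset)
        scaled = resemblance_features(
            [3.7 * z + 1.2 for z in zmaps], templates, tiny_roiset
        )
        np.testing.assert_allclose(base, scaled, atol=1e-12)

    def test_degradation_lowers_every_resemblance(self, rng):
        roiset = example_roiset()
        templates = {}
        base_maps = {net: rng.standard_normal((10, 10, 8)) for net in set(roiset.networks)}
        templates = build_network_templates(
            {
                net: [m + 0.1 * rng.standard_normal(m.shape) for _ in range(4)]
                for net, m in base_maps.items()
            }
        )
        noise = {r.name: rng.standard_normal((10, 10, 8)) for r in roiset}
        intact = [
            templates[r.network].tmap + 0.5 * noise[r.name] for r in roiset
        ]
        degraded = [
            0.2 * templates[r.network].tmap + 2.0 * noise[r.name] for r in roiset
        ]
        res_intact = resemblance_features(intact, templates, roiset)
        res_degraded = resemblance_features(degraded, templates, roiset)
        assert np.all(res_intact > res_degraded)


class TestAssembleFeatureVector:
    def _profile(self, rng, n=22):
        return ConnectivityProfile(
            subject_id="s1",
            fc=rng.standard_normal(n * (n - 1) // 2) * 0.3,
            resemblance=rng.uniform(-0.5, 0.9, n),
        )

    def _subject(self, etiology="trauma"):
        return SubjectRecord(
            id="s1",
            group="patient",
            age=40.0,
            duration=6.0,
            etiology=etiology,
            crsr_t0=7,
        )

    def test_total_imaging_feature_count(self, rng):
        vec, names = assemble_feature_vector(self._profile(rng), self._subject())
        assert len(vec) == N_IMAGING_FEATURES + 4 == 257
        assert sum(1 for n in names if not n.startswith(("age", "duration", "etiology"))) == 253

    def test_trauma_reference_coding(self, rng):
        vec, names = assemble_feature_vector(self._profile(rng), self._subject("trauma"))
        assert vec[names.index("etiology_stroke")] == 0
        assert vec[names.index("etiology_anoxia")] == 0

    def test_anoxia_dummy_coding(self, rng):
        vec, names = assemble_feature_vector(self._profile(rng), self._subject("anoxia"))
        assert vec[names.index("etiology_anoxia")] == 1
        assert vec[names.index("etiology_stroke")] == 0

    def test_missing_clinical_field_rejected(self, rng):
        control = SubjectRecord(id="c", group="control", age=30.0, duration=None,
                                etiology=None, crsr_t0=23)
        with pytest.raises(ConfigurationError, match="etiology|duration"):
            assemble_feature_vector(self._profile(rng), control)

    def test_roundtrip_noise_free_volume(self, rng, tiny_roiset):
        ts = rng.standard_normal((6, 30))
        run = gen_bold_nifti(ts, tiny_roiset, (16, 16, 12), voxel_size_mm=4.0)
        recovered = extract_roi_timeseries(run, tiny_roiset)
        fc_direct = pairwise_fc(ts)
        fc_recovered = pairwise_fc(recovered)
        np.testing.assert_allclose(fc_recovered, fc_direct, atol=1e-10)
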