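"""Segmentation, region partitioning, N/P ratios, staging, structures."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as hst

from _oracles import count_particles_bruteforce
from lamindyn import imagequant as iq
from lamindyn import synthetic as syn


def _disk_mask(shape, center, radius_px):
    yy, xx = np.indices(shape)
    return np.hypot(yy - center[0], xx - center[1]) <= radius_px


def _jaccard(a, b):
    return (a & b).sum() / (a | b).sum()


class TestSegmentNuclei:
    def test_blank_image_empty_mask(self):
        img = iq.NucleusImage({"lamin": np.zeros((64, 64))}, pixel_size=0.1)
        assert iq.segment_nuclei(img).ids.size == 0

    def test_disjoint_disks_recovered(self):
        cfg = syn.SyntheticNucleusConfig(n_nuclei=3, noise_sd=0.0, seed=4,
                                         nucleus_radius=4.0)
        image, truth = syn.gen_nucleus_image(cfg)
        mask = iq.segment_nuclei(image)
        assert mask.ids.size == 3
        label_truth = truth.extra["label_image"]
        for nid in mask.ids:
            m = mask.mask_of(nid)
            overlap = [_jaccard(m, label_truth == k)
                       for k in range(1, 4)]
            assert max(overlap) >= 0.95

    def test_touching_disks_split_by_watershed(self):
        shape = (200, 200)
        img = np.full(shape, 5.0)
        # two disks of radius 40 px overlapping by ~25% of a radius
        img[_disk_mask(shape, (100, 65), 40)] = 200.0
        img[_disk_mask(shape, (100, 135), 40)] = 200.0
        mask = iq.segment_nuclei(
            iq.NucleusImage({"lamin": img}, pixel_size=0.1),
            watershed_min_distance=20)
        assert mask.ids.size == 2


class TestPartitionRegions:
    def test_disk_partition_set_identity(self):
        shape = (64, 64)
        nucleus = _disk_mask(shape, (32, 32), 20)
        mask = iq.NucleusMask(nucleus.astype(int))
        part, = iq.partition_regions(mask, rim_width=3.0, pixel_size=1.0)
        assert not (part.periphery_mask & part.nucleoplasm_mask).any()
        assert np.array_equal(part.periphery_mask | part.nucleoplasm_mask,
                              nucleus)
        inner = _disk_mask(shape, (32, 32), 17)
        assert _jaccard(part.nucleoplasm_mask, inner) >= 0.95

    def test_rim_larger_than_nucleus_flagged(self):
        nucleus = _disk_mask((32, 32), (16, 16), 5)
        part, = iq.partition_regions(iq.NucleusMask(nucleus.astype(int)),
                                     rim_width=6.0, pixel_size=1.0)
        assert part.too_small and not part.nucleoplasm_mask.any()

    @given(hst.integers(0, 10_000))
    def test_partition_identities_on_random_blobs(self, seed):
        rng = np.random.default_rng(seed)
        blob = rng.random((40, 40)) > 0.6
        from scipy import ndimage as ndi
        labels, _ = ndi.label(blob)
        mask = iq.NucleusMask(labels)
        for part in iq.partition_regions(mask, rim_width=2.0, pixel_size=1.0):
            nucleus = mask.mask_of(part.nucleus_id)
            assert not (part.periphery_mask & part.nucleoplasm_mask).any()
            assert np.array_equal(
                part.periphery_mask | part.nucleoplasm_mask, nucleus)


class TestNPRatioAuto:
    def _single_nucleus_record(self, cfg):
        image, _ = syn.gen_nucleus_image(cfg)
        mask = iq.segment_nuclei(image)
        part, = iq.partition_regions(mask, cfg.rim_width_true, cfg.pixel_size)
        return iq.np_ratio_auto(image, part)

    def test_uniform_intensity_ratio_one(self):
        nucleus = _disk_mask((64, 64), (32, 32), 20)
        part, = iq.partition_regions(iq.NucleusMask(nucleus.astype(int)),
                                     rim_width=3.0, pixel_size=1.0)
        img = iq.NucleusImage({"lamin": np.full((64, 64), 37.0)},
                              pixel_size=1.0)
        assert iq.np_ratio_auto(img, part).ratio == pytest.approx(1.0)

    def test_noiseless_synthetic_nucleus_recovers_truth(self):
        cfg = syn.SyntheticNucleusConfig(noise_sd=0.0, seed=5)
        rec = self._single_nucleus_record(cfg)
        assert rec.ratio == pytest.approx(0.25, rel=0.02)

    def test_dark_nucleoplasm_gives_zero_ratio(self):
        cfg = syn.SyntheticNucleusConfig(noise_sd=0.0, seed=5,
                                         nucleoplasm_intensity=0.0,
                                         background_intensity=0.0)
        rec = self._single_nucleus_record(cfg)
        assert rec.ratio == 0.0

    def test_ratio_invariant_under_global_scaling(self):
        cfg = syn.SyntheticNucleusConfig(noise_sd=3.0, seed=6)
        image, _ = syn.gen_nucleus_image(cfg)
        mask = iq.segment_nuclei(image)
        part, = iq.partition_regions(mask, 0.8, cfg.pixel_size)
        r1 = iq.np_ratio_auto(image, part).ratio
        scaled = iq.NucleusImage(
            {"lamin": image.channels["lamin"] * 7.3}, cfg.pixel_size)
        r2 = iq.np_ratio_auto(scaled, part).ratio
        assert r1 == pytest.approx(r2, rel=1e-12)

    def test_zstack_uses_min_and_max_projections(self):
        nucleus = _disk_mask((64, 64), (32, 32), 20)
        part, = iq.partition_regions(iq.NucleusMask(nucleus.astype(int)),
                                     rim_width=3.0, pixel_size=1.0)
        stack = np.stack([np.full((64, 64), 10.0), np.full((64, 64), 40.0)])
        img = iq.NucleusImage({"lamin": stack}, pixel_size=1.0)
        rec = iq.np_ratio_auto(img, part)
        assert rec.n_intensity == 10.0 and rec.p_intensity == 40.0


class TestNPRatioLine:
    def test_stated_arithmetic(self):
        y = np.full(40, 25.0)
        y[2], y[37] = 100.0, 100.0
        rec = iq.np_ratio_line(iq.LineProfile(np.arange(40), y))
        assert rec.ratio == pytest.approx(0.25)

    def test_flat_profile_ratio_one(self):
        y = np.full(40, 13.0)
        rec = iq.np_ratio_line(iq.LineProfile(np.arange(40), y))
        assert rec.ratio == pytest.approx(1.0)

    def test_asymmetric_peaks_averaged(self):
        y = np.full(44, 50.0)
        y[1], y[42] = 80.0, 120.0
        rec = iq.np_ratio_line(iq.LineProfile(np.arange(44), y))
        assert rec.p_intensity == pytest.approx(100.0)
        assert rec.ratio == pytest.approx(0.5)

    def test_short_profile_rejected(self):
        with pytest.raises(ValueError):
            iq.np_ratio_line(iq.LineProfile(np.arange(20), np.ones(20)))


class TestNormalizeSeries:
    def test_auto_anchor_before_first_significant_rise(self):
        out, idx = iq.normalize_series([0.2, 0.2, 0.4, 0.6], anchor="auto")
        assert idx == 1
        assert np.allclose(out, [1.0, 1.0, 2.0, 3.0])

    def test_explicit_anchor_zero(self):
        out, idx = iq.normalize_series([0.5, 1.0, 1.5], anchor=0)
        assert idx == 0 and out[0] == 1.0

    def test_constant_series_all_ones(self):
        out, _ = iq.normalize_series([0.4] * 5, anchor=0)
        assert np.allclose(out, 1.0)

    def test_auto_anchor_unresolvable_on_flat_series(self):
        with pytest.raises(ValueError):
            iq.normalize_series([0.3, 0.3, 0.3], anchor="auto")

    def test_zero_anchor_ratio_rejected(self):
        with pytest.raises(ValueError):
            iq.normalize_series([0.0, 1.0], anchor=0)


class TestDapiAndStaging:
    def test_integrated_density_is_sum(self):
        labels = np.zeros((20, 20), dtype=int)
        labels[:10, :10] = 1
        dna = np.full((20, 20), 2.0)
        img = iq.NucleusImage({"dna": dna}, pixel_size=1.0)
        dens = iq.integrated_dapi(iq.NucleusMask(labels), img)
        assert dens[1] == pytest.approx(200.0)
        img2 = iq.NucleusImage({"dna": dna * 2}, pixel_size=1.0)
        assert iq.integrated_dapi(iq.NucleusMask(labels), img2)[1] == \
            pytest.approx(400.0)

    def test_4c_to_2c_density_ratio_near_two(self):
        ratios = []
        for seed in range(6):
            cfg = syn.SyntheticNucleusConfig(n_nuclei=2, noise_sd=0.0,
                                             nucleus_radius=4.0, seed=seed)
            image, truth = syn.gen_nucleus_image(cfg)
            mask = iq.NucleusMask(truth.extra["label_image"])
            dens = iq.integrated_dapi(mask, image)
            labs = truth.true_cell_cycle_label
            if set(labs) != {"G1", "S-G2"}:
                continue
            d = [dens[i + 1] for i in range(2)]
            hi, lo = (d[0], d[1]) if labs[0] == "S-G2" else (d[1], d[0])
            ratios.append(hi / lo)
        assert np.mean(ratios) == pytest.approx(2.0, rel=0.15)

    def test_bimodal_population_staged_correctly(self):
        rng = np.random.default_rng(0)
        g1 = rng.lognormal(np.log(1e5), 0.06, 200)
        sg2 = rng.lognormal(np.log(2e5), 0.06, 200)
        dens = np.concatenate([g1, sg2])
        truth = ["G1"] * 200 + ["S-G2"] * 200
        stages, hist = iq.stage_cell_cycle(dens, (5e4, 1.45e5, 3e5))
        agree = np.mean([s == t for s, t in zip(stages, truth)])
        assert agree >= 0.95
        assert hist[0].sum() == 400

    def test_below_gate_unassigned(self):
        stages, _ = iq.stage_cell_cycle(np.array([1.0]), (10.0, 20.0, 30.0))
        assert stages == ["unassigned"]

    def test_empty_input_empty_histogram(self):
        stages, hist = iq.stage_cell_cycle(np.array([]), (1.0, 2.0, 3.0))
        assert stages == [] and hist[0].size == 0

    def test_non_monotone_gates_rejected(self):
        with pytest.raises(ValueError):
            iq.stage_cell_cycle(np.array([1.0]), (2.0, 1.0, 3.0))


SPOTS_FIXTURES = [
    # 7 spots, 2 centred within the 0.8 um rim -> 5
    ([((0.0, 0.0), 0.5), ((2.0, 0.0), 0.4), ((0.0, 2.0), 0.6),
      ((-2.0, -2.0), 0.3), ((1.5, -1.5), 0.5),
      ((0.0, 4.4), 0.2), ((-4.4, 0.0), 0.2)], 5),
    # above the 5 um^2 area cap -> 0
    ([((0.0, 0.0), 6.0)], 0),
    ([], 0),
    # mixed areas, all interior
    ([((0.0, -2.5), 1.0), ((2.5, 0.0), 0.1), ((-2.0, 2.0), 2.5)], 3),
]


class TestStructures:
    @pytest.mark.parametrize("spots,expected", SPOTS_FIXTURES)
    def test_counts_match_construction_truth(self, spots, expected):
        cfg = syn.SyntheticNucleusConfig(noise_sd=0.0, seed=0)
        image, truth = syn.gen_structure_image(spots, cfg)
        assert truth.true_structure_count == expected
        mask = iq.segment_nuclei(image)
        records = iq.detect_structures(image, mask)
        assert len(records) == expected

    @pytest.mark.parametrize("spots,expected", SPOTS_FIXTURES)
    def test_counts_match_bruteforce_oracle(self, spots, expected):
        cfg = syn.SyntheticNucleusConfig(noise_sd=0.0, seed=0,
                                         image_size=(256, 256),
                                         nucleus_radius=5.0,
                                         pixel_size=0.08)
        image, _ = syn.gen_structure_image(spots, cfg)
        mask = iq.segment_nuclei(image)
        records = iq.detect_structures(image, mask)
        nucleus = mask.mask_of(mask.ids[0])
        avg = image.plane("lamin", "mean")
        thr = iq.threshold_huang(avg[nucleus])
        oracle = count_particles_bruteforce(
            avg > thr, nucleus, cfg.pixel_size,
            rim=iq.DEFAULT_RIM_UM, area_bounds=iq.DEFAULT_AREA_BOUNDS)
        assert len(records) == oracle

    def test_empty_nucleoplasm_zero_records(self):
        cfg = syn.SyntheticNucleusConfig(noise_sd=0.0, seed=0)
        image, _ = syn.gen_structure_image([], cfg)
        mask = iq.segment_nuclei(image)
        assert iq.detect_structures(image, mask) == []

    def test_summary_counts_and_pooled_mean_area(self):
        recs = [iq.ParticleRecord(1, 0.5, (0, 0), 2.0)] * 3 + \
               [iq.ParticleRecord(2, 0.5, (0, 0), 2.0)] * 5
        counts, mean_area = iq.summarize_structures(recs)
        assert counts == {1: 3, 2: 5}
        assert mean_area == pytest.approx(0.5)

    def test_no_structures_flagged_mean(self):
        counts, mean_area = iq.summarize_structures([])
        assert counts == {} and np.isnan(mean_area)


class TestHuangThreshold:
    def test_separates_bimodal_values(self):
        rng = np.random.default_rng(1)
        vals = np.concatenate([rng.normal(50, 3, 5000),
                               rng.normal(200, 3, 500)])
        thr = iq.threshold_huang(vals)
        assert 60 < thr < 190

    def test_flat_input_returns_value(self):
        assert iq.threshold_huang(np.full(100, 7.0)) == 7.0
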