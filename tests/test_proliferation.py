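"""Arrest-front binning, profile recovery, classification, zone dynamics."""

import math

import numpy as np
import pytest

from conftest import grid_cell_map, make_band_maps
from laminametrics import proliferation as pro
from laminametrics import synthetic as syn


def expected_bin_probabilities(cmap: syn.CellMap, model: syn.FrontModel) -> np.ndarray:
    """Oracle: mean assignment probability of the cells in each field."""
    span = pro.front_axis_span(cmap.width_um)
    xn = (cmap.cells.x_um.to_numpy() - span[0]) / (span[1] - span[0])
    p = model(xn)
    fields = pro.bin_fields(cmap)
    edges = np.array([f.x_center - f.field_width / 2 for f in fields] +
                     [fields[-1].x_center + fields[-1].field_width / 2])
    idx = np.clip(np.searchsorted(edges, cmap.cells.x_um.to_numpy(), side="right") - 1,
                  0, len(fields) - 1)
    return np.array([p[idx == i].mean() for i in range(len(fields))])


class TestBinning:
    def test_field_count_from_width(self):
        cmap = grid_cell_map(1000.0, 100.0)
        fields = pro.bin_fields(cmap)
        assert len(fields) == 5  # 1000 um / 200 um

    def test_uniform_lattice_gives_equal_totals(self):
        fields = pro.bin_fields(grid_cell_map(1000.0, 100.0))
        totals = {f.n_total for f in fields}
        assert len(totals) == 1

    def test_partial_field_kept_when_at_least_half(self):
        fields = pro.bin_fields(grid_cell_map(1100.0, 100.0))
        assert len(fields) == 6 and fields[-1].field_width == pytest.approx(100.0)

    def test_partial_field_merged_when_sliver(self):
        fields = pro.bin_fields(grid_cell_map(1050.0, 100.0))
        assert len(fields) == 5 and fields[-1].field_width == pytest.approx(250.0)

    def test_all_positive_map_all_fractions_one(self):
        cmap = grid_cell_map(1000.0, 100.0, gus=np.ones(1000, dtype=bool))
        prof = pro.fraction_profile(pro.bin_fields(cmap))
        assert prof.fractions == pytest.approx(np.ones(5))

    def test_band_outside_map_rejected(self):
        with pytest.raises(ValueError, match="band"):
            pro.bin_fields(grid_cell_map(1000.0, 100.0), band=(50.0, 200.0))


class TestProfiles:
    def test_profile_needs_three_fields(self):
        fields = pro.bin_fields(grid_cell_map(400.0, 100.0))
        with pytest.raises(ValueError, match="at least 3"):
            pro.fraction_profile(fields)

    def test_empty_field_rejected(self):
        f = pro.CellField(0, 100.0, 200.0, 100.0, n_total=0, n_gus=0)
        g = pro.CellField(1, 300.0, 200.0, 100.0, n_total=10, n_gus=1)
        h = pro.CellField(2, 500.0, 200.0, 100.0, n_total=10, n_gus=1)
        with pytest.raises(ValueError, match="empty"):
            pro.fraction_profile([f, g, h])

    def test_col0_recovery_midrib_and_margin(self, col0_band_maps):
        """Pooling 11 leaves recovers ~25% at the midrib-adjacent field and
        ~10% at the margin within two pooled binomial SEs."""
        profiles = [pro.fraction_profile(pro.bin_fields(m)) for m in col0_band_maps]
        avg = pro.average_profiles(profiles)
        assert avg.fractions[0] == pytest.approx(0.25, abs=2 * avg.se[0])
        assert avg.fractions[-1] == pytest.approx(0.10, abs=2 * avg.se[-1])

    def test_tni_recovery_interior_peak(self, tni_band_maps):
        profiles = [pro.fraction_profile(pro.bin_fields(m)) for m in tni_band_maps]
        avg = pro.average_profiles(profiles)
        interior = avg.fractions[1:-1]
        k = 1 + int(np.argmax(interior))
        assert avg.fractions[k] == pytest.approx(0.40, abs=2.5 * avg.se[k])

    def test_profile_recovery_coverage_all_presets(self):
        """Binned fractions estimate the per-field assignment probability
        with close-to-nominal 2-SE coverage (>= 90% over replicate/bin pairs)."""
        hits = total = 0
        for preset in ("col0_like", "tni_like", "jawD_like"):
            model = syn.FRONT_PRESETS[preset]
            for rep, cmap in enumerate(make_band_maps(preset, 7, base_seed=5000)):
                prof = pro.fraction_profile(pro.bin_fields(cmap))
                exp = expected_bin_probabilities(cmap, model)
                hits += int(np.sum(np.abs(prof.fractions - exp) <= 2 * np.maximum(prof.se, 1e-9)))
                total += len(exp)
        assert hits / total >= 0.90


class TestClassification:
    @staticmethod
    def profile_from_fractions(fracs, n=150):
        fields = [
            pro.CellField(i, 100 + 200.0 * i, 200.0, 100.0, n, int(round(f * n)))
            for i, f in enumerate(fracs)
        ]
        return pro.fraction_profile(fields)

    def test_noiseless_preset_shapes(self):
        lin = np.linspace(0.25, 0.10, 5)
        assert pro.classify_front(self.profile_from_fractions(lin)).label == "mild_convex"
        tni = [0.27, 0.40, 0.34, 0.25, 0.15]
        assert (
            pro.classify_front(self.profile_from_fractions(tni)).label
            == "strong_convex_with_midrib_dip"
        )
        jaw = np.linspace(0.10, 0.30, 5)
        assert pro.classify_front(self.profile_from_fractions(jaw)).label == "concave"
        flat = np.full(5, 0.2)
        assert pro.classify_front(self.profile_from_fractions(flat)).label == "flat"

    @pytest.mark.parametrize(
        "preset, expected",
        [
            ("col0_like", "mild_convex"),
            ("tni_like", "strong_convex_with_midrib_dip"),
            ("jawD_like", "concave"),
        ],
    )
    def test_simulated_replicates_classify_consistently(self, preset, expected):
        """Averaged 5-leaf profiles at >= 100 cells/field reproduce the
        qualitative front shapes in every replicate."""
        for rep in range(5):
            maps = make_band_maps(preset, 5, base_seed=7000 + 100 * rep)
            avg = pro.average_profiles(
                [pro.fraction_profile(pro.bin_fields(m)) for m in maps]
            )
            assert pro.classify_front(avg).label == expected

    def test_too_few_fields_rejected(self):
        prof = self.profile_from_fractions([0.2, 0.3, 0.2])
        with pytest.raises(ValueError, match="at least 4"):
            pro.classify_front(prof)


class TestZoneLength:
    def test_step_profile(self):
        # 2 mm leaf fully proliferating over the basal 0.6 mm
        cmap = grid_cell_map(200.0, 2000.0)
        cmap.cells["gus"] = cmap.cells["y_um"] < 600.0
        assert pro.zone_length(cmap) == pytest.approx(0.6, abs=0.02)

    def test_all_proliferating_full_length(self):
        cmap = grid_cell_map(200.0, 2000.0)
        cmap.cells["gus"] = True
        assert pro.zone_length(cmap) == pytest.approx(2.0)

    def test_threshold_sweep_monotone(self):
        # GUS fraction declines tipward, so a stricter (lower) threshold is
        # reached further from the base: zone length is non-increasing in
        # the threshold
        cmap = grid_cell_map(200.0, 2000.0)
        rng = np.random.default_rng(3)
        p = 1.0 - cmap.cells["y_um"].to_numpy() / 2000.0  # monotone decline
        cmap.cells["gus"] = rng.random(len(p)) < p
        zones = [pro.zone_length(cmap, threshold=t) for t in (0.05, 0.10, 0.15, 0.20)]
        assert all(b <= a for a, b in zip(zones, zones[1:]))

    def test_empty_column_rejected(self):
        cmap = grid_cell_map(200.0, 500.0)
        with pytest.raises(ValueError, match="midrib-adjacent"):
            pro.zone_length(cmap, column_width_um=1.0)


class TestZoneSlope:
    def test_exact_fit_and_r2(self):
        recs = [
            pro.ProliferationZoneRecord(L, 1.25 - 0.37 * L) for L in (1.0, 1.5, 2.0, 2.5, 3.0)
        ]
        slope, r2 = pro.zone_slope(recs)
        assert slope == pytest.approx(-0.37)
        assert r2 == pytest.approx(1.0)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(0)
        L = rng.uniform(1, 3, 15)
        z = np.clip(1.0 - 0.3 * L + rng.normal(0, 0.05, 15), 0, None)
        base = [pro.ProliferationZoneRecord(a, min(b, a)) for a, b in zip(L, z)]
        scaled = [
            pro.ProliferationZoneRecord(10 * a, min(10 * b, 10 * a)) for a, b in zip(L, z)
        ]
        assert pro.zone_slope(scaled)[0] == pytest.approx(pro.zone_slope(base)[0])

    def test_degenerate_lengths_rejected(self):
        recs = [pro.ProliferationZoneRecord(2.0, 1.0)] * 3
        with pytest.raises(ValueError, match="leaf lengths equal"):
            pro.zone_slope(recs)

    def test_record_invariant(self):
        with pytest.raises(ValueError):
            pro.ProliferationZoneRecord(leaf_length=1.0, zone_length=1.5)
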