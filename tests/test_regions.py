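"""17-region scheme: assignment, area-weighted summaries, partition."""

import numpy as np
import pytest

from sclsettle.errors import RegionSchemeError
from sclsettle.reconstruction import PolarGrid, PolarThicknessMap
from sclsettle.regions import (
    DEFAULT_SCHEME,
    RegionScheme,
    count_regions,
    region_areas,
    region_of,
    summarize_regions,
)


def cartesian_oracle(field, scheme=DEFAULT_SCHEME, n=2400):
    """Independent region means by brute-force integration on a fine
    Cartesian grid with its own region-assignment logic."""
    half = scheme.outer_radius
    step = 2 * half / n
    ax = -half + step * (np.arange(n) + 0.5)
    x, y = np.meshgrid(ax, ax, indexing="ij")
    r = np.hypot(x, y)
    theta = np.degrees(np.arctan2(y, x)) % 360.0
    inside = r <= scheme.outer_radius
    sectors = ["N", "SN", "S", "ST", "T", "IT", "I", "IN"]
    sect_idx = np.floor(((theta + 22.5) % 360.0) / 45.0).astype(int)
    vals = field(x, y)
    out = {}
    for lab in scheme.labels:
        if lab == "C":
            mask = inside & (r < scheme.central_radius)
        else:
            ann, s = lab.split("-")
            lo, hi = (
                (scheme.central_radius, scheme.mid_radius)
                if ann == "M"
                else (scheme.mid_radius, scheme.outer_radius)
            )
            mask = inside & (r >= lo) & (r < hi) & (sect_idx == sectors.index(s))
        out[lab] = float(vals[mask].mean())
    return out


def field_map(field, grid=None):
    grid = grid or PolarGrid()
    r = grid.r_centers[:, None]
    th = np.deg2rad(grid.theta_centers)[None, :]
    return PolarThicknessMap(grid, field(r * np.cos(th), r * np.sin(th)))


class TestRegionOf:
    def test_seventeen_regions_in_default_scheme(self):
        assert count_regions() == 17
        assert len(set(DEFAULT_SCHEME.labels)) == 17

    def test_scheme_variants_count(self):
        assert count_regions(RegionScheme(sectored_annuli=())) == 3

    @pytest.mark.parametrize(
        "r,theta,label",
        [
            (0.0, 0.0, "C"),
            (0.0, 123.0, "C"),
            (3.5, 90.0, "M-S"),     # mid-peripheral superior
            (5.5, 270.0, "P-I"),    # peripheral inferior
            (3.0, 0.0, "M-N"),
            (5.9, 180.0, "P-T"),
            (2.0, 0.0, "M-N"),      # half-open radial interval
            (5.0, 0.0, "P-N"),
            (6.0, 45.0, "P-SN"),    # outer edge included
            (3.0, 22.5, "M-SN"),    # sector border -> counter-clockwise
            (3.0, 337.5, "M-N"),
        ],
    )
    def test_assignment_examples(self, r, theta, label):
        assert region_of(r, theta) == label

    def test_radius_outside_scheme_rejected(self):
        with pytest.raises(RegionSchemeError):
            region_of(6.4, 0.0)


class TestSummarizeRegions:
    def test_constant_field_means(self):
        pmap = field_map(lambda x, y: np.full(np.shape(x), 300.0))
        out = summarize_regions(pmap)
        reg = out[out["level"] == "region"]
        assert len(reg) == 17
        assert np.allclose(reg["mean_um"], 300.0)
        assert np.allclose(reg["coverage"], 1.0)

    def test_linear_field_matches_integration_oracle(self):
        field = lambda x, y: 300.0 + 20.0 * np.asarray(y)  # noqa: E731
        pmap = field_map(field)
        out = summarize_regions(pmap)
        got = dict(zip(out["region"], out["mean_um"]))
        expected = cartesian_oracle(field)
        for lab, val in expected.items():
            assert got[lab] == pytest.approx(val, abs=0.5), lab
        # +y superior: superior sectors thicker than inferior ones
        assert got["M-S"] > got["M-I"]

    def test_smooth_field_matches_integration_oracle(self):
        field = lambda x, y: (  # noqa: E731
            320.0
            + 12.0 * np.asarray(x)
            - 18.0 * np.asarray(y)
            + 3.0 * np.asarray(x) * np.asarray(y)
            + 2.0 * (np.asarray(x) ** 2 - np.asarray(y) ** 2)
        )
        out = summarize_regions(field_map(field))
        got = dict(zip(out["region"], out["mean_um"]))
        for lab, val in cartesian_oracle(field).items():
            assert got[lab] == pytest.approx(val, abs=0.5), lab

    def test_partition_conserves_disc_integral(self, rng):
        grid = PolarGrid()
        vals = 300.0 + 50.0 * rng.random((grid.n_r, grid.n_theta))
        pmap = PolarThicknessMap(grid, vals)
        out = summarize_regions(pmap)
        reg = out[out["level"] == "region"]
        areas = region_areas(grid)
        total = sum(m * areas[lab] for lab, m in zip(reg["region"], reg["mean_um"]))
        direct = float(np.sum(vals * grid.cell_weights))
        assert total == pytest.approx(direct, rel=1e-9)
        assert sum(areas.values()) == pytest.approx(
            np.pi * 36.0, rel=1e-3
        )  # quadrature area of the 12-mm disc

    def test_rotationally_symmetric_field_has_equal_sector_means(self):
        field = lambda x, y: 250.0 + 30.0 * np.hypot(x, y)  # noqa: E731
        out = summarize_regions(field_map(field))
        got = dict(zip(out["region"], out["mean_um"]))
        for ann in ("M", "P"):
            sector_means = [v for k, v in got.items() if k.startswith(f"{ann}-")]
            assert max(sector_means) - min(sector_means) < 0.1

    def test_missing_sector_reported_missing_not_imputed(self):
        grid = PolarGrid()
        vals = np.full((grid.n_r, grid.n_theta), 300.0)
        pmap = PolarThicknessMap(grid, vals)
        from sclsettle.regions import region_index_map

        labels = region_index_map(grid)
        vals[labels == "M-S"] = np.nan
        out = summarize_regions(pmap)
        got = out.set_index("region")
        assert np.isnan(got.loc["M-S", "mean_um"])
        others = got.loc[[lab for lab in DEFAULT_SCHEME.labels if lab != "M-S"]]
        assert np.allclose(others["mean_um"], 300.0)

    def test_zonal_aggregates_pool_sectors_by_area(self):
        field = lambda x, y: 300.0 + 20.0 * np.asarray(y)  # noqa: E731
        out = summarize_regions(field_map(field))
        zones = out[out["level"] == "zone"].set_index("region")
        reg = out[out["level"] == "region"].set_index("region")
        m_sectors = [f"M-{s}" for s in ("N", "SN", "S", "ST", "T", "IT", "I", "IN")]
        # equal-area sectors: pooled zone mean = plain mean of sector means
        assert zones.loc["M", "mean_um"] == pytest.approx(
            reg.loc[m_sectors, "mean_um"].mean(), abs=1e-9
        )
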