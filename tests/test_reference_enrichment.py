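"""Reference inputs, enrichment arithmetic, MDC logic, and summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from riverref import reference_enrichment as re_
from riverref import synthetic_catchments as sc


def _catchment(**over):
    base = dict(
        id="c1", biome="b", continent="Europe", latitude=45.0,
        crop_pct=40.0, pasture_pct=0.0, urban_pct=0.0, forest_pct=30.0,
        rangeland_pct=30.0, lentic_pct=0.0, olsen_p=20.0, pop_density=100.0,
        slope=3.0, runoff=400.0, pet=900.0, area=50.0, population=5000.0,
        permafrost=False, excluded=False,
    )
    base.update(over)
    return pd.DataFrame([base])


class TestReferenceInputs:
    def test_displaced_land_split_equally(self):
        out = re_.reference_inputs(_catchment())
        assert out["forest_pct"].iloc[0] == pytest.approx(50.0)
        assert out["rangeland_pct"].iloc[0] == pytest.approx(50.0)
        assert out["crop_pct"].iloc[0] == 0.0

    def test_urban_only_catchment(self):
        out = re_.reference_inputs(
            _catchment(crop_pct=0.0, urban_pct=100.0, forest_pct=0.0,
                       rangeland_pct=0.0)
        )
        assert out["forest_pct"].iloc[0] == pytest.approx(50.0)
        assert out["rangeland_pct"].iloc[0] == pytest.approx(50.0)

    def test_pristine_catchment_only_constants_change(self):
        pristine = _catchment(crop_pct=0.0, forest_pct=60.0, rangeland_pct=40.0)
        out = re_.reference_inputs(pristine)
        assert out["forest_pct"].iloc[0] == 60.0
        assert out["olsen_p"].iloc[0] == 2.0
        assert out["pop_density"].iloc[0] == 0.001

    def test_biophysical_fields_untouched(self):
        c = _catchment()
        out = re_.reference_inputs(c)
        for col in ("latitude", "biome", "slope", "runoff", "pet", "area",
                    "lentic_pct"):
            assert (out[col] == c[col]).all()

    def test_land_total_preserved(self, catchments):
        out = re_.reference_inputs(catchments)
        cols = ["crop_pct", "pasture_pct", "urban_pct",
                "forest_pct", "rangeland_pct", "lentic_pct"]
        np.testing.assert_allclose(
            out[cols].sum(axis=1), catchments[cols].sum(axis=1)
        )


class TestEnrichment:
    @pytest.mark.parametrize(
        "cur,ref,expected", [(1.0, 1.0, 0.0), (1.35, 1.0, 35.0), (0.5, 1.0, -50.0)]
    )
    def test_arithmetic(self, cur, ref, expected):
        assert re_.enrichment(cur, ref) == pytest.approx(expected)

    def test_rejects_nonpositive_reference(self):
        with pytest.raises(ValueError):
            re_.enrichment(1.0, 0.0)

    def test_footnote_ci_rule(self):
        lo, hi = re_.enrichment_ci((2.0, 4.0), (1.0, 3.0), 2.0)
        assert lo == pytest.approx(-50.0)
        assert hi == pytest.approx(150.0)

    def test_degenerate_ci_reduces_to_point(self):
        lo, hi = re_.enrichment_ci((1.35, 1.35), (1.0, 1.0), 1.0)
        assert lo == hi == pytest.approx(35.0)

    @given(
        widen=st.floats(0.0, 2.0),
        cur_lo=st.floats(0.5, 2.0),
        width=st.floats(0.0, 2.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_widening_never_narrows(self, widen, cur_lo, width):
        cur = (cur_lo, cur_lo + width)
        ref = (1.0, 2.0)
        lo, hi = re_.enrichment_ci(cur, ref, 1.5)
        lo2, hi2 = re_.enrichment_ci((cur[0] - widen, cur[1] + widen), ref, 1.5)
        assert lo2 <= lo and hi2 >= hi

    def test_unordered_interval_rejected(self):
        with pytest.raises(ValueError):
            re_.enrichment_ci((4.0, 2.0), (1.0, 3.0), 2.0)


class TestIsMDC:
    def test_boundary_values_inclusive(self):
        c = _catchment(olsen_p=5.0, pop_density=0.001, crop_pct=0.0,
                       urban_pct=0.0, forest_pct=80.0, rangeland_pct=0.0,
                       pasture_pct=20.0)
        assert re_.is_mdc(c).iloc[0]

    @pytest.mark.parametrize(
        "field,value",
        [("olsen_p", 6.0), ("pop_density", 0.01), ("crop_pct", 1.0),
         ("urban_pct", 1.0), ("forest_pct", 10.0)],
    )
    def test_single_violation_disqualifies(self, field, value):
        base = dict(olsen_p=4.0, pop_density=0.001, crop_pct=0.0,
                    urban_pct=0.0, forest_pct=85.0, rangeland_pct=0.0,
                    pasture_pct=15.0)
        base[field] = value
        assert not re_.is_mdc(_catchment(**base)).iloc[0]

    def test_reference_inputs_of_natural_catchment_is_mdc(self, catchments):
        ref = re_.reference_inputs(catchments)
        natural = ref["forest_pct"] + ref["rangeland_pct"] >= 80.0
        assert re_.is_mdc(ref.loc[natural]).all()

    def test_caption_variant_is_stricter(self, catchments):
        default = re_.is_mdc(catchments).sum()
        strict = re_.is_mdc(catchments, olsen_max=2.0).sum()
        assert strict <= default


class TestMDCValidation:
    def _inputs(self, bias=0.0):
        truth = sc.TruthParams(seed=3, noise_sd_log=0.0)
        c = sc.generate_catchments(200, truth, mdc_fraction=0.3)
        # observed medians come from the catchments as they are; reference
        # predictions from the pristine counterfactual of each catchment
        obs = pd.DataFrame(
            {
                "site_id": c["id"],
                "median_conc": sc.true_medians(c, truth, "TN").to_numpy(),
            }
        )
        true_ref = sc.true_medians(
            re_.reference_inputs(c), truth, "TN"
        ).to_numpy()
        ref_preds = pd.DataFrame(
            {
                "id": c["id"],
                "point": true_ref * (1 + bias),
                "lower": true_ref * (0.7 + bias),
                "upper": true_ref * (1.3 + bias),
            }
        )
        return ref_preds, c, obs

    def test_zero_noise_all_within_ci(self):
        ref_preds, c, obs = self._inputs()
        report = re_.mdc_validation(ref_preds, c, obs)
        assert not report.empty
        assert report["within_ci"].all()

    def test_biased_predictions_fall_outside(self):
        ref_preds, c, obs = self._inputs(bias=2.0)
        report = re_.mdc_validation(ref_preds, c, obs)
        assert not report["within_ci"].any()

    def test_low_confidence_flag(self):
        ref_preds, c, obs = self._inputs()
        report = re_.mdc_validation(ref_preds, c, obs)
        counts = report.set_index("biome")["n_mdc"]
        flags = report.set_index("biome")["low_confidence"]
        assert (flags == (counts <= 5)).all()

    def test_no_mdc_catchments_empty_report(self):
        ref_preds, c, obs = self._inputs()
        c = c.assign(crop_pct=10.0)  # cropland disqualifies everything
        report = re_.mdc_validation(ref_preds, c, obs)
        assert report.empty


class TestSummarise:
    def _enrichments(self, c):
        return pd.DataFrame(
            {
                "id": c["id"],
                "analyte": "TN",
                "enrichment_pct": np.arange(len(c), dtype=float),
                "enrichment_lower": np.arange(len(c), dtype=float) - 10,
                "enrichment_upper": np.arange(len(c), dtype=float) + 10,
                "reference_within_current_ci": [True] * len(c),
            }
        )

    def test_single_catchment_group(self):
        c = _catchment()
        e = self._enrichments(c)
        out = re_.summarise(e, c, "continent")
        assert out["enrichment_pct"].iloc[0] == 0.0
        assert out["n"].iloc[0] == 1

    def test_area_weighted_mean(self):
        c = pd.concat([_catchment(id="c1", area=1.0),
                       _catchment(id="c2", area=3.0)], ignore_index=True)
        e = self._enrichments(c)
        e["enrichment_pct"] = [0.0, 40.0]
        out = re_.summarise(e, c, "world")
        assert out["enrichment_pct"].iloc[0] == pytest.approx(30.0)

    def test_excluded_catchments_dropped(self):
        c = pd.concat([_catchment(id="c1"),
                       _catchment(id="c2", excluded=True)], ignore_index=True)
        e = self._enrichments(c)
        out = re_.summarise(e, c, "world")
        assert out["n"].iloc[0] == 1

    def test_all_excluded_empty_with_warning(self, caplog):
        c = _catchment(excluded=True)
        e = self._enrichments(c)
        with caplog.at_level("WARNING"):
            out = re_.summarise(e, c, "world")
        assert out.empty
        assert "excluded" in caplog.text

    def test_invalid_group_by(self):
        c = _catchment()
        with pytest.raises(ValueError):
            re_.summarise(self._enrichments(c), c, "country")
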