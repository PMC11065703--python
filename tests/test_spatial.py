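import numpy as np
import pandas as pd
import pytest

from senescape import (
    ImagingCellTable,
    PlaqueSet,
    call_markers,
    classify_peri_plaque,
    peri_vs_nonplaque_contrast,
    qc_trim,
    senescent_proportion_per_cluster,
)


def _cells(rows, channels=("Iba1", "GLB1")):
    df = pd.DataFrame(rows)
    return ImagingCellTable(table=df, channels=list(channels))


def _cell_row(i, roi="r1", sample="s1", x=10.0, y=10.0, **intensities):
    row = {"cell_id": f"c{i}", "roi_id": roi, "sample_id": sample, "x_um": x, "y_um": y,
           "Iba1": 1.0, "GLB1": 1.0}
    row.update(intensities)
    return row


class TestQcTrim:
    def _roi_cells(self, n_rois, cells_per_roi=5, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        i = 0
        for r in range(n_rois):
            base = r + 1.0  # distinct ROI means
            for _ in range(cells_per_roi):
                rows.append(
                    _cell_row(i, roi=f"r{r:03d}", sample=f"s{r // 4}",
                              GLB1=base + rng.uniform(-0.01, 0.01),
                              Iba1=rng.uniform(1, 10))
                )
                i += 1
        return _cells(rows)

    def test_hundred_rois_one_percent_removes_exactly_one(self):
        cells = self._roi_cells(100)
        trimmed, rec = qc_trim(cells, trim_frac=0.01)
        assert rec.n_rois_removed == 1
        assert trimmed.table["roi_id"].nunique() == 99
        # the removed ROI is the lowest-mean one
        assert "r000" not in set(trimmed.table["roi_id"])

    def test_zero_trim_is_identity(self):
        cells = self._roi_cells(10)
        trimmed, rec = qc_trim(cells, trim_frac=0.0)
        assert len(trimmed) == len(cells)
        assert rec.n_rois_removed == 0 and rec.n_cells_removed == 0

    def test_ties_at_cutoff_removed_inclusively(self):
        rows = [
            _cell_row(i, roi="r1", GLB1=5.0, Iba1=v)
            for i, v in enumerate([1.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0])
        ]
        # second ROI so ROI-level trim keeps both
        rows += [_cell_row(100 + i, roi="r2", GLB1=6.0, Iba1=5.0) for i in range(3)]
        trimmed, rec = qc_trim(_cells(rows), trim_frac=0.1)
        kept_r1 = trimmed.table[trimmed.table["roi_id"] == "r1"]
        assert not (kept_r1["Iba1"] == 1.0).any()  # both tied minima removed

    def test_idempotent_with_frozen_cutoffs(self):
        cells = self._roi_cells(50, seed=3)
        once, rec = qc_trim(cells, trim_frac=0.02)
        twice, rec2 = qc_trim(once, trim_frac=0.02, frozen=rec)
        assert len(twice) == len(once)
        assert rec2.n_rois_removed == 0 and rec2.n_cells_removed == 0

    def test_all_rois_removed_errors(self):
        rows = [_cell_row(i, roi="r1", GLB1=1.0) for i in range(3)]
        with pytest.raises(ValueError, match="all ROIs"):
            qc_trim(_cells(rows), trim_frac=0.4)

    def test_invalid_trim_frac(self):
        with pytest.raises(ValueError, match="trim_frac"):
            qc_trim(self._roi_cells(5), trim_frac=0.6)


class TestCallMarkers:
    def test_fixed_threshold_strictly_greater(self):
        cells = _cells([_cell_row(0, Iba1=3.0), _cell_row(1, Iba1=7.0)])
        calls = call_markers(cells, {"Iba1": ("fixed", 5.0)})
        assert calls["Iba1_pos"].tolist() == [False, True]

    def test_zero_threshold_on_nonnegative(self):
        cells = _cells([_cell_row(0, Iba1=0.0), _cell_row(1, Iba1=0.01)])
        calls = call_markers(cells, {"Iba1": ("fixed", 0.0)})
        assert calls["Iba1_pos"].tolist() == [False, True]

    def test_unknown_channel_errors(self):
        cells = _cells([_cell_row(0)])
        with pytest.raises(ValueError, match="unknown channel"):
            call_markers(cells, {"CD45": ("fixed", 1.0)})

    def test_rule_provenance_recorded(self):
        cells = _cells([_cell_row(0), _cell_row(1, Iba1=9.0)])
        calls = call_markers(cells, {"Iba1": ("quantile", 0.5)})
        assert calls.attrs["rules"]["Iba1"] == ("quantile", 0.5)

    def test_otsu_separates_bimodal_mixture(self):
        """Otsu on a planted two-component log-normal mixture misassigns < 2%."""
        rng = np.random.default_rng(9)
        n = 2000
        positive = rng.random(n) < 0.4
        intens = np.where(positive, rng.lognormal(2.5, 0.3, n), rng.lognormal(-1.0, 0.3, n))
        rows = [_cell_row(i, Iba1=float(v)) for i, v in enumerate(intens)]
        calls = call_markers(_cells(rows), {"Iba1": ("otsu",)})
        misassigned = (calls["Iba1_pos"].to_numpy() != positive).mean()
        assert misassigned < 0.02


class TestClusterProportions:
    def _calls(self):
        rows = []
        # sample s1: 4 Iba1+ microglia, 1 of them GLB1+
        for i in range(4):
            rows.append({"cell_id": f"c{i}", "roi_id": "r1" if i < 2 else "r2",
                         "sample_id": "s1", "Iba1_pos": True, "GLB1_pos": i == 0,
                         "cluster": "Micro"})
        # sample s2: only 2 microglia -> excluded
        for i in range(2):
            rows.append({"cell_id": f"d{i}", "roi_id": "r3", "sample_id": "s2",
                         "Iba1_pos": True, "GLB1_pos": False, "cluster": "Micro"})
        return pd.DataFrame(rows)

    def test_ratio_and_exclusion(self):
        calls = self._calls()
        props = senescent_proportion_per_cluster(
            calls.drop(columns="cluster"), calls["cluster"], {"Micro": "Iba1"},
            senescence_channels=["GLB1"],
        ).set_index("sample_id")
        assert props.loc["s1", "proportion"] == pytest.approx(0.25)
        assert props.loc["s2", "excluded"].item()

    def test_roi_counts_sum_to_sample_level(self):
        calls = self._calls()
        props = senescent_proportion_per_cluster(
            calls.drop(columns="cluster"), calls["cluster"], {"Micro": "Iba1"},
            senescence_channels=["GLB1"], min_cells=1,
        )
        by_roi = calls[calls["Iba1_pos"]].groupby("sample_id").size()
        assert (props.set_index("sample_id")["n_cells"] == by_roi).all()


class TestPeriPlaque:
    def _one_plaque(self):
        return PlaqueSet(
            disks=pd.DataFrame(
                {"roi_id": ["r1"], "plaque_id": [1], "cx_um": [100.0],
                 "cy_um": [100.0], "radius_um": [20.0]}
            )
        )

    @pytest.mark.parametrize(
        "offset, expected",
        [(5.0, True), (10.0, True), (15.0, False)],  # inclusive at exactly 10
    )
    def test_centroid_mode_exact_distances(self, offset, expected):
        cells = _cells([_cell_row(0, x=100.0 + 20.0 + offset, y=100.0)])
        out = classify_peri_plaque(cells, self._one_plaque(), radius_um=10.0)
        assert out.iloc[0]["peri_plaque"] == expected
        assert out.iloc[0]["distance_um"] == pytest.approx(offset)

    def test_inside_plaque_distance_zero(self):
        cells = _cells([_cell_row(0, x=105.0, y=95.0)])
        out = classify_peri_plaque(cells, self._one_plaque())
        assert out.iloc[0]["distance_um"] == 0.0 and out.iloc[0]["peri_plaque"]

    def test_no_plaques_infinite_distance(self):
        cells = _cells([_cell_row(0)])
        out = classify_peri_plaque(cells, PlaqueSet())
        assert np.isinf(out.iloc[0]["distance_um"])
        assert not out.iloc[0]["peri_plaque"]

    def test_rotation_translation_invariance(self):
        rng = np.random.default_rng(4)
        pts = rng.uniform(50, 450, (30, 2))
        disks = pd.DataFrame(
            {"roi_id": "r1", "plaque_id": [1, 2], "cx_um": [150.0, 300.0],
             "cy_um": [200.0, 350.0], "radius_um": [15.0, 25.0]}
        )
        cells = _cells([_cell_row(i, x=p[0], y=p[1]) for i, p in enumerate(pts)])
        base = classify_peri_plaque(cells, PlaqueSet(disks=disks.copy()))
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        shift = np.array([37.0, -12.0])
        pts2 = pts @ rot.T + shift
        centers2 = disks[["cx_um", "cy_um"]].to_numpy() @ rot.T + shift
        disks2 = disks.copy()
        disks2[["cx_um", "cy_um"]] = centers2
        cells2 = _cells([_cell_row(i, x=p[0], y=p[1]) for i, p in enumerate(pts2)])
        moved = classify_peri_plaque(cells2, PlaqueSet(disks=disks2))
        np.testing.assert_allclose(base["distance_um"], moved["distance_um"], atol=1e-9)
        np.testing.assert_array_equal(base["peri_plaque"], moved["peri_plaque"])

    def test_mask_mode_agrees_with_centroid_on_disks(self):
        """At 1 um/px, mask dilation matches the continuous rule within 1 px."""
        rng = np.random.default_rng(7)
        disks = pd.DataFrame(
            {"roi_id": "r1", "plaque_id": [1, 2], "cx_um": [120.0, 380.0],
             "cy_um": [130.0, 360.0], "radius_um": [18.0, 12.0]}
        )
        pts = rng.uniform(0, 500, (300, 2))
        cells = _cells([_cell_row(i, x=p[0], y=p[1]) for i, p in enumerate(pts)])
        ps = PlaqueSet(disks=disks)
        cen = classify_peri_plaque(cells, ps, radius_um=10.0, mode="centroid")
        msk = classify_peri_plaque(cells, ps, radius_um=10.0, mode="mask",
                                   scale_um_per_px=1.0)
        disagree = cen["peri_plaque"].to_numpy() != msk["peri_plaque"].to_numpy()
        # disagreements only within 1 px (1 um) of the decision boundary
        assert np.all(np.abs(cen.loc[disagree, "distance_um"] - 10.0) <= 1.5)

    def test_invalid_radius_and_mode(self):
        cells = _cells([_cell_row(0)])
        with pytest.raises(ValueError, match="radius"):
            classify_peri_plaque(cells, self._one_plaque(), radius_um=0)
        with pytest.raises(ValueError, match="mode"):
            classify_peri_plaque(cells, self._one_plaque(), mode="banana")


class TestPeriContrast:
    def _setup(self, peri_rate=0.3, non_rate=0.03, n_samples=10, seed=0):
        rng = np.random.default_rng(seed)
        prox_rows, call_rows = [], []
        i = 0
        for s in range(n_samples):
            sample = f"s{s}"
            for _ in range(120):
                peri = rng.random() < 0.25
                rate = peri_rate if peri else non_rate
                call_rows.append(
                    {"cell_id": f"c{i}", "roi_id": f"{sample}_r0", "sample_id": sample,
                     "Iba1_pos": True, "GLB1_pos": bool(rng.random() < rate)}
                )
                prox_rows.append(
                    {"cell_id": f"c{i}", "roi_id": f"{sample}_r0", "sample_id": sample,
                     "peri_plaque": peri}
                )
                i += 1
        return pd.DataFrame(prox_rows), pd.DataFrame(call_rows)

    def test_planted_contrast_recovered(self):
        prox, calls = self._setup()
        props, tests = peri_vs_nonplaque_contrast(prox, calls)
        glb1 = props[props["marker"] == "GLB1"]
        assert glb1["prop_peri"].mean() == pytest.approx(0.30, abs=0.08)
        assert glb1["prop_non"].mean() == pytest.approx(0.03, abs=0.03)
        assert tests["GLB1"]["p_value"] < 0.05

    def test_identical_rates_null(self):
        prox, calls = self._setup(peri_rate=0.1, non_rate=0.1, seed=5)
        props, tests = peri_vs_nonplaque_contrast(prox, calls)
        assert tests["GLB1"]["p_value"] > 0.05

    def test_no_peri_cells_skipped_with_reason(self):
        prox, calls = self._setup()
        prox["peri_plaque"] = False
        props, tests = peri_vs_nonplaque_contrast(prox, calls)
        assert props.empty and "skipped" in tests
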