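"""Morphometric feature extraction: analytic shapes, identities, filters."""

import numpy as np
import pandas as pd
import pytest
from skimage.draw import disk as draw_disk, ellipse as draw_ellipse

from nephromorph import MaskSpec, generate_mask
from nephromorph.core_io import (
    ARTERY,
    GLOMERULUS,
    LUMEN,
    TUBULE,
    TUFT,
    ClassSchema,
    PixelCalibration,
    SemanticMap,
)
from nephromorph.morphometry import (
    FEATURE_COLUMNS,
    apply_filters,
    compute_features,
    summarize_patient,
    summarize_slide,
)
from nephromorph.postprocess import extract_instances

SCHEMA = ClassSchema()


def instance_map_from(labels, mpp=0.5, patient="p1", slide="s1"):
    sm = SemanticMap(labels=np.asarray(labels, np.int32), schema=SCHEMA,
                     calibration=PixelCalibration(mpp), patient_id=patient,
                     slide_id=slide)
    return extract_instances(sm)


def single_shape_map(cls, rr, cc, shape=(128, 128), mpp=0.5):
    lab = np.zeros(shape, np.int32)
    lab[rr, cc] = SCHEMA.code(cls)
    return instance_map_from(lab, mpp=mpp)


class TestAnalyticShapes:
    def test_disc_features_match_circle_values(self):
        rr, cc = draw_disk((64, 64), 50)
        ft = compute_features(single_shape_map(GLOMERULUS, rr, cc))
        row = ft.iloc[0]
        assert row["area"] == pytest.approx(np.pi * 50**2 * 0.25, rel=0.02)
        assert row["d_max"] == pytest.approx(50.0, rel=0.02)  # 100 px * 0.5
        assert row["circularity"] >= 0.95
        assert row["eccentricity"] <= 0.15
        assert row["elongation"] <= 0.05
        assert row["solidity"] >= 0.98

    def test_two_to_one_ellipse_eccentricity_and_elongation(self):
        rr, cc = draw_ellipse(64, 64, 50, 25)
        ft = compute_features(single_shape_map(TUFT, rr, cc))
        row = ft.iloc[0]
        assert row["eccentricity"] == pytest.approx(np.sqrt(3) / 2, abs=0.05)
        assert row["elongation"] == pytest.approx(0.5, abs=0.05)

    def test_solidity_one_and_circularity_below_one_for_rectangle(self):
        lab = np.zeros((64, 64), np.int32)
        lab[10:40, 10:50] = SCHEMA.code(GLOMERULUS)
        ft = compute_features(instance_map_from(lab))
        assert ft.iloc[0]["solidity"] == pytest.approx(1.0, abs=0.01)
        assert ft.iloc[0]["circularity"] <= 1.0

    def test_shape_columns_only_for_glomeruli_and_tufts(self, small_mask):
        _, imap, _ = small_mask
        ft = compute_features(imap)
        shaped = ft["class"].isin([GLOMERULUS, TUFT])
        for col in ["circularity", "eccentricity", "elongation", "solidity"]:
            assert ft.loc[shaped, col].notna().all()
            assert ft.loc[~shaped, col].isna().all()


class TestStructuralIdentities:
    def test_tuft_fraction_and_bowman_area_identities(self, small_mask):
        """bowman + tuft = glomerulus and fraction = tuft/glomerulus, exactly."""
        _, imap, _ = small_mask
        ft = compute_features(imap).set_index("instance_id")
        for tid in imap.ids_of_class(TUFT):
            pid = imap.records[tid].parent
            glom, tuft = ft.loc[pid], ft.loc[tid]
            assert glom["bowman_area"] + tuft["area"] == pytest.approx(
                glom["area"], abs=1e-9
            )
            assert glom["tuft_area_fraction"] == pytest.approx(
                tuft["area"] / glom["area"], abs=1e-12
            )

    def test_glomerulus_without_tuft_has_missing_tuft_columns(self):
        rr, cc = draw_disk((32, 32), 20)
        ft = compute_features(single_shape_map(GLOMERULUS, rr, cc, shape=(64, 64)))
        assert np.isnan(ft.iloc[0]["tuft_area_fraction"])
        assert np.isnan(ft.iloc[0]["bowman_area"])

    def test_wall_area_is_artery_minus_lumen(self, small_mask):
        _, imap, _ = small_mask
        ft = compute_features(imap).set_index("instance_id")
        for lid in imap.ids_of_class(LUMEN):
            aid = imap.records[lid].parent
            assert ft.loc[aid, "wall_area"] == pytest.approx(
                ft.loc[aid, "area"] - ft.loc[lid, "area"], abs=1e-9
            )
            assert ft.loc[aid, "wall_diameter"] == pytest.approx(
                (ft.loc[aid, "d_max"] - ft.loc[lid, "d_max"]) / 2, abs=1e-9
            )


class TestDistances:
    def brute_force_min_dist(self, imap, iid, candidates):
        from nephromorph.morphometry import _boundary_pixels, _measurement_mask

        a = _boundary_pixels(*_measurement_mask(imap, iid))
        best = np.inf
        for j in candidates:
            b = _boundary_pixels(*_measurement_mask(imap, j))
            d = np.sqrt(((a[:, None, :] - b[None, :, :]) ** 2).sum(-1)).min()
            best = min(best, d)
        return best

    def test_dist_min_equals_brute_force(self, small_mask):
        _, imap, _ = small_mask
        ft = compute_features(imap).set_index("instance_id")
        mpp = imap.calibration.microns_per_pixel
        for tid in imap.ids_of_class(TUBULE)[:5]:
            others = [j for j in imap.records if j != tid]
            bf = self.brute_force_min_dist(imap, tid, others) * mpp
            expected = 0.0 if bf <= np.sqrt(2) * mpp else bf
            assert ft.loc[tid, "dist_min"] == pytest.approx(expected, abs=1e-9)

    def test_touching_structures_report_zero_distance(self):
        lab = np.zeros((20, 30), np.int32)
        lab[5:15, 5:15] = SCHEMA.code(TUBULE)
        lab[5:15, 15:24] = SCHEMA.code(GLOMERULUS)  # abutting columns 14|15
        imap = instance_map_from(lab)
        ft = compute_features(imap)
        assert (ft.loc[ft["class"] == TUBULE, "dist_min"] == 0).all()

    def test_nearest_glomerulus_distance_only_among_glomeruli(self, small_mask):
        _, imap, _ = small_mask
        ft = compute_features(imap)
        gloms = ft["class"] == GLOMERULUS
        assert ft.loc[gloms, "nearest_glomerulus_distance"].notna().all()
        assert ft.loc[ft["class"] == TUBULE, "nearest_glomerulus_distance"].isna().all()


class TestInvariances:
    def test_translation_invariance(self):
        rr, cc = draw_ellipse(40, 40, 20, 12, rotation=0.7)
        ft1 = compute_features(single_shape_map(TUFT, rr, cc))
        ft2 = compute_features(single_shape_map(TUFT, rr + 30, cc + 40))
        for col in ["area", "d_max", "perimeter", "eccentricity", "solidity"]:
            assert ft1.iloc[0][col] == pytest.approx(ft2.iloc[0][col], abs=1e-9)

    def test_calibration_scaling_laws(self, small_mask):
        """Areas scale with s^2, lengths with s, dimensionless features not at all."""
        _, imap, _ = small_mask
        ft1 = compute_features(imap)
        imap2 = type(imap)(
            labels=imap.labels, records=imap.records, schema=imap.schema,
            calibration=PixelCalibration(1.0),  # 2x the original 0.5
        )
        ft2 = compute_features(imap2)
        np.testing.assert_allclose(ft2["area"], ft1["area"] * 4, rtol=1e-12)
        np.testing.assert_allclose(ft2["d_max"], ft1["d_max"] * 2, rtol=1e-12)
        with np.errstate(invalid="ignore"):
            np.testing.assert_allclose(
                ft2["dist_min"].dropna(), ft1["dist_min"].dropna() * 2, rtol=1e-12
            )
        np.testing.assert_allclose(
            ft2["eccentricity"].dropna(), ft1["eccentricity"].dropna(), rtol=1e-12
        )

    def test_id_permutation_invariance(self, small_mask):
        _, imap, _ = small_mask
        ids = sorted(imap.records)
        perm = {old: new + 1 for new, old in enumerate(reversed(ids))}
        lut = np.zeros(max(ids) + 1, np.int32)
        for old, new in perm.items():
            lut[old] = new
        from nephromorph.postprocess import InstanceMap, InstanceRecord, _link_children

        records = {
            perm[i]: InstanceRecord(perm[i], r.class_name, r.n_pixels, r.bbox)
            for i, r in imap.records.items()
        }
        imap2 = InstanceMap(labels=lut[imap.labels], records=records,
                            schema=imap.schema, calibration=imap.calibration)
        _link_children(imap2)
        ft1 = compute_features(imap).set_index("instance_id")
        ft2 = compute_features(imap2).set_index("instance_id")
        for i in ids:
            for col in ["area", "d_max", "dist_min"]:
                a, b = ft1.loc[i, col], ft2.loc[perm[i], col]
                assert (np.isnan(a) and np.isnan(b)) or a == pytest.approx(b)


class TestFilters:
    def make_table(self, dmaxes):
        rows = []
        for i, d in enumerate(dmaxes, start=1):
            rows.append({"patient_id": "p", "slide_id": "s", "instance_id": i,
                         "class": ARTERY, "parent_id": None, "d_max": d})
            rows.append({"patient_id": "p", "slide_id": "s",
                         "instance_id": 100 + i, "class": LUMEN,
                         "parent_id": i, "d_max": d / 2})
        df = pd.DataFrame(rows)
        for col in FEATURE_COLUMNS:
            if col not in df:
                df[col] = np.nan
        return df

    def test_small_arteriole_excluded_boundary_retained(self):
        ft = apply_filters(self.make_table([45.0, 50.0, 80.0]))
        arteries = ft[ft["class"] == ARTERY]
        assert sorted(arteries["d_max"]) == [50.0, 80.0]  # strict < 50 removed
        # the excluded artery's lumen goes with it
        assert 101 not in set(ft["instance_id"])
        assert 102 in set(ft["instance_id"])

    def test_table_without_arteries_unchanged(self):
        df = pd.DataFrame(
            {"patient_id": ["p"], "slide_id": ["s"], "instance_id": [1],
             "class": [TUBULE], "parent_id": [None], "d_max": [30.0]}
        )
        out = apply_filters(df)
        pd.testing.assert_frame_equal(out, df)


class TestSummaries:
    def test_slide_summary_area_percentages(self):
        lab = np.zeros((40, 40), np.int32)
        t = SCHEMA.code(TUBULE)
        lab[0:10, 0:10] = t
        lab[0:10, 15:25] = t
        lab[15:25, 0:10] = t  # 3 tubules of 100 px each
        imap = instance_map_from(lab, mpp=1.0)
        ft = compute_features(imap)
        summary = summarize_slide(ft, imap, tissue_area_um2=1000.0)
        assert summary.per_class.loc[TUBULE, "count"] == 3
        assert summary.per_class.loc[TUBULE, "area_pct"] == pytest.approx(30.0)

    def test_glomeruli_without_tuft_fraction(self, small_mask):
        _, imap, _ = small_mask
        ft = compute_features(imap)
        s = summarize_slide(ft, imap, tissue_area_um2=ft["area"].sum())
        assert s.glomeruli_without_tuft_fraction == 0.0  # generator links all

    def test_zero_tissue_area_errors(self, small_mask):
        _, imap, _ = small_mask
        with pytest.raises(ValueError):
            summarize_slide(compute_features(imap), imap, tissue_area_um2=0.0)

    def test_patient_median_and_pooling(self):
        ft = pd.DataFrame(
            {
                "patient_id": ["p1"] * 3 + ["p2"],
                "slide_id": ["s1", "s1", "s2", "s1"],  # p1 pooled over slides
                "instance_id": [1, 2, 3, 4],
                "class": [TUBULE] * 4,
                "parent_id": [None] * 4,
            }
        )
        for col in FEATURE_COLUMNS:
            ft[col] = np.nan
        ft["area"] = [1.0, 2.0, 3.0, 7.0]
        out = summarize_patient(ft).set_index("patient_id")
        assert out.loc["p1", "area"] == 2.0  # median of {1,2,3} across slides
        assert out.loc["p2", "area"] == 7.0  # single instance = itself
        assert out.loc["p1", "n"] == 3

    def test_unknown_statistic_rejected(self):
        with pytest.raises(ValueError):
            summarize_patient(pd.DataFrame({"patient_id": []}), statistic="mode")
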