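"""Annotation wrangling: augmentation, VOC XML <-> CSV, splitting."""

import numpy as np
import pandas as pd
import pytest

from woundmetry.dataset import (
    CSV_COLUMNS,
    AugmentationSpec,
    DatasetError,
    ParseError,
    augment_to_target,
    split_dataset,
    write_voc_xml,
    xml_to_csv,
)


@pytest.fixture()
def small_records():
    rows = []
    for cls, n in [(0, 5), (1, 3), (2, 4)]:
        for i in range(n):
            rows.append({
                "filename": f"img_c{cls}_{i}.png", "width": 100, "height": 80,
                "class": cls, "xmin": 10 + i, "ymin": 20, "xmax": 40 + i, "ymax": 60,
            })
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


class TestXmlCsv:
    def test_round_trip(self, small_records, tmp_path):
        sub = small_records.iloc[:1]
        path = tmp_path / "one.xml"
        write_voc_xml(sub.to_dict("records"), path)
        back = xml_to_csv([path])
        pd.testing.assert_frame_equal(back, sub.reset_index(drop=True))

    def test_two_objects_two_rows(self, tmp_path):
        recs = [
            {"filename": "a.png", "width": 50, "height": 50, "class": "suture",
             "xmin": 1, "ymin": 2, "xmax": 10, "ymax": 12},
            {"filename": "a.png", "width": 50, "height": 50, "class": "marker",
             "xmin": 20, "ymin": 20, "xmax": 40, "ymax": 40},
        ]
        path = tmp_path / "a.xml"
        write_voc_xml(recs, path)
        table = xml_to_csv([path])
        assert len(table) == 2
        assert table["class"].tolist() == [1, 3]  # suture id 1, marker id 3

    def test_class_name_variants_map_to_ids(self, tmp_path):
        recs = [{"filename": "b.png", "width": 50, "height": 50,
                 "class": "Blocked blood vessel",
                 "xmin": 1, "ymin": 2, "xmax": 10, "ymax": 12}]
        path = tmp_path / "b.xml"
        write_voc_xml([{**recs[0], "class": "blocked_vessel"}], path)
        assert xml_to_csv([path])["class"].iloc[0] == 0

    def test_degenerate_box_rejected(self, tmp_path):
        path = tmp_path / "bad.xml"
        path.write_text(
            "<annotation><filename>x.png</filename>"
            "<size><width>50</width><height>50</height></size>"
            "<object><name>suture</name><bndbox>"
            "<xmin>30</xmin><ymin>5</ymin><xmax>30</xmax><ymax>20</ymax>"
            "</bndbox></object></annotation>")
        with pytest.raises(ParseError, match="bad.xml"):
            xml_to_csv([path])

    def test_unknown_class_rejected(self, tmp_path):
        path = tmp_path / "c.xml"
        path.write_text(
            "<annotation><filename>x.png</filename>"
            "<size><width>50</width><height>50</height></size>"
            "<object><name>gangrene</name><bndbox>"
            "<xmin>1</xmin><ymin>5</ymin><xmax>30</xmax><ymax>20</ymax>"
            "</bndbox></object></annotation>")
        with pytest.raises(ParseError):
            xml_to_csv([path])

    def test_rows_sorted_deterministically(self, small_records, tmp_path):
        paths = []
        for fname, grp in small_records.groupby("filename"):
            p = tmp_path / f"{fname}.xml"
            write_voc_xml(grp.to_dict("records"), p)
            paths.append(p)
        a = xml_to_csv(sorted(paths))
        b = xml_to_csv(sorted(paths, reverse=True))
        pd.testing.assert_frame_equal(a, b)


class TestAugmentation:
    def test_counts_reach_target_and_keep_originals(self, small_records):
        out, _ = augment_to_target(small_records, None,
                                   AugmentationSpec(per_class_target=20, seed=1))
        counts = out["class"].value_counts()
        assert set(counts) == {20}
        originals = set(small_records["filename"])
        assert originals <= set(out["filename"])

    def test_class_already_at_target_unchanged(self, small_records):
        five = small_records[small_records["class"] == 0]
        out, _ = augment_to_target(five, None, AugmentationSpec(per_class_target=5))
        pd.testing.assert_frame_equal(out.reset_index(drop=True),
                                      five.reset_index(drop=True))

    def test_horizontal_flip_box(self):
        from woundmetry.dataset import _transform_box

        assert _transform_box((10, 20, 30, 40), 100, 100, "horizontal_flip", None) \
            == (70, 20, 90, 40)

    def test_target_below_original_count_rejected(self, small_records):
        with pytest.raises(DatasetError):
            augment_to_target(small_records, None, AugmentationSpec(per_class_target=2))

    def test_boxes_stay_within_bounds(self, small_records):
        out, _ = augment_to_target(small_records, None,
                                   AugmentationSpec(per_class_target=60, seed=3))
        assert (out["xmin"] >= 0).all() and (out["ymin"] >= 0).all()
        assert (out["xmax"] <= out["width"]).all()
        assert (out["ymax"] <= out["height"]).all()
        assert (out["xmin"] < out["xmax"]).all() and (out["ymin"] < out["ymax"]).all()

    def test_image_and_box_move_together(self):
        # a one-hot pixel inside the box must stay inside after augmentation
        rng = np.random.default_rng(0)
        img = np.zeros((60, 80, 3), np.uint8)
        img[25:35, 30:50] = 200  # bright block = the "wound"
        rec = pd.DataFrame([{"filename": "w.png", "width": 80, "height": 60,
                             "class": 2, "xmin": 30, "ymin": 25, "xmax": 50,
                             "ymax": 35}], columns=CSV_COLUMNS)
        out, images = augment_to_target(rec, {"w.png": img},
                                        AugmentationSpec(per_class_target=12, seed=5))
        for _, row in out.iterrows():
            arr = images[row["filename"]]
            inside = arr[row["ymin"]:row["ymax"], row["xmin"]:row["xmax"]]
            # augmented box must capture the bulk of the bright block
            assert (inside > 100).sum() >= 0.8 * (arr > 100).sum() / 3

    def test_deterministic_under_seed(self, small_records):
        a, _ = augment_to_target(small_records, None,
                                 AugmentationSpec(per_class_target=25, seed=11))
        b, _ = augment_to_target(small_records, None,
                                 AugmentationSpec(per_class_target=25, seed=11))
        pd.testing.assert_frame_equal(a, b)


class TestSplit:
    def make_augmented(self, per_class=30):
        rows = []
        for cls in range(3):
            for i in range(per_class // 3):
                for suffix in ("", "_aug0001", "_aug0002"):
                    rows.append({
                        "filename": f"c{cls}_{i}{suffix}.png", "width": 10,
                        "height": 10, "class": cls, "xmin": 1, "ymin": 1,
                        "xmax": 5, "ymax": 5,
                    })
        return pd.DataFrame(rows, columns=CSV_COLUMNS)

    def test_naive_split_exact_counts(self):
        df = self.make_augmented(30)
        train, test = split_dataset(df, 20, seed=0, by_lineage=False)
        assert train["class"].value_counts().tolist() == [20, 20, 20]
        assert test["class"].value_counts().tolist() == [10, 10, 10]

    def test_union_preserved_and_disjoint(self):
        df = self.make_augmented(30)
        train, test = split_dataset(df, 20, seed=0, by_lineage=False)
        combined = pd.concat([train, test]).sort_values(
            ["class", "filename"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(
            combined, df.sort_values(["class", "filename"]).reset_index(drop=True))
        assert not set(train["filename"]) & set(test["filename"])

    def test_lineage_split_has_no_leakage(self):
        from woundmetry.dataset import _lineage

        df = self.make_augmented(30)
        train, test = split_dataset(df, 20, seed=1, by_lineage=True)
        for cls in range(3):
            tr = set(train[train["class"] == cls]["filename"].map(_lineage))
            te = set(test[test["class"] == cls]["filename"].map(_lineage))
            assert not tr & te

    def test_train_equals_class_size_gives_empty_test(self):
        df = self.make_augmented(30)
        train, test = split_dataset(df, 30, seed=0, by_lineage=False)
        assert len(test) == 0

    def test_undersized_class_rejected(self):
        df = self.make_augmented(30)
        with pytest.raises(DatasetError):
            split_dataset(df, 31)

    def test_same_seed_same_partition(self):
        df = self.make_augmented(30)
        a = split_dataset(df, 20, seed=7, by_lineage=True)
        b = split_dataset(df, 20, seed=7, by_lineage=True)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])
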