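"""Dataset preparation: augmentation, VOC-XML -> CSV conversion, splitting.

The detector's training data goes through three steps before use: each
class is augmented to a fixed per-class target (horizontal/vertical flips,
bounded translation, bounded shear), the per-image Pascal-VOC XML
annotations are flattened to a single CSV table with a fixed class-id map
(blocked blood vessel 0, suture 1, ulceration 2, with the hospital marker
carried as an additional class 3), and records are split per class into
train and test partitions.

Splitting defaults to lineage-aware assignment: all augmented copies of one
original image land on the same side, so the test partition never contains
near-duplicates of training images.  ``by_lineage=False`` reproduces plain
per-record splitting (exact per-class counts, at the price of leakage).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from lxml import etree

from .geometry import BoundingBox

__all__ = [
    "CLASS_NAME_TO_ID",
    "DatasetError",
    "ParseError",
    "AugmentationSpec",
    "xml_to_csv",
    "write_voc_xml",
    "augment_to_target",
    "split_dataset",
    "CSV_COLUMNS",
]

logger = logging.getLogger(__name__)

CSV_COLUMNS = ["filename", "width", "height", "class", "xmin", "ymin", "xmax", "ymax"]

#: fixed class-id map; names are normalized (lowercased, spaces/hyphens -> _)
CLASS_NAME_TO_ID = {
    "blocked_vessel": 0,
    "blocked_blood_vessel": 0,
    "suture": 1,
    "ulceration": 2,
    "marker": 3,
}

_AUG_SUFFIX = re.compile(r"_aug\d{4}$")


class DatasetError(ValueError):
    pass


class ParseError(DatasetError):
    pass


def _normalize_class(name: str) -> int:
    key = re.sub(r"[\s\-]+", "_", str(name).strip().lower())
    if key not in CLASS_NAME_TO_ID:
        raise ParseError(f"unknown class name {name!r}")
    return CLASS_NAME_TO_ID[key]


# ---------------------------------------------------------------------------
# VOC XML <-> CSV
# ---------------------------------------------------------------------------

def xml_to_csv(xml_files) -> pd.DataFrame:
    """Flatten Pascal-VOC XML annotation files into one table.

    One row per annotated object with columns
    ``filename,width,height,class,xmin,ymin,xmax,ymax`` (class as its fixed
    integer id), sorted by ``(filename, xmin, ymin)`` for determinism.
    """
    rows = []
    for path in xml_files:
        path = Path(path)
        try:
            tree = etree.parse(str(path))
        except (etree.XMLSyntaxError, OSError) as exc:
            raise ParseError(f"{path}: malformed XML ({exc})") from exc
        root = tree.getroot()
        try:
            filename = root.findtext("filename")
            width = int(root.findtext("size/width"))
            height = int(root.findtext("size/height"))
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}: missing filename/size fields") from exc
        for obj in root.iter("object"):
            name = obj.findtext("name")
            try:
                xmin = int(round(float(obj.findtext("bndbox/xmin"))))
                ymin = int(round(float(obj.findtext("bndbox/ymin"))))
                xmax = int(round(float(obj.findtext("bndbox/xmax"))))
                ymax = int(round(float(obj.findtext("bndbox/ymax"))))
            except (TypeError, ValueError) as exc:
                raise ParseError(f"{path}: malformed bndbox") from exc
            if not (xmin < xmax and ymin < ymax):
                raise ParseError(f"{path}: degenerate box ({xmin},{ymin},{xmax},{ymax})")
            rows.append({
                "filename": filename, "width": width, "height": height,
                "class": _normalize_class(name),
                "xmin": xmin, "ymin": ymin, "xmax": xmax, "ymax": ymax,
            })
    frame = pd.DataFrame(rows, columns=CSV_COLUMNS)
    return frame.sort_values(["filename", "xmin", "ymin"]).reset_index(drop=True)


def write_voc_xml(records, path) -> None:
    """Write one image's annotation records as a Pascal-VOC XML file.

    ``records`` is a list of dicts (or DataFrame rows) sharing one
    ``filename``; class may be a name or an id.
    """
    records = [dict(r) for r in records]
    if not records:
        raise DatasetError("no records to write")
    id_to_name = {0: "blocked_vessel", 1: "suture", 2: "ulceration", 3: "marker"}
    root = etree.Element("annotation")
    etree.SubElement(root, "filename").text = str(records[0]["filename"])
    size = etree.SubElement(root, "size")
    etree.SubElement(size, "width").text = str(records[0]["width"])
    etree.SubElement(size, "height").text = str(records[0]["height"])
    etree.SubElement(size, "depth").text = "3"
    for rec in records:
        cls = rec["class"]
        name = id_to_name[int(cls)] if not isinstance(cls, str) else cls
        obj = etree.SubElement(root, "object")
        etree.SubElement(obj, "name").text = name
        box = etree.SubElement(obj, "bndbox")
        for k in ("xmin", "ymin", "xmax", "ymax"):
            etree.SubElement(box, k).text = str(int(rec[k]))
    tree = etree.ElementTree(root)
    tree.write(str(path), pretty_print=True, xml_declaration=False,
               encoding="utf-8")


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AugmentationSpec:
    """Augmentation policy: which geometric ops may be sampled, how many
    records each class should end up with, and the seed."""

    ops: tuple[str, ...] = ("horizontal_flip", "vertical_flip", "translate", "shear")
    per_class_target: int = 900
    max_translate_frac: float = 0.10
    max_shear_deg: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        valid = {"horizontal_flip", "vertical_flip", "translate", "shear"}
        bad = set(self.ops) - valid
        if bad:
            raise DatasetError(f"unknown augmentation ops: {sorted(bad)}")
        if not self.ops:
            raise DatasetError("at least one op required")


def _shear_matrix(deg_x: float, deg_y: float) -> np.ndarray:
    m = np.eye(3)
    m[0, 1] = np.tan(np.radians(deg_x))
    m[1, 0] = np.tan(np.radians(deg_y))
    return m


def _transform_box(box_vals, width, height, op, op_params) -> tuple[int, int, int, int]:
    """Map a box through one geometric op; shear takes the axis-aligned hull
    of the transformed corners, translation clamps to bounds."""
    xmin, ymin, xmax, ymax = box_vals
    if op == "horizontal_flip":
        return width - xmax, ymin, width - xmin, ymax
    if op == "vertical_flip":
        return xmin, height - ymax, xmax, height - ymin
    if op == "translate":
        dx, dy = op_params
        x0 = int(np.clip(xmin + dx, 0, width - 1))
        x1 = int(np.clip(xmax + dx, x0 + 1, width))
        y0 = int(np.clip(ymin + dy, 0, height - 1))
        y1 = int(np.clip(ymax + dy, y0 + 1, height))
        return x0, y0, x1, y1
    if op == "shear":
        m = op_params
        corners = np.array([
            [xmin, ymin, 1], [xmax, ymin, 1], [xmin, ymax, 1], [xmax, ymax, 1],
        ], dtype=float)
        mapped = corners @ m.T
        xs, ys = mapped[:, 0], mapped[:, 1]
        x0 = int(np.clip(np.floor(xs.min()), 0, width - 1))
        x1 = int(np.clip(np.ceil(xs.max()), x0 + 1, width))
        y0 = int(np.clip(np.floor(ys.min()), 0, height - 1))
        y1 = int(np.clip(np.ceil(ys.max()), y0 + 1, height))
        return x0, y0, x1, y1
    raise DatasetError(f"unknown op {op}")


def _transform_image(image: np.ndarray, op, op_params) -> np.ndarray:
    from skimage.transform import AffineTransform, warp

    if op == "horizontal_flip":
        return image[:, ::-1]
    if op == "vertical_flip":
        return image[::-1, :]
    if op == "translate":
        dx, dy = op_params
        tform = AffineTransform(translation=(-dx, -dy))
        out = warp(image.astype(float), tform, mode="edge", order=0)
        return out.astype(image.dtype)
    if op == "shear":
        m = op_params
        tform = AffineTransform(matrix=np.linalg.inv(m))
        out = warp(image.astype(float), tform, mode="edge", order=1)
        return np.clip(np.round(out), 0, 255).astype(image.dtype)
    raise DatasetError(f"unknown op {op}")


def _sample_ops(spec: AugmentationSpec, width: int, height: int, rng):
    """A random non-empty op composition with sampled magnitudes."""
    chosen = [op for op in spec.ops if rng.random() < 0.5]
    if not chosen:
        chosen = [spec.ops[int(rng.integers(len(spec.ops)))]]
    out = []
    for op in chosen:
        if op == "translate":
            dx = int(rng.integers(-int(spec.max_translate_frac * width),
                                  int(spec.max_translate_frac * width) + 1))
            dy = int(rng.integers(-int(spec.max_translate_frac * height),
                                  int(spec.max_translate_frac * height) + 1))
            out.append((op, (dx, dy)))
        elif op == "shear":
            sx = float(rng.uniform(-spec.max_shear_deg, spec.max_shear_deg))
            sy = float(rng.uniform(-spec.max_shear_deg, spec.max_shear_deg))
            out.append((op, _shear_matrix(sx, sy)))
        else:
            out.append((op, None))
    return out


def augment_to_target(records: pd.DataFrame, images: dict | None,
                      spec: AugmentationSpec) -> tuple[pd.DataFrame, dict]:
    """Grow every class to exactly ``spec.per_class_target`` records.

    Originals are retained; additional records are created by sampling
    (seeded, with replacement) an original of the class and a random op
    composition, transforming box and — when ``images`` is given — pixels
    consistently.  Augmented filenames get a deterministic ``_augNNNN``
    suffix.  With ``images=None`` only the records are produced, which keeps
    printed-scale bookkeeping runs cheap.
    """
    records = pd.DataFrame(records, columns=CSV_COLUMNS).copy()
    records["class"] = records["class"].map(_normalize_class) \
        if records["class"].dtype == object else records["class"].astype(int)
    out_images = dict(images) if images else {}
    rng = np.random.default_rng(spec.seed)

    groups = {cls: grp for cls, grp in records.groupby("class")}
    new_rows = []
    counter = 0
    for cls in sorted(groups):
        grp = groups[cls]
        n = len(grp)
        if n == 0:
            raise DatasetError(f"class {cls} is empty")
        if n > spec.per_class_target:
            raise DatasetError(
                f"class {cls} has {n} records, above target {spec.per_class_target}"
            )
        need = spec.per_class_target - n
        for _ in range(need):
            row = grp.iloc[int(rng.integers(n))].to_dict()
            w, h = int(row["width"]), int(row["height"])
            ops = _sample_ops(spec, w, h, rng)
            box = (row["xmin"], row["ymin"], row["xmax"], row["ymax"])
            img = out_images.get(row["filename"]) if out_images else None
            for op, op_params in ops:
                box = _transform_box(box, w, h, op, op_params)
                if img is not None:
                    img = _transform_image(img, op, op_params)
            stem = str(row["filename"]).rsplit(".", 1)[0]
            ext = str(row["filename"]).rsplit(".", 1)[-1]
            new_name = f"{stem}_aug{counter:04d}.{ext}"
            counter += 1
            row.update({"filename": new_name, "xmin": box[0], "ymin": box[1],
                        "xmax": box[2], "ymax": box[3]})
            BoundingBox(*[row[k] for k in ("xmin", "ymin", "xmax", "ymax")])
            new_rows.append(row)
            if img is not None:
                out_images[new_name] = img
    if new_rows:
        augmented = pd.concat(
            [records, pd.DataFrame(new_rows, columns=CSV_COLUMNS)],
            ignore_index=True)
    else:
        augmented = records.reset_index(drop=True)
    return augmented, out_images


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def _lineage(filename: str) -> str:
    stem = str(filename).rsplit(".", 1)[0]
    return _AUG_SUFFIX.sub("", stem)


def split_dataset(records: pd.DataFrame, train_per_class: int = 700,
                  seed: int = 0, by_lineage: bool = True
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-class train/test split.

    With ``by_lineage=False``: seeded shuffle of each class's records, first
    ``train_per_class`` to train, rest to test (exact counts).  With
    ``by_lineage=True`` (default) whole augmentation lineages are assigned
    together, so the train count per class is the closest achievable value
    not below ``train_per_class`` minus one lineage; no augmented copy of a
    test original can appear in train.
    """
    records = pd.DataFrame(records, columns=CSV_COLUMNS)
    rng = np.random.default_rng(seed)
    train_parts, test_parts = [], []
    for cls, grp in records.groupby("class"):
        n = len(grp)
        if n < train_per_class:
            raise DatasetError(
                f"class {cls} has {n} records, fewer than train_per_class="
                f"{train_per_class}"
            )
        if by_lineage:
            lineages = grp["filename"].map(_lineage)
            unique = sorted(lineages.unique())
            order = rng.permutation(len(unique))
            taken: list[str] = []
            count = 0
            for idx in order:
                if count >= train_per_class:
                    break
                taken.append(unique[idx])
                count += int((lineages == unique[idx]).sum())
            sel = lineages.isin(taken)
            train_parts.append(grp[sel])
            test_parts.append(grp[~sel])
        else:
            perm = rng.permutation(n)
            train_parts.append(grp.iloc[perm[:train_per_class]])
            test_parts.append(grp.iloc[perm[train_per_class:]])
    train = pd.concat(train_parts, ignore_index=True)
    test = pd.concat(test_parts, ignore_index=True)
    return train, test
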