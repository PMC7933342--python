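"""Per-image morphology profiles: percent of mitochondrial area (2D) or
volume (3D) classified into each morphology, with group aggregation."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthgen import CLASS_NAMES


@dataclass
class MorphologyProfile:
    """Percent of total mitochondrial area/volume per morphology in one image."""

    image_id: str
    percent_by_class: dict[str, float] = field(default_factory=dict)
    total: float = 0.0  # µm² in 2D, µm³ in 3D
    n_objects: int = 0
    empty: bool = False

    def validate(self) -> None:
        if self.empty:
            return
        vals = np.array(list(self.percent_by_class.values()))
        if (vals < 0).any() or abs(vals.sum() - 100.0) > 1e-9:
            raise ValueError("profile percentages must be >= 0 and sum to 100")


def _profile(sizes_by_class, image_id, total, n_objects) -> MorphologyProfile:
    if total <= 0:
        return MorphologyProfile(
            image_id, {c: 0.0 for c in CLASS_NAMES}, 0.0, 0, empty=True
        )
    percent = {c: 100.0 * sizes_by_class.get(c, 0.0) / total for c in sizes_by_class}
    for c in CLASS_NAMES:
        percent.setdefault(c, 0.0)
    prof = MorphologyProfile(image_id, percent, total, n_objects)
    prof.validate()
    return prof


def percent_area_profile(objects, image_id: str = "") -> MorphologyProfile:
    """Percent of total 2D object area per predicted morphology."""
    sizes: dict[str, float] = {}
    total = 0.0
    for obj in objects:
        if obj.predicted_class is None:
            raise ValueError(f"object {obj.label} has no predicted class")
        a = obj.area_um2
        if a <= 0:
            raise ValueError(f"object {obj.label} has non-positive area")
        cls = str(obj.predicted_class)
        sizes[cls] = sizes.get(cls, 0.0) + a
        total += a
    return _profile(sizes, image_id, total, len(list(objects)))


def percent_volume_profile(objects, image_id: str = "") -> MorphologyProfile:
    """Percent of total 3D object volume per predicted morphology."""
    sizes: dict[str, float] = {}
    total = 0.0
    n = 0
    for obj in objects:
        if obj.predicted_class is None:
            raise ValueError(f"object {obj.label} has no predicted class")
        v = obj.volume_um3
        if v <= 0:
            raise ValueError(f"object {obj.label} has non-positive volume")
        cls = str(obj.predicted_class)
        sizes[cls] = sizes.get(cls, 0.0) + v
        total += v
        n += 1
    return _profile(sizes, image_id, total, n)


def profiles_to_frame(profiles) -> pd.DataFrame:
    rows = []
    for p in profiles:
        row = {"image_id": p.image_id, "total": p.total,
               "n_objects": p.n_objects, "empty": p.empty}
        row.update({c: p.percent_by_class.get(c, 0.0) for c in CLASS_NAMES})
        rows.append(row)
    return pd.DataFrame(rows, columns=["image_id", *CLASS_NAMES, "total",
                                       "n_objects", "empty"])


def profiles_from_table(
    table: pd.DataFrame,
    size_column: str = "area_um2",
    class_column: str = "predicted_class",
) -> list[MorphologyProfile]:
    """Build per-image profiles from a flat object table.

    The table needs ``image_id``, the predicted class column and a size
    column (area in 2D, volume in 3D).
    """
    for col in ("image_id", class_column, size_column):
        if col not in table.columns:
            raise ValueError(f"missing column {col!r}")
    profiles = []
    for image_id, sub in table.groupby("image_id", sort=True):
        if sub[class_column].isna().any():
            raise ValueError(f"unclassified objects in image {image_id!r}")
        sizes = sub.groupby(class_column)[size_column].sum().to_dict()
        profiles.append(
            _profile(sizes, str(image_id), float(sub[size_column].sum()), len(sub))
        )
    return profiles


def aggregate_groups(
    profiles, group_of_image: dict[str, str]
) -> pd.DataFrame:
    """Per-group mean and sample SD of the class percentages.

    Groups with a single image report SD = 0 (flagged by n = 1).
    """
    rows = []
    for p in profiles:
        if p.image_id not in group_of_image:
            raise ValueError(f"image {p.image_id!r} has no group assignment")
        rows.append(
            {"group": group_of_image[p.image_id],
             **{c: p.percent_by_class.get(c, 0.0) for c in CLASS_NAMES}}
        )
    df = pd.DataFrame(rows)
    out = []
    for group, sub in df.groupby("group", sort=True):
        for cls in CLASS_NAMES:
            vals = sub[cls].to_numpy(dtype=float)
            sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
            out.append(
                {"group": group, "class": cls, "mean_percent": float(vals.mean()),
                 "sd_percent": sd, "n": len(vals)}
            )
    return pd.DataFrame(out, columns=["group", "class", "mean_percent",
                                      "sd_percent", "n"])
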