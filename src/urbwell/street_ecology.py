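"""Street-scene descriptors and the street ecological index (SE).

Semantic segmentation of street-view imagery (19 Cityscapes-style
classes, four view angles per sample point: 0/90/180/270 degrees) is
reduced to four descriptors — per-point sums over the N=4 images of the
per-image pixel fractions of:

    GN (greenness)    vegetation
    GY (grayness)     building + wall + fence + pole
                      + traffic_light + traffic_sign
    OP (openness)     terrain + sky + road + sidewalk
    CR (crowdedness)  person + rider + car + truck + bus + train
                      + motorcycle + bicycle

and the combined street ecological index SE = (GN * OP) / (GY * CR).
When the 19 classes tile every image, GN + GY + OP + CR = N exactly.

Segmentation itself is out of scope here: pixel-count tables are inputs
(CSV with columns ``point_id,view,<19 class columns>,sum_pixels``).
The class list uses "terrain" for the ground/terrain element; input
headers are normalized to lower-case snake_case before matching.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: canonical class order for the 19 scene elements
CLASSES: tuple[str, ...] = (
    "road", "sidewalk", "building", "wall", "fence", "pole",
    "traffic_light", "traffic_sign", "vegetation", "terrain", "sky",
    "person", "rider", "car", "truck", "bus", "train", "motorcycle",
    "bicycle",
)

GROUPS: dict[str, tuple[str, ...]] = {
    "GN": ("vegetation",),
    "GY": ("building", "wall", "fence", "pole", "traffic_light",
           "traffic_sign"),
    "OP": ("terrain", "sky", "road", "sidewalk"),
    "CR": ("person", "rider", "car", "truck", "bus", "train",
           "motorcycle", "bicycle"),
}

N_VIEWS = 4
VIEWS = (0, 90, 180, 270)

# synonyms seen in segmentation exports -> canonical name
_ALIASES = {"ground": "terrain", "pedestrian": "person", "cyclist": "rider",
            "trafficlight": "traffic_light", "trafficsign": "traffic_sign"}


class IncompletePointError(ValueError):
    """A sample point is missing one or more of its N view images."""


@dataclass
class SceneIndices:
    """Descriptor values for one sample point (or a zone mean)."""

    GN: float
    GY: float
    OP: float
    CR: float

    def se(self, epsilon: float | None = None) -> float:
        return se_index(self, epsilon=epsilon)


def normalize_class_name(name: str) -> str:
    key = name.strip().lower().replace(" ", "_").replace("-", "_")
    return _ALIASES.get(key, _ALIASES.get(key.replace("_", ""), key))


def scene_fractions(
    counts: np.ndarray,
    sums: np.ndarray,
    n_views: int = N_VIEWS,
) -> SceneIndices:
    """Descriptors for one point from its per-view pixel counts.

    Parameters
    ----------
    counts : (n_views, 19) array
        Pixel counts per image in canonical ``CLASSES`` order.
    sums : (n_views,) array
        Total pixels per image (the denominator of each fraction).
    """
    counts = np.asarray(counts, dtype=float)
    sums = np.asarray(sums, dtype=float)
    if counts.shape != (n_views, len(CLASSES)):
        raise IncompletePointError(
            f"expected {n_views}x{len(CLASSES)} counts, got {counts.shape}"
        )
    if np.any(sums <= 0):
        raise ValueError("every image must have sum_pixels > 0")
    if np.any(counts < 0):
        raise ValueError("negative pixel count")
    idx = {c: k for k, c in enumerate(CLASSES)}
    out = {}
    for name, members in GROUPS.items():
        cols = [idx[m] for m in members]
        out[name] = float((counts[:, cols].sum(axis=1) / sums).sum())
    return SceneIndices(**out)


def se_index(idx: SceneIndices, epsilon: float | None = None) -> float:
    """SE = (GN * OP) / (GY * CR).

    ``epsilon`` optionally floors GY and CR away from zero (e.g. a
    vegetation-only point); by default a zero denominator is an error.
    """
    gy, cr = idx.GY, idx.CR
    if epsilon is not None:
        gy, cr = max(gy, epsilon), max(cr, epsilon)
    if gy * cr == 0:
        raise ZeroDivisionError(
            "SE undefined: GY*CR = 0 (pass epsilon to regularize)"
        )
    return (idx.GN * idx.OP) / (gy * cr)


def indices_from_table(
    table: pd.DataFrame,
    n_views: int = N_VIEWS,
    epsilon: float | None = None,
) -> pd.DataFrame:
    """Per-point GN/GY/OP/CR/SE from a long count table.

    ``table`` needs columns ``point_id``, ``view``, the 19 class columns
    (any recognized spelling) and ``sum_pixels``.
    """
    ren = {c: normalize_class_name(c) for c in table.columns}
    table = table.rename(columns=ren)
    missing = [c for c in CLASSES if c not in table.columns]
    if missing:
        raise KeyError(f"count table missing class columns: {missing}")
    rows = []
    for pid, grp in table.groupby("point_id", sort=True):
        if len(grp) != n_views:
            raise IncompletePointError(
                f"point {pid!r} has {len(grp)} views, expected {n_views}"
            )
        idx = scene_fractions(
            grp[list(CLASSES)].to_numpy(),
            grp["sum_pixels"].to_numpy(),
            n_views=n_views,
        )
        rows.append({
            "point_id": pid, "GN": idx.GN, "GY": idx.GY,
            "OP": idx.OP, "CR": idx.CR,
            "SE": se_index(idx, epsilon=epsilon),
        })
    return pd.DataFrame(rows)


def aggregate_points(
    point_indices: pd.DataFrame,
    zone_of_point: pd.Series,
    min_points: int = 1,
    statistic: str = "mean_of_se",
) -> pd.DataFrame:
    """Zone-level descriptor means from per-point indices.

    ``statistic`` selects how zone SE is formed: ``"mean_of_se"``
    (default; arithmetic mean of the per-point index, matching the
    per-point definition) or ``"se_of_means"`` (index of the zone-mean
    fractions).  Zones with fewer than ``min_points`` points are
    returned flagged (``ok = False``) so callers can exclude them.
    """
    if statistic not in ("mean_of_se", "se_of_means"):
        raise ValueError(f"unknown statistic {statistic!r}")
    df = point_indices.copy()
    df["zone"] = zone_of_point.reindex(df["point_id"]).to_numpy()
    df = df[df["zone"].notna()]
    out = []
    for zone, grp in df.groupby("zone", sort=True):
        rec = {
            "zone": zone, "n_points": len(grp),
            "GN": grp["GN"].mean(), "GY": grp["GY"].mean(),
            "OP": grp["OP"].mean(), "CR": grp["CR"].mean(),
            "ok": len(grp) >= min_points,
        }
        if statistic == "mean_of_se":
            rec["SE"] = grp["SE"].mean()
        else:
            rec["SE"] = se_index(SceneIndices(
                rec["GN"], rec["GY"], rec["OP"], rec["CR"]))
        out.append(rec)
    return pd.DataFrame(out)
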