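"""Object-based cross-channel colocalization and per-site measurement vector.

A synapse is operationally defined as a postsynaptic punctum (Psd95 for
excitatory, Gphn for inhibitory) sharing at least one pixel with a Syn1
punctum after registration. Pairing is strictly object overlap on label
maps — never intensity correlation. Densities are counts per μm of MAP2
dendrite length measured on the same site.

The per-site vector tracks 21 parameters: for each of the three puncta
channels the count, density, median area, median eccentricity and median
expression (15); for each pair class the pair count and pair density (4);
the dendrite length (1); and the total pairwise overlap area (1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from synaptoquant.config import PAIR_CLASSES, PUNCTA_CHANNELS, pair_class_name
from synaptoquant.dendrites import DendriteSkeleton
from synaptoquant.puncta import PunctaLabelMap, PunctaObject

__all__ = ["SynapsePair", "SiteMeasurements", "find_pairs", "count_pairs",
           "assemble_site", "PARAMETERS"]


@dataclass
class SynapsePair:
    pair_class: str  # e.g. "Psd95-Syn1"
    post_id: int
    syn1_id: int
    overlap_area_px: int


def _param_names() -> list[str]:
    names = []
    for ch in PUNCTA_CHANNELS:
        c = ch.lower()
        names += [
            f"{c}_count",
            f"{c}_density_per_um",
            f"{c}_median_area_um2",
            f"{c}_median_eccentricity",
            f"{c}_median_expression",
        ]
    for post, pre in PAIR_CLASSES:
        k = f"pair_{post.lower()}_{pre.lower()}"
        names += [f"{k}_count", f"{k}_density_per_um"]
    names += ["dendrite_length_um", "total_pair_overlap_px"]
    return names


#: The 21 tracked per-site parameters, in reporting order.
PARAMETERS: tuple[str, ...] = tuple(_param_names())

#: Parameters that divide by dendrite length; sites flagged for low
#: dendritic outgrowth are excluded from these during aggregation.
DENSITY_PARAMETERS: tuple[str, ...] = tuple(
    p for p in PARAMETERS if p.endswith("_density_per_um")
)


@dataclass
class SiteMeasurements:
    plate: str
    well: str
    site: int
    values: dict[str, float] = field(default_factory=dict)
    low_dendrite_flag: bool = False

    def to_row(self) -> dict:
        row = {"plate": self.plate, "well": self.well, "site": self.site}
        row.update({p: self.values.get(p, math.nan) for p in PARAMETERS})
        row["low_dendrite_flag"] = self.low_dendrite_flag
        return row


def find_pairs(
    post_labels: PunctaLabelMap, syn1_labels: PunctaLabelMap
) -> list[SynapsePair]:
    """All (postsynaptic, Syn1) object pairs sharing at least one pixel."""
    if post_labels.labels.shape != syn1_labels.labels.shape:
        raise ValueError(
            f"label map shapes differ: {post_labels.labels.shape} vs "
            f"{syn1_labels.labels.shape}"
        )
    cls = pair_class_name(post_labels.channel or "post", syn1_labels.channel or "Syn1")
    both = (post_labels.labels > 0) & (syn1_labels.labels > 0)
    if not both.any():
        return []
    p = post_labels.labels[both].astype(np.int64)
    s = syn1_labels.labels[both].astype(np.int64)
    keys, counts = np.unique(p * (syn1_labels.n_objects + 1) + s, return_counts=True)
    pairs = [
        SynapsePair(
            pair_class=cls,
            post_id=int(k // (syn1_labels.n_objects + 1)),
            syn1_id=int(k % (syn1_labels.n_objects + 1)),
            overlap_area_px=int(n),
        )
        for k, n in zip(keys, counts)
    ]
    pairs.sort(key=lambda pr: (pr.post_id, pr.syn1_id))
    return pairs


def count_pairs(pairs: list[SynapsePair]) -> int:
    """The pair count statistic: distinct postsynaptic objects with any overlap.

    A postsynaptic punctum straddling two Syn1 puncta still counts once.
    """
    return len({p.post_id for p in pairs})


def _median(values: list[float]) -> float:
    return float(np.median(values)) if values else math.nan


def assemble_site(
    punctae: dict[str, list[PunctaObject]],
    pairs: dict[str, list[SynapsePair]],
    skeleton: DendriteSkeleton,
    plate: str,
    well: str,
    site: int,
    min_dendrite_length_um: float = 0.0,
) -> SiteMeasurements:
    """Fill the 21-parameter per-site vector.

    Densities are count / dendrite length; with zero dendrite length they
    are left undefined (NaN) rather than zero, and the site is flagged —
    it still contributes to count statistics.
    """
    length = skeleton.total_length_um
    low_flag = length < min_dendrite_length_um or length <= 0
    vals: dict[str, float] = {}
    for ch in PUNCTA_CHANNELS:
        objs = punctae.get(ch, [])
        c = ch.lower()
        vals[f"{c}_count"] = float(len(objs))
        vals[f"{c}_density_per_um"] = len(objs) / length if length > 0 else math.nan
        vals[f"{c}_median_area_um2"] = _median([o.area_um2 for o in objs])
        vals[f"{c}_median_eccentricity"] = _median([o.eccentricity for o in objs])
        vals[f"{c}_median_expression"] = _median([o.expression for o in objs])
    total_overlap = 0
    for post, pre in PAIR_CLASSES:
        cls = pair_class_name(post, pre)
        plist = pairs.get(cls, [])
        n = count_pairs(plist)
        k = f"pair_{post.lower()}_{pre.lower()}"
        vals[f"{k}_count"] = float(n)
        vals[f"{k}_density_per_um"] = n / length if length > 0 else math.nan
        total_overlap += sum(p.overlap_area_px for p in plist)
    vals["dendrite_length_um"] = length
    vals["total_pair_overlap_px"] = float(total_overlap)
    return SiteMeasurements(
        plate=plate, well=well, site=site, values=vals, low_dendrite_flag=low_flag
    )
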