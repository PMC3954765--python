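"""Synthetic 4-channel field and plate generator with full ground truth.

Emulates high-content images of dissociated neuronal cultures: a MAP2
channel containing curvilinear dendrites of known total centerline length,
and three puncta channels (Psd95, Gphn, Syn1) containing small Gaussian
spots preferentially seeded on dendrites, with a configurable fraction of
postsynaptic puncta colocalized with Syn1. Acquisition artifacts — a
smooth multiplicative illumination gradient, integer translational channel
misalignment, and additive Gaussian noise — are applied last, so every
planted quantity (spot centers, pairs, centerline length, shifts, per-well
effect multipliers) is known exactly and recorded in a ground-truth ledger.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.draw import line

from synaptoquant.config import CHANNELS, PAIR_CLASSES, PUNCTA_CHANNELS, SimConfig, pair_class_name
from synaptoquant.types import FieldImageSet

__all__ = [
    "FieldGroundTruth",
    "PlateGroundTruth",
    "simulate_field",
    "simulate_plate",
    "write_plate",
    "illumination_field",
]


class SizingError(ValueError):
    """Configuration would place puncta outside the frame after shifting."""


@dataclass
class FieldGroundTruth:
    """Everything planted into one simulated field."""

    puncta_centers: dict[str, np.ndarray]  # channel -> (n, 2) float (row, col)
    puncta_radius_px: float
    pairs: dict[str, list[tuple[int, int]]]  # class -> [(post_idx, syn1_idx)]
    dendrite_length_um: float
    channel_shift_px: dict[str, tuple[int, int]]
    effect_multiplier: float


@dataclass
class PlateGroundTruth:
    """Plate-level ledger: per-field truths plus layout and planted effects."""

    fields: dict[tuple[str, int], FieldGroundTruth] = field(default_factory=dict)
    layout: pd.DataFrame | None = None  # plate, well, shrna_id, gene, role
    effects: dict[str, float] = field(default_factory=dict)

    def planted_hit_genes(
        self, threshold_fraction: float = 0.40, min_hairpins: int = 2
    ) -> set[str]:
        """Genes whose planted effects satisfy the multi-hairpin knockdown rule.

        A gene qualifies when at least ``min_hairpins`` of its hairpins carry
        an effect multiplier ≤ 1 − ``threshold_fraction`` (boundary inclusive).
        """
        if self.layout is None:
            return set()
        lib = self.layout[self.layout["role"] == "library"]
        hits: set[str] = set()
        for gene, grp in lib.groupby("gene"):
            shrnas = grp["shrna_id"].unique()
            n_pass = sum(
                1
                for s in shrnas
                if self.effects.get(s, 1.0) <= 1.0 - threshold_fraction
            )
            if n_pass >= min_hairpins:
                hits.add(gene)
        return hits


# ---------------------------------------------------------------------------
# geometry helpers


def _dendrite_polylines(
    config: SimConfig, rng: np.random.Generator
) -> tuple[list[np.ndarray], float]:
    """Smoothed random-walk polylines totalling the configured length.

    Returns the polylines (each (k, 2) float, row/col px) and the analytic
    total centerline length in μm (sum of segment lengths × pixel size).
    """
    h, w = config.image_height_px, config.image_width_px
    margin = 8.0
    step = 4.0
    total_px = config.dendrite_total_length_um / config.pixel_size_um
    n_trees = max(config.n_dendrite_trees, 0)
    polylines: list[np.ndarray] = []
    total_len_px = 0.0
    if n_trees == 0 or total_px <= 0:
        return polylines, 0.0
    per_tree = total_px / n_trees
    center = np.array([h / 2.0, w / 2.0])
    for _ in range(n_trees):
        pos = np.array(
            [rng.uniform(margin, h - margin), rng.uniform(margin, w - margin)]
        )
        heading = rng.uniform(0, 2 * np.pi)
        pts = [pos.copy()]
        length = 0.0
        while length < per_tree - 1e-9:
            this_step = min(step, per_tree - length)
            # gentle curvature: the walk must be smooth at the scale of the
            # ridge cross-section, or downstream smoothing would shorten it
            heading += rng.normal(0.0, 0.12)
            # steer smoothly back toward the interior near the frame edge
            dist_edge = min(pos[0] - margin, h - margin - pos[0],
                            pos[1] - margin, w - margin - pos[1])
            if dist_edge < 20.0:
                to_center = np.arctan2(*(center - pos))
                diff = (to_center - heading + np.pi) % (2 * np.pi) - np.pi
                gain = 0.25 * (1.0 - dist_edge / 20.0)
                heading += np.clip(gain * diff, -0.35, 0.35)
            nxt = pos + this_step * np.array([np.sin(heading), np.cos(heading)])
            nxt[0] = min(max(nxt[0], margin), h - margin)
            nxt[1] = min(max(nxt[1], margin), w - margin)
            seg = float(np.hypot(*(nxt - pos)))
            if seg < 0.5 * this_step:
                # pinned against the frame edge: relaunch pointing inward so
                # the walk always makes real progress
                heading = np.arctan2(*(center - pos)) + rng.normal(0.0, 0.3)
                continue
            length += seg
            pos = nxt
            pts.append(pos.copy())
        total_len_px += length
        polylines.append(np.asarray(pts))
    return polylines, total_len_px * config.pixel_size_um


def _rasterize_centerline(
    polylines: list[np.ndarray], shape: tuple[int, int]
) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    for pts in polylines:
        ipts = np.rint(pts).astype(int)
        for (r0, c0), (r1, c1) in zip(ipts[:-1], ipts[1:]):
            rr, cc = line(r0, c0, r1, c1)
            mask[np.clip(rr, 0, shape[0] - 1), np.clip(cc, 0, shape[1] - 1)] = True
    return mask


def _sample_centers(
    n: int,
    existing: list[np.ndarray],
    dendrite_px: np.ndarray,
    config: SimConfig,
    margin: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Rejection-sample spot centers with a minimum pairwise separation.

    A fraction of centers is seeded on dendrite centerline pixels (with
    ±1 px jitter) so that densities per μm dendrite are meaningful; the
    rest are uniform over the in-frame region. Separation is relaxed after
    repeated failures so dense configurations still terminate.
    """
    h, w = config.image_height_px, config.image_width_px
    n_existing = len(existing)
    cap = n_existing + n
    centers = np.empty((cap, 2))
    for i, c in enumerate(existing):
        centers[i] = c
    filled = n_existing
    min_sep = config.min_separation_px
    on_dendrite = dendrite_px.size > 0
    for _ in range(n):
        sep = min_sep
        for attempt in range(200):
            if attempt and attempt % 50 == 0:
                sep *= 0.7  # relax to guarantee termination
            if on_dendrite and rng.random() < config.on_dendrite_fraction:
                idx = rng.integers(len(dendrite_px))
                cand = dendrite_px[idx] + rng.normal(0.0, 1.0, size=2)
            else:
                cand = np.array(
                    [rng.uniform(margin, h - margin), rng.uniform(margin, w - margin)]
                )
            if cand[0] < margin:
                cand[0] = margin
            elif cand[0] > h - margin:
                cand[0] = h - margin
            if cand[1] < margin:
                cand[1] = margin
            elif cand[1] > w - margin:
                cand[1] = w - margin
            if filled == 0:
                break
            diff = centers[:filled] - cand
            if np.min(diff[:, 0] ** 2 + diff[:, 1] ** 2) >= sep * sep:
                break
        centers[filled] = cand
        filled += 1
    return centers[n_existing:].copy()


def _render_spots(
    shape: tuple[int, int], centers: np.ndarray, radius_px: float, peak: float
) -> np.ndarray:
    """Additively render isotropic 2-D Gaussian spots truncated at 3σ."""
    img = np.zeros(shape, dtype=np.float64)
    sigma = radius_px / 2.0
    ext = int(np.ceil(3.0 * sigma))
    for r0, c0 in centers:
        rlo, rhi = int(np.floor(r0)) - ext, int(np.floor(r0)) + ext + 1
        clo, chi = int(np.floor(c0)) - ext, int(np.floor(c0)) + ext + 1
        rlo_c, rhi_c = max(rlo, 0), min(rhi, shape[0])
        clo_c, chi_c = max(clo, 0), min(chi, shape[1])
        rr = np.arange(rlo_c, rhi_c)[:, None]
        cc = np.arange(clo_c, chi_c)[None, :]
        d2 = (rr - r0) ** 2 + (cc - c0) ** 2
        spot = peak * np.exp(-d2 / (2.0 * sigma**2))
        spot[d2 > (3.0 * sigma) ** 2] = 0.0
        img[rlo_c:rhi_c, clo_c:chi_c] += spot
    return img


def _translate(image: np.ndarray, shift: tuple[int, int]) -> np.ndarray:
    """Integer translation with zero fill at exposed borders."""
    dr, dc = int(shift[0]), int(shift[1])
    out = np.zeros_like(image)
    h, w = image.shape
    r_src = slice(max(0, -dr), min(h, h - dr))
    c_src = slice(max(0, -dc), min(w, w - dc))
    r_dst = slice(max(0, dr), min(h, h + dr))
    c_dst = slice(max(0, dc), min(w, w + dc))
    out[r_dst, c_dst] = image[r_src, c_src]
    return out


from functools import lru_cache


@lru_cache(maxsize=32)
def _illumination_field_cached(
    shape: tuple[int, int], amplitude: float, channel: str
) -> np.ndarray:
    """Smooth multiplicative illumination field, deterministic per channel.

    A tilted plane whose orientation depends on the channel, plus a mild
    center-bright vignette, scaled so the field spans roughly
    1 ± amplitude/2. Identical for every site of a plate, which is what a
    per-plate flat-field estimator assumes.
    """
    h, w = shape
    rr = (np.arange(h)[:, None] / max(h - 1, 1)) - 0.5
    cc = (np.arange(w)[None, :] / max(w - 1, 1)) - 0.5
    tilts = {"MAP2": (1, 0), "Psd95": (0, 1), "Gphn": (1, 1), "Syn1": (-1, 1)}
    gr, gc = tilts.get(channel, (1, 0))
    plane = (gr * rr + gc * cc) / np.hypot(gr, gc)
    vignette = 0.25 - (rr**2 + cc**2)
    g = 0.7 * plane + 0.3 * vignette
    g = g - g.mean()
    span = g.max() - g.min()
    if span > 0:
        g = g / span
    out = 1.0 + amplitude * g
    out.setflags(write=False)  # cached: guard against accidental mutation
    return out


def illumination_field(
    shape: tuple[int, int], amplitude: float, channel: str
) -> np.ndarray:
    return _illumination_field_cached(tuple(shape), float(amplitude), channel)


# ---------------------------------------------------------------------------
# field and plate simulation


def simulate_field(
    config: SimConfig,
    effect_multiplier: float = 1.0,
    rng: np.random.Generator | None = None,
    plate: str = "plate1",
    well: str = "A01",
    site: int = 1,
) -> tuple[FieldImageSet, FieldGroundTruth]:
    """Simulate one 4-channel field and its ground truth.

    ``effect_multiplier`` scales the planted puncta count in every synapse
    channel (the in-silico analogue of an shRNA knocking down
    synaptogenesis); 1.0 is the untreated/negative-control condition.
    """
    if effect_multiplier < 0:
        raise ValueError("effect_multiplier must be >= 0")
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    h, w = config.image_height_px, config.image_width_px
    sigma = config.puncta_radius_px / 2.0
    margin = 3.0 * sigma + config.max_shift_px + 1
    if 2 * margin >= min(h, w):
        raise SizingError(
            f"frame {h}x{w} too small for puncta of radius "
            f"{config.puncta_radius_px} px with shifts up to "
            f"{config.max_shift_px} px (needs margin {margin:.1f} px per side)"
        )

    polylines, dendrite_len_um = _dendrite_polylines(config, rng)
    centerline = _rasterize_centerline(polylines, (h, w))
    dendrite_px = np.argwhere(centerline).astype(float)

    # Syn1 first, then postsynaptic channels borrowing Syn1 centers for
    # the colocalized fraction.
    counts = {
        ch: int(round(effect_multiplier * config.puncta_per_channel.get(ch, 0)))
        for ch in PUNCTA_CHANNELS
    }
    centers: dict[str, np.ndarray] = {}
    pairs: dict[str, list[tuple[int, int]]] = {
        pair_class_name(p, s): [] for p, s in PAIR_CLASSES
    }
    centers["Syn1"] = _sample_centers(
        counts["Syn1"], [], dendrite_px, config, margin, rng
    )
    for post, pre in PAIR_CLASSES:
        n_post = counts[post]
        n_coloc = min(int(round(config.coloc_fraction(post) * n_post)), len(centers[pre]))
        chosen = rng.choice(len(centers[pre]), size=n_coloc, replace=False) if n_coloc else np.empty(0, dtype=int)
        coloc_centers = centers[pre][chosen].reshape(n_coloc, 2)
        free = _sample_centers(
            n_post - n_coloc, list(coloc_centers), dendrite_px, config, margin, rng
        )
        centers[post] = np.concatenate([coloc_centers, free], axis=0)
        pairs[pair_class_name(post, pre)] = [
            (i, int(chosen[i])) for i in range(n_coloc)
        ]

    images: dict[str, np.ndarray] = {}
    scene_map2 = np.zeros((h, w))
    if centerline.any():
        blurred = gaussian_filter(
            centerline.astype(float), sigma=config.dendrite_sigma_px
        )
        scene_map2 = blurred * (config.dendrite_peak_intensity / blurred.max())
    images["MAP2"] = scene_map2
    for ch in PUNCTA_CHANNELS:
        images[ch] = _render_spots(
            (h, w), centers[ch], config.puncta_radius_px, config.puncta_peak_intensity
        )

    shifts = {ch: tuple(config.channel_shift_px.get(ch, (0, 0))) for ch in CHANNELS}
    for ch in CHANNELS:
        img = _translate(images[ch], shifts[ch]) if shifts[ch] != (0, 0) else images[ch]
        img = img + config.background_level
        if config.illum_gradient_amplitude > 0:
            img = img * illumination_field(
                (h, w), config.illum_gradient_amplitude, ch
            )
        if config.noise_sd > 0:
            img = img + rng.normal(0.0, config.noise_sd, size=(h, w))
        images[ch] = np.clip(img, 0.0, None).astype(np.float32)

    fis = FieldImageSet(plate=plate, well=well, site=site, images=images)
    gt = FieldGroundTruth(
        puncta_centers=centers,
        puncta_radius_px=config.puncta_radius_px,
        pairs=pairs,
        dendrite_length_um=dendrite_len_um,
        channel_shift_px=shifts,
        effect_multiplier=effect_multiplier,
    )
    return fis, gt


def _field_rng(seed: int, well: str, site: int) -> np.random.Generator:
    """Deterministic per-field substream derived from (well, site).

    One plate seed fans out into independent streams so fields can be
    generated in any order (or in parallel) with identical output.
    """
    well_key = sum(ord(c) * 131**i for i, c in enumerate(well)) % (2**20)
    return np.random.default_rng([seed, well_key, site])


def simulate_plate(
    config: SimConfig,
    layout: pd.DataFrame,
    effects: dict[str, float],
    sites_per_well: int = 9,
) -> tuple[list[FieldImageSet], PlateGroundTruth]:
    """Simulate every site of a plate described by a plate-map layout.

    ``layout`` needs columns plate, well, shrna_id, gene, role; ``effects``
    maps each non-empty well's shrna_id to its planted effect multiplier.
    Negative-control wells are forced to 1.0.
    """
    layout = layout.reset_index(drop=True)
    effects = dict(effects)
    known = set(layout["shrna_id"].dropna())
    for shrna in effects:
        if shrna not in known:
            raise ValueError(f"effects entry {shrna!r} absent from plate layout")
    for _, row in layout.iterrows():
        if row["role"] == "negative_control":
            effects[row["shrna_id"]] = 1.0
        elif row["role"] != "empty" and row["shrna_id"] not in effects:
            raise ValueError(f"no effect entry for shRNA {row['shrna_id']!r}")

    fields: list[FieldImageSet] = []
    truth = PlateGroundTruth(layout=layout, effects=effects)
    for _, row in layout.iterrows():
        if row["role"] == "empty":
            continue
        mult = effects[row["shrna_id"]]
        for site in range(1, sites_per_well + 1):
            rng = _field_rng(config.rng_seed, str(row["well"]), site)
            fis, gt = simulate_field(
                config,
                effect_multiplier=mult,
                rng=rng,
                plate=str(row["plate"]),
                well=str(row["well"]),
                site=site,
            )
            fields.append(fis)
            truth.fields[(str(row["well"]), site)] = gt
    return fields, truth


def write_plate(
    fields: list[FieldImageSet],
    truth: PlateGroundTruth,
    config: SimConfig,
    out_dir: str | Path,
) -> None:
    """Write TIFFs plus ground-truth CSV tables and the config YAML."""
    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for fis in fields:
        for ch, img in fis.images.items():
            name = f"{fis.plate}_{fis.well}_s{fis.site}_{ch}.tif"
            tifffile.imwrite(out / name, img.astype(np.float32))
    punctae_rows, pair_rows = [], []
    for (well, site), gt in truth.fields.items():
        for ch, cs in gt.puncta_centers.items():
            for i, (r, c) in enumerate(cs):
                punctae_rows.append(
                    dict(well=well, site=site, channel=ch, index=i, row=r, col=c,
                         radius_px=gt.puncta_radius_px)
                )
        for cls, pl in gt.pairs.items():
            for pi, si in pl:
                pair_rows.append(
                    dict(well=well, site=site, pair_class=cls,
                         post_index=pi, syn1_index=si)
                )
    pd.DataFrame(punctae_rows).to_csv(out / "punctae.csv", index=False)
    pd.DataFrame(pair_rows).to_csv(out / "pairs.csv", index=False)
    if truth.layout is not None:
        truth.layout.to_csv(out / "layout.csv", index=False)
    pd.DataFrame(
        [{"shrna_id": k, "effect": v} for k, v in truth.effects.items()]
    ).to_csv(out / "effects.csv", index=False)
    config.to_yaml(out / "sim_config.yaml")
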