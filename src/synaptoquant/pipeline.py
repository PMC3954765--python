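"""End-to-end pipeline driver: images in, screen tables out.

Stage order: per-plate illumination estimation → per-site division
correction → MI registration of Psd95/Gphn to Syn1 → top-hat puncta
segmentation (3 channels) → tubeness/skeleton dendrite length → object
pairing and the 21-parameter site vector → well/hairpin aggregation →
negative-control normalization → hit calling. Sites are independent, so
processing order cannot change any output.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from synaptoquant import dendrites, illumination, pairing, puncta, registration
from synaptoquant.config import PAIR_CLASSES, PUNCTA_CHANNELS, PipelineConfig, pair_class_name
from synaptoquant.io import FieldImageRef, discover_plate, load_field, write_csv
from synaptoquant.pairing import SiteMeasurements
from synaptoquant.screen import (
    PlateMap,
    aggregate_shrnas,
    aggregate_wells,
    call_hits,
    normalize_to_controls,
)
from synaptoquant.types import FieldImageSet

logger = logging.getLogger("synaptoquant")

__all__ = ["PipelineResult", "analyze_site", "analyze_fields", "run_pipeline"]

#: Channels registered to Syn1 (MAP2 is deliberately left unregistered).
REGISTERED_CHANNELS = ("Psd95", "Gphn")


@dataclass
class PipelineResult:
    """All tables produced by one pipeline run."""

    sites: pd.DataFrame
    wells: pd.DataFrame
    shrna_summary: pd.DataFrame
    gene_hits: pd.DataFrame
    registration_log: pd.DataFrame
    warnings_log: pd.DataFrame
    regression: pd.DataFrame | None = None
    population_tests: pd.DataFrame | None = None
    punctae: pd.DataFrame | None = None
    pairs: pd.DataFrame | None = None
    timings: pd.DataFrame | None = None
    illum: dict[str, illumination.IlluminationFunction] = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_csv(self.sites, out / "sites.csv")
        write_csv(self.wells, out / "wells.csv")
        write_csv(self.shrna_summary, out / "shrna_summary.csv")
        write_csv(self.gene_hits, out / "gene_hits.csv")
        write_csv(self.registration_log, out / "registration.csv")
        write_csv(self.warnings_log, out / "warnings.csv")
        if self.regression is not None:
            write_csv(self.regression, out / "regression.csv")
        if self.population_tests is not None:
            write_csv(self.population_tests, out / "population_tests.csv")
        if self.punctae is not None:
            write_csv(self.punctae, out / "punctae.csv")
        if self.pairs is not None:
            write_csv(self.pairs, out / "pairs.csv")
        if self.timings is not None:
            write_csv(self.timings, out / "timings.csv")


def compute_plate_illumination(
    fields: list[FieldImageSet] | list[FieldImageRef],
    config: PipelineConfig,
    plate: str = "",
) -> dict[str, illumination.IlluminationFunction]:
    """One illumination function per channel from every image of the plate."""
    out = {}
    for ch in list(PUNCTA_CHANNELS) + ["MAP2"]:
        images = []
        for f in fields:
            img = f.images[ch] if isinstance(f, FieldImageSet) else None
            if img is None:
                img = load_field(f).images[ch]
            images.append(img)
        out[ch] = illumination.compute_illumination(
            images, config.illum_filter_size_px, channel=ch, plate=plate
        )
    return out


def calibrate_puncta_thresholds(
    fields: list[FieldImageSet],
    illum: dict[str, illumination.IlluminationFunction],
    config: PipelineConfig,
) -> dict[str, float]:
    """Per-batch empirical segmentation thresholds, one per puncta channel.

    Pools top-hat-enhanced pixels from a subsample of the plate's sites and
    sets threshold = median + k × 1.4826·MAD. Unlike a per-image Otsu this
    is robust when foreground is sparse (e.g. strong-knockdown wells, where
    Otsu's between-class criterion can collapse into the noise floor), and
    it is the same threshold for every site of the batch — matching how
    such screens calibrate their object filters per experimental batch.
    """
    # canonical site order so calibration is invariant to processing order
    ordered = sorted(fields, key=lambda f: (f.plate, f.well, f.site))
    step = max(len(ordered) // max(config.batch_threshold_sample_sites, 1), 1)
    sample = ordered[::step][: config.batch_threshold_sample_sites]
    out: dict[str, float] = {}
    for ch in PUNCTA_CHANNELS:
        pool = []
        for fis in sample:
            corr = illumination.apply_correction(fis.images[ch], illum[ch])
            enh = puncta.tophat_enhance(corr, config.se_diameter_px[ch])
            pool.append(enh.ravel()[::7])
        pooled = np.concatenate(pool)
        med = float(np.median(pooled))
        mad = float(np.median(np.abs(pooled - med)))
        if mad > 0:
            out[ch] = med + config.batch_threshold_k_mad * 1.4826 * mad
        else:
            # degenerate background (e.g. noise-free input): per-site Otsu
            out[ch] = float("nan")
    return out


def analyze_site(
    fis: FieldImageSet,
    illum: dict[str, illumination.IlluminationFunction],
    config: PipelineConfig,
    batch_thresholds: dict[str, float] | None = None,
) -> tuple[SiteMeasurements, list[registration.ShiftEstimate], dict]:
    """Run the full per-site analysis; returns measurements, shifts, details.

    ``batch_thresholds`` supplies the plate-level calibrated threshold for
    channels configured as ``"batch"``; if omitted, it is calibrated from
    this site alone.
    """
    corrected = {
        ch: illumination.apply_correction(fis.images[ch], illum[ch])
        for ch in fis.images
    }
    shifts: list[registration.ShiftEstimate] = []
    for ch in REGISTERED_CHANNELS:
        est = registration.estimate_shift(
            corrected[ch],
            corrected["Syn1"],
            radius_px=config.registration_radius_px,
            n_bins=config.registration_bins,
            channel=ch,
        )
        corrected[ch] = registration.apply_shift(
            corrected[ch], est, fill=float(np.median(corrected[ch]))
        )
        shifts.append(est)

    needs_batch = [
        ch for ch in PUNCTA_CHANNELS if config.puncta_threshold[ch] == "batch"
    ]
    if needs_batch and batch_thresholds is None:
        batch_thresholds = calibrate_puncta_thresholds([fis], illum, config)

    label_maps: dict[str, puncta.PunctaLabelMap] = {}
    objects: dict[str, list[puncta.PunctaObject]] = {}
    for ch in PUNCTA_CHANNELS:
        thr = config.puncta_threshold[ch]
        if thr == "batch":
            thr = batch_thresholds[ch]
            if isinstance(thr, float) and np.isnan(thr):
                thr = "auto"
        enhanced = puncta.tophat_enhance(corrected[ch], config.se_diameter_px[ch])
        lm = puncta.segment_punctae(
            enhanced,
            threshold=thr,
            low_intensity_cutoff=config.low_intensity_cutoff[ch],
            min_area_px=config.min_area_px,
            channel=ch,
            se_diameter_px=config.se_diameter_px[ch],
        )
        label_maps[ch] = lm
        objects[ch] = puncta.measure_punctae(lm, corrected[ch], config.pixel_size_um)

    tub = dendrites.tubeness_enhance(corrected["MAP2"], config.tubeness_sigma_px)
    skel = dendrites.skeletonize_measure(
        tub,
        threshold=config.dendrite_threshold,
        spur_length_px=config.spur_length_px,
        pixel_size_um=config.pixel_size_um,
        tubeness_sigma_px=config.tubeness_sigma_px,
    )

    pairs = {
        pair_class_name(post, pre): pairing.find_pairs(label_maps[post], label_maps[pre])
        for post, pre in PAIR_CLASSES
    }
    meas = pairing.assemble_site(
        objects,
        pairs,
        skel,
        plate=fis.plate,
        well=fis.well,
        site=fis.site,
        min_dendrite_length_um=config.min_dendrite_length_um,
    )
    return meas, shifts, {"objects": objects, "pairs": pairs, "labels": label_maps}


def analyze_fields(
    fields: list[FieldImageSet],
    config: PipelineConfig,
    platemap: PlateMap,
    illum: dict[str, illumination.IlluminationFunction] | None = None,
    collect_objects: bool = False,
) -> PipelineResult:
    """Run the pipeline on in-memory fields (shared by run_pipeline and tests)."""
    if illum is None:
        illum = compute_plate_illumination(fields, config)
    batch_thresholds = None
    if any(config.puncta_threshold[ch] == "batch" for ch in PUNCTA_CHANNELS):
        batch_thresholds = calibrate_puncta_thresholds(fields, config=config, illum=illum)
    site_rows, reg_rows, warn_rows = [], [], []
    obj_rows, pair_rows, timing_rows = [], [], []
    n_err = 0
    for fis in fields:
        t_start = time.perf_counter()
        try:
            meas, shifts, details = analyze_site(fis, illum, config, batch_thresholds)
        except Exception as exc:  # keep going; fail at the end if too many
            n_err += 1
            warn_rows.append(
                {"plate": fis.plate, "well": fis.well, "site": fis.site,
                 "kind": "site_error", "message": str(exc)}
            )
            logger.warning("site %s/%s/%s failed: %s", fis.plate, fis.well, fis.site, exc)
            continue
        timing_rows.append(
            {"plate": fis.plate, "well": fis.well, "site": fis.site,
             "elapsed_s": time.perf_counter() - t_start}
        )
        site_rows.append(meas.to_row())
        if meas.low_dendrite_flag:
            warn_rows.append(
                {"plate": fis.plate, "well": fis.well, "site": fis.site,
                 "kind": "low_dendrite",
                 "message": f"length {meas.values['dendrite_length_um']:.1f} um"}
            )
        for est in shifts:
            reg_rows.append(
                {"plate": fis.plate, "well": fis.well, "site": fis.site,
                 "channel": est.channel, "drow": est.shift[0], "dcol": est.shift[1],
                 "mi_bits": est.mi_bits, "boundary_flag": est.at_boundary}
            )
            if est.at_boundary:
                warn_rows.append(
                    {"plate": fis.plate, "well": fis.well, "site": fis.site,
                     "kind": "shift_at_boundary",
                     "message": f"{est.channel} shift {est.shift}"}
                )
        if collect_objects:
            for ch, objs in details["objects"].items():
                for o in objs:
                    obj_rows.append(
                        {"plate": fis.plate, "well": fis.well, "site": fis.site,
                         "channel": ch, "object_id": o.object_id,
                         "centroid_row": o.centroid[0], "centroid_col": o.centroid[1],
                         "area_px": o.area_px, "area_um2": o.area_um2,
                         "eccentricity": o.eccentricity,
                         "median_intensity": o.median_intensity,
                         "integrated_intensity": o.integrated_intensity,
                         "expression": o.expression}
                    )
            for cls, plist in details["pairs"].items():
                for p in plist:
                    pair_rows.append(
                        {"plate": fis.plate, "well": fis.well, "site": fis.site,
                         "pair_class": cls, "post_id": p.post_id,
                         "syn1_id": p.syn1_id, "overlap_area_px": p.overlap_area_px}
                    )
    if fields and n_err / len(fields) > config.max_site_error_fraction:
        raise RuntimeError(
            f"{n_err}/{len(fields)} sites failed "
            f"(> {config.max_site_error_fraction:.0%})"
        )
    sites = pd.DataFrame(site_rows)
    wells = aggregate_wells(sites) if len(sites) else pd.DataFrame()
    if len(wells):
        summary = aggregate_shrnas(wells, platemap)
        summary = normalize_to_controls(summary, wells, platemap)
        hits = call_hits(
            summary,
            parameter=config.hit_parameter,
            threshold_fraction=config.hit_threshold_fraction,
            min_hairpins=config.hit_min_hairpins,
        )
        hits_df = pd.DataFrame([vars(h) for h in hits])
        regression_df = _cross_readout_table(summary)
        population_df = _population_table(summary, config.hit_parameter)
    else:
        summary, hits_df = pd.DataFrame(), pd.DataFrame()
        regression_df = population_df = None
    return PipelineResult(
        sites=sites,
        wells=wells,
        shrna_summary=summary,
        gene_hits=hits_df,
        registration_log=pd.DataFrame(reg_rows),
        warnings_log=pd.DataFrame(warn_rows),
        regression=regression_df,
        population_tests=population_df,
        punctae=pd.DataFrame(obj_rows) if collect_objects else None,
        pairs=pd.DataFrame(pair_rows) if collect_objects else None,
        timings=pd.DataFrame(timing_rows),
        illum=illum,
    )


def _cross_readout_table(summary: pd.DataFrame) -> pd.DataFrame:
    """OLS consistency between the excitatory and inhibitory density
    readouts (and each against Syn1 density), per role subset."""
    from synaptoquant.screen import cross_readout_regression

    pairs = [
        ("pair_psd95_syn1_density_per_um", "pair_gphn_syn1_density_per_um"),
        ("psd95_density_per_um", "syn1_density_per_um"),
        ("gphn_density_per_um", "syn1_density_per_um"),
    ]
    rows = []
    for roles in (("library",), ("negative_control",)):
        for x, y in pairs:
            try:
                fit = cross_readout_regression(summary, x, y, roles=roles)
            except ValueError:
                continue
            rows.append(
                {"roles": "+".join(roles), "parameter_x": x, "parameter_y": y,
                 "slope": fit.slope, "intercept": fit.intercept,
                 "r_squared": fit.r_squared, "n": fit.n}
            )
    return pd.DataFrame(rows)


def _population_table(summary: pd.DataFrame, parameter: str) -> pd.DataFrame:
    """Library vs negative-control population t-tests on normalized medians."""
    from synaptoquant.screen import population_comparison

    rows = []
    for param in {parameter, "dendrite_length_um"}:
        try:
            p, (xa, _), (xb, _) = population_comparison(
                summary, param, ("library",), ("negative_control",)
            )
        except ValueError:
            continue
        rows.append(
            {"parameter": param, "group_a": "library",
             "group_b": "negative_control", "p_value": p,
             "n_a": len(xa), "n_b": len(xb)}
        )
    return pd.DataFrame(sorted(rows, key=lambda r: r["parameter"]))


def run_pipeline(
    config: PipelineConfig,
    plate_root: str | Path,
    plate_map: str | Path | PlateMap,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Discover a plate on disk, analyze it, and write all output tables."""
    platemap = (
        plate_map if isinstance(plate_map, PlateMap) else PlateMap.from_csv(plate_map)
    )
    refs, skipped = discover_plate(plate_root, config)
    if skipped:
        logger.warning("skipping %d incomplete sites", len(skipped))
    fields = [load_field(r) for r in refs]
    result = analyze_fields(fields, config, platemap, collect_objects=True)
    if skipped:
        skip_df = pd.DataFrame(skipped)
        skip_df["kind"] = "incomplete_site"
        result.warnings_log = pd.concat(
            [result.warnings_log, skip_df], ignore_index=True
        )
    out = Path(out_dir if out_dir is not None else config.output_dir)
    result.write(out)
    config.to_yaml(out / "config_echo.yaml")
    return result
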