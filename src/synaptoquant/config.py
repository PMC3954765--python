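"""Configuration objects for the simulator and the analysis pipeline.

Both configs round-trip through YAML so that a run can be reproduced from
the config echo written to the output directory.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

#: Canonical channel names, in acquisition order.
CHANNELS: tuple[str, ...] = ("MAP2", "Psd95", "Gphn", "Syn1")

#: Synapse (puncta) channels, i.e. everything but the dendrite marker.
PUNCTA_CHANNELS: tuple[str, ...] = ("Psd95", "Gphn", "Syn1")

#: Colocalization pair classes as (postsynaptic, presynaptic) channel names.
#: Psd95–Syn1 pairs are the operational excitatory synapse, Gphn–Syn1 the
#: inhibitory one.
PAIR_CLASSES: tuple[tuple[str, str], ...] = (("Psd95", "Syn1"), ("Gphn", "Syn1"))


def pair_class_name(post: str, pre: str) -> str:
    return f"{post}-{pre}"


@dataclass
class SimConfig:
    """Parameters of the synthetic 4-channel field generator.

    The defaults describe one imaged site of a dissociated cortical culture
    at high magnification: a 256×256 px field (0.5 μm/px → 128×128 μm),
    a few hundred μm of MAP2-positive dendrite, and tens of synaptic
    puncta per marker channel, most of them sitting on dendrites, with a
    controllable fraction of postsynaptic puncta colocalized with Syn1.
    """

    image_height_px: int = 256
    image_width_px: int = 256
    pixel_size_um: float = 0.5

    # Dendrites (MAP2 channel)
    n_dendrite_trees: int = 3
    dendrite_total_length_um: float = 400.0
    dendrite_sigma_px: float = 2.0
    dendrite_peak_intensity: float = 80.0

    # Puncta (synapse channels)
    puncta_per_channel: dict[str, int] = field(
        default_factory=lambda: {"Psd95": 60, "Gphn": 60, "Syn1": 60}
    )
    puncta_radius_px: float = 3.0
    puncta_peak_intensity: float = 100.0
    min_separation_px: float = 8.0
    on_dendrite_fraction: float = 0.9
    coloc_fraction_psd95_syn1: float = 0.7
    coloc_fraction_gphn_syn1: float = 0.7

    # Acquisition artifacts
    background_level: float = 10.0
    illum_gradient_amplitude: float = 0.15
    channel_shift_px: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {
            "MAP2": (0, 0),
            "Psd95": (2, -1),
            "Gphn": (-1, 2),
            "Syn1": (0, 0),
        }
    )
    max_shift_px: int = 5
    noise_sd: float = 5.0

    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.image_height_px <= 0 or self.image_width_px <= 0:
            raise ValueError("image dimensions must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        for name in ("coloc_fraction_psd95_syn1", "coloc_fraction_gphn_syn1"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.noise_sd < 0 or self.illum_gradient_amplitude < 0:
            raise ValueError("noise_sd and illum_gradient_amplitude must be >= 0")
        for ch, (dr, dc) in self.channel_shift_px.items():
            if abs(dr) > self.max_shift_px or abs(dc) > self.max_shift_px:
                raise ValueError(
                    f"channel {ch} shift ({dr},{dc}) exceeds max_shift_px="
                    f"{self.max_shift_px}"
                )

    def coloc_fraction(self, post_channel: str) -> float:
        return {
            "Psd95": self.coloc_fraction_psd95_syn1,
            "Gphn": self.coloc_fraction_gphn_syn1,
        }[post_channel]

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["channel_shift_px"] = {
            ch: list(sh) for ch, sh in data["channel_shift_px"].items()
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        data = yaml.safe_load(Path(path).read_text())
        if "channel_shift_px" in data:
            data["channel_shift_px"] = {
                ch: tuple(sh) for ch, sh in data["channel_shift_px"].items()
            }
        return cls(**data)


@dataclass
class PipelineConfig:
    """Parameters of the analysis pipeline, one per tunable stage.

    Thresholds may be the string ``"auto"`` (Otsu) or a number; the
    low-intensity and minimum-area object filters are exposed per batch,
    as are the structuring-element diameters per puncta channel.
    """

    # channel-name map: file suffix -> canonical channel
    channel_map: dict[str, str] = field(
        default_factory=lambda: {ch: ch for ch in CHANNELS}
    )
    pixel_size_um: float = 0.5

    # illumination
    illum_filter_size_px: int = 100

    # registration (Psd95 and Gphn aligned to Syn1)
    registration_radius_px: int = 10
    registration_bins: int = 64

    # puncta segmentation
    se_diameter_px: dict[str, int] = field(
        default_factory=lambda: {"Psd95": 7, "Gphn": 7, "Syn1": 7}
    )
    # "batch": plate-level robust background threshold (median + k·MAD of
    # pooled top-hat pixels, the package's per-batch empirical calibration);
    # "auto": per-site Otsu; or a number.
    puncta_threshold: dict[str, float | str] = field(
        default_factory=lambda: {"Psd95": "batch", "Gphn": "batch", "Syn1": "batch"}
    )
    batch_threshold_k_mad: float = 4.0
    batch_threshold_sample_sites: int = 16
    low_intensity_cutoff: dict[str, float] = field(
        default_factory=lambda: {"Psd95": 0.0, "Gphn": 0.0, "Syn1": 0.0}
    )
    min_area_px: int = 4

    # dendrites
    tubeness_sigma_px: float = 2.0
    dendrite_threshold: float | str = "auto"
    spur_length_px: int = 5
    min_dendrite_length_um: float = 50.0

    # screen statistics
    hit_parameter: str = "pair_psd95_syn1_density_per_um"
    hit_threshold_fraction: float = 0.40
    hit_min_hairpins: int = 2

    # pipeline behaviour
    max_site_error_fraction: float = 0.5
    rng_seed: int = 0
    output_dir: str = "synaptoquant_out"

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        mapped = sorted(self.channel_map.values())
        if mapped != sorted(CHANNELS):
            raise ValueError(
                f"channel_map must cover each of {CHANNELS} exactly once, "
                f"got {mapped}"
            )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))
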