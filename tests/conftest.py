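import numpy as np
import pandas as pd
import pytest

from synaptoquant.config import SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def clean_sim_config():
    """Artifact-free simulator: no noise, no gradient, no channel shifts."""
    return SimConfig(
        noise_sd=0.0,
        illum_gradient_amplitude=0.0,
        channel_shift_px={ch: (0, 0) for ch in ("MAP2", "Psd95", "Gphn", "Syn1")},
    )


def make_layout(
    n_genes: int = 4,
    hairpins_per_gene: int = 5,
    n_negative: int = 4,
    plate: str = "P1",
) -> pd.DataFrame:
    """One-well-per-hairpin plate map with trailing negative-control wells."""
    wells = iter(f"{r}{c:02d}" for r in "ABCDEFGH" for c in range(1, 13))
    rows = []
    for g in range(n_genes):
        for h in range(hairpins_per_gene):
            rows.append(
                dict(plate=plate, well=next(wells), shrna_id=f"g{g}h{h}",
                     gene=f"gene{g}", role="library")
            )
    for k in range(n_negative):
        rows.append(
            dict(plate=plate, well=next(wells), shrna_id=f"neg{k}",
                 gene=f"ctrlgene{k}", role="negative_control")
        )
    return pd.DataFrame(rows)
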