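"""Screen-level aggregation, normalization and hit calling.

Per-site measurements are aggregated by median first within each well and
then across replicate wells of the same hairpin (median, MAD, %CV). Each
hairpin's medians are normalized against the median of the negative-control
wells of the same plate — non-targeting hairpins define the null
distribution — and compared to the controls with a two-tailed Welch t-test.
A gene is nominated as a hit when at least ``min_hairpins`` of its hairpins
reduce the chosen synaptogenesis readout by at least the threshold fraction
(default: 2 of its hairpins at ≥40% reduction, boundary inclusive).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from synaptoquant.pairing import DENSITY_PARAMETERS, PARAMETERS

__all__ = [
    "PlateMap",
    "HitCall",
    "RegressionResult",
    "aggregate_well",
    "aggregate_wells",
    "aggregate_shrna",
    "aggregate_shrnas",
    "normalize_to_controls",
    "call_hits",
    "cross_readout_regression",
    "population_comparison",
]

ROLES = ("library", "negative_control", "positive_control", "empty")


@dataclass
class PlateMap:
    """Well → hairpin assignment: plate, well, shrna_id, gene, role."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"plate", "well", "shrna_id", "gene", "role"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"plate map missing columns: {sorted(missing)}")
        bad_roles = set(self.table["role"]) - set(ROLES)
        if bad_roles:
            raise ValueError(f"unknown roles in plate map: {sorted(bad_roles)}")
        dup = self.table.duplicated(subset=["plate", "well"])
        if dup.any():
            rows = self.table.loc[dup, ["plate", "well"]].to_records(index=False)
            raise ValueError(f"duplicate (plate, well) entries: {list(rows)}")
        scored = self.table[self.table["role"].isin(("library", "positive_control"))]
        genes_per_shrna = scored.groupby("shrna_id")["gene"].nunique()
        multi = genes_per_shrna[genes_per_shrna > 1]
        if len(multi):
            raise ValueError(
                f"shRNAs mapped to multiple genes: {list(multi.index)}"
            )

    @classmethod
    def from_csv(cls, path: str | Path) -> "PlateMap":
        return cls(pd.read_csv(path, dtype={"well": str, "plate": str}))

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


@dataclass
class HitCall:
    gene: str
    parameter: str
    n_hairpins_passing: int
    n_hairpins_total: int
    threshold_fraction: float
    is_hit: bool


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    n: int


# ---------------------------------------------------------------------------
# aggregation


def aggregate_well(sites: pd.DataFrame) -> pd.DataFrame:
    """Median over the sites of one well, per parameter.

    Sites flagged for low dendritic outgrowth are excluded from density
    parameters only (their counts and morphology are still informative).
    Returns a long table (parameter, value, n_sites); a parameter with no
    usable site is NaN with n_sites 0.
    """
    keys = sites[["plate", "well"]].drop_duplicates()
    if len(keys) != 1:
        raise ValueError(f"aggregate_well got sites from {len(keys)} wells")
    rows = []
    for param in PARAMETERS:
        usable = sites
        if param in DENSITY_PARAMETERS:
            usable = sites[~sites["low_dendrite_flag"].astype(bool)]
        vals = usable[param].dropna()
        rows.append(
            {
                "plate": keys.iloc[0]["plate"],
                "well": keys.iloc[0]["well"],
                "parameter": param,
                "value": float(np.median(vals)) if len(vals) else np.nan,
                "n_sites": int(len(vals)),
            }
        )
    return pd.DataFrame(rows)


def aggregate_wells(sites: pd.DataFrame) -> pd.DataFrame:
    """Apply :func:`aggregate_well` to every (plate, well) in a site table."""
    parts = [
        aggregate_well(grp) for _, grp in sites.groupby(["plate", "well"], sort=True)
    ]
    return pd.concat(parts, ignore_index=True)


def aggregate_shrna(well_values: pd.DataFrame, shrna_id: str) -> pd.DataFrame:
    """Replicate-well statistics for one hairpin: median, MAD, %CV.

    MAD is the unscaled median absolute deviation from the median; %CV is
    100 × sample standard deviation / mean, undefined (NaN) for a zero
    mean or a single replicate.
    """
    rows = []
    for param, grp in well_values.groupby("parameter"):
        vals = grp["value"].dropna().to_numpy()
        if len(vals) == 0:
            med = mad = cv = np.nan
        else:
            med = float(np.median(vals))
            mad = float(np.median(np.abs(vals - med)))
            mean = float(np.mean(vals))
            if len(vals) < 2 or mean == 0:
                cv = np.nan
                if mean == 0:
                    warnings.warn(
                        f"%CV undefined for {shrna_id}/{param}: zero mean"
                    )
            else:
                cv = 100.0 * float(np.std(vals, ddof=1)) / mean
        rows.append(
            {
                "shrna_id": shrna_id,
                "parameter": param,
                "median": med,
                "mad": mad,
                "pct_cv": cv,
                "n_replicates": int(len(vals)),
            }
        )
    return pd.DataFrame(rows)


def aggregate_shrnas(wells: pd.DataFrame, platemap: PlateMap) -> pd.DataFrame:
    """Aggregate well medians over replicate wells for every hairpin."""
    merged = wells.merge(
        platemap.table[["plate", "well", "shrna_id", "gene", "role"]],
        on=["plate", "well"],
        how="inner",
    )
    merged = merged[merged["role"] != "empty"]
    parts = []
    for shrna, grp in merged.groupby("shrna_id", sort=True):
        summ = aggregate_shrna(grp, shrna)
        summ["gene"] = grp["gene"].iloc[0]
        summ["role"] = grp["role"].iloc[0]
        parts.append(summ)
    return pd.concat(parts, ignore_index=True)


# ---------------------------------------------------------------------------
# normalization and tests


def normalize_to_controls(
    summaries: pd.DataFrame, wells: pd.DataFrame, platemap: PlateMap
) -> pd.DataFrame:
    """Normalize each hairpin against its plate's negative-control null.

    Per parameter, each hairpin's median is divided by the median of the
    negative-control well-medians from the same plate, and its replicate
    well values are compared to those control wells with a two-tailed
    Welch (unequal-variance) t-test.
    """
    merged = wells.merge(
        platemap.table[["plate", "well", "shrna_id", "role"]],
        on=["plate", "well"],
        how="inner",
    )
    plates_of = (
        merged[merged["role"] != "empty"].groupby("shrna_id")["plate"].unique()
    )
    ctrl = merged[merged["role"] == "negative_control"]
    for plate in merged["plate"].unique():
        if not len(ctrl[ctrl["plate"] == plate]):
            raise ValueError(f"plate {plate!r} has no negative-control wells")

    out = summaries.copy()
    out["normalized"] = np.nan
    out["p_value"] = np.nan
    for idx, row in out.iterrows():
        plates = plates_of.get(row["shrna_id"], [])
        cvals = ctrl[
            (ctrl["plate"].isin(plates)) & (ctrl["parameter"] == row["parameter"])
        ]["value"].dropna()
        if not len(cvals):
            continue
        ctrl_median = float(np.median(cvals))
        if ctrl_median != 0:
            out.at[idx, "normalized"] = row["median"] / ctrl_median
        svals = merged[
            (merged["shrna_id"] == row["shrna_id"])
            & (merged["parameter"] == row["parameter"])
        ]["value"].dropna()
        if len(svals) >= 2 and len(cvals) >= 2:
            t = stats.ttest_ind(svals, cvals, equal_var=False)
            out.at[idx, "p_value"] = float(t.pvalue)
    return out


def call_hits(
    summaries: pd.DataFrame,
    parameter: str = "pair_psd95_syn1_density_per_um",
    threshold_fraction: float = 0.40,
    min_hairpins: int = 2,
    roles: tuple[str, ...] = ("library",),
) -> list[HitCall]:
    """Multi-hairpin knockdown rule on normalized medians.

    A hairpin passes when its normalized value is ≤ 1 − threshold_fraction
    (boundary inclusive, i.e. "reduction by ≥40%"); a gene is a hit when at
    least ``min_hairpins`` of its hairpins pass.
    """
    sel = summaries[
        (summaries["parameter"] == parameter) & (summaries["role"].isin(roles))
    ]
    calls: list[HitCall] = []
    for gene, grp in sel.groupby("gene", sort=True):
        vals = grp.dropna(subset=["normalized"])
        if not len(vals):
            warnings.warn(f"gene {gene!r} has no scorable hairpins; skipped")
            continue
        passing = int((vals["normalized"] <= 1.0 - threshold_fraction).sum())
        calls.append(
            HitCall(
                gene=str(gene),
                parameter=parameter,
                n_hairpins_passing=passing,
                n_hairpins_total=int(len(vals)),
                threshold_fraction=threshold_fraction,
                is_hit=passing >= min_hairpins,
            )
        )
    return calls


def cross_readout_regression(
    summaries: pd.DataFrame,
    parameter_x: str,
    parameter_y: str,
    roles: tuple[str, ...] = ("library",),
) -> RegressionResult:
    """OLS of one normalized readout on another over a role subset.

    Mirrors the screen-wide consistency check between, e.g., excitatory and
    inhibitory synapse density readouts.
    """
    sel = summaries[summaries["role"].isin(roles)]
    x = sel[sel["parameter"] == parameter_x].set_index("shrna_id")["normalized"]
    y = sel[sel["parameter"] == parameter_y].set_index("shrna_id")["normalized"]
    joined = pd.concat([x.rename("x"), y.rename("y")], axis=1).dropna()
    if len(joined) < 3:
        raise ValueError(f"regression needs >= 3 points, got {len(joined)}")
    if np.var(joined["x"].to_numpy()) == 0:
        raise ValueError("zero variance in x")
    fit = stats.linregress(joined["x"], joined["y"])
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n=int(len(joined)),
    )


def population_comparison(
    summaries: pd.DataFrame,
    parameter: str,
    roles_a: tuple[str, ...] = ("library",),
    roles_b: tuple[str, ...] = ("negative_control",),
    values_a: np.ndarray | None = None,
    values_b: np.ndarray | None = None,
):
    """Two-tailed Welch t-test between two populations of normalized medians.

    Returns (p_value, ecdf_a, ecdf_b) where each ECDF is a (sorted values,
    cumulative fraction) pair for plotting. Populations may alternatively
    be passed directly via ``values_a``/``values_b``.
    """

    def _extract(roles):
        sel = summaries[
            (summaries["parameter"] == parameter) & (summaries["role"].isin(roles))
        ]
        return sel["normalized"].dropna().to_numpy()

    a = np.asarray(values_a, dtype=float) if values_a is not None else _extract(roles_a)
    b = np.asarray(values_b, dtype=float) if values_b is not None else _extract(roles_b)
    if len(a) < 2 or len(b) < 2:
        raise ValueError(
            f"population comparison needs >= 2 per group, got {len(a)} and {len(b)}"
        )
    t = stats.ttest_ind(a, b, equal_var=False)

    def _ecdf(v):
        s = np.sort(v)
        return s, np.arange(1, len(s) + 1) / len(s)

    return float(t.pvalue), _ecdf(a), _ecdf(b)
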