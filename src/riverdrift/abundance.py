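"""Theoretical absolute abundances from qPCR totals and growth kinetics.

qPCR totals are 16S rRNA gene copies per mL of filtered water. Multiplying
a taxon's relative amplicon proportion by the site total gives its
theoretical absolute abundance in the same unit. NOTE: no 16S
copy-number-per-cell correction is applied; all values are gene copies,
not cells (stated in every output header written by the CLI).

Apparent growth between two points separated by a known water transit time
is summarized as the exponential-phase doubling time
t_d = transit * ln 2 / ln(nf / n0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConstantSeriesError, ValidationError
from .network import PearsonResult, pearson_with_p
from .tables import TransectMetadata


@dataclass
class QpcrSeries:
    """Per-site qPCR totals (mean copies/mL, sd, distance from the lake)."""

    table: pd.DataFrame  # index site_id; columns copies_per_ml, sd, distance_m

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.table)
        for col in ("copies_per_ml", "distance_m"):
            if col not in df.columns:
                raise ValidationError(f"qPCR series missing column {col!r}")
        if "sd" not in df.columns:
            df["sd"] = 0.0
        if (df["copies_per_ml"] <= 0).any():
            raise ValidationError("qPCR means must be > 0")
        if (df["sd"] < 0).any():
            raise ValidationError("qPCR standard deviations must be >= 0")
        self.table = df

    @classmethod
    def from_metadata(cls, metadata: TransectMetadata) -> "QpcrSeries":
        if metadata.qpcr is None:
            raise ValidationError("metadata carries no qPCR table")
        df = metadata.qpcr.copy()
        df["distance_m"] = metadata.site_distances().reindex(df.index)
        types = metadata.samples.drop_duplicates("site_id").set_index("site_id")["site_type"]
        df["site_type"] = types.reindex(df.index)
        return cls(df)


def theoretical_abundance(rel_prop: float, total: float) -> float:
    """Absolute abundance (copies/mL) = relative proportion x qPCR total."""
    if not (np.isfinite(rel_prop) and np.isfinite(total)):
        raise ValidationError("inputs must be finite")
    if not 0 <= rel_prop <= 1:
        raise ValidationError(f"relative proportion must lie in [0, 1], got {rel_prop}")
    if total <= 0:
        raise ValidationError("qPCR total must be > 0")
    return float(rel_prop * total)


@dataclass(frozen=True)
class DoublingTime:
    """Doubling time in minutes; ``growth`` is False when nf <= n0.

    For nf == n0 the doubling time is +inf; for nf < n0 it is negative
    (a halving, reported explicitly rather than masked).
    """

    minutes: float
    growth: bool


def doubling_time(n0: float, nf: float, transit_minutes: float) -> DoublingTime:
    """Exponential-phase doubling time over a transit of known duration."""
    if n0 <= 0 or nf <= 0 or transit_minutes <= 0:
        raise ValidationError("abundances and transit time must be > 0")
    ratio = nf / n0
    if ratio == 1.0:
        return DoublingTime(minutes=math.inf, growth=False)
    minutes = transit_minutes * math.log(2.0) / math.log(ratio)
    return DoublingTime(minutes=float(minutes), growth=ratio > 1.0)


def qpcr_distance_check(series: QpcrSeries, river_only: bool = True) -> PearsonResult:
    """Pearson test of qPCR totals against distance from the lake.

    A constant series is flagged as NaN (degenerate) instead of raising.
    ``river_only`` drops the lake (distance 0) and any tributary rows.
    """
    df = series.table.dropna(subset=["distance_m"])
    if river_only:
        if "site_type" in df.columns and df["site_type"].notna().any():
            df = df[df["site_type"] == "river"]
        else:
            df = df[df["distance_m"] > 0]
    if len(df) < 3:
        raise ValidationError("qPCR distance check needs >= 3 river sites")
    try:
        return pearson_with_p(
            df["distance_m"].to_numpy(float), df["copies_per_ml"].to_numpy(float)
        )
    except ConstantSeriesError:
        return PearsonResult(r=float("nan"), p=float("nan"), n=len(df))


def abundance_profile(
    rel_props: pd.Series, totals: pd.Series, sd: pd.Series | None = None
) -> pd.DataFrame:
    """Theoretical abundance per site for one OTU, with optional qPCR sd
    propagated first-order (delta method): sd_abs = rel_prop * sd_total."""
    sites = rel_props.index
    out = pd.DataFrame(
        {
            "rel_prop": rel_props.astype(float),
            "copies_per_ml": [
                theoretical_abundance(rel_props[s], totals[s]) for s in sites
            ],
        },
        index=sites,
    )
    if sd is not None:
        out["sd_copies_per_ml"] = rel_props.astype(float) * sd.reindex(sites).astype(float)
    return out
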