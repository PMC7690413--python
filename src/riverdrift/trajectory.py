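"""Presence/absence trajectory classification along the transect.

Every OTU's ordered detection series (lake first, then river sites
downstream) falls in exactly one of four classes:

``stable``
    detected at every position, lake through terminal site;
``lost``
    detected in the lake and a contiguous upstream prefix, then never again
    (pattern ``1^a 0^b``, a >= 1, b >= 1);
``emerging``
    absent in the lake and any upstream prefix, then detected at every site
    from first detection onward (pattern ``0^a 1^b``);
``unstable``
    everything else (intermittent detection; the all-absent series cannot
    occur after duplicate-consistency filtering and is classed unstable).

The lake is position 0 of the series, so the degenerate lake-only pattern
``1 0^n`` counts as lost; it is flagged separately in summaries. Tributary
samples never enter a trajectory series; they are used only for origin
attribution of OTUs reaching the terminal site.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .tables import ProportionTable, TransectMetadata

STABLE = "stable"
LOST = "lost"
EMERGING = "emerging"
UNSTABLE = "unstable"
TRAJECTORY_CLASSES = (STABLE, UNSTABLE, EMERGING, LOST)

ORIGIN_LAKE_AND_TRIBUTARIES = "lake_and_tributaries"
ORIGIN_TRIBUTARIES_ONLY = "tributaries_only"
ORIGIN_LAKE_ONLY = "lake_only"
ORIGIN_NEITHER = "neither"


@dataclass(frozen=True)
class DetectionProfile:
    """Ordered presence/absence series for one OTU (s0 = lake)."""

    otu_id: str
    series: tuple[bool, ...]

    def __post_init__(self) -> None:
        if len(self.series) < 2:
            raise ValidationError("detection series needs the lake plus >= 1 river site")
        object.__setattr__(self, "series", tuple(bool(s) for s in self.series))


def classify_series(series) -> str:
    """Classify a raw boolean series; see the module docstring for the rules."""
    s = np.asarray(series, dtype=bool)
    if s.ndim != 1 or s.size < 2:
        raise ValidationError("series must be 1-D with length >= 2")
    if s.all():
        return STABLE
    transitions = int(np.count_nonzero(s[1:] != s[:-1]))
    if transitions == 1 and s[0]:
        return LOST
    if transitions == 1 and s[-1]:
        return EMERGING
    return UNSTABLE


def classify_trajectory(profile: DetectionProfile) -> str:
    return classify_series(profile.series)


def detection_profiles(props: ProportionTable, metadata: TransectMetadata) -> list[DetectionProfile]:
    """Build lake+river detection profiles from a preprocessed table."""
    order = [metadata.lake_site, *metadata.river_sites]
    det = props.detection_frame().loc[order]
    return [
        DetectionProfile(otu_id=o, series=tuple(det[o].to_numpy()))
        for o in props.otu_ids
    ]


def summarize_classes(profiles: list[DetectionProfile]) -> pd.DataFrame:
    """Counts and fractions per trajectory class (fractions sum to 1).

    The degenerate lake-only pattern (present in the lake, never in the
    river) is included under ``lost`` and reported in the extra
    ``lost_lake_only`` column of that row.
    """
    if not profiles:
        raise ValidationError("summarize_classes needs >= 1 profile")
    counts = {c: 0 for c in TRAJECTORY_CLASSES}
    lake_only = 0
    for prof in profiles:
        cls = classify_trajectory(prof)
        counts[cls] += 1
        if cls == LOST and not any(prof.series[1:]):
            lake_only += 1
    total = len(profiles)
    out = pd.DataFrame(
        {
            "count": [counts[c] for c in TRAJECTORY_CLASSES],
            "fraction": [counts[c] / total for c in TRAJECTORY_CLASSES],
        },
        index=pd.Index(TRAJECTORY_CLASSES, name="trajectory"),
    )
    out["lost_lake_only"] = 0
    out.loc[LOST, "lost_lake_only"] = lake_only
    return out


def first_last_sites(
    profiles: list[DetectionProfile], distances: np.ndarray | list[float]
) -> pd.DataFrame:
    """Distance intervals bracketing disappearance (lost) or appearance (emerging).

    ``distances`` aligns with the series positions (lake first). For a lost
    OTU the bracket is (last present distance, first absent distance]; for an
    emerging OTU it is (last absent distance, first present distance].
    Stable and unstable OTUs get null brackets, not an error.
    """
    d = np.asarray(distances, dtype=float)
    rows = []
    for prof in profiles:
        if len(prof.series) != d.size:
            raise ValidationError("distances do not align with the detection series")
        s = np.asarray(prof.series, dtype=bool)
        cls = classify_series(s)
        lower = upper = np.nan
        if cls == LOST:
            last_present = int(np.flatnonzero(s)[-1])
            lower, upper = d[last_present], d[last_present + 1]
        elif cls == EMERGING:
            first_present = int(np.flatnonzero(s)[0])
            lower, upper = d[first_present - 1], d[first_present]
        rows.append((prof.otu_id, cls, lower, upper))
    return pd.DataFrame(
        rows, columns=["otu_id", "trajectory", "bracket_lower_m", "bracket_upper_m"]
    ).set_index("otu_id")


def classify_origin(
    detected_terminal: bool, detected_lake: bool, tributary_detections: dict[str, bool]
) -> str:
    """Origin class of an OTU detected at the terminal (DWTP) river site."""
    if not detected_terminal:
        raise ValidationError("origin is only defined for OTUs detected at the terminal site")
    in_trib = any(bool(v) for v in tributary_detections.values())
    if detected_lake and in_trib:
        return ORIGIN_LAKE_AND_TRIBUTARIES
    if in_trib:
        return ORIGIN_TRIBUTARIES_ONLY
    if detected_lake:
        return ORIGIN_LAKE_ONLY
    return ORIGIN_NEITHER


def origin_classes(props: ProportionTable, metadata: TransectMetadata) -> pd.DataFrame:
    """Origin attribution for every OTU detected at the terminal river site."""
    det = props.detection_frame()
    terminal = metadata.terminal_river_site
    lake = metadata.lake_site
    tribs = metadata.tributary_sites
    rows = []
    for otu in props.otu_ids:
        if not det.loc[terminal, otu]:
            continue
        trib_flags = {t: bool(det.loc[t, otu]) for t in tribs}
        rows.append(
            (otu, classify_origin(True, bool(det.loc[lake, otu]), trib_flags))
        )
    return pd.DataFrame(rows, columns=["otu_id", "origin"]).set_index("otu_id")
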