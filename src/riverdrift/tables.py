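"""Core data containers for transect community data.

The pipeline operates on three tabular objects:

``CountTable``
    Integer OTU counts, samples x OTUs, with optional taxonomy lineages.
``TransectMetadata``
    Per-sample site assignments and per-site environmental / qPCR tables for
    an ordered lake -> river transect with tributaries.
``ProportionTable``
    Per-site averaged relative proportions plus duplicate-consistent
    detection flags; the unit of every downstream statistic.

All containers validate their invariants on construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

SITE_TYPES = ("lake", "river", "tributary")

#: Mandated preprocessing order; each stage may only follow earlier ones.
PIPELINE_ORDER = (
    "filter_taxa",
    "rarefy",
    "duplicate_consistency",
    "average_duplicates",
    "abundance_subset",
)

REQUIRED_SAMPLE_COLUMNS = (
    "sample_id",
    "site_id",
    "site_type",
    "distance_m",
    "duplicate_label",
)


def _check_unique(ids, what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dupes = sorted(seen[seen.duplicated()].unique().tolist())
        raise ValidationError(f"duplicate {what}: {dupes}")


@dataclass
class CountTable:
    """Samples x OTUs matrix of non-negative integer sequence counts.

    Parameters
    ----------
    sample_ids, otu_ids
        Opaque unique identifiers for rows and columns of ``counts``.
    counts
        Integer matrix of shape ``(n_samples, n_otus)`` with entries >= 0.
    taxonomy
        Optional map ``otu_id -> semicolon-delimited lineage string``.
    provenance
        Ordered record of the preprocessing stages already applied; used to
        enforce the pipeline order (see :data:`PIPELINE_ORDER`).
    site_detection
        Filled by ``preprocess.duplicate_consistency``: boolean site x OTU
        frame marking OTUs detected in *all* duplicates of a site.
    """

    sample_ids: list[str]
    otu_ids: list[str]
    counts: np.ndarray
    taxonomy: dict[str, str] | None = None
    provenance: tuple[str, ...] = ()
    site_detection: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.otu_ids = [str(o) for o in self.otu_ids]
        _check_unique(self.sample_ids, "sample ids")
        _check_unique(self.otu_ids, "otu ids")
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise ValidationError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.otu_ids)} OTUs"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(counts, 1), 0)):
                raise ValidationError("counts must be integers")
            counts = counts.astype(np.int64)
        if (counts < 0).any():
            i, j = np.argwhere(counts < 0)[0]
            raise ValidationError(
                f"negative count at sample {self.sample_ids[i]!r}, OTU {self.otu_ids[j]!r}"
            )
        self.counts = counts.astype(np.int64, copy=False)
        if self.taxonomy is not None:
            unknown = set(self.taxonomy) - set(self.otu_ids)
            if unknown:
                raise ValidationError(f"taxonomy keys are not otu_ids: {sorted(unknown)}")

    # -- convenience accessors -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    def sample_sums(self) -> pd.Series:
        return pd.Series(self.counts.sum(axis=1), index=self.sample_ids, name="total")

    def otu_sums(self) -> pd.Series:
        return pd.Series(self.counts.sum(axis=0), index=self.otu_ids, name="total")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.otu_ids)

    def select_otus(self, keep: np.ndarray | list[str]) -> "CountTable":
        """Subset columns, preserving taxonomy/provenance."""
        if isinstance(keep, np.ndarray) and keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            pos = {o: i for i, o in enumerate(self.otu_ids)}
            idx = np.array([pos[o] for o in keep], dtype=int)
        otu_ids = [self.otu_ids[i] for i in idx]
        tax = None
        if self.taxonomy is not None:
            tax = {o: self.taxonomy[o] for o in otu_ids if o in self.taxonomy}
        det = None
        if self.site_detection is not None:
            det = self.site_detection.loc[:, otu_ids].copy()
        return CountTable(
            sample_ids=list(self.sample_ids),
            otu_ids=otu_ids,
            counts=self.counts[:, idx].copy(),
            taxonomy=tax,
            provenance=self.provenance,
            site_detection=det,
        )

    def with_stage(self, stage: str) -> "CountTable":
        return replace(self, provenance=self.provenance + (stage,))


@dataclass
class TransectMetadata:
    """Sample-to-site mapping and per-site tables for one transect.

    ``samples`` must carry :data:`REQUIRED_SAMPLE_COLUMNS`. Distances are
    meters of cumulative water-channel distance from the lake; the lake is
    canonically at 0 (a nonzero lake distance is normalized with a warning)
    and tributaries carry the distance of their confluence. River sites are
    ordered upstream -> downstream by increasing distance.
    """

    samples: pd.DataFrame
    env: pd.DataFrame | None = None
    qpcr: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.samples).copy()
        missing = [c for c in REQUIRED_SAMPLE_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"metadata missing required column(s): {missing}")
        bad_types = set(df["site_type"]) - set(SITE_TYPES)
        if bad_types:
            raise ValidationError(f"unknown site_type value(s): {sorted(bad_types)}")
        df["distance_m"] = pd.to_numeric(df["distance_m"], errors="raise").astype(float)
        _check_unique(df["sample_id"], "sample ids")

        # one type/distance per site
        per_site = df.groupby("site_id", sort=False).agg(
            site_type=("site_type", "nunique"), distance_m=("distance_m", "nunique")
        )
        incoherent = per_site[(per_site > 1).any(axis=1)].index.tolist()
        if incoherent:
            raise ValidationError(f"sites with conflicting type/distance: {incoherent}")

        lake_sites = df.loc[df.site_type == "lake", "site_id"].unique()
        if len(lake_sites) != 1:
            raise ValidationError(
                f"transect must have exactly one lake site, found {len(lake_sites)}"
            )
        lake_mask = df.site_type == "lake"
        if (df.loc[lake_mask, "distance_m"] != 0).any():
            warnings.warn(
                "lake distance normalized to 0 m (the lake is the transect origin)",
                stacklevel=2,
            )
            df.loc[lake_mask, "distance_m"] = 0.0

        river = df[df.site_type == "river"].drop_duplicates("site_id")
        dists = river["distance_m"].to_numpy()
        if len(dists) != len(np.unique(dists)):
            raise ValidationError("river sites with equal distance_m")
        if (dists <= 0).any():
            raise ValidationError("river distances must be > 0 m (lake is at 0)")

        # canonical order: lake, river by distance, tributaries by distance
        rank = {"lake": 0, "river": 1, "tributary": 2}
        df = df.sort_values(
            by=["site_type", "distance_m", "site_id", "duplicate_label"],
            key=lambda s: s.map(rank) if s.name == "site_type" else s,
            kind="stable",
        ).reset_index(drop=True)
        self.samples = df

        for name in ("env", "qpcr"):
            tab = getattr(self, name)
            if tab is None:
                continue
            tab = pd.DataFrame(tab)
            if "site_id" in tab.columns:
                tab = tab.set_index("site_id")
            unknown = set(tab.index) - set(df["site_id"])
            if unknown:
                raise ValidationError(f"{name} table has unknown site(s): {sorted(unknown)}")
            setattr(self, name, tab)

    # -- site-level views ------------------------------------------------------

    @property
    def lake_site(self) -> str:
        return self.samples.loc[self.samples.site_type == "lake", "site_id"].iloc[0]

    @property
    def river_sites(self) -> list[str]:
        sub = self.samples[self.samples.site_type == "river"].drop_duplicates("site_id")
        return sub.sort_values("distance_m")["site_id"].tolist()

    @property
    def tributary_sites(self) -> list[str]:
        sub = self.samples[self.samples.site_type == "tributary"].drop_duplicates("site_id")
        return sub.sort_values("distance_m")["site_id"].tolist()

    @property
    def ordered_sites(self) -> list[str]:
        """Lake, then river sites downstream, then tributaries."""
        return [self.lake_site, *self.river_sites, *self.tributary_sites]

    @property
    def terminal_river_site(self) -> str:
        return self.river_sites[-1]

    def site_distances(self) -> pd.Series:
        sub = self.samples.drop_duplicates("site_id").set_index("site_id")
        return sub.loc[self.ordered_sites, "distance_m"]

    def site_samples(self, site_id: str) -> list[str]:
        return self.samples.loc[self.samples.site_id == site_id, "sample_id"].tolist()

    def samples_by_site(self) -> dict[str, list[str]]:
        return {s: self.site_samples(s) for s in self.ordered_sites}


@dataclass
class ProportionTable:
    """Per-site averaged relative proportions with detection flags.

    ``proportions`` has shape ``(n_sites, n_otus)``; each row sums to <= 1
    (exactly 1 when no OTU was excluded after averaging). ``detected`` marks
    OTUs present in all duplicates of the site. ``otu_totals`` carries the
    pre-averaging sequence totals per OTU over the whole dataset, which is
    the quantity abundance subsetting thresholds against.
    """

    site_ids: list[str]
    otu_ids: list[str]
    proportions: np.ndarray
    detected: np.ndarray
    otu_totals: np.ndarray = field(default=None)  # type: ignore[assignment]
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        _check_unique(self.site_ids, "site ids")
        _check_unique(self.otu_ids, "otu ids")
        shape = (len(self.site_ids), len(self.otu_ids))
        p = np.asarray(self.proportions, dtype=float)
        d = np.asarray(self.detected, dtype=bool)
        if p.shape != shape or d.shape != shape:
            raise ValidationError("proportions/detected shape mismatch")
        if (p < 0).any() or (p > 1 + 1e-9).any():
            raise ValidationError("proportions must lie in [0, 1]")
        if (p.sum(axis=1) > 1 + 1e-9).any():
            raise ValidationError("site proportions sum above 1")
        if (d & (p <= 0)).any():
            raise ValidationError("detection flag set where proportion is 0")
        if self.otu_totals is None:
            self.otu_totals = np.zeros(len(self.otu_ids))
        self.otu_totals = np.asarray(self.otu_totals, dtype=float)
        if self.otu_totals.shape != (len(self.otu_ids),):
            raise ValidationError("otu_totals length mismatch")
        self.proportions, self.detected = p, d

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    def site_vector(self, site_id: str) -> np.ndarray:
        return self.proportions[self.site_ids.index(site_id)]

    def detection_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.detected, index=self.site_ids, columns=self.otu_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.proportions, index=self.site_ids, columns=self.otu_ids)

    def select_otus(self, keep: np.ndarray | list[str]) -> "ProportionTable":
        if isinstance(keep, np.ndarray) and keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            pos = {o: i for i, o in enumerate(self.otu_ids)}
            idx = np.array([pos[o] for o in keep], dtype=int)
        return ProportionTable(
            site_ids=list(self.site_ids),
            otu_ids=[self.otu_ids[i] for i in idx],
            proportions=self.proportions[:, idx].copy(),
            detected=self.detected[:, idx].copy(),
            otu_totals=self.otu_totals[idx].copy(),
            provenance=self.provenance,
        )


def check_stage_order(provenance: tuple[str, ...], stage: str) -> None:
    """Raise :class:`PipelineOrderError` if ``stage`` would run after a later one."""
    from .errors import PipelineOrderError

    rank = PIPELINE_ORDER.index(stage)
    for done in provenance:
        if done in PIPELINE_ORDER and PIPELINE_ORDER.index(done) > rank:
            raise PipelineOrderError(
                f"cannot apply {stage!r} after {done!r}; required order is "
                + " -> ".join(PIPELINE_ORDER)
            )
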