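"""Table conditioning: taxon exclusion, rarefaction, duplicate filtering.

The canonical pipeline, in mandated order, is::

    filter_taxa -> rarefy -> duplicate_consistency -> average_duplicates
                -> abundance_subset

Each operation records itself in the table's ``provenance`` and refuses to
run after a later stage (out-of-order calls raise
:class:`~riverdrift.errors.PipelineOrderError`).

Conventions
-----------
* "Detected" means count >= 1 after rarefaction, in *all* duplicates of a
  site; an OTU detected at no site is dropped from the table entirely.
* Site proportions are the arithmetic mean of the duplicate-level relative
  proportions, computed after the detection flags are fixed.
* Abundance subsets threshold on pre-averaging sequence totals over the
  whole dataset (e.g. 0.001 keeps OTUs holding >= 0.1% of all reads).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .errors import ValidationError
from .tables import CountTable, ProportionTable, TransectMetadata, check_stage_order

logger = logging.getLogger(__name__)


def filter_taxa(table: CountTable, exclude: list[str]) -> CountTable:
    """Drop OTUs whose lineage contains any excluded rank keyword.

    Matching is case-insensitive and per rank: the lineage is split on ``;``
    and an OTU is removed iff any rank equals one of ``exclude``.
    Untaxonomized OTUs are kept and logged.
    """
    check_stage_order(table.provenance, "filter_taxa")
    if not exclude:
        warnings.warn("filter_taxa called with an empty exclusion list; no-op")
        return table.with_stage("filter_taxa")
    wanted = {k.strip().lower() for k in exclude}
    taxonomy = table.taxonomy or {}
    missing = [o for o in table.otu_ids if o not in taxonomy]
    if missing:
        logger.info("filter_taxa: %d OTUs lack taxonomy and are kept", len(missing))
    keep = np.ones(table.n_otus, dtype=bool)
    for j, otu in enumerate(table.otu_ids):
        lineage = taxonomy.get(otu)
        if lineage is None:
            continue
        ranks = {r.strip().lower() for r in str(lineage).split(";")}
        if ranks & wanted:
            keep[j] = False
    logger.info("filter_taxa: removed %d of %d OTUs", int((~keep).sum()), table.n_otus)
    return table.select_otus(keep).with_stage("filter_taxa")


def rarefy(table: CountTable, depth: int | str = "min", seed: int = 0) -> CountTable:
    """Subsample every sample without replacement to a common depth.

    ``depth="min"`` resolves to the smallest sample total. A numeric depth
    larger than some sample's total is an error naming the offending samples.
    A single seeded draw is taken per sample (no multiple-rarefaction
    averaging); a sample already at the target depth is returned unchanged.
    """
    check_stage_order(table.provenance, "rarefy")
    totals = table.counts.sum(axis=1)
    if depth == "min":
        depth = int(totals.min())
    depth = int(depth)
    if depth < 1:
        raise ValidationError("rarefaction depth must be >= 1")
    short = [s for s, t in zip(table.sample_ids, totals) if t < depth]
    if short:
        raise ValidationError(
            f"rarefaction depth {depth} exceeds the total of sample(s): {short}"
        )
    rng = np.random.default_rng(seed)
    out = np.empty_like(table.counts)
    for i in range(table.n_samples):
        row = table.counts[i]
        if totals[i] == depth:
            out[i] = row
        else:
            out[i] = rng.multivariate_hypergeometric(row, depth)
    return CountTable(
        sample_ids=list(table.sample_ids),
        otu_ids=list(table.otu_ids),
        counts=out,
        taxonomy=dict(table.taxonomy) if table.taxonomy else None,
        provenance=table.provenance + ("rarefy",),
    )


def duplicate_consistency(table: CountTable, metadata: TransectMetadata) -> CountTable:
    """Keep only duplicate-consistent detections.

    An OTU is flagged detected at a site iff its count is > 0 in *all*
    duplicates of that site; OTUs detected at no site are removed entirely.
    The flags are attached as ``table.site_detection`` (site x OTU booleans).
    Idempotent.
    """
    check_stage_order(table.provenance, "duplicate_consistency")
    by_site = metadata.samples_by_site()
    n_dups = {site: len(samps) for site, samps in by_site.items()}
    expected = max(n_dups.values())
    unpaired = [s for s, n in n_dups.items() if n != expected]
    if unpaired:
        raise ValidationError(
            f"sites without the full set of {expected} duplicates: {unpaired}"
        )
    missing = [
        s for samps in by_site.values() for s in samps if s not in table.sample_ids
    ]
    if missing:
        raise ValidationError(f"metadata samples absent from the count table: {missing}")

    frame = table.to_dataframe()
    detection = pd.DataFrame(
        {site: (frame.loc[samps] > 0).all(axis=0) for site, samps in by_site.items()}
    ).T
    detection = detection.loc[list(by_site)]
    keep = detection.any(axis=0).to_numpy()
    logger.info(
        "duplicate_consistency: %d of %d OTUs detected at >= 1 site",
        int(keep.sum()),
        table.n_otus,
    )
    result = table.select_otus(keep)
    result.site_detection = detection.loc[:, result.otu_ids]
    if "duplicate_consistency" not in result.provenance:
        result = result.with_stage("duplicate_consistency")
        result.site_detection = detection.loc[:, result.otu_ids]
    return result


def average_duplicates(table: CountTable, metadata: TransectMetadata) -> ProportionTable:
    """Average duplicate-level relative proportions per site.

    Requires :func:`duplicate_consistency` first (the detection flags must be
    fixed before averaging). Proportions of non-detected OTUs are retained as
    computed; detection is carried over unchanged.
    """
    if "duplicate_consistency" not in table.provenance or table.site_detection is None:
        from .errors import PipelineOrderError

        raise PipelineOrderError("average_duplicates requires duplicate_consistency first")
    check_stage_order(table.provenance, "average_duplicates")
    frame = table.to_dataframe()
    totals = frame.sum(axis=1)
    empty = totals[totals == 0].index.tolist()
    if empty:
        raise ValidationError(f"zero-total duplicate sample(s): {empty}")
    rel = frame.div(totals, axis=0)
    by_site = metadata.samples_by_site()
    site_ids = list(by_site)
    props = np.vstack([rel.loc[samps].mean(axis=0).to_numpy() for samps in by_site.values()])
    detected = table.site_detection.loc[site_ids, table.otu_ids].to_numpy()
    # detection implies presence in every duplicate, hence a positive mean
    return ProportionTable(
        site_ids=site_ids,
        otu_ids=list(table.otu_ids),
        proportions=props,
        detected=detected,
        otu_totals=frame.sum(axis=0).to_numpy(float),
        provenance=table.provenance + ("average_duplicates",),
    )


def abundance_subset(table, threshold_fraction: float):
    """Keep OTUs holding at least ``threshold_fraction`` of all sequences.

    Works on a :class:`CountTable` (totals from counts) or a
    :class:`ProportionTable` (totals from the attached pre-averaging
    ``otu_totals``). 16S and 18S tables are expected to be subset
    independently, each against its own grand total.
    """
    if not 0 < threshold_fraction < 1:
        raise ValidationError("threshold_fraction must lie in (0, 1)")
    check_stage_order(table.provenance, "abundance_subset")
    if isinstance(table, CountTable):
        totals = table.counts.sum(axis=0).astype(float)
    else:
        totals = np.asarray(table.otu_totals, dtype=float)
    grand = totals.sum()
    if grand <= 0:
        raise ValidationError("cannot subset a table with zero total counts")
    keep = totals >= threshold_fraction * grand
    out = table.select_otus(keep)
    out.provenance = table.provenance + ("abundance_subset",)
    return out
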