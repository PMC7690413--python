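"""Convenience wrapper chaining the standard preprocessing pipeline."""

from __future__ import annotations

from .preprocess import (
    abundance_subset,
    average_duplicates,
    duplicate_consistency,
    filter_taxa,
    rarefy,
)
from .tables import CountTable, ProportionTable, TransectMetadata

DEFAULT_EXCLUDE_16S = ("Eukaryota", "Archaea", "Chloroplast")
DEFAULT_EXCLUDE_18S = ("Bacteria", "Archaea", "Metazoa")


def preprocess_pipeline(
    table: CountTable,
    metadata: TransectMetadata,
    exclude: tuple[str, ...] = DEFAULT_EXCLUDE_16S,
    depth: int | str = "min",
    seed: int = 0,
    subset: float | None = None,
) -> ProportionTable:
    """filter_taxa -> rarefy -> duplicate_consistency -> average_duplicates
    (-> abundance_subset when ``subset`` is given)."""
    out = filter_taxa(table, list(exclude))
    out = rarefy(out, depth=depth, seed=seed)
    out = duplicate_consistency(out, metadata)
    props = average_duplicates(out, metadata)
    if subset is not None:
        props = abundance_subset(props, subset)
    return props
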