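import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import riverdrift as rd

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture()
def small_table() -> rd.CountTable:
    """2 sites x 2 duplicates, 3 OTUs, with taxonomy."""
    return rd.CountTable(
        sample_ids=["L_a", "L_b", "R1_a", "R1_b"],
        otu_ids=["o1", "o2", "o3"],
        counts=np.array([[50, 30, 20], [55, 25, 20], [10, 60, 30], [12, 58, 30]]),
        taxonomy={
            "o1": "Bacteria;Cyanobacteria;Chloroplast",
            "o2": "Bacteria;Bacteroidetes;Pseudarcicella",
            "o3": "Bacteria;Actinobacteria;hgcI_clade",
        },
    )


@pytest.fixture()
def small_metadata() -> rd.TransectMetadata:
    return rd.TransectMetadata(
        samples=pd.DataFrame(
            {
                "sample_id": ["L_a", "L_b", "R1_a", "R1_b"],
                "site_id": ["L", "L", "R1", "R1"],
                "site_type": ["lake", "lake", "river", "river"],
                "distance_m": [0.0, 0.0, 48.0, 48.0],
                "duplicate_label": ["a", "b", "a", "b"],
            }
        )
    )


def make_metadata(river_distances, tributaries=(), n_dups=2) -> rd.TransectMetadata:
    """Metadata factory for synthetic fixtures (lake + rivers + tributaries)."""
    rows = []
    labels = [chr(ord("a") + i) for i in range(n_dups)]

    def add(site, stype, dist):
        for lab in labels:
            rows.append(
                {
                    "sample_id": f"{site}_{lab}",
                    "site_id": site,
                    "site_type": stype,
                    "distance_m": dist,
                    "duplicate_label": lab,
                }
            )

    add("Lake", "lake", 0.0)
    for i, d in enumerate(river_distances):
        add(f"R{i + 1:02d}", "river", float(d))
    for name, d in tributaries:
        add(name, "tributary", float(d))
    return rd.TransectMetadata(samples=pd.DataFrame(rows))


@pytest.fixture(scope="session")
def default_run():
    """One full simulated transect at study scale, preprocessed both ways."""
    design = rd.with_seed(rd.default_design(), 20170)
    table, metadata, truth = rd.simulate_counts(design)
    props = rd.preprocess_pipeline(table, metadata, seed=20170)
    subset = rd.abundance_subset(props, 0.001)
    return {
        "design": design,
        "table": table,
        "metadata": metadata,
        "truth": truth,
        "props": props,
        "subset": subset,
    }
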