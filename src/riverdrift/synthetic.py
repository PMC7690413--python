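"""Synthetic lake-to-river transect generator with full ground truth.

The generator emulates a ~11 km meandering-river transect fed by one lake
and several tributaries, sampled in duplicate at a fixed sequencing depth.
Each OTU follows one of five archetypes along the main stem:

``lake_decaying``   unnormalized mass p0 * exp(-lambda * d) (d in km);
``river_rising``    logistic in distance, rise_max / (1 + exp(-k (d - d0)));
``stable``          constant lake proportion;
``tributary_seeded``absent upstream, injected at a confluence;
``rare_intermittent`` small constant mass, toggled on/off per site by an
                    occupancy probability (the rare biosphere).

At a confluence with flow fraction f, every downstream mass is
(1 - f) * upstream + f * tributary. A bulk "filler" OTU absorbs whatever
mass the named archetypes do not carry, so each site's expected proportions
form an exact probability vector. Sequencing noise is a multinomial draw of
the site's proportions at fixed depth, one independent draw per duplicate
(optionally Dirichlet-multinomial for overdispersion, off by default).

Ground-truth trajectory / trend / origin labels are a function of the
design only, never of a realized sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ValidationError
from .tables import CountTable, TransectMetadata
from .trajectory import UNSTABLE, classify_series

ARCHETYPES = (
    "lake_decaying",
    "river_rising",
    "stable",
    "tributary_seeded",
    "rare_intermittent",
)

#: lake bulk OTU absorbing residual mass along the main stem
BULK_OTU = "OTU_bulk"

# relative range of the mean model below which a trend is called flat
FLAT_TOLERANCE = 0.02


@dataclass(frozen=True)
class OtuSpec:
    """Mean-model parameters for one simulated OTU."""

    otu_id: str
    archetype: str
    lake_proportion: float = 0.0
    decay_per_km: float = 0.0
    rise_max: float = 0.0
    rise_midpoint_km: float = 0.0
    rise_rate_per_km: float = 0.0
    tributary: str | None = None
    tributary_proportion: float = 0.0
    occupancy: float = 1.0
    taxonomy: str | None = None

    def __post_init__(self) -> None:
        if self.archetype not in ARCHETYPES:
            raise ValidationError(f"unknown archetype {self.archetype!r}")
        for name in ("lake_proportion", "rise_max", "tributary_proportion", "occupancy"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{self.otu_id}: {name} must lie in [0, 1], got {v}")
        if self.decay_per_km < 0:
            raise ValidationError(f"{self.otu_id}: decay rate must be >= 0")
        if self.archetype == "tributary_seeded" and not self.tributary:
            raise ValidationError(f"{self.otu_id}: tributary_seeded needs a source tributary")


@dataclass(frozen=True)
class Tributary:
    name: str
    confluence_m: float
    flow_fraction: float = 0.1

    def __post_init__(self) -> None:
        if not 0 <= self.flow_fraction < 1:
            raise ValidationError(f"{self.name}: flow fraction must lie in [0, 1)")
        if self.confluence_m <= 0:
            raise ValidationError(f"{self.name}: confluence must be downstream of the lake")


@dataclass(frozen=True)
class EnvGradient:
    """Linear-in-distance environmental parameter with Gaussian noise."""

    name: str
    lake_value: float
    terminal_value: float
    tributary_value: float
    noise_sd: float


DEFAULT_ENV_GRADIENTS = (
    EnvGradient("temperature_c", 15.0, 12.0, 9.2, 0.15),
    EnvGradient("toc_mg_per_l", 4.36, 3.63, 3.2, 0.05),
    EnvGradient("turbidity_ntu", 1.24, 2.14, 3.7, 0.05),
    EnvGradient("total_nitrogen_mg_per_l", 0.206, 0.456, 0.6, 0.01),
    EnvGradient("no3_no2_mg_per_l", 0.01, 0.24, 0.43, 0.005),
    EnvGradient("conductivity_umhos_per_cm", 86.2, 159.0, 207.5, 2.0),
    EnvGradient("alkalinity_mg_per_l_caco3", 18.1, 33.8, 43.9, 0.5),
    EnvGradient("apparent_color_ptco", 23.0, 27.0, 38.0, 0.4),
    EnvGradient("ph", 7.4, 7.4, 7.6, 0.05),
    EnvGradient("total_phosphorus_ug_per_l", 11.0, 11.0, 13.0, 1.2),
)

#: default river sampling distances (m); 48 m first site, 11 km terminal site
DEFAULT_RIVER_DISTANCES_M = (
    48, 350, 700, 1000, 1400, 1800, 2400, 3000, 3700, 4400,
    5200, 6000, 6800, 7500, 8200, 8900, 9500, 9800, 9900, 11000,
)

DEFAULT_TRIBUTARIES = (
    Tributary("Jaune", 1200.0, 0.1),
    Tributary("EauxFraiches", 7000.0, 0.1),
    Tributary("Nelson", 10000.0, 0.1),
    Tributary("Golf", 10950.0, 0.1),
)


@dataclass(frozen=True)
class TransectDesign:
    """Full parameterization of one synthetic transect."""

    river_distances_m: tuple[float, ...] = DEFAULT_RIVER_DISTANCES_M
    tributaries: tuple[Tributary, ...] = DEFAULT_TRIBUTARIES
    otus: tuple[OtuSpec, ...] = ()
    depth: int = 36180
    n_duplicates: int = 2
    seed: int = 0
    env_gradients: tuple[EnvGradient, ...] = DEFAULT_ENV_GRADIENTS
    qpcr_mean: float = 5.4e5
    qpcr_sd: float = 1.4e5
    overdispersion: float | None = None  # Dirichlet concentration scale; None = pure multinomial

    def __post_init__(self) -> None:
        d = np.asarray(self.river_distances_m, dtype=float)
        if d.size < 3 or (np.diff(d) <= 0).any() or (d <= 0).any():
            raise ValidationError("river distances must be > 0 and strictly increasing")
        if self.depth < 1:
            raise ValidationError("depth must be >= 1")
        if self.n_duplicates < 1:
            raise ValidationError("n_duplicates must be >= 1")
        ids = [s.otu_id for s in self.otus]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate otu_id in design")
        names = [t.name for t in self.tributaries]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate tributary names")
        lake_total = sum(
            s.lake_proportion
            for s in self.otus
            if s.archetype in ("lake_decaying", "stable", "rare_intermittent")
        )
        if lake_total > 1 + 1e-9:
            raise ValidationError(f"lake archetype proportions sum to {lake_total:.3f} > 1")
        for trib in self.tributaries:
            seeded = sum(
                s.tributary_proportion
                for s in self.otus
                if s.archetype == "tributary_seeded" and s.tributary == trib.name
            )
            if seeded > 1 + 1e-9:
                raise ValidationError(f"tributary {trib.name}: seeded proportions sum > 1")
        unknown = {
            s.tributary
            for s in self.otus
            if s.archetype == "tributary_seeded" and s.tributary not in set(names)
        }
        if unknown:
            raise ValidationError(f"seeded OTUs reference unknown tributaries: {sorted(unknown)}")

    # -- identifiers -----------------------------------------------------------

    @property
    def n_river_sites(self) -> int:
        return len(self.river_distances_m)

    def tributary_bulk_id(self, name: str) -> str:
        return f"{BULK_OTU}_{name}"

    @property
    def otu_ids(self) -> list[str]:
        """Declared OTUs, then the lake bulk, then one bulk per tributary."""
        return (
            [s.otu_id for s in self.otus]
            + [BULK_OTU]
            + [self.tributary_bulk_id(t.name) for t in self.tributaries]
        )

    @property
    def site_ids(self) -> list[str]:
        rivers = [f"R{i + 1:02d}" for i in range(self.n_river_sites)]
        return ["Lake", *rivers, *[t.name for t in self.tributaries]]

    def site_distance(self, index: int) -> float:
        n = self.n_river_sites
        if index == 0:
            return 0.0
        if 1 <= index <= n:
            return float(self.river_distances_m[index - 1])
        return float(self.tributaries[index - n - 1].confluence_m)

    def site_type(self, index: int) -> str:
        if index == 0:
            return "lake"
        if index <= self.n_river_sites:
            return "river"
        return "tributary"


# ---------------------------------------------------------------------------
# mean model
# ---------------------------------------------------------------------------

def _dilution(design: TransectDesign, d_m: float) -> float:
    out = 1.0
    for trib in design.tributaries:
        if trib.confluence_m <= d_m:
            out *= 1.0 - trib.flow_fraction
    return out


def _tributary_vector(design: TransectDesign, trib: Tributary) -> np.ndarray:
    """Expected proportions inside one tributary's own community."""
    ids = design.otu_ids
    index = {o: i for i, o in enumerate(ids)}
    vec = np.zeros(len(ids))
    seeded = 0.0
    for spec in design.otus:
        if spec.archetype == "tributary_seeded" and spec.tributary == trib.name:
            vec[index[spec.otu_id]] = spec.tributary_proportion
            seeded += spec.tributary_proportion
    vec[index[design.tributary_bulk_id(trib.name)]] = 1.0 - seeded
    return vec


def _mainstem_vector(design: TransectDesign, d_m: float) -> np.ndarray:
    """Expected proportions of the lake (d=0) or a river site at d_m meters."""
    ids = design.otu_ids
    index = {o: i for i, o in enumerate(ids)}
    d_km = d_m / 1000.0
    dil = _dilution(design, d_m)
    vec = np.zeros(len(ids))
    for spec in design.otus:
        i = index[spec.otu_id]
        if spec.archetype == "lake_decaying":
            vec[i] = spec.lake_proportion * math.exp(-spec.decay_per_km * d_km) * dil
        elif spec.archetype in ("stable", "rare_intermittent"):
            vec[i] = spec.lake_proportion * dil
        elif spec.archetype == "river_rising":
            z = spec.rise_rate_per_km * (d_km - spec.rise_midpoint_km)
            vec[i] = spec.rise_max / (1.0 + math.exp(-z)) * dil
        elif spec.archetype == "tributary_seeded":
            trib = next(t for t in design.tributaries if t.name == spec.tributary)
            if trib.confluence_m <= d_m:
                vec[i] = (
                    trib.flow_fraction
                    * spec.tributary_proportion
                    * dil
                    / _dilution(design, trib.confluence_m)
                )
    # tributary bulk communities mixed in at their confluences
    for trib in design.tributaries:
        if trib.confluence_m <= d_m:
            seeded = sum(
                s.tributary_proportion
                for s in design.otus
                if s.archetype == "tributary_seeded" and s.tributary == trib.name
            )
            vec[index[design.tributary_bulk_id(trib.name)]] = (
                trib.flow_fraction * (1.0 - seeded) * dil / _dilution(design, trib.confluence_m)
            )
    residual = 1.0 - vec.sum()
    if residual < -1e-9:
        raise ValidationError("design over-allocates mass; no room for the bulk OTU")
    vec[index[BULK_OTU]] = max(residual, 0.0)
    return vec


def expected_proportions(design: TransectDesign, site_index: int) -> np.ndarray:
    """Deterministic mean proportions at one site (see :attr:`TransectDesign.site_ids`).

    Index 0 is the lake, 1..n the river sites downstream, then the
    tributaries. The result is a probability vector (sums to 1 within 1e-12)
    over :attr:`TransectDesign.otu_ids`.
    """
    n_sites = 1 + design.n_river_sites + len(design.tributaries)
    if not 0 <= site_index < n_sites:
        raise ValidationError(f"site_index {site_index} out of range [0, {n_sites})")
    if site_index <= design.n_river_sites:
        vec = _mainstem_vector(design, design.site_distance(site_index))
    else:
        vec = _tributary_vector(design, design.tributaries[site_index - design.n_river_sites - 1])
    total = vec.sum()
    if abs(total - 1.0) > 1e-12:
        vec = vec / total
    return vec


def expected_matrix(design: TransectDesign) -> pd.DataFrame:
    """Expected proportions for every site (rows) and OTU (columns)."""
    rows = [
        expected_proportions(design, i)
        for i in range(1 + design.n_river_sites + len(design.tributaries))
    ]
    return pd.DataFrame(np.vstack(rows), index=design.site_ids, columns=design.otu_ids)


def expected_bray_curtis_to_lake(design: TransectDesign) -> pd.Series:
    """Mean-model Bray-Curtis between the lake and each river site."""
    from .community import bray_curtis

    mat = expected_matrix(design)
    lake = mat.iloc[0].to_numpy()
    values = [
        bray_curtis(lake, mat.iloc[i].to_numpy())
        for i in range(1, design.n_river_sites + 1)
    ]
    return pd.Series(values, index=np.asarray(design.river_distances_m, float), name="bray_curtis")


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """True trajectory / trend / origin label per OTU, from the design alone."""

    labels: pd.DataFrame
    detection_threshold: float

    def trajectory(self, otu_id: str) -> str:
        return self.labels.loc[otu_id, "trajectory"]


def _trend_sign(series: np.ndarray) -> str:
    lo, hi = series.min(), series.max()
    scale = max(series.mean(), 1e-300)
    if (hi - lo) / scale < FLAT_TOLERANCE:
        return "0"
    slope = np.polyfit(np.arange(series.size, dtype=float), series, 1)[0]
    if slope < 0:
        return "-"
    return "+" if slope > 0 else "0"


def ground_truth_labels(design: TransectDesign, detection_threshold: float = 1.0) -> GroundTruth:
    """Design-level labels: trajectory class, trend sign, terminal-site origin.

    The trajectory label applies the trajectory classifier to the *expected*
    detection pattern (expected count = depth * mean proportion, detected iff
    >= ``detection_threshold`` reads) over [lake, river sites]. OTUs with an
    intermittent occupancy (0 < occupancy < 1) are unstable by construction.
    The trend sign is the sign of the mean-model slope over river sites, with
    a small relative-range tolerance for flatness. Origin is attributed from
    the expected pattern at the terminal site, the lake, and each tributary's
    own community.
    """
    if detection_threshold < 1:
        raise ValidationError("detection threshold must be >= 1 read")
    mat = expected_matrix(design)
    n = design.n_river_sites
    main = mat.iloc[: n + 1]  # lake + river
    expected_counts = main.to_numpy() * design.depth
    pattern = expected_counts >= detection_threshold
    trib_vectors = {
        t.name: _tributary_vector(design, t) * design.depth for t in design.tributaries
    }
    specs = {s.otu_id: s for s in design.otus}
    trib_conf = {t.name: t.confluence_m for t in design.tributaries}
    ids = design.otu_ids
    otu_pos = {o: i for i, o in enumerate(ids)}

    rows = []
    for otu in ids:
        j = otu_pos[otu]
        spec = specs.get(otu)
        if spec is not None and spec.archetype == "rare_intermittent" and 0 < spec.occupancy < 1:
            archetype, trajectory, trend = "rare_intermittent", UNSTABLE, "0"
        else:
            if spec is not None:
                archetype = spec.archetype
            elif otu == BULK_OTU:
                archetype = "bulk"
            else:
                archetype = "tributary_bulk"
            trajectory = classify_series(pattern[:, j])
            trend = _trend_sign(main.iloc[1:, j].to_numpy())
        confluence = math.nan
        if spec is not None and spec.archetype == "tributary_seeded":
            confluence = trib_conf[spec.tributary]
        elif otu.startswith(BULK_OTU + "_"):
            confluence = trib_conf[otu[len(BULK_OTU) + 1 :]]
        if pattern[-1, j]:
            in_lake = bool(pattern[0, j])
            in_trib = any(
                vec[j] >= detection_threshold for vec in trib_vectors.values()
            )
            if in_lake and in_trib:
                origin = "lake_and_tributaries"
            elif in_trib:
                origin = "tributaries_only"
            elif in_lake:
                origin = "lake_only"
            else:
                origin = "neither"
        else:
            origin = None
        rows.append((otu, archetype, trajectory, trend, origin, confluence))
    labels = pd.DataFrame(
        rows,
        columns=["otu_id", "archetype", "trajectory", "trend", "origin", "confluence_m"],
    ).set_index("otu_id")
    return GroundTruth(labels=labels, detection_threshold=detection_threshold)


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def simulate_counts(design: TransectDesign) -> tuple[CountTable, TransectMetadata, GroundTruth]:
    """Draw one replicated transect dataset from the design.

    Each duplicate is an independent multinomial draw of size ``depth`` from
    the site's expected proportions; rare OTUs are first toggled per site by
    their occupancy probability (the removed mass goes to the bulk OTU, so
    every other OTU keeps its exact mean-model proportion). Environmental
    parameters are linear-in-distance with Gaussian noise; qPCR totals
    fluctuate around a constant with no distance trend. Identical seeds give
    identical output.
    """
    rng = np.random.default_rng(design.seed)
    ids = design.otu_ids
    otu_pos = {o: i for i, o in enumerate(ids)}
    bulk_i = otu_pos[BULK_OTU]
    rare = [
        (otu_pos[s.otu_id], s.occupancy)
        for s in design.otus
        if s.archetype == "rare_intermittent"
    ]
    n_sites = 1 + design.n_river_sites + len(design.tributaries)

    sample_ids: list[str] = []
    sample_rows: list[dict] = []
    count_rows: list[np.ndarray] = []
    for si in range(n_sites):
        site_id = design.site_ids[si]
        p = expected_proportions(design, si).copy()
        if design.site_type(si) != "tributary":
            for j, occ in rare:
                if p[j] > 0 and rng.random() >= occ:
                    p[bulk_i] += p[j]
                    p[j] = 0.0
        p = np.clip(p, 0.0, None)
        p /= p.sum()
        for dup in range(design.n_duplicates):
            if design.overdispersion:
                alive = p > 0
                draw = np.zeros_like(p)
                draw[alive] = rng.dirichlet(p[alive] * design.overdispersion)
                counts = rng.multinomial(design.depth, draw)
            else:
                counts = rng.multinomial(design.depth, p)
            label = chr(ord("a") + dup)
            sample_ids.append(f"{site_id}_{label}")
            sample_rows.append(
                {
                    "sample_id": f"{site_id}_{label}",
                    "site_id": site_id,
                    "site_type": design.site_type(si),
                    "distance_m": design.site_distance(si),
                    "duplicate_label": label,
                }
            )
            count_rows.append(counts)

    taxonomy = {s.otu_id: s.taxonomy for s in design.otus if s.taxonomy}
    table = CountTable(
        sample_ids=sample_ids,
        otu_ids=ids,
        counts=np.vstack(count_rows),
        taxonomy=taxonomy or None,
    )

    d_max = float(design.river_distances_m[-1])
    env_rows = {}
    qpcr_rows = {}
    for si in range(n_sites):
        site_id = design.site_ids[si]
        vals = {}
        for g in design.env_gradients:
            if design.site_type(si) == "tributary":
                mean = g.tributary_value
            else:
                d = design.site_distance(si)
                mean = g.lake_value + (g.terminal_value - g.lake_value) * d / d_max
            vals[g.name] = mean + rng.normal(0.0, g.noise_sd)
        env_rows[site_id] = vals
        qpcr_rows[site_id] = {
            "copies_per_ml": max(rng.normal(design.qpcr_mean, design.qpcr_sd), 1e4),
            "sd": abs(rng.normal(design.qpcr_sd / 2, design.qpcr_sd / 10)),
        }
    metadata = TransectMetadata(
        samples=pd.DataFrame(sample_rows),
        env=pd.DataFrame(env_rows).T,
        qpcr=pd.DataFrame(qpcr_rows).T,
    )
    return table, metadata, ground_truth_labels(design)


# ---------------------------------------------------------------------------
# default designs at study scale
# ---------------------------------------------------------------------------

def _decay_rate(p0: float, depth: int, crossing_km: float) -> float:
    """Decay rate placing the 1-expected-read crossing at ``crossing_km``."""
    return math.log(p0 * depth) / crossing_km


def _rise_rate(p_max: float, depth: int, midpoint_km: float) -> float:
    """Logistic rate keeping the lake >= ~4 nats below one expected read."""
    return (math.log(100.0 * p_max * depth) + 1.5) / midpoint_km


_STABLE_16S_GENERA = (
    "Bacteria;Actinobacteria;Frankiales;Sporichthyaceae;hgcI_clade",
    "Bacteria;Proteobacteria;Betaproteobacteriales;Burkholderiaceae;Polynucleobacter",
    "Bacteria;Actinobacteria;Frankiales;Sporichthyaceae;Candidatus_Planktophila",
    "Bacteria;Bacteroidetes;Flavobacteriales;Crocinitomicaceae;Fluviicola",
    "Bacteria;Proteobacteria;Betaproteobacteriales;Methylophilaceae;Methylotenera",
    "Bacteria;Actinobacteria;Microtrichales;Ilumatobacteraceae;CL500-29",
    "Bacteria;Proteobacteria;Alphaproteobacteria;SAR11_clade;LD12",
    "Bacteria;Bacteroidetes;Chitinophagales;Chitinophagaceae;Sediminibacterium",
)

_DECAYING_16S = (
    "Bacteria;Cyanobacteria;Synechococcales;Cyanobiaceae;Cyanobium_PCC-6307",
    "Bacteria;Verrucomicrobia;Chthoniobacterales;Chthoniobacteraceae;FukuN18",
    "Bacteria;Verrucomicrobia;Verrucomicrobiales;Rubritaleaceae;Luteolibacter",
    "Bacteria;Proteobacteria;Betaproteobacteriales;Burkholderiaceae;Limnobacter",
    "Bacteria;Planctomycetes;Planctomycetales;Planctomycetaceae;Planctomyces",
    "Bacteria;Verrucomicrobia;Verrucomicrobiales;Verrucomicrobiaceae;Terrimicrobium",
)

_SLOW_DECAYING_16S = (
    "Bacteria;Verrucomicrobia;Methylacidiphilales;Unc_Methylacidiphilaceae",
    "Bacteria;Planctomycetes;Planctomycetales;Gemmataceae;Gemmata",
    "Bacteria;Cyanobacteria;Nostocales;Aphanizomenonaceae;Dolichospermum",
    "Bacteria;Proteobacteria;Betaproteobacteriales;Burkholderiaceae;Rhodoferax",
    "Bacteria;Actinobacteria;Frankiales;Sporichthyaceae;hgcI_clade_lake",
    "Bacteria;Planctomycetes;Pirellulales;Pirellulaceae;Pirellula",
    "Bacteria;Verrucomicrobia;Opitutales;Opitutaceae;Opitutus",
)

_CONTAMINANT_LINEAGES_16S = (
    "Eukaryota;Ochrophyta;Chrysophyceae;Unc_Chrysophyceae",
    "Archaea;Thaumarchaeota;Nitrososphaeria;Nitrosopumilales",
    "Bacteria;Cyanobacteria;Oxyphotobacteria;Chloroplast",
)


def default_design(domain: str = "bacteria", seed: int = 0, **overrides) -> TransectDesign:
    """Study-scale default design: 1 lake + 20 river sites + 4 tributaries.

    ``domain="bacteria"`` uses depth 36,180 (16S-like table); ``"eukaryote"``
    uses depth 10,075 (18S-like) with fewer, different archetypes. Decay and
    rise rates are placed by their detection-boundary crossings (see
    docs/methods.md) so trajectory classes are recoverable at these depths.
    """
    if domain == "bacteria":
        depth = overrides.pop("depth", 36180)
        otus = _bacteria_archetypes(depth)
    elif domain == "eukaryote":
        depth = overrides.pop("depth", 10075)
        otus = _eukaryote_archetypes(depth)
    else:
        raise ValidationError(f"unknown domain {domain!r}")
    return TransectDesign(otus=tuple(otus), depth=depth, seed=seed, **overrides)


def _geometric(lo: float, hi: float, n: int) -> list[float]:
    return [hi * (lo / hi) ** (i / (n - 1)) for i in range(n)]


def _bacteria_archetypes(depth: int) -> list[OtuSpec]:
    otus: list[OtuSpec] = []
    # fast decayers cross the 1-expected-read boundary inside the transect
    # (these become "lost"); slow decayers decline throughout but stay
    # detectable to the terminal site, spreading the drift over the full
    # 11 km so the Bray-Curtis increase is progressive, not front-loaded.
    decaying_p0 = (0.04, 0.025, 0.018, 0.012, 0.008, 0.006)
    crossings_km = (2.0, 2.8, 3.6, 4.4, 5.5, 6.8)
    for k, (p0, d_star, tax) in enumerate(zip(decaying_p0, crossings_km, _DECAYING_16S)):
        otus.append(
            OtuSpec(
                otu_id=f"OTU_dec{k + 1:02d}",
                archetype="lake_decaying",
                lake_proportion=p0,
                decay_per_km=_decay_rate(p0, depth, d_star),
                taxonomy=tax,
            )
        )
    slow = ((0.08, 0.05), (0.07, 0.07), (0.06, 0.09), (0.05, 0.12),
            (0.04, 0.16), (0.03, 0.22), (0.015, 0.3))
    for k, ((p0, lam), tax) in enumerate(zip(slow, _SLOW_DECAYING_16S)):
        otus.append(
            OtuSpec(
                otu_id=f"OTU_slo{k + 1:02d}",
                archetype="lake_decaying",
                lake_proportion=p0,
                decay_per_km=lam,
                taxonomy=tax,
            )
        )
    rising = (
        (0.06, 2.0, "Bacteria;Actinobacteria;Microbacteriaceae;Candidatus_Rhodoluna"),
        (0.03, 3.0, "Bacteria;Proteobacteria;Betaproteobacteriales;Limnohabitans"),
    )
    for k, (p_max, mid, tax) in enumerate(rising):
        otus.append(
            OtuSpec(
                otu_id=f"OTU_ris{k + 1:02d}",
                archetype="river_rising",
                rise_max=p_max,
                rise_midpoint_km=mid,
                rise_rate_per_km=_rise_rate(p_max, depth, mid),
                taxonomy=tax,
            )
        )
    seeded = (
        ("Jaune", 0.287, "Bacteria;Bacteroidetes;Cytophagales;Spirosomaceae;Pseudarcicella"),
        ("Jaune", 0.12, "Bacteria;Bacteroidetes;Flavobacteriales;Flavobacteriaceae;Flavobacterium"),
        ("Nelson", 0.15, "Bacteria;Bacteroidetes;Chitinophagales;Sediminibacterium_trib"),
    )
    for k, (trib, p, tax) in enumerate(seeded):
        otus.append(
            OtuSpec(
                otu_id=f"OTU_see{k + 1:02d}",
                archetype="tributary_seeded",
                tributary=trib,
                tributary_proportion=p,
                taxonomy=tax,
            )
        )
    for k, p0 in enumerate(_geometric(0.0015, 0.015, 55)):
        tax = _STABLE_16S_GENERA[k % len(_STABLE_16S_GENERA)]
        otus.append(
            OtuSpec(
                otu_id=f"OTU_sta{k + 1:02d}",
                archetype="stable",
                lake_proportion=p0,
                taxonomy=f"{tax}_{k + 1}",
            )
        )
    for k, tax in enumerate(_CONTAMINANT_LINEAGES_16S):
        otus.append(
            OtuSpec(
                otu_id=f"OTU_con{k + 1:02d}",
                archetype="stable",
                lake_proportion=2e-4,
                taxonomy=tax,
            )
        )
    for k in range(300):
        otus.append(
            OtuSpec(
                otu_id=f"OTU_rar{k + 1:03d}",
                archetype="rare_intermittent",
                lake_proportion=2e-5 * 4.0 ** (k / 299),
                occupancy=0.3 + 0.5 * (k % 7) / 6,
                taxonomy=f"Bacteria;rare_biosphere;clade_{k % 23}",
            )
        )
    return otus


_STABLE_18S_LINEAGES = (
    "Eukaryota;Hacrobia;Cryptophyceae;Cryptomonadales;Cryptomonas",
    "Eukaryota;Stramenopiles;Chrysophyceae;Ochromonadales;Spumella",
    "Eukaryota;Alveolata;Ciliophora;Oligotrichia;Strombidium",
    "Eukaryota;Stramenopiles;Chrysophyceae;Clade_D",
    "Eukaryota;Alveolata;Dinoflagellata;Gymnodiniaceae;Gymnodinium",
)


def _eukaryote_archetypes(depth: int) -> list[OtuSpec]:
    otus: list[OtuSpec] = [
        OtuSpec(
            otu_id="OTU_J",
            archetype="lake_decaying",
            lake_proportion=0.05,
            decay_per_km=_decay_rate(0.05, depth, 0.25),
            taxonomy="Eukaryota;Alveolata;Ciliophora;Peniculida;Unc_Ciliophora",
        )
    ]
    slow = ((0.05, 0.06), (0.04, 0.09), (0.03, 0.13), (0.02, 0.2), (0.01, 0.3))
    for k, (p0, lam) in enumerate(slow):
        otus.append(
            OtuSpec(
                otu_id=f"OTU_eslo{k + 1}",
                archetype="lake_decaying",
                lake_proportion=p0,
                decay_per_km=lam,
                taxonomy=f"Eukaryota;Hacrobia;Cryptophyceae;Cryptomonas_lake_{k + 1}",
            )
        )
    rising = [(0.01 + 0.004 * k, 0.5 + 0.1 * k) for k in range(7)]
    for k, (p_max, mid) in enumerate(rising):
        otus.append(
            OtuSpec(
                otu_id=f"OTU_eris{k + 1}",
                archetype="river_rising",
                rise_max=p_max,
                rise_midpoint_km=mid,
                rise_rate_per_km=_rise_rate(p_max, depth, mid),
                taxonomy=f"Eukaryota;Stramenopiles;Chrysophyceae;Clade_{chr(ord('D') + k)}",
            )
        )
    otus.append(
        OtuSpec(
            otu_id="OTU_A",
            archetype="tributary_seeded",
            tributary="Jaune",
            tributary_proportion=0.22,
            taxonomy="Eukaryota;Fungi;Ascomycota;Dothideomycetes;Unc_Dothideomycetes",
        )
    )
    otus.append(
        OtuSpec(
            otu_id="OTU_B",
            archetype="tributary_seeded",
            tributary="Nelson",
            tributary_proportion=0.15,
            taxonomy="Eukaryota;Rhizaria;Cercozoa;Novel_Clade_10",
        )
    )
    for k, p0 in enumerate(_geometric(0.004, 0.025, 30)):
        tax = _STABLE_18S_LINEAGES[k % len(_STABLE_18S_LINEAGES)]
        otus.append(
            OtuSpec(
                otu_id=f"OTU_esta{k + 1:02d}",
                archetype="stable",
                lake_proportion=p0,
                taxonomy=f"{tax}_{k + 1}",
            )
        )
    contaminants = (
        "Bacteria;Proteobacteria;Unclassified",
        "Archaea;Euryarchaeota;Unclassified",
        "Eukaryota;Opisthokonta;Metazoa;Arthropoda;Copepoda",
    )
    for k, tax in enumerate(contaminants):
        otus.append(
            OtuSpec(
                otu_id=f"OTU_econ{k + 1}",
                archetype="stable",
                lake_proportion=2e-4,
                taxonomy=tax,
            )
        )
    for k in range(200):
        otus.append(
            OtuSpec(
                otu_id=f"OTU_erar{k + 1:03d}",
                archetype="rare_intermittent",
                lake_proportion=2e-5 * 4.0 ** (k / 199),
                occupancy=0.3 + 0.5 * (k % 7) / 6,
                taxonomy=f"Eukaryota;rare_biosphere;clade_{k % 17}",
            )
        )
    return otus


def with_seed(design: TransectDesign, seed: int) -> TransectDesign:
    """Same design, different random seed."""
    return replace(design, seed=seed)
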