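"""Seeded synthetic river-microbiome datasets with planted lagged indicators.

The generator emulates a large-river monitoring survey: stations ordered
along the river from source to mouth, sampled on three lateral transects
(left, center, right), with smooth environmental gradients, a compositional
16S community, and a discrete biological status class that is driven —
exactly, when the response noise is zero — by the windowed-standardized,
lagged abundance series of a small set of planted indicator ASVs. Planted
indicators come in redundancy groups of near-identical clones so that the
downstream co-exclusion analysis has a known ground truth.

The latent response is computed from the *realized* (sampled, Hellinger-
transformed) abundances with the same feature construction the screening
module searches over, which makes indicator recovery well-posed: at zero
response noise the status class is an exact deterministic function of the
planted indicators' lagged transformed values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import RANKS, Dataset, hellinger_transform
from .screening import LagSpec, base_design, lagged_design_matrix

__all__ = [
    "GradientSpec",
    "RiverDesign",
    "PlantedSignal",
    "default_signal",
    "simulate_river",
    "simulate_community",
    "latent_response",
    "simulate_dataset",
    "write_fixture",
]

TRANSECTS = ("left", "center", "right")


@dataclass(frozen=True)
class GradientSpec:
    """Monotone linear trend for one environmental variable.

    ``value(t) = start + (end - start) * t + N(0, noise_sd)`` where t runs
    0 -> 1 from source to mouth.
    """

    start: float
    end: float
    noise_sd: float = 0.0

    def trend(self, t: np.ndarray) -> np.ndarray:
        return self.start + (self.end - self.start) * np.asarray(t, float)


def _default_gradients() -> dict[str, GradientSpec]:
    # Magnitudes chosen to look like a long temperate lowland river in
    # summer: slightly alkaline water cooling the gradient of pH, falling
    # conductivity and nutrients downstream (dilution), warming water,
    # rising chlorophyll a, declining DOC, declining fecal indicators
    # (log10(x+1) scale, as delivered by monitoring programs).
    return {
        "pH": GradientSpec(8.35, 7.90, 0.05),
        "conductivity": GradientSpec(470.0, 340.0, 12.0),
        "water_temp": GradientSpec(11.0, 22.5, 0.6),
        "Ntot": GradientSpec(3.2, 1.4, 0.15),
        "chl_a": GradientSpec(0.4, 6.2, 0.25),
        "DOC": GradientSpec(3.6, 2.4, 0.12),
        "log_total_coliforms": GradientSpec(4.2, 2.8, 0.2),
        "log_e_coli": GradientSpec(3.5, 2.2, 0.2),
    }


@dataclass
class RiverDesign:
    """Geometry and environment of the synthetic river survey."""

    n_stations: int = 60
    transects: tuple[str, ...] = TRANSECTS
    distance_to_mouth: np.ndarray | None = None  # km, strictly decreasing
    gradients: dict[str, GradientSpec] = field(default_factory=_default_gradients)
    #: latent-scale cut points separating consecutive status classes; the
    #: defaults sit in the gaps between the latent levels the default
    #: planted signal produces, so classes are well separated
    class_cutpoints: tuple[float, ...] = (-1.05, 0.85)
    #: if set, cut points are taken at these quantiles of the latent instead
    class_quantiles: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_stations < 10:
            raise ValueError("n_stations must be >= 10")
        if self.distance_to_mouth is None:
            self.distance_to_mouth = np.linspace(2600.0, 15.0, self.n_stations)
        self.distance_to_mouth = np.asarray(self.distance_to_mouth, float)
        if len(self.distance_to_mouth) != self.n_stations:
            raise ValueError("distance_to_mouth length != n_stations")
        if (self.distance_to_mouth <= 0).any():
            raise ValueError("distance_to_mouth must be strictly positive")
        if not (np.diff(self.distance_to_mouth) < 0).all():
            raise ValueError(
                "distance_to_mouth must be strictly decreasing downstream"
            )

    @property
    def class_labels(self) -> list[str]:
        n = (len(self.class_quantiles) if self.class_quantiles is not None
             else len(self.class_cutpoints)) + 1
        roman = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII"]
        return roman[:n]


@dataclass
class PlantedSignal:
    """Ground-truth indicator structure planted into the community.

    Each redundancy group is a tuple of taxon ids; the first member is the
    group parent whose spatial profile is generated, the rest are clones
    (parent intensity times log-normal jitter). One lag, window and effect
    weight applies per group: the latent response is the weighted sum of the
    groups' windowed-standardized lagged (Hellinger) series, z-scored per
    group, plus Gaussian noise with sd *noise_sd*.

    ``switch_fractions`` gives, per group, the river-length fractions at
    which the parent's abundance switches between its low and high regime
    (profiles start in the high regime at the source).
    """

    redundancy_groups: tuple[tuple[str, ...], ...] = (
        ("ASV_ind_a1", "ASV_ind_a2"),
        ("ASV_ind_b1", "ASV_ind_b2"),
    )
    true_lag: tuple[int, ...] = (2, 1)
    true_window: tuple[int, ...] = (1, 1)
    effect_weights: tuple[float, ...] = (1.0, 0.5)
    switch_fractions: tuple[tuple[float, ...], ...] = (
        (0.30, 0.70, 0.90),
        (0.15, 0.50, 0.85, 0.95),
    )
    #: high-regime over low-regime intensity ratio of indicator profiles
    high_low_ratio: float = 20.0
    #: sd of the log-normal multiplicative jitter applied to clones
    clone_jitter_sd: float = 0.05
    #: number of background taxa whose intensities shift weakly with the
    #: indicator regimes (a regime shift moves the whole community, which is
    #: what makes real bioindicators part of detectable community structure)
    n_coupled_taxa: int = 30
    #: sd of the log-intensity shift of coupled background taxa
    coupling_sd: float = 0.5
    #: sd of the Gaussian noise on the latent response
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        n = len(self.redundancy_groups)
        for name in ("true_lag", "true_window", "effect_weights",
                     "switch_fractions"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} must have one entry per group")
        if any(l < 0 for l in self.true_lag):
            raise ValueError("lags must be >= 0")
        if any(w < 1 for w in self.true_window):
            raise ValueError("windows must be >= 1")
        ids = self.indicator_ids
        if len(set(ids)) != len(ids):
            raise ValueError("indicator ids must be unique")

    @property
    def indicator_ids(self) -> tuple[str, ...]:
        return tuple(t for g in self.redundancy_groups for t in g)

    @property
    def parents(self) -> tuple[str, ...]:
        return tuple(g[0] for g in self.redundancy_groups)

    def lag_specs(self) -> list[LagSpec]:
        """The ground-truth feature spec of each group parent."""
        return [
            LagSpec(g[0], window=w, lag=l)
            for g, w, l in zip(self.redundancy_groups, self.true_window,
                               self.true_lag)
        ]


def default_signal(noise_sd: float = 0.0) -> PlantedSignal:
    """Two complementary indicator groups (lags 2 and 1), two clones each."""
    return PlantedSignal(noise_sd=noise_sd)


# ---------------------------------------------------------------------------
# metadata
# ---------------------------------------------------------------------------

def _bin_latent(latent: np.ndarray, design: RiverDesign) -> pd.Categorical:
    if design.class_quantiles is not None:
        cuts = np.quantile(latent, design.class_quantiles)
    else:
        cuts = np.asarray(design.class_cutpoints, float)
    codes = np.digitize(latent, cuts)
    labels = design.class_labels
    return pd.Categorical.from_codes(codes, categories=labels, ordered=True)


def simulate_river(design: RiverDesign, seed: int = 0) -> pd.DataFrame:
    """Environmental metadata for every (station, transect).

    Environmental variables follow the design's linear trends plus seeded
    Gaussian noise, independently per transect. The standalone latent
    saprobity is the z-scored chlorophyll *a* column (the eutrophication
    proxy), binned by the design's cut points into the status class; when a
    community with planted indicators is simulated on top
    (:func:`simulate_dataset`), the status class is recomputed from the
    indicators instead.
    """
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, 1.0, design.n_stations)
    rows = []
    for transect in design.transects:
        frame = pd.DataFrame(
            {
                "transect": transect,
                "station": np.arange(design.n_stations),
                "distance_to_mouth": design.distance_to_mouth,
            },
            index=[f"{transect[0].upper()}{s:03d}"
                   for s in range(design.n_stations)],
        )
        for name, g in design.gradients.items():
            frame[name] = g.trend(t) + rng.normal(0.0, g.noise_sd,
                                                  design.n_stations)
        rows.append(frame)
    meta = pd.concat(rows)
    meta.index.name = "sample_id"
    chl = meta["chl_a"].to_numpy(float)
    sd = chl.std(ddof=0)
    latent = (chl - chl.mean()) / (sd if sd > 0 else 1.0)
    meta["latent_saprobity"] = latent
    meta["status_class"] = _bin_latent(latent, design)
    return meta


# ---------------------------------------------------------------------------
# community
# ---------------------------------------------------------------------------

_NOISE_LINEAGES = [
    # (Phylum, Class, Order, Family, Genus) pools the noise taxa cycle over
    ("Actinobacteriota", "Actinobacteria", "Frankiales", "Sporichthyaceae", "hgcI_clade"),
    ("Actinobacteriota", "Acidimicrobiia", "Microtrichales", "Ilumatobacteraceae", "CL500-29_marine_group"),
    ("Proteobacteria", "Gammaproteobacteria", "Burkholderiales", "Comamonadaceae", "Limnohabitans"),
    ("Proteobacteria", "Alphaproteobacteria", "Sphingomonadales", "Sphingomonadaceae", "Sphingomonas"),
    ("Bacteroidota", "Bacteroidia", "Chitinophagales", "Chitinophagaceae", "Sediminibacterium"),
    ("Verrucomicrobiota", "Verrucomicrobiae", "Methylacidiphilales", "Methylacidiphilaceae", "LD19"),
    ("Cyanobacteria", "Cyanobacteriia", "Synechococcales", "Cyanobiaceae", "Cyanobium_PCC-6307"),
    ("Planctomycetota", "Planctomycetes", "Pirellulales", "Pirellulaceae", "Pirellula"),
]

_INDICATOR_LINEAGES = [
    ("Bacteroidota", "Bacteroidia", "Flavobacteriales", "Crocinitomicaceae", "Fluviicola"),
    ("Proteobacteria", "Gammaproteobacteria", "Pseudomonadales", "Moraxellaceae", "Acinetobacter"),
    ("Bacteroidota", "Bacteroidia", "Flavobacteriales", "Flavobacteriaceae", "Flavobacterium"),
    ("Actinobacteriota", "Actinobacteria", "Micrococcales", "Microbacteriaceae", "Rhodoluna"),
]


def _indicator_profile(n: int, fractions: tuple[float, ...],
                       offset: int = 0) -> np.ndarray:
    """High/low regime profile over stations: 1 in the high regime, 0 in the
    low; regimes alternate at the given river-length fractions (shifted by
    *offset* stations), starting high at the source."""
    switches = np.floor(np.asarray(fractions, float) * n).astype(int) + offset
    switches = np.clip(switches, 1, n - 1)
    prof = np.zeros(n)
    state, prev = 1.0, 0
    for s in list(switches) + [n]:
        prof[prev:s] = state
        state = 1.0 - state
        prev = s
    return prof


def _taxonomy_frame(signal: PlantedSignal, noise_ids: list[str]) -> pd.DataFrame:
    rows = {}
    for gi, group in enumerate(signal.redundancy_groups):
        lineage = _INDICATOR_LINEAGES[gi % len(_INDICATOR_LINEAGES)]
        for member in group:
            rows[member] = ("Bacteria",) + lineage
    for j, tid in enumerate(noise_ids):
        lineage = _NOISE_LINEAGES[j % len(_NOISE_LINEAGES)]
        rows[tid] = ("Bacteria",) + lineage
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(RANKS))


def simulate_community(
    design: RiverDesign,
    signal: PlantedSignal,
    n_noise_taxa: int = 200,
    library_size: int = 50_000,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compositional count table with planted indicators, plus taxonomy.

    Background taxa get log-normal latent intensities whose log-means follow
    an AR(1) longitudinal succession (rho = 0.6) independently per transect.
    Indicator parents follow their high/low regime profile; clones are the
    parent intensity times log-normal jitter. Counts are multinomial draws
    closing each sample to *library_size*. Clones of a redundancy group share
    a genus; noise taxa cycle over >= 4 phyla.
    """
    noise_ids = [f"ASV_{j + 1:04d}" for j in range(n_noise_taxa)]
    overlap = set(noise_ids) & set(signal.indicator_ids)
    if overlap:
        raise ValueError(f"indicator ids collide with noise ids: {sorted(overlap)}")
    taxa = list(signal.indicator_ids) + noise_ids
    if library_size < len(taxa):
        raise ValueError("library_size smaller than the number of taxa")

    rng = np.random.default_rng(seed)
    n = design.n_stations
    rho, innov_sd = 0.6, 0.2
    n_groups = len(signal.redundancy_groups)
    n_coupled = min(signal.n_coupled_taxa, n_noise_taxa)
    coupled_idx = rng.choice(n_noise_taxa, n_coupled, replace=False)
    coupled_delta = rng.normal(0.0, signal.coupling_sd, n_coupled)
    coupled_group = np.arange(n_coupled) % n_groups
    # a taxon's typical abundance is a property of the taxon, shared by all
    # three transects; only the longitudinal AR fluctuations differ laterally
    base_level = rng.normal(0.0, 0.9, n_noise_taxa)

    frames = []
    for ti, transect in enumerate(design.transects):
        log_int = np.empty((n, len(taxa)))
        # planted indicators: regime switches shifted a couple of stations
        # between transects (lateral water masses mix slowly, so the three
        # longitudinal series are similar but not identical)
        offset = [0, 2, -2][ti % 3] * max(1, n // 60)
        profiles = [
            _indicator_profile(n, signal.switch_fractions[gi], offset)
            for gi in range(n_groups)
        ]
        col = 0
        for gi, group in enumerate(signal.redundancy_groups):
            base = np.log(0.3) + profiles[gi] * np.log(signal.high_low_ratio)
            parent = base + rng.normal(0.0, 0.03, n)
            for mi, _member in enumerate(group):
                jitter = (0.0 if mi == 0
                          else rng.normal(0.0, signal.clone_jitter_sd, n))
                log_int[:, col] = parent + jitter
                col += 1
        # background: station-autocorrelated log intensities; a subset of
        # taxa shifts weakly with the indicator regimes (regime shifts move
        # the whole community, not just the indicators)
        ar = np.empty((n, n_noise_taxa))
        ar[0] = rng.normal(0.0, innov_sd, n_noise_taxa)
        for s in range(1, n):
            ar[s] = rho * ar[s - 1] + rng.normal(0.0, innov_sd * np.sqrt(1 - rho**2),
                                                 n_noise_taxa)
        background = base_level + ar
        for k, (ci, delta) in enumerate(zip(coupled_idx, coupled_delta)):
            background[:, ci] = background[:, ci] + delta * profiles[coupled_group[k]]
        log_int[:, col:] = background
        intensity = np.exp(log_int)
        probs = intensity / intensity.sum(axis=1, keepdims=True)
        counts = np.vstack([rng.multinomial(library_size, p) for p in probs])
        frames.append(pd.DataFrame(
            counts,
            index=[f"{transect[0].upper()}{s:03d}" for s in range(n)],
            columns=taxa,
        ))
    abundance = pd.concat(frames)
    abundance.index.name = "sample_id"
    taxonomy = _taxonomy_frame(signal, noise_ids)
    taxonomy.index.name = "taxon_id"
    return abundance, taxonomy


def latent_response(
    abundance: pd.DataFrame,
    metadata: pd.DataFrame,
    signal: PlantedSignal,
) -> pd.Series:
    """Noise-free latent response of the planted signal.

    For each redundancy group the parent's Hellinger series is passed
    through the group's (window, lag) transform within each transect,
    z-scored over all samples, weighted and summed. This is exactly the
    feature construction the screening module searches over.
    """
    hell = hellinger_transform(abundance).loc[metadata.index]
    base = base_design(metadata)
    design = lagged_design_matrix(base, hell, signal.lag_specs())
    latent = np.zeros(len(metadata))
    for spec, weight in zip(signal.lag_specs(), signal.effect_weights):
        f = design[spec.column].to_numpy(float)
        sd = f.std(ddof=0)
        latent += weight * (f - f.mean()) / (sd if sd > 0 else 1.0)
    return pd.Series(latent, index=metadata.index, name="latent_response")


def simulate_dataset(
    design: RiverDesign | None = None,
    signal: PlantedSignal | None = None,
    n_noise_taxa: int = 200,
    library_size: int = 50_000,
    seed: int = 0,
) -> Dataset:
    """Full synthetic dataset: metadata + community + indicator-driven class.

    The status class is the cut-point binning of the planted latent response
    (indicator features plus Gaussian noise of sd ``signal.noise_sd``),
    overriding the environment-driven class of :func:`simulate_river`.
    """
    design = design or RiverDesign()
    signal = signal or default_signal()
    ss = np.random.SeedSequence(seed)
    s_river, s_comm, s_noise = (int(c.generate_state(1)[0]) % (2**31 - 1)
                                for c in ss.spawn(3))
    metadata = simulate_river(design, seed=s_river)
    abundance, taxonomy = simulate_community(
        design, signal, n_noise_taxa=n_noise_taxa, library_size=library_size,
        seed=s_comm,
    )
    abundance = abundance.loc[metadata.index]
    latent = latent_response(abundance, metadata, signal).to_numpy()
    if signal.noise_sd > 0:
        latent = latent + np.random.default_rng(s_noise).normal(
            0.0, signal.noise_sd, len(latent))
    metadata["latent_saprobity"] = latent
    metadata["status_class"] = _bin_latent(latent, design)
    return Dataset(abundance=abundance, taxonomy=taxonomy, metadata=metadata)


def write_fixture(dataset: Dataset, directory) -> dict[str, Path]:
    """Write a dataset as the three TSV tables readable by ``load_dataset``."""
    from .io import write_dataset

    if dataset.n_samples == 0 or dataset.n_taxa == 0:
        raise ValueError("refusing to write an empty dataset")
    return write_dataset(dataset, Path(directory))
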