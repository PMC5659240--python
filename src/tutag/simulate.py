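"""Synthetic TU-tagging count data with known ground truth.

The generator emulates a metabolic-labeling purification experiment in a
layered tissue. Three sample types share one gene universe: two purified
types driven by layer-restricted Cre lines (``Sepw1`` weighted to layer 2/3
with minor layer-4 mass, ``Nr5a1`` concentrated on layer 4) and a ``WT``
background type whose purified material is carryover from unlabeled tissue.

Per gene g the model carries a baseline abundance lambda_g, a probability
vector of layer weights w_{g,l}, and an mRNA half-life t_g. Over a labeling
window of T hours the newly transcribed fraction of a steady-state pool
under first-order decay is

    r_g = 1 - exp(-ln2 * T / t_g).

A purified sample of population profile pi (probabilities over layers) has
expected abundance

    mu_g = (1 - b) * lambda_g * (sum_l pi_l w_{g,l}) * r_g + b * bg_g,

where bg_g = lambda_g * (sum_l pi_tissue,l w_{g,l}) is total (unlabeled)
tissue RNA and b is the background-contamination fraction; the background
carries no newly-transcribed weighting. The WT background type is pure
carryover scaled by a capture efficiency: mu_g = wt_capture_scale * bg_g.
Counts are negative binomial with a dispersion--mean trend
phi(mu) = a0 + a1/mu and per-sample library scalings.

Because the purified/total contrast is a newly-transcribed/total ratio,
genes with short half-lives (r_g near 1) are enriched against the
background comparison by transcription dynamics alone — the key noise mode
this generator plants so downstream stages can be tested against it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import CountMatrix, LayerGeneSets, SampleSheet, write_counts, write_sample_sheet, write_yaml

__all__ = [
    "SimulationConfig",
    "SimulationConfigError",
    "GeneCatalog",
    "TruthTable",
    "generate_catalog",
    "new_fraction",
    "expected_abundance",
    "truth_table",
    "simulate_counts",
    "marker_gene_sets",
    "write_simulation",
]

LAYERS_DEFAULT = ("L2/3", "L4", "L5", "L6", "L6b", "unpatterned")
UNPATTERNED = "unpatterned"


class SimulationConfigError(ValueError):
    """Configuration error naming the offending field."""


def _default_profiles() -> dict[str, list[float]]:
    # Sepw1: layer 2/3 with lesser layer-4 mass; Nr5a1: sparse layer 4;
    # WT: uniform over layer mass (bulk tissue).
    return {
        "Sepw1": [0.60, 0.20, 0.05, 0.05, 0.05, 0.05],
        "Nr5a1": [0.04, 0.80, 0.04, 0.04, 0.04, 0.04],
        "WT": [1 / 6] * 6,
    }


@dataclass
class SimulationConfig:
    """Study conditions for one simulated TU-tagging experiment.

    Defaults mirror the real design: three purified sample types, three
    replicates each, a 5-hour labeling window, and 2% planted markers per
    patterned layer (100 per layer at 5000 genes, the per-layer database
    scale relative to the transcriptome).
    """

    n_genes: int = 5000
    n_replicates_per_type: int = 3
    labeling_window_h: float = 5.0
    background_fraction: float = 0.25
    wt_capture_scale: float = 0.3
    layer_names: tuple[str, ...] = LAYERS_DEFAULT
    population_profiles: dict[str, list[float]] = field(default_factory=_default_profiles)
    background_types: tuple[str, ...] = ("WT",)
    tissue_profile: list[float] | None = None  # None -> uniform over layers
    effect_size: float = 6.0
    frac_markers_per_layer: float = 0.02
    dispersion_a0: float = 0.01
    dispersion_a1: float = 1.0
    library_size_range: tuple[float, float] = (0.5, 1.5)
    baseline_median: float = 500.0
    baseline_sigma: float = 1.0
    half_life_median_h: float = 4.0
    half_life_sigma: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        if not (isinstance(self.n_genes, (int, np.integer)) and self.n_genes > 0):
            raise SimulationConfigError("n_genes must be a positive integer")
        if not (isinstance(self.n_replicates_per_type, (int, np.integer)) and self.n_replicates_per_type > 0):
            raise SimulationConfigError("n_replicates_per_type must be a positive integer")
        if self.labeling_window_h <= 0:
            raise SimulationConfigError("labeling_window_h must be > 0")
        if not 0 <= self.background_fraction < 1:
            raise SimulationConfigError("background_fraction must be in [0, 1)")
        if not 0 < self.wt_capture_scale < 1:
            raise SimulationConfigError("wt_capture_scale must be in (0, 1)")
        if UNPATTERNED not in self.layer_names:
            raise SimulationConfigError(f"layer_names must include {UNPATTERNED!r}")
        L = len(self.layer_names)
        for name, prof in self.population_profiles.items():
            p = np.asarray(prof, dtype=float)
            if p.shape != (L,):
                raise SimulationConfigError(
                    f"population_profiles[{name!r}] must have {L} entries"
                )
            if (p < 0).any() or not math.isclose(p.sum(), 1.0, abs_tol=1e-6):
                raise SimulationConfigError(
                    f"population_profiles[{name!r}] must be a probability vector"
                )
        for bt in self.background_types:
            if bt not in self.population_profiles:
                raise SimulationConfigError(
                    f"background_types entry {bt!r} has no population profile"
                )
        if self.tissue_profile is not None:
            p = np.asarray(self.tissue_profile, dtype=float)
            if p.shape != (L,) or (p < 0).any() or not math.isclose(p.sum(), 1.0, abs_tol=1e-6):
                raise SimulationConfigError("tissue_profile must be a probability vector over layers")
        if self.effect_size <= 0:
            raise SimulationConfigError("effect_size must be > 0")
        if not 0 <= self.frac_markers_per_layer <= 1:
            raise SimulationConfigError("frac_markers_per_layer must be in [0, 1]")
        if self.dispersion_a0 < 0 or self.dispersion_a1 < 0:
            raise SimulationConfigError("dispersion coefficients must be >= 0")
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise SimulationConfigError("library_size_range must satisfy 0 < low <= high")
        for fname in ("baseline_median", "baseline_sigma", "half_life_median_h", "half_life_sigma"):
            if getattr(self, fname) <= 0:
                raise SimulationConfigError(f"{fname} must be > 0")

    @property
    def patterned_layers(self) -> list[str]:
        return [l for l in self.layer_names if l != UNPATTERNED]

    def tissue(self) -> np.ndarray:
        if self.tissue_profile is not None:
            return np.asarray(self.tissue_profile, dtype=float)
        return np.full(len(self.layer_names), 1.0 / len(self.layer_names))

    def to_dict(self) -> dict:
        return {
            "n_genes": int(self.n_genes),
            "n_replicates_per_type": int(self.n_replicates_per_type),
            "labeling_window_h": float(self.labeling_window_h),
            "background_fraction": float(self.background_fraction),
            "wt_capture_scale": float(self.wt_capture_scale),
            "layer_names": list(self.layer_names),
            "population_profiles": {k: [float(x) for x in v] for k, v in self.population_profiles.items()},
            "background_types": list(self.background_types),
            "tissue_profile": None if self.tissue_profile is None else [float(x) for x in self.tissue_profile],
            "effect_size": float(self.effect_size),
            "frac_markers_per_layer": float(self.frac_markers_per_layer),
            "dispersion_a0": float(self.dispersion_a0),
            "dispersion_a1": float(self.dispersion_a1),
            "library_size_range": [float(x) for x in self.library_size_range],
            "baseline_median": float(self.baseline_median),
            "baseline_sigma": float(self.baseline_sigma),
            "half_life_median_h": float(self.half_life_median_h),
            "half_life_sigma": float(self.half_life_sigma),
            "seed": int(self.seed),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        kwargs = dict(d)
        for key in ("layer_names", "background_types"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        if "library_size_range" in kwargs:
            kwargs["library_size_range"] = tuple(kwargs["library_size_range"])
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg


@dataclass
class GeneCatalog:
    """Per-gene ground truth: baseline abundance, layer weights, half-life.

    ``table`` is indexed by gene_id with columns ``baseline``,
    ``half_life_h``, ``home_layer`` and one ``w_<layer>`` column per layer.
    """

    table: pd.DataFrame
    layer_names: tuple[str, ...]

    @property
    def weight_columns(self) -> list[str]:
        return [f"w_{l}" for l in self.layer_names]

    def weights(self) -> np.ndarray:
        return self.table[self.weight_columns].to_numpy()


@dataclass
class TruthTable:
    """Expected means per sample type plus planted labels and kinetics.

    Indexed by gene_id; columns ``home_layer``, ``is_L23_marker``,
    ``new_fraction`` and ``expected_mean_<type>`` per sample type.
    """

    table: pd.DataFrame

    def expected_mean(self, sample_type: str) -> pd.Series:
        col = f"expected_mean_{sample_type}"
        if col not in self.table.columns:
            known = [c[len("expected_mean_"):] for c in self.table.columns if c.startswith("expected_mean_")]
            raise KeyError(f"unknown sample type {sample_type!r}; known types: {known}")
        return self.table[col]


def _rng_streams(seed: int, n: int) -> list[np.random.Generator]:
    # One root stream per run; independent child streams per stage so adding
    # genes or samples in one stage never perturbs draws in another.
    children = np.random.SeedSequence(seed).spawn(n)
    return [np.random.default_rng(c) for c in children]


def generate_catalog(config: SimulationConfig) -> GeneCatalog:
    """Draw a gene catalog with planted layer markers.

    Exactly ``round(frac_markers_per_layer * n_genes)`` markers are planted
    per patterned layer; marker weights start from the shared uniform base
    distribution with the home-layer weight multiplied by ``effect_size``
    and renormalized (``effect_size=1`` therefore plants no signal).
    """
    config.validate()
    rng_assign, rng_base, rng_half = _rng_streams(config.seed, 3)

    G, L = config.n_genes, len(config.layer_names)
    gene_ids = [f"g{i:05d}" for i in range(G)]
    n_per_layer = round(config.frac_markers_per_layer * G)
    patterned = config.patterned_layers
    if n_per_layer * len(patterned) > G:
        raise SimulationConfigError("frac_markers_per_layer too large for n_genes")

    home = np.array([UNPATTERNED] * G, dtype=object)
    marker_idx = rng_assign.choice(G, size=n_per_layer * len(patterned), replace=False)
    for k, layer in enumerate(patterned):
        home[marker_idx[k * n_per_layer:(k + 1) * n_per_layer]] = layer

    weights = np.full((G, L), 1.0 / L)
    for k, layer in enumerate(config.layer_names):
        is_home = home == layer
        if layer != UNPATTERNED and is_home.any():
            weights[is_home, k] *= config.effect_size
    weights /= weights.sum(axis=1, keepdims=True)

    baseline = config.baseline_median * np.exp(
        rng_base.normal(0.0, config.baseline_sigma, size=G)
    )
    half_life = config.half_life_median_h * np.exp(
        rng_half.normal(0.0, config.half_life_sigma, size=G)
    )

    table = pd.DataFrame(
        {"baseline": baseline, "half_life_h": half_life, "home_layer": home},
        index=pd.Index(gene_ids, name="gene_id"),
    )
    for k, layer in enumerate(config.layer_names):
        table[f"w_{layer}"] = weights[:, k]
    return GeneCatalog(table, tuple(config.layer_names))


def new_fraction(half_life_h: np.ndarray | float, window_h: float) -> np.ndarray | float:
    """Newly transcribed fraction r = 1 - exp(-ln2 * T / t) of a steady pool."""
    return 1.0 - np.exp(-np.log(2.0) * window_h / np.asarray(half_life_h, dtype=float))


def expected_abundance(
    catalog: GeneCatalog, config: SimulationConfig, sample_type: str
) -> pd.Series:
    """Expected (pre-library-scaling) abundance mu_g for one sample type."""
    if sample_type not in config.population_profiles:
        raise KeyError(
            f"unknown sample type {sample_type!r}; known types: "
            f"{sorted(config.population_profiles)}"
        )
    lam = catalog.table["baseline"].to_numpy()
    W = catalog.weights()
    bg = lam * (W @ config.tissue())
    if sample_type in config.background_types:
        mu = config.wt_capture_scale * bg
    else:
        pi = np.asarray(config.population_profiles[sample_type], dtype=float)
        r = new_fraction(catalog.table["half_life_h"].to_numpy(), config.labeling_window_h)
        b = config.background_fraction
        mu = (1.0 - b) * lam * (W @ pi) * r + b * bg
    return pd.Series(mu, index=catalog.table.index, name=f"mu_{sample_type}")


def truth_table(catalog: GeneCatalog, config: SimulationConfig) -> TruthTable:
    tab = pd.DataFrame(index=catalog.table.index)
    tab["home_layer"] = catalog.table["home_layer"]
    tab["is_L23_marker"] = catalog.table["home_layer"] == "L2/3"
    tab["half_life_h"] = catalog.table["half_life_h"]
    tab["new_fraction"] = new_fraction(
        catalog.table["half_life_h"].to_numpy(), config.labeling_window_h
    )
    for sample_type in config.population_profiles:
        tab[f"expected_mean_{sample_type}"] = expected_abundance(catalog, config, sample_type)
    return TruthTable(tab)


def simulate_counts(
    catalog: GeneCatalog, config: SimulationConfig
) -> tuple[CountMatrix, SampleSheet, TruthTable]:
    """Sample NB counts for every sample of every type.

    Counts are NB with mean ``s_j * mu_g`` (s_j ~ Uniform(library_size_range))
    and dispersion ``phi = a0 + a1 / (s_j * mu_g)``; ``a0 = a1 = 0`` reduces
    to Poisson. Fully reproducible from ``config.seed``.
    """
    config.validate()
    _, _, _, rng_lib, rng_counts = _rng_streams(config.seed, 5)

    truth = truth_table(catalog, config)
    sample_types = list(config.population_profiles)
    n_rep = config.n_replicates_per_type
    sample_ids, type_of = [], {}
    for t in sample_types:
        for i in range(n_rep):
            sid = f"{t}_{i + 1}"
            sample_ids.append(sid)
            type_of[sid] = t

    lo, hi = config.library_size_range
    lib = rng_lib.uniform(lo, hi, size=len(sample_ids))

    counts = np.zeros((config.n_genes, len(sample_ids)), dtype=np.int64)
    for j, sid in enumerate(sample_ids):
        mu = truth.expected_mean(type_of[sid]).to_numpy() * lib[j]
        phi = config.dispersion_a0 + np.divide(
            config.dispersion_a1, mu, out=np.zeros_like(mu), where=mu > 0
        )
        pois = phi <= 0
        col = np.zeros_like(mu)
        if pois.any():
            col[pois] = rng_counts.poisson(mu[pois])
        nb = ~pois & (mu > 0)
        if nb.any():
            size = 1.0 / phi[nb]
            p = size / (size + mu[nb])
            col[nb] = rng_counts.negative_binomial(size, p)
        counts[:, j] = col
    df = pd.DataFrame(counts, index=catalog.table.index.copy(), columns=sample_ids)
    matrix = CountMatrix(df)
    sheet = SampleSheet(type_of)
    return matrix, sheet, truth


def marker_gene_sets(catalog: GeneCatalog) -> LayerGeneSets:
    """Planted marker lists per layer — the simulation's 'database' gene sets."""
    sets: dict[str, list[str]] = {}
    for layer, sub in catalog.table.groupby("home_layer", sort=False):
        sets[str(layer)] = list(sub.index)
    ordered = {l: sets[l] for l in catalog.layer_names if l in sets}
    return LayerGeneSets(ordered)


def write_simulation(
    outdir: str | Path,
    matrix: CountMatrix,
    sheet: SampleSheet,
    truth: TruthTable,
    config: SimulationConfig,
) -> dict[str, Path]:
    """Write counts, sample sheet, truth table and config into a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "counts.tsv",
        "samples": outdir / "samples.tsv",
        "truth": outdir / "truth.tsv",
        "config": outdir / "config.yaml",
    }
    write_counts(matrix, paths["counts"])
    write_sample_sheet(sheet, paths["samples"])
    truth.table.to_csv(paths["truth"], sep="\t", index_label="gene_id")
    write_yaml(config.to_dict(), paths["config"])
    return paths
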