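"""Synthetic single-cell, spatial-spot and ISS data with full ground truth.

The generator emulates the data structure of a developmental heart atlas:

* a labelled single-cell reference -- K discrete cell states, each with a
  dedicated block of marker genes enriched ``marker_fold`` over baseline;
* spatial sections -- spots on a square lattice partitioned into contiguous
  rectangular niches, each niche with its own Dirichlet mean over states;
  per-spot proportions are drawn from the niche's Dirichlet and spot counts
  from the implied linear mixture of state profiles;
* multiple sections spanning a postconceptional-week (PCW) age covariate;
* 5-round x 5-channel one-hot ISS barcodes with additive background and
  half-normal noise.

Every generated object carries its ground truth (state profiles, per-spot
proportions, niche ids, planted ISS genes), so downstream estimators can be
scored exactly. One global seed drives a hierarchical stream (reference /
sections / ISS), making each component independently reproducible.

Count noise models: ``none`` (exact expected values -- the noise-free limit
used for exact recovery tests), ``poisson``, or ``nb`` (gamma-Poisson with a
single shared dispersion, the standard scRNA-seq overdispersion convention;
variance = mu + dispersion * mu^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd

from cardioniche.deconvolution import SpatialSection
from cardioniche.iss import Codebook, SignalTensor

_NOISE_MODELS = ("none", "poisson", "nb")


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic study.

    Defaults are a desk-scale rendition of the atlas design: a handful of
    well-separated cell states with dedicated markers, sections of a few
    hundred Visium-like spots (~5,000 counts each) organized into contiguous
    niches, and section ages spanning PCW 5.5-14.
    """

    n_states: int = 6
    n_genes: int = 200
    markers_per_state: int = 10
    marker_fold: float = 20.0
    n_cells_per_state: int = 100
    n_sections: int = 3
    spots_per_section: int = 400
    grid_side: int = 20
    n_niches: int = 3
    dirichlet_concentration: float = 30.0
    niche_dominance: float = 0.75
    spot_depth: float = 5000.0
    count_noise: str = "poisson"
    nb_dispersion: float = 0.3
    pcw_per_section: list[float] = field(default_factory=lambda: [5.5, 8.0, 13.0])
    fixed_mixture: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if min(
            self.n_states,
            self.n_genes,
            self.markers_per_state,
            self.n_cells_per_state,
            self.n_sections,
            self.spots_per_section,
            self.grid_side,
            self.n_niches,
        ) < 1:
            raise ValueError("all counts must be >= 1")
        if self.markers_per_state * self.n_states > self.n_genes:
            raise ValueError(
                "marker budget exceeds gene count: "
                f"{self.markers_per_state} x {self.n_states} > {self.n_genes}"
            )
        if self.n_niches > self.n_states:
            raise ValueError("n_niches must be <= n_states")
        if self.count_noise not in _NOISE_MODELS:
            raise ValueError(f"count_noise must be one of {_NOISE_MODELS}")
        if self.spots_per_section > self.grid_side**2:
            raise ValueError("grid too small for spots_per_section")
        if len(self.pcw_per_section) != self.n_sections:
            raise ValueError("pcw_per_section length must equal n_sections")
        if any(p < 5.5 or p > 14 for p in self.pcw_per_section):
            raise ValueError("pcw values must lie in [5.5, 14]")
        if self.marker_fold <= 0 or self.spot_depth <= 0:
            raise ValueError("marker_fold and spot_depth must be positive")

    @property
    def state_names(self) -> list[str]:
        return [f"state_{k}" for k in range(self.n_states)]

    @property
    def gene_names(self) -> list[str]:
        return [f"gene_{g:04d}" for g in range(self.n_genes)]

    def rng_streams(self) -> dict[str, np.random.Generator]:
        """Hierarchical child streams so modules regenerate independently."""
        children = np.random.SeedSequence(self.seed).spawn(3)
        return {
            "reference": np.random.default_rng(children[0]),
            "sections": np.random.default_rng(children[1]),
            "iss": np.random.default_rng(children[2]),
        }


@dataclass
class SyntheticTruth:
    """Ground truth for generated objects.

    ``state_profiles``: genes x states expected relative expression (columns
    sum to 1). ``proportions``: per section, spots x states compositions.
    ``niche_of_spot``: per section, spot -> niche id. ``iss_gene_of_spot``:
    planted gene per ISS spot.
    """

    state_profiles: pd.DataFrame | None = None
    proportions: dict[str, pd.DataFrame] = field(default_factory=dict)
    niche_of_spot: dict[str, np.ndarray] = field(default_factory=dict)
    niche_means: pd.DataFrame | None = None
    iss_gene_of_spot: np.ndarray | None = None

    def validate(self) -> None:
        for sec, P in self.proportions.items():
            arr = P.to_numpy()
            if (arr < 0).any() or np.abs(arr.sum(axis=1) - 1).max() > 1e-9:
                raise ValueError(f"section {sec}: proportions off the simplex")
        if self.niche_means is not None:
            n_niches = self.niche_means.shape[0]
            for sec, niches in self.niche_of_spot.items():
                if niches.max() >= n_niches:
                    raise ValueError(f"section {sec}: niche id out of range")


def truth_profiles(config: SyntheticConfig) -> pd.DataFrame:
    """Expected relative expression per state: baseline 1, markers at marker_fold.

    Gene block ``k * markers_per_state .. (k+1) * markers_per_state`` marks
    state k; columns are normalized to sum to 1.
    """
    M = np.ones((config.n_genes, config.n_states))
    for k in range(config.n_states):
        lo = k * config.markers_per_state
        M[lo : lo + config.markers_per_state, k] = config.marker_fold
    M /= M.sum(axis=0, keepdims=True)
    return pd.DataFrame(M, index=config.gene_names, columns=config.state_names)


def _draw_counts(
    expected: np.ndarray, noise: str, dispersion: float, rng: np.random.Generator
) -> np.ndarray:
    if noise == "none":
        return expected.copy()
    if noise == "poisson":
        return rng.poisson(expected).astype(float)
    # gamma-Poisson: mean mu, variance mu + dispersion * mu^2
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, expected * dispersion)
    return rng.poisson(lam).astype(float)


def generate_reference(
    config: SyntheticConfig,
) -> tuple[ad.AnnData, SyntheticTruth]:
    """Simulate the labelled single-cell reference.

    Each cell's expected counts are ``spot_depth x`` its state's relative
    profile; counts are drawn under ``count_noise``. Cells carry state,
    donor and PCW metadata (donors cycle through the configured section
    ages). Deterministic given the config seed.
    """
    rng = config.rng_streams()["reference"]
    profiles = truth_profiles(config)
    P = profiles.to_numpy()

    n_cells = config.n_states * config.n_cells_per_state
    states = np.repeat(np.arange(config.n_states), config.n_cells_per_state)
    expected = config.spot_depth * P[:, states].T  # cells x genes
    X = _draw_counts(expected, config.count_noise, config.nb_dispersion, rng)

    donor_idx = np.arange(n_cells) % config.n_sections
    obs = pd.DataFrame(
        {
            "state": [config.state_names[s] for s in states],
            "donor": [f"donor_{d}" for d in donor_idx],
            "pcw": [config.pcw_per_section[d] for d in donor_idx],
        },
        index=pd.Index([f"cell_{i:05d}" for i in range(n_cells)], name="barcode"),
    )
    adata = ad.AnnData(
        X=X, obs=obs, var=pd.DataFrame(index=pd.Index(config.gene_names, name="gene"))
    )
    truth = SyntheticTruth(state_profiles=profiles)
    return adata, truth


def niche_mean_table(config: SyntheticConfig) -> pd.DataFrame:
    """Dirichlet mean composition per niche.

    States are dealt to niches round-robin; a niche's dominant states share
    ``niche_dominance`` of its mass, the rest is uniform over all states.
    """
    means = np.full(
        (config.n_niches, config.n_states),
        (1.0 - config.niche_dominance) / config.n_states,
    )
    owners: list[list[int]] = [[] for _ in range(config.n_niches)]
    for k in range(config.n_states):
        owners[k % config.n_niches].append(k)
    for i, states in enumerate(owners):
        means[i, states] += config.niche_dominance / len(states)
    return pd.DataFrame(
        means,
        index=pd.Index(range(config.n_niches), name="niche"),
        columns=config.state_names,
    )


def _niche_layout(config: SyntheticConfig) -> tuple[np.ndarray, np.ndarray]:
    """Row-major lattice coordinates and contiguous vertical-strip niche ids."""
    side = config.grid_side
    idx = np.arange(config.spots_per_section)
    xs = idx % side
    ys = idx // side
    niche = np.minimum(xs * config.n_niches // side, config.n_niches - 1)
    return np.column_stack([xs, ys]).astype(float), niche.astype(int)


def generate_sections(
    config: SyntheticConfig, profiles: pd.DataFrame | None = None
) -> tuple[list[SpatialSection], SyntheticTruth]:
    """Simulate spatially structured spot sections with known compositions.

    The lattice is split into ``n_niches`` contiguous vertical strips. Every
    spot's composition is drawn from its niche's Dirichlet
    (``alpha = concentration x niche mean``; ``fixed_mixture`` uses the mean
    exactly, the infinite-concentration limit), and its counts from the
    mixture of state profiles at ``spot_depth`` under the noise model.
    """
    rng = config.rng_streams()["sections"]
    if profiles is None:
        profiles = truth_profiles(config)
    if list(profiles.columns) != config.state_names:
        raise ValueError("profiles do not cover the configured states")
    G = profiles.to_numpy()  # genes x states

    means = niche_mean_table(config)
    coords, niche_ids = _niche_layout(config)

    sections: list[SpatialSection] = []
    truth = SyntheticTruth(state_profiles=profiles, niche_means=means)
    for s in range(config.n_sections):
        sec_id = f"section_{s}"
        P = np.empty((config.spots_per_section, config.n_states))
        for i, niche in enumerate(niche_ids):
            mean = means.iloc[niche].to_numpy()
            if config.fixed_mixture:
                P[i] = mean
            else:
                P[i] = rng.dirichlet(config.dirichlet_concentration * mean)
        expected = config.spot_depth * (P @ G.T)
        X = _draw_counts(expected, config.count_noise, config.nb_dispersion, rng)
        spot_ids = [f"{sec_id}_spot_{i:04d}" for i in range(config.spots_per_section)]
        sections.append(
            SpatialSection(
                counts=X,
                gene_ids=list(profiles.index),
                spot_ids=spot_ids,
                coords=coords,
                section_id=sec_id,
                pcw=float(config.pcw_per_section[s]),
            )
        )
        truth.proportions[sec_id] = pd.DataFrame(
            P, index=pd.Index(spot_ids, name="spot_id"), columns=config.state_names
        )
        truth.niche_of_spot[sec_id] = niche_ids.copy()
    truth.validate()
    return sections, truth


def generate_iss(
    codebook: Codebook,
    n_spots: int,
    background: float = 0.0,
    signal: float = 1.0,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
    extent: float = 1000.0,
) -> tuple[SignalTensor, SyntheticTruth]:
    """Simulate an ISS signal tensor with planted gene identities.

    Each spot is assigned a codebook gene uniformly at random and placed
    uniformly on a plane of the given extent. Its coded channel carries
    ``signal + background``, every other channel ``background``; independent
    additive half-normal noise (scale ``noise_sd``) keeps intensities
    non-negative.
    """
    if signal <= 0:
        raise ValueError("signal must be positive")
    if background < 0 or noise_sd < 0:
        raise ValueError("background and noise_sd must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    gene_idx = rng.integers(len(codebook.genes), size=n_spots)
    genes = [codebook.genes[i] for i in gene_idx]
    I = np.full((n_spots, codebook.n_rounds, codebook.n_channels), background, dtype=float)
    for i, g in enumerate(genes):
        for r, ch in enumerate(codebook.code[g]):
            I[i, r, ch] += signal
    if noise_sd > 0:
        I += np.abs(rng.normal(0.0, noise_sd, size=I.shape))
    xy = rng.uniform(0, extent, size=(n_spots, 2))

    tensor = SignalTensor(intensities=I, x=xy[:, 0], y=xy[:, 1])
    truth = SyntheticTruth(iss_gene_of_spot=np.array(genes))
    return tensor, truth
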