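"""Synthetic two-habitat, size-fractionated metacommunities with known
assembly regimes.

The generator builds a pure-birth phylogeny, evolves a habitat-preference
trait along it by Brownian motion, and assembles samples for two habitats
(melt pond ``MP`` and sea water ``SW``, each with micro/nano/pico size
fractions) under one of four regimes:

``selection``
    Sampling weight of taxon i in sample s is the lognormal metacommunity
    abundance times a Gaussian niche filter
    exp(-(trait_i - env_s)^2 / (2 filter_width^2)); the two habitats get
    distinct environmental optima, so cross-habitat comparisons experience
    heterogeneous selection.
``dispersal_limited``
    Each sample draws neutrally from its own random subset of the taxon
    pool (fraction ``subset_fraction``), with sample-specific lognormal
    drift multipliers on the metacommunity abundances, emulating isolated
    localities whose compositions have drifted apart.
``neutral_drift``
    Every sample is an independent multinomial draw from one shared
    lognormal metacommunity.
``mixed``
    SW samples are assembled under ``dispersal_limited`` and MP samples
    under ``neutral_drift`` (with an optionally reduced MP source pool),
    mirroring a seascape where open-water communities are dispersal
    limited while pond communities drift.

Read depths are Poisson(``depth_mean``); the salinity covariate is the
habitat mean (SW ~ 29, MP ~ 2.5, typical of Arctic surface sea water and
closed melt ponds) plus Gaussian noise.  Sequencing error, chimeras, and
PCR bias are deliberately not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from .tables_io import ZotuTable, validate_metadata

REGIMES = ("selection", "dispersal_limited", "neutral_drift", "mixed")

SALINITY_MEAN = {"SW": 29.0, "MP": 2.5}
TEMPERATURE_MEAN = {"SW": 2.0, "MP": -0.3}


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of one synthetic metacommunity scenario.

    Defaults give each pure regime a clearly recoverable signature at
    moderate size: 100 taxa, 8 samples per habitat, ~5000 reads/sample.
    """

    n_taxa: int = 100
    n_samples_per_group: int = 8
    regime: str = "neutral_drift"
    trait_sigma: float = 1.0
    filter_width: float = 0.35
    env_by_habitat: dict = field(
        default_factory=lambda: {"MP": -1.0, "SW": 1.0}
    )
    lognormal_mu: float = 0.0
    lognormal_sigma: float = 1.5
    subset_fraction: float = 0.3
    drift_sigma: float = 2.0
    mp_pool_fraction: float = 1.0
    depth_mean: int = 5000
    salinity_sd: float = 1.0
    seed: int = 0

    def validate(self) -> "ScenarioConfig":
        if self.n_taxa < 4:
            raise ValueError("n_taxa must be >= 4")
        if self.n_samples_per_group < 2:
            raise ValueError("n_samples_per_group must be >= 2")
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}; one of {REGIMES}")
        for name in ("trait_sigma", "filter_width", "lognormal_sigma",
                     "drift_sigma", "salinity_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 < self.subset_fraction <= 1:
            raise ValueError("subset_fraction must be in (0, 1]")
        if not 0 < self.mp_pool_fraction <= 1:
            raise ValueError("mp_pool_fraction must be in (0, 1]")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be > 0")
        if self.regime in ("selection", "mixed"):
            if set(self.env_by_habitat) != {"MP", "SW"}:
                raise ValueError("env_by_habitat must map both MP and SW")
        return self


@dataclass
class GroundTruth:
    """What the generator actually did, for regime-recovery checks."""

    sample_regime: pd.Series
    sample_env: pd.Series
    taxon_trait: pd.Series

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"regime": self.sample_regime, "environment": self.sample_env}
        )
        df.index.name = "sample_id"
        return df


def simulate_tree(n_taxa: int, seed: int = 0,
                  normalize_height: bool = True) -> TreeNode:
    """Pure-birth (Yule) rooted binary tree with ``n_taxa`` tips.

    Branch lengths are exponential waiting times (unit birth rate per
    lineage); with ``normalize_height`` the tree is rescaled so the
    maximum root-to-tip distance is 1, making trait-model parameters
    comparable across tree sizes.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    rng = np.random.default_rng(seed)
    root = TreeNode(name=None, length=None)
    left = TreeNode(length=0.0)
    right = TreeNode(length=0.0)
    root.extend([left, right])
    active = [left, right]
    t = 0.0
    birth = {id(left): 0.0, id(right): 0.0}
    while len(active) < n_taxa:
        t += rng.exponential(1.0 / len(active))
        k = int(rng.integers(len(active)))
        parent = active.pop(k)
        parent.length = t - birth.pop(id(parent))
        ca, cb = TreeNode(length=0.0), TreeNode(length=0.0)
        parent.extend([ca, cb])
        birth[id(ca)] = birth[id(cb)] = t
        active.extend([ca, cb])
    t += rng.exponential(1.0 / len(active))
    for node in active:
        node.length = t - birth[id(node)]
    for i, tip in enumerate(root.tips()):
        tip.name = f"ZOTU_{i + 1}"
    if normalize_height:
        depths = [sum(a.length for a in tip.ancestors() if a.length) + tip.length
                  for tip in root.tips()]
        scale = max(depths)
        for node in root.traverse(include_self=False):
            node.length /= scale
    return root


def evolve_trait_bm(tree: TreeNode, trait_sigma: float,
                    seed: int = 0) -> pd.Series:
    """Brownian-motion trait values per tip, root value 0.

    Along each branch of length L the trait gains an independent
    N(0, trait_sigma^2 * L) increment, so a tip's marginal variance is
    trait_sigma^2 times its root-to-tip path length and covariances follow
    shared path lengths.
    """
    rng = np.random.default_rng(seed)
    values = {id(tree): 0.0}
    for node in tree.preorder(include_self=False):
        step = rng.normal(0.0, trait_sigma * np.sqrt(node.length)) \
            if node.length > 0 and trait_sigma > 0 else 0.0
        values[id(node)] = values[id(node.parent)] + step
    return pd.Series(
        {tip.name: values[id(tip)] for tip in tree.tips()}, name="trait"
    )


def expected_weights(config: ScenarioConfig, meta_p: np.ndarray,
                     traits: np.ndarray, habitat: str,
                     regime: str) -> np.ndarray:
    """Expected (pre-noise) sampling weights for one sample, normalized."""
    w = meta_p.copy()
    if regime == "selection":
        env = config.env_by_habitat[habitat]
        w = w * np.exp(-((traits - env) ** 2) / (2.0 * config.filter_width ** 2))
    total = w.sum()
    if total <= 0:
        raise ValueError("all sampling weights are zero; check filter_width")
    return w / total


def assemble_samples(
    config: ScenarioConfig, tree: TreeNode, traits: pd.Series
) -> tuple[ZotuTable, pd.DataFrame, GroundTruth]:
    """Draw a ZOTU table, metadata, and ground truth under one scenario."""
    config = config.validate()
    taxa = [t.name for t in tree.tips()]
    if set(traits.index) != set(taxa):
        raise ValueError("traits must be defined for every tip")
    trait_v = traits.loc[taxa].to_numpy()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    n_taxa = len(taxa)

    meta_abund = rng.lognormal(config.lognormal_mu, config.lognormal_sigma,
                               n_taxa)
    meta_p = meta_abund / meta_abund.sum()

    pool = {"SW": np.ones(n_taxa, dtype=bool)}
    if config.mp_pool_fraction < 1.0:
        k = max(4, int(round(config.mp_pool_fraction * n_taxa)))
        idx = rng.choice(n_taxa, size=k, replace=False)
        mask = np.zeros(n_taxa, dtype=bool)
        mask[idx] = True
        pool["MP"] = mask
    else:
        pool["MP"] = np.ones(n_taxa, dtype=bool)

    fractions = ["micro", "nano", "pico"]
    counts = {}
    meta_rows = []
    regimes = {}
    envs = {}
    for habitat in ("SW", "MP"):
        regime = config.regime
        if config.regime == "mixed":
            regime = "dispersal_limited" if habitat == "SW" else "neutral_drift"
        for i in range(config.n_samples_per_group):
            sid = f"{habitat}{i + 1:02d}"
            w = expected_weights(config, meta_p * pool[habitat], trait_v,
                                 habitat, regime)
            if regime == "dispersal_limited":
                n_pool = int(pool[habitat].sum())
                k = max(2, int(round(config.subset_fraction * n_pool)))
                candidates = np.nonzero(pool[habitat])[0]
                subset = rng.choice(candidates, size=k, replace=False)
                mask = np.zeros(n_taxa)
                mask[subset] = 1.0
                drift = rng.lognormal(0.0, config.drift_sigma, n_taxa)
                w = w * mask * drift
                w = w / w.sum()
            depth = max(1, int(rng.poisson(config.depth_mean)))
            counts[sid] = rng.multinomial(depth, w)
            salinity = SALINITY_MEAN[habitat] + rng.normal(0, config.salinity_sd)
            temperature = TEMPERATURE_MEAN[habitat] + rng.normal(0, 0.5)
            meta_rows.append(
                {
                    "sample_id": sid,
                    "habitat": habitat,
                    "size_fraction": fractions[i % 3],
                    "salinity": salinity,
                    "temperature": temperature,
                }
            )
            regimes[sid] = regime
            envs[sid] = (config.env_by_habitat.get(habitat, 0.0)
                         if regime == "selection" else np.nan)

    table = ZotuTable(
        pd.DataFrame(counts, index=pd.Index(taxa, name="#ZOTU_ID"),
                     dtype=np.int64)
    )
    metadata = validate_metadata(pd.DataFrame(meta_rows))
    truth = GroundTruth(
        sample_regime=pd.Series(regimes, name="regime"),
        sample_env=pd.Series(envs, name="environment"),
        taxon_trait=traits.loc[taxa],
    )
    return table, metadata, truth


def simulate_scenario(
    config: ScenarioConfig,
) -> tuple[ZotuTable, TreeNode, pd.DataFrame, GroundTruth]:
    """Tree + traits + samples for one scenario, all from ``config.seed``."""
    config = config.validate()
    tree = simulate_tree(config.n_taxa, seed=config.seed)
    traits = evolve_trait_bm(tree, config.trait_sigma, seed=config.seed + 1)
    table, metadata, truth = assemble_samples(config, tree, traits)
    return table, tree, metadata, truth


def read_scenario_config(path) -> ScenarioConfig:
    """Parse a plain-text ``key = value`` scenario configuration file."""
    fields = {f.name: f.type for f in ScenarioConfig.__dataclass_fields__.values()}
    kwargs = {}
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"malformed config line: {line!r}")
            key, value = (part.strip() for part in line.split("=", 1))
            if key not in fields:
                raise ValueError(f"unknown scenario parameter {key!r}")
            if key == "regime":
                kwargs[key] = value
            elif key == "env_by_habitat":
                pairs = [p.split(":") for p in value.split(",")]
                kwargs[key] = {h.strip(): float(v) for h, v in pairs}
            elif key in ("n_taxa", "n_samples_per_group", "depth_mean", "seed"):
                kwargs[key] = int(value)
            else:
                kwargs[key] = float(value)
    return ScenarioConfig(**kwargs).validate()
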