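"""Synthetic benchmark instances for the whole pipeline.

Real inputs — a genome-scale interactome, curated disease-gene scores, and
herb/compound/target catalogs — are large, licensed, or proprietary. This
module generates statistically analogous stand-ins so every pipeline stage
can be exercised and validated offline:

* a connected scale-free interactome (preferential attachment), capturing
  the heavy-tailed degree distribution of real protein networks;
* a planted, connected disease module with Beta-distributed node weights;
* a formula (Dirichlet dosage ratios), per-herb compound abundances
  (log-normal), and a compound-protein catalog with Beta-distributed
  confidences whose edges land inside the disease module's one-hop
  neighborhood with a controllable ``enrichment`` probability —
  enrichment 0 is a random-formula negative control;
* multi-source disease score tables as noisy, partially missing copies of
  the planted weights (Gaussian noise on the logit scale), with one source
  rendered qualitative.

All draws come from named substreams of one master seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .config import DEFAULT_CONFIG, WeightingConfig
from .herbs import CompoundAbundanceTable, FormulaComposition, InteractionCatalog
from .network import InteractionNetwork, neighbors
from .weighting import WeightedProteinSet, normalize_weights

__all__ = [
    "SimulationConfig",
    "generate_interactome",
    "plant_disease_module",
    "generate_formula_inputs",
    "generate_source_scores",
    "simulate_instance",
]

# Substream names: stable tags so adding a generator never shifts another's draws.
_STREAMS = ("interactome", "module", "formula", "sources")


@dataclass(frozen=True)
class SimulationConfig:
    """Declared distributions and sizes of one synthetic benchmark instance.

    Defaults describe a desk-scale instance: a 2000-node scale-free network
    (attachment 3) with a planted 100-node module, a four-herb formula with
    symmetric Dirichlet(1) dosage ratios, 20 compounds per herb with 5
    protein partners each, log-normal(0, 1) abundances, Beta(4, 2)
    interaction confidences (right-skewed, as prediction confidences tend
    to be), 10% of catalog pairs marked experimentally validated (P = 1),
    and module weights drawn Beta(2, 2).
    """

    n_nodes: int = 2000
    attachment: int = 3
    module_size: int = 100
    module_weight_dist: str = "beta"
    module_weight_params: tuple[float, float] = (2.0, 2.0)
    n_herbs: int = 4
    dosage_concentration: float = 1.0
    compounds_per_herb: int = 20
    targets_per_compound: int = 5
    abundance_mu: float = 0.0
    abundance_sigma: float = 1.0
    interaction_beta: tuple[float, float] = (4.0, 2.0)
    validated_fraction: float = 0.1
    enrichment: float = 0.5
    noise_sd: float = 0.1
    missing_rate: float = 0.1
    n_sources: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 10:
            raise ValueError("n_nodes must be >= 10")
        if not (1 <= self.attachment < self.n_nodes):
            raise ValueError("attachment must lie in [1, n_nodes)")
        if not (0 < self.module_size < self.n_nodes):
            raise ValueError("module_size must lie in (0, n_nodes)")
        if not (0.0 <= self.enrichment <= 1.0):
            raise ValueError("enrichment must lie in [0, 1]")
        if self.module_weight_dist not in ("beta", "truncated_exponential"):
            raise ValueError(f"unknown weight distribution {self.module_weight_dist!r}")
        for name in ("n_herbs", "compounds_per_herb", "targets_per_compound"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _rng(cfg: SimulationConfig, stream: str) -> np.random.Generator:
    idx = _STREAMS.index(stream)
    return np.random.default_rng(
        np.random.SeedSequence(entropy=cfg.seed, spawn_key=(idx,))
    )


def _symbol(i: int) -> str:
    return f"P{i:05d}"


def generate_interactome(cfg: SimulationConfig) -> InteractionNetwork:
    """Connected scale-free network by preferential attachment.

    With n nodes and attachment m the generator yields exactly (n - m) * m
    edges; m = 1 gives a tree.
    """
    rng = _rng(cfg, "interactome")
    graph = nx.barabasi_albert_graph(cfg.n_nodes, cfg.attachment, seed=rng)
    graph = nx.relabel_nodes(graph, {i: _symbol(i) for i in graph.nodes})
    return InteractionNetwork(graph)


def plant_disease_module(
    net: InteractionNetwork,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
    wcfg: WeightingConfig = DEFAULT_CONFIG,
) -> WeightedProteinSet:
    """Grow a connected module by randomized breadth-first expansion.

    Starting from a random seed node, frontier nodes are admitted in
    rng-shuffled breadth-first order until the module reaches its size, so
    the induced subgraph is connected by construction. Node weights are
    drawn from the configured distribution and rescaled into (0, 1].
    """
    if rng is None:
        rng = _rng(cfg, "module")
    order = sorted(net.nodes)
    start = order[int(rng.integers(len(order)))]
    chosen: list[str] = [start]
    chosen_set = {start}
    frontier = [start]
    while len(chosen) < cfg.module_size:
        if not frontier:
            raise ValueError(
                f"cannot grow a connected module of size {cfg.module_size}: "
                f"component exhausted at {len(chosen)} nodes"
            )
        nxt: list[str] = []
        for node in frontier:
            for nb in sorted(net.graph.neighbors(node)):
                if nb not in chosen_set:
                    chosen_set.add(nb)
                    nxt.append(nb)
        rng.shuffle(nxt)
        room = cfg.module_size - len(chosen)
        chosen.extend(nxt[:room])
        frontier = nxt
    a, b = cfg.module_weight_params
    if cfg.module_weight_dist == "beta":
        draws = rng.beta(a, b, size=len(chosen))
    else:  # exponential with rate a truncated to (0, 1), by inverse CDF
        u = rng.random(size=len(chosen))
        draws = -np.log(1.0 - u * (1.0 - np.exp(-a))) / a
    raw = dict(zip(chosen, draws))
    return normalize_weights(raw, wcfg, label="disease-associated:synthetic")


def generate_formula_inputs(
    net: InteractionNetwork,
    module: WeightedProteinSet,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
    name: str = "synthetic-formula",
) -> tuple[FormulaComposition, CompoundAbundanceTable, InteractionCatalog]:
    """Formula, abundances, and a catalog enriched toward the module.

    Each compound-protein edge lands inside ``module ∪ N(module)`` with
    probability ``cfg.enrichment`` and uniformly elsewhere otherwise;
    enrichment 1 forces every edge into the module neighborhood and
    enrichment 0 yields a fully random (negative-control) formula.
    """
    if rng is None:
        rng = _rng(cfg, "formula")
    herbs = [f"herb{i + 1}" for i in range(cfg.n_herbs)]
    ratios_arr = rng.dirichlet([cfg.dosage_concentration] * cfg.n_herbs)
    ratios_arr = ratios_arr / ratios_arr.sum()
    formula = FormulaComposition(name, dict(zip(herbs, ratios_arr)))

    pool_in = sorted(module.members | neighbors(net, module.members))
    pool_out = sorted(net.nodes - set(pool_in))
    if not pool_out:
        pool_out = pool_in

    abundance: dict[tuple[str, str], float] = {}
    confidence: dict[tuple[str, str], float] = {}
    provenance: dict[tuple[str, str], str] = {}
    a, b = cfg.interaction_beta
    for herb in herbs:
        for k in range(cfg.compounds_per_herb):
            compound = f"{herb}-c{k + 1:03d}"
            abundance[(herb, compound)] = float(
                rng.lognormal(cfg.abundance_mu, cfg.abundance_sigma)
            )
            partners: set[str] = set()
            while len(partners) < cfg.targets_per_compound:
                pool = pool_in if rng.random() < cfg.enrichment else pool_out
                partners.add(pool[int(rng.integers(len(pool)))])
            for protein in sorted(partners):
                if rng.random() < cfg.validated_fraction:
                    confidence[(compound, protein)] = 1.0
                    provenance[(compound, protein)] = "validated"
                else:
                    confidence[(compound, protein)] = float(rng.beta(a, b))
                    provenance[(compound, protein)] = "predicted"
    return (
        formula,
        CompoundAbundanceTable(abundance),
        InteractionCatalog(confidence, provenance),
    )


def generate_source_scores(
    truth: WeightedProteinSet,
    universe: set[str],
    noise_sd: float = 0.1,
    missing_rate: float = 0.1,
    n_sources: int = 5,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Noisy multi-source evidence tables around a planted weight vector.

    Each quantitative source perturbs the truth weights with independent
    Gaussian noise on the logit scale (rank-preserving at noise_sd = 0) and
    drops each entry with probability ``missing_rate``; the last source is
    qualitative (listed targets scored 1.0). Universe members outside the
    truth set are missing everywhere.
    """
    if not truth.members <= universe:
        raise ValueError("truth set must be contained in the universe")
    if rng is None:
        rng = np.random.default_rng(0)
    symbols = sorted(universe)
    truth_arr = np.array(
        [truth.weights.get(s, np.nan) for s in symbols], dtype=float
    )
    clipped = np.clip(truth_arr, 1e-9, 1.0 - 1e-9)
    logit = np.log(clipped / (1.0 - clipped))
    columns: dict[str, np.ndarray] = {}
    for j in range(n_sources):
        name = f"source{j + 1}"
        present = ~np.isnan(truth_arr)
        keep = present & (rng.random(len(symbols)) >= missing_rate)
        col = np.full(len(symbols), np.nan)
        if j == n_sources - 1 and n_sources > 1:
            col[keep] = 1.0  # qualitative: listed targets only
        else:
            noisy = logit + rng.normal(0.0, max(noise_sd, 0.0), size=len(symbols))
            col[keep] = 1.0 / (1.0 + np.exp(-noisy[keep]))
        columns[name] = col
    return pd.DataFrame(columns, index=pd.Index(symbols, name="symbol"))


def simulate_instance(cfg: SimulationConfig) -> dict:
    """Generate one coherent benchmark instance from a single config."""
    net = generate_interactome(cfg)
    module = plant_disease_module(net, cfg)
    formula, abundance, catalog = generate_formula_inputs(net, module, cfg)
    sources = generate_source_scores(
        module,
        net.nodes,
        noise_sd=cfg.noise_sd,
        missing_rate=cfg.missing_rate,
        n_sources=cfg.n_sources,
        rng=_rng(cfg, "sources"),
    )
    return {
        "config": cfg,
        "network": net,
        "module": module,
        "formula": formula,
        "abundance": abundance,
        "catalog": catalog,
        "sources": sources,
    }


def write_instance(instance: dict, out_dir: str | Path) -> None:
    """Write a simulated instance as the standard TSVs plus a JSON manifest."""
    from . import io as hio
    from .network import write_edge_list

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_edge_list(instance["network"], out / "edges.tsv")
    hio.write_weights_tsv(instance["module"], out / "disease_module.tsv")
    hio.write_formula_tsv(instance["formula"], out / "formula.tsv")
    hio.write_abundance_tsv(instance["abundance"], out / "abundance.tsv")
    hio.write_catalog_tsv(instance["catalog"], out / "catalog.tsv")
    hio.write_source_table(instance["sources"], out / "sources.tsv")
    manifest = {
        "generator": "herbnet.simulate",
        "config": instance["config"].to_dict(),
        "files": [
            "edges.tsv",
            "disease_module.tsv",
            "formula.tsv",
            "abundance.tsv",
            "catalog.tsv",
            "sources.tsv",
        ],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
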