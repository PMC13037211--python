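"""Degree-aware permutation nulls and proximity Z-scores.

The observed proximity of an intervention set H to a disease module D is
compared against a null distribution built by repeatedly replacing H with
random node sets of the same size whose degree profile matches H bin by
bin (the disease side stays fixed, the convention in drug-disease proximity
work). Each sampled node inherits the weight of the reference node it
replaces, so the weight multiset — and hence the scale of the weighted
metric — is preserved under the null.

    Z = (S_obs - mu_rand) / sigma_rand

with mu_rand and sigma_rand the mean and (n-1) standard deviation of the
resampled scores. A more negative Z means the intervention sits closer to
the disease module than degree-matched chance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .network import DegreeBinning, InteractionNetwork, build_degree_bins
from .weighting import WeightedProteinSet

logger = logging.getLogger(__name__)

__all__ = [
    "ProximityResult",
    "DistanceField",
    "sample_degree_matched",
    "null_zscore",
    "null_zscores_shared",
    "convergence_curve",
]

METRICS = ("proximity_unweighted", "proximity_weighted")


@dataclass(frozen=True)
class ProximityResult:
    """Observed score, permutation null summary, and Z-score."""

    metric: str
    s_obs: float
    mu_rand: float
    sigma_rand: float
    zscore: float
    n_perm: int
    seed: int
    pairs_dropped: int = 0
    null_values: np.ndarray | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "s_obs": self.s_obs,
            "mu_rand": self.mu_rand,
            "sigma_rand": self.sigma_rand,
            "zscore": self.zscore,
            "n_perm": self.n_perm,
            "seed": self.seed,
            "dropped_pairs": self.pairs_dropped,
        }


class DistanceField:
    """BFS distances from every network node to each node of a fixed set.

    Precomputing the field once makes rescoring hundreds of permuted
    intervention sets a cheap array operation: row i of ``matrix`` holds
    the distances from network node i to each disease node (inf where
    unreachable).
    """

    def __init__(self, net: InteractionNetwork, fixed: Sequence[str]):
        self.node_order = sorted(net.graph.nodes)
        self.node_index = {n: i for i, n in enumerate(self.node_order)}
        self.fixed = list(fixed)
        matrix = np.full((len(self.node_order), len(self.fixed)), np.inf)
        for j, d in enumerate(self.fixed):
            lengths = nx.single_source_shortest_path_length(net.graph, d)
            for node, length in lengths.items():
                matrix[self.node_index[node], j] = length
        self.matrix = matrix

    def rows(self, nodes: Sequence[str]) -> np.ndarray:
        idx = [self.node_index[n] for n in nodes]
        return self.matrix[idx, :]


def _closest_proximity(sub: np.ndarray) -> tuple[float, int]:
    """Mean over rows of the minimum finite entry; returns (value, n_dropped)."""
    mins = sub.min(axis=1)
    finite = np.isfinite(mins)
    if not finite.any():
        raise ValueError("no herb protein can reach any disease protein")
    return float(mins[finite].mean()), int((~finite).sum())


def _weighted_proximity(
    sub: np.ndarray, w_h: np.ndarray, w_d: np.ndarray
) -> tuple[float, int]:
    finite = np.isfinite(sub)
    if not finite.any():
        raise ValueError("no (h, d) pair is connected")
    wprod = np.outer(w_h, w_d)
    num = float((np.where(finite, sub, 0.0) * wprod).sum())
    den = float(wprod[finite].sum())
    return num / den, int((~finite).sum())


def _score(metric: str, sub: np.ndarray, w_h: np.ndarray, w_d: np.ndarray):
    if metric == "proximity_unweighted":
        return _closest_proximity(sub)
    if metric == "proximity_weighted":
        return _weighted_proximity(sub, w_h, w_d)
    raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")


def sample_degree_matched(
    net: InteractionNetwork,
    reference: WeightedProteinSet,
    bins: DegreeBinning,
    rng: np.random.Generator,
) -> WeightedProteinSet:
    """Draw a random node set degree-matched to ``reference``.

    For each degree bin, as many distinct nodes as the reference holds in
    that bin are drawn uniformly without replacement from the bin's
    population; each drawn node inherits the weight of the reference node
    it replaces, preserving the weight multiset exactly.
    """
    missing = reference.members - net.nodes
    if missing:
        raise ValueError(f"reference nodes not in network: {sorted(missing)[:5]}")
    by_bin: dict[int, list[str]] = {}
    for node in sorted(reference.members):
        by_bin.setdefault(bins.bin_of[node], []).append(node)
    sampled: dict[str, float] = {}
    for bin_id, ref_nodes in sorted(by_bin.items()):
        population = bins.members[bin_id]
        if len(population) < len(ref_nodes):
            raise ValueError(
                f"degree bin {bins.intervals[bin_id]} holds {len(population)} "
                f"node(s) but must supply {len(ref_nodes)}; rebuild the binning "
                "with a larger min_bin_size"
            )
        draw = rng.choice(len(population), size=len(ref_nodes), replace=False)
        for ref_node, k in zip(ref_nodes, draw):
            sampled[population[k]] = reference.weight_of(ref_node)
    return WeightedProteinSet(sampled, label=f"null:{reference.label}")


def null_zscores_shared(
    net: InteractionNetwork,
    H: WeightedProteinSet,
    D: WeightedProteinSet,
    metrics: Sequence[str] = METRICS,
    n_perm: int = 500,
    seed: int | np.random.SeedSequence = 0,
    bins: DegreeBinning | None = None,
    min_bin_size: int = 100,
    field_: DistanceField | None = None,
    keep_null: bool = False,
) -> dict[str, ProximityResult]:
    """Z-scores for several metrics evaluated on one shared set of null draws.

    Scoring every requested metric on the same permuted sets makes
    weighted-versus-unweighted comparisons paired, removing between-draw
    noise from the contrast.
    """
    for m in metrics:
        if m not in METRICS:
            raise ValueError(f"unknown metric {m!r}; expected one of {METRICS}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    outside = (H.members | D.members) - net.nodes
    if outside:
        raise ValueError(
            f"{len(outside)} node(s) not in the network; apply restrict_to_network"
        )
    if bins is None:
        bins = build_degree_bins(net, min_bin_size=min(min_bin_size, net.n_nodes))
    if field_ is None:
        field_ = DistanceField(net, sorted(D.members))

    d_order = field_.fixed
    w_d = np.array([D.weight_of(d) for d in d_order])
    h_order = sorted(H.members)
    w_h_obs = np.array([H.weight_of(h) for h in h_order])
    sub_obs = field_.rows(h_order)

    observed: dict[str, tuple[float, int]] = {
        m: _score(m, sub_obs, w_h_obs, w_d) for m in metrics
    }

    master = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    children = master.spawn(n_perm)
    nulls = {m: np.empty(n_perm) for m in metrics}
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        null_set = sample_degree_matched(net, H, bins, rng)
        null_order = sorted(null_set.members)
        w_h = np.array([null_set.weight_of(n) for n in null_order])
        sub = field_.rows(null_order)
        for m in metrics:
            nulls[m][i], _ = _score(m, sub, w_h, w_d)

    seed_repr = int(master.entropy) if isinstance(master.entropy, int) else 0
    results = {}
    for m in metrics:
        s_obs, dropped = observed[m]
        mu = float(nulls[m].mean())
        sigma = float(nulls[m].std(ddof=1)) if n_perm > 1 else 0.0
        if sigma == 0.0:
            raise ValueError(
                f"degenerate null for {m}: sigma_rand = 0 over {n_perm} draws"
            )
        results[m] = ProximityResult(
            metric=m,
            s_obs=s_obs,
            mu_rand=mu,
            sigma_rand=sigma,
            zscore=(s_obs - mu) / sigma,
            n_perm=n_perm,
            seed=seed_repr,
            pairs_dropped=dropped,
            null_values=nulls[m].copy() if keep_null else None,
        )
    return results


def null_zscore(
    net: InteractionNetwork,
    H: WeightedProteinSet,
    D: WeightedProteinSet,
    metric: str = "proximity_weighted",
    n_perm: int = 500,
    seed: int | np.random.SeedSequence = 0,
    bins: DegreeBinning | None = None,
    min_bin_size: int = 100,
    field_: DistanceField | None = None,
    keep_null: bool = False,
) -> ProximityResult:
    """Permutation Z-score of one proximity metric (see module docstring)."""
    return null_zscores_shared(
        net,
        H,
        D,
        metrics=(metric,),
        n_perm=n_perm,
        seed=seed,
        bins=bins,
        min_bin_size=min_bin_size,
        field_=field_,
        keep_null=keep_null,
    )[metric]


def convergence_curve(
    net: InteractionNetwork,
    H: WeightedProteinSet,
    D: WeightedProteinSet,
    metric: str = "proximity_weighted",
    perm_grid: Sequence[int] = (50, 100, 200, 500),
    n_repeats: int = 20,
    seed: int = 0,
    bins: DegreeBinning | None = None,
    min_bin_size: int = 100,
) -> pd.DataFrame:
    """Spread of the Z-score across independent estimates as n_perm grows.

    For each permutation count in ``perm_grid``, ``n_repeats`` independent
    Z estimates are computed; their standard deviation quantifies how many
    permutations are needed for a stable Z.
    """
    if list(perm_grid) != sorted(perm_grid):
        raise ValueError("perm_grid must be ascending")
    if bins is None:
        bins = build_degree_bins(net, min_bin_size=min(min_bin_size, net.n_nodes))
    field_ = DistanceField(net, sorted(D.members))
    master = np.random.SeedSequence(seed)
    rows = []
    for gi, n_perm in enumerate(perm_grid):
        zs = []
        for r in range(n_repeats):
            child = np.random.SeedSequence(entropy=master.entropy, spawn_key=(gi, r))
            res = null_zscore(
                net, H, D, metric, n_perm=n_perm, seed=child, bins=bins, field_=field_
            )
            zs.append(res.zscore)
        zs_arr = np.asarray(zs)
        rows.append(
            {
                "n_perm": n_perm,
                "mean_z": float(zs_arr.mean()),
                "sd_z": float(zs_arr.std(ddof=1)) if n_repeats > 1 else 0.0,
                "n_repeats": n_repeats,
            }
        )
    return pd.DataFrame(rows)
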