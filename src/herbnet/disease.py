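"""Multi-source disease-target evidence: normalization, integration, ranking.

Each evidence source (curated databases, a qualitative target list, or
literature-mining mention counts) contributes one score column per target.
Columns are normalized to (0, 1] and combined either multiplicatively —
a consensus filter that rewards targets supported by every source — or
additively, the conventional alternative kept for comparison. The top-N
targets of the integrated ranking form the weighted disease module used by
the network metrics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .config import DEFAULT_CONFIG, WeightingConfig
from .weighting import WeightedProteinSet, normalize_weights

__all__ = [
    "IntegratedScoreTable",
    "normalize_llm_counts",
    "minmax_normalize_source",
    "score_qualitative_source",
    "integrate_multiplicative",
    "integrate_additive",
    "top_n",
    "compare_rankings",
]


@dataclass(frozen=True)
class IntegratedScoreTable:
    """Integrated per-target weights under one integration scheme.

    ``scores`` is indexed by target symbol; ``scheme`` is ``"multiplicative"``
    or ``"additive"``. Ranking is total: descending score, ties broken by
    ascending symbol.
    """

    scores: pd.Series
    scheme: str

    def __post_init__(self) -> None:
        if self.scheme not in ("multiplicative", "additive"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.scores.empty:
            raise ValueError("integrated score table is empty")
        if self.scores.index.has_duplicates:
            raise ValueError("duplicate target symbols in integrated table")
        if self.scheme == "multiplicative" and not (self.scores > 0).all():
            raise ValueError("multiplicative scores must be strictly positive")

    def __len__(self) -> int:
        return len(self.scores)

    def ordered(self) -> pd.Series:
        """Scores sorted by the canonical total order (score desc, symbol asc)."""
        frame = self.scores.rename("score").reset_index()
        frame.columns = ["symbol", "score"]
        frame = frame.sort_values(
            ["score", "symbol"], ascending=[False, True], kind="mergesort"
        )
        return frame.set_index("symbol")["score"]

    def ranks(self) -> pd.Series:
        """1-based competition-free ranks (midranks for tied scores)."""
        r = scipy.stats.rankdata(-self.scores.to_numpy())
        return pd.Series(r, index=self.scores.index)

    def to_frame(self) -> pd.DataFrame:
        ordered = self.ordered()
        return pd.DataFrame(
            {
                "symbol": ordered.index,
                "targetscore": ordered.to_numpy(),
                "rank": np.arange(1, len(ordered) + 1),
            }
        )


def normalize_llm_counts(counts: Mapping[str, int]) -> dict[str, float]:
    """Scale literature mention counts to [0, 1] by the maximum count."""
    if not counts:
        raise ValueError("empty count table")
    if any(c < 0 for c in counts.values()):
        raise ValueError("mention counts must be nonnegative")
    peak = max(counts.values())
    if peak == 0:
        raise ValueError("all mention counts are zero; scores undefined")
    return {s: c / peak for s, c in counts.items()}


def minmax_normalize_source(
    scores: Mapping[str, float], cfg: WeightingConfig = DEFAULT_CONFIG
) -> dict[str, float]:
    """Min-max scale a quantitative source into [0, 1], lifting zeros.

    The observed minimum maps to zero, which would annihilate any
    multiplicative product; exact zeros are therefore replaced by
    ``cfg.epsilon_zero`` so the output lies in (0, 1].
    """
    if not scores:
        raise ValueError("empty score table")
    values = np.asarray(list(scores.values()), dtype=float)
    lo, hi = values.min(), values.max()
    if hi == lo:
        raise ValueError(
            "constant score column: min-max scaling is undefined; drop the "
            "source or treat it as qualitative"
        )
    out = {}
    for s, v in scores.items():
        scaled = (v - lo) / (hi - lo)
        out[s] = cfg.epsilon_zero if scaled == 0.0 else scaled
    return out


def score_qualitative_source(
    listed: set[str], universe: set[str], cfg: WeightingConfig = DEFAULT_CONFIG
) -> dict[str, float]:
    """Score a presence/absence source: 1.0 if listed, epsilon_missing if not."""
    if not listed <= universe:
        raise ValueError("listed targets must be a subset of the universe")
    return {s: 1.0 if s in listed else cfg.epsilon_missing for s in universe}


def integrate_multiplicative(
    table: pd.DataFrame, cfg: WeightingConfig = DEFAULT_CONFIG
) -> IntegratedScoreTable:
    """Consensus product of normalized source scores.

    ``table`` holds one normalized (0, 1] column per source with NaN for
    targets missing from a source; missing entries are imputed with
    ``cfg.epsilon_missing`` before the product, so any gap in the evidence
    sharply demotes a target without ever zeroing it.
    """
    _validate_source_table(table)
    filled = table.astype(float).fillna(cfg.epsilon_missing)
    if (filled <= 0).any().any() or (filled > 1).any().any():
        raise ValueError("source scores must be normalized into (0, 1]")
    return IntegratedScoreTable(filled.prod(axis=1), "multiplicative")


def integrate_additive(table: pd.DataFrame) -> IntegratedScoreTable:
    """Sum of normalized source scores, with missing entries imputed as zero."""
    _validate_source_table(table)
    filled = table.astype(float).fillna(0.0)
    if (filled < 0).any().any() or (filled > 1).any().any():
        raise ValueError("source scores must be normalized into [0, 1]")
    return IntegratedScoreTable(filled.sum(axis=1), "additive")


def top_n(
    table: IntegratedScoreTable,
    n: int,
    cfg: WeightingConfig = DEFAULT_CONFIG,
    label: str = "disease-associated",
) -> WeightedProteinSet:
    """Select the n top-ranked targets as a weighted disease module.

    Integrated scores of the selected targets are rescaled into (0, 1] by
    the same smoothed max-min mapping used for herb weights, giving the
    disease-side node weights for weighted proximity.
    """
    if not (1 <= n <= len(table)):
        raise ValueError(f"n={n} outside [1, {len(table)}]")
    chosen = table.ordered().iloc[:n]
    return normalize_weights(chosen.to_dict(), cfg, label=label)


def compare_rankings(
    a: IntegratedScoreTable,
    b: IntegratedScoreTable,
    n_grid: Sequence[int],
) -> pd.DataFrame:
    """Jaccard overlap and Spearman correlation of two rankings over top-N cuts.

    For each ``n``: the Jaccard index of the two top-n sets, and the Spearman
    correlation of the two tables' ranks over the union of the two top-n
    sets. A union member absent from one table receives that table's worst
    rank plus one.
    """
    universe = set(a.scores.index) | set(b.scores.index)
    rows = []
    ranks_a, ranks_b = a.ranks(), b.ranks()
    for n in n_grid:
        if n > len(universe):
            raise ValueError(f"n={n} exceeds the target universe ({len(universe)})")
        top_a = set(a.ordered().index[:n])
        top_b = set(b.ordered().index[:n])
        union = sorted(top_a | top_b)
        jac = len(top_a & top_b) / len(union)
        ra = np.array([ranks_a.get(s, len(a) + 1.0) for s in union])
        rb = np.array([ranks_b.get(s, len(b) + 1.0) for s in union])
        rho = scipy.stats.spearmanr(ra, rb).statistic if len(union) > 1 else 1.0
        rows.append({"n": n, "jaccard": jac, "spearman": rho})
    return pd.DataFrame(rows)


def _validate_source_table(table: pd.DataFrame) -> None:
    if table.shape[1] < 1:
        raise ValueError("need at least one source column")
    if table.index.has_duplicates:
        dupes = table.index[table.index.duplicated()].unique().tolist()[:5]
        raise ValueError(f"duplicate target symbols: {dupes}")
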