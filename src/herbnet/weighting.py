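"""Weighted protein sets and the (0, 1] weight normalization.

A :class:`WeightedProteinSet` is the common currency of the package: both
the herb side (proteins targeted by a formula's compounds) and the disease
side (prioritized disease-associated proteins) are node sets over the
interactome carrying strictly positive weights in (0, 1].
"""

from __future__ import annotations

import logging
from collections.abc import Iterator, Mapping
from dataclasses import dataclass

from .config import DEFAULT_CONFIG, WeightingConfig

logger = logging.getLogger(__name__)

__all__ = ["WeightedProteinSet", "normalize_weights", "combine_interventions"]


@dataclass(frozen=True)
class WeightedProteinSet:
    """A nonempty set of protein symbols with weights in (0, 1]."""

    weights: Mapping[str, float]
    label: str = "unlabeled"

    def __post_init__(self) -> None:
        if not self.weights:
            raise ValueError("a weighted protein set must be nonempty")
        bad = {s: w for s, w in self.weights.items() if not (0.0 < w <= 1.0)}
        if bad:
            raise ValueError(
                f"weights must lie in (0, 1]; offending entries: {_preview(bad)}"
            )
        object.__setattr__(self, "weights", dict(self.weights))

    @property
    def members(self) -> set[str]:
        return set(self.weights)

    def __len__(self) -> int:
        return len(self.weights)

    def __iter__(self) -> Iterator[str]:
        return iter(self.weights)

    def __contains__(self, symbol: object) -> bool:
        return symbol in self.weights

    def weight_of(self, symbol: str) -> float:
        return self.weights[symbol]

    def subset(self, symbols: set[str], label: str | None = None) -> "WeightedProteinSet":
        kept = {s: w for s, w in self.weights.items() if s in symbols}
        return WeightedProteinSet(kept, label or self.label)


def normalize_weights(
    raw: Mapping[str, float],
    cfg: WeightingConfig = DEFAULT_CONFIG,
    label: str = "herb-related",
) -> WeightedProteinSet:
    """Rescale raw weights into (0, 1] by smoothed max-min scaling.

    ``w_norm = (w - min) / (max - min) * (1 - eps) + eps`` with
    ``eps = cfg.epsilon_norm``, so the minimum maps to exactly ``eps`` and
    the maximum to exactly 1.0. A degenerate profile (all raw weights equal)
    carries no ranking information; every weight is set to 1.0 and a warning
    is emitted.
    """
    if not raw:
        raise ValueError("cannot normalize an empty weight map")
    values = list(raw.values())
    lo, hi = min(values), max(values)
    if hi == lo:
        logger.warning(
            "degenerate weight profile (%d proteins share raw weight %g); "
            "assigning uniform weight 1.0",
            len(raw),
            lo,
        )
        return WeightedProteinSet({s: 1.0 for s in raw}, label)
    eps = cfg.epsilon_norm
    span = hi - lo
    scaled = {s: (w - lo) / span * (1.0 - eps) + eps for s, w in raw.items()}
    return WeightedProteinSet(scaled, label)


def combine_interventions(
    a: WeightedProteinSet, b: WeightedProteinSet, label: str = "combined"
) -> WeightedProteinSet:
    """Merge two intervention target sets (e.g. a formula plus a drug).

    The union of members is taken; a protein present in both keeps the larger
    of its two weights, reflecting the stronger of the two lines of targeting
    evidence.
    """
    merged = dict(a.weights)
    for symbol, w in b.weights.items():
        if symbol in merged:
            merged[symbol] = max(merged[symbol], w)
        else:
            merged[symbol] = w
    return WeightedProteinSet(merged, label)


def _preview(mapping: Mapping[str, float], limit: int = 5) -> str:
    items = list(mapping.items())[:limit]
    body = ", ".join(f"{s}: {w!r}" for s, w in items)
    suffix = ", ..." if len(mapping) > limit else ""
    return "{" + body + suffix + "}"
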