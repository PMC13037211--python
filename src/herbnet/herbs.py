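"""Herb-side protein weighting from formula composition and compound data.

A formula is a set of herbs with dosage ratios R_h summing to one. Each
herb contributes compounds with relative abundances A_{c,h}, and each
compound engages proteins with interaction confidences P(c, j) in (0, 1].
The raw weight of protein j accumulates over every (herb, compound)
contribution:

    W_j_raw = sum_h sum_c R_h * A_{c,h} * P(c, j)

Three nested weighting methods are supported:

* method 1 — dosage ratios only (A and P treated as 1.0);
* method 2 — dosage ratios and compound abundances (P treated as 1.0);
* method 3 — the full product including interaction confidences.

Raw weights are then rescaled into (0, 1] by :func:`normalize_weights`.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Literal, Mapping

from .config import DEFAULT_CONFIG, WeightingConfig
from .weighting import WeightedProteinSet, combine_interventions, normalize_weights

logger = logging.getLogger(__name__)

__all__ = [
    "FormulaComposition",
    "CompoundAbundanceTable",
    "InteractionCatalog",
    "compute_raw_weights",
    "normalize_weights",
    "combine_interventions",
    "herb_protein_set",
]

RATIO_TOL = 1e-9


@dataclass(frozen=True)
class FormulaComposition:
    """A named formula: herb identifiers with normalized dosage ratios."""

    name: str
    ratios: Mapping[str, float]

    def __post_init__(self) -> None:
        if not self.ratios:
            raise ValueError(f"formula {self.name!r} has no herbs")
        if any(r <= 0 for r in self.ratios.values()):
            raise ValueError(f"formula {self.name!r}: dosage ratios must be positive")
        total = sum(self.ratios.values())
        if abs(total - 1.0) > RATIO_TOL:
            raise ValueError(
                f"formula {self.name!r}: dosage ratios sum to {total!r}, expected 1"
            )
        object.__setattr__(self, "ratios", dict(self.ratios))

    @property
    def herbs(self) -> set[str]:
        return set(self.ratios)

    @classmethod
    def single_agent(cls, name: str, herb: str | None = None) -> "FormulaComposition":
        """A one-component 'formula', e.g. a single-compound drug carrier."""
        return cls(name, {herb or name: 1.0})


@dataclass(frozen=True)
class CompoundAbundanceTable:
    """Relative abundance A_{c,h} of each compound within each herb.

    Also defines herb-compound membership: a compound belongs to the herbs
    it has an abundance entry for (a compound may occur in several herbs
    with distinct abundances).
    """

    abundance: Mapping[tuple[str, str], float]

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.abundance.values()):
            raise ValueError("abundances must be strictly positive")
        object.__setattr__(self, "abundance", dict(self.abundance))

    def compounds_of(self, herb: str) -> list[str]:
        return sorted(c for (h, c) in self.abundance if h == herb)

    def get(self, herb: str, compound: str) -> float:
        return self.abundance[(herb, compound)]


@dataclass(frozen=True)
class InteractionCatalog:
    """Compound-protein interaction confidences P(c, j) in (0, 1].

    Experimentally validated pairs carry P = 1.0 by definition; predicted
    pairs carry a similarity-based confidence below 1.
    """

    confidence: Mapping[tuple[str, str], float]
    provenance: Mapping[tuple[str, str], str] | None = None

    def __post_init__(self) -> None:
        if not self.confidence:
            raise ValueError("interaction catalog is empty")
        bad = {k: p for k, p in self.confidence.items() if not (0.0 < p <= 1.0)}
        if bad:
            raise ValueError(f"confidences must lie in (0, 1]: {list(bad)[:5]}")
        if self.provenance is not None:
            for key, tag in self.provenance.items():
                if tag not in ("validated", "predicted"):
                    raise ValueError(f"unknown provenance tag {tag!r} for {key}")
                if tag == "validated" and self.confidence.get(key) != 1.0:
                    raise ValueError(
                        f"validated interaction {key} must have P = 1.0, "
                        f"got {self.confidence.get(key)}"
                    )
        object.__setattr__(self, "confidence", dict(self.confidence))

    def partners_of(self, compound: str) -> list[tuple[str, float]]:
        return sorted(
            (j, p) for (c, j), p in self.confidence.items() if c == compound
        )

    @property
    def proteins(self) -> set[str]:
        return {j for (_, j) in self.confidence}


def compute_raw_weights(
    formula: FormulaComposition,
    abundance: CompoundAbundanceTable,
    catalog: InteractionCatalog,
    method: Literal[1, 2, 3] = 3,
    once_per_herb: bool = False,
) -> dict[str, float]:
    """Accumulate raw protein weights W_j_raw for one formula.

    ``once_per_herb`` applies to method 1 only: by default an herb
    contributes R_h once per interacting compound (the literal reading of
    the accumulation formula, where compound multiplicity counts); with
    ``once_per_herb=True`` each herb contributes R_h at most once per
    protein, the alternative reading of a purely proportion-based weight.
    """
    if method not in (1, 2, 3):
        raise ValueError(f"method must be 1, 2 or 3, got {method!r}")
    if once_per_herb and method != 1:
        raise ValueError("once_per_herb only applies to method 1")

    partners_cache: dict[str, list[tuple[str, float]]] = {}
    raw: dict[str, float] = defaultdict(float)
    n_pairs = 0
    for herb, ratio in sorted(formula.ratios.items()):
        compounds = abundance.compounds_of(herb)
        if not compounds:
            logger.warning(
                "herb %r of formula %r has no compounds in the abundance table",
                herb,
                formula.name,
            )
        herb_hits: set[str] = set()
        for compound in compounds:
            if compound not in partners_cache:
                partners_cache[compound] = catalog.partners_of(compound)
            a = 1.0 if method == 1 else abundance.get(herb, compound)
            for protein, p in partners_cache[compound]:
                conf = p if method == 3 else 1.0
                if once_per_herb:
                    if protein in herb_hits:
                        continue
                    herb_hits.add(protein)
                raw[protein] += ratio * a * conf
                n_pairs += 1
    if not raw:
        raise ValueError(
            f"formula {formula.name!r}: no compound of any herb interacts with "
            "a protein in the catalog"
        )
    logger.info(
        "formula %r, method %d: %d proteins from %d contributions",
        formula.name,
        method,
        len(raw),
        n_pairs,
    )
    return dict(raw)


def herb_protein_set(
    formula: FormulaComposition,
    abundance: CompoundAbundanceTable,
    catalog: InteractionCatalog,
    method: Literal[1, 2, 3] = 3,
    cfg: WeightingConfig = DEFAULT_CONFIG,
    once_per_herb: bool = False,
) -> WeightedProteinSet:
    """Raw weighting followed by (0, 1] normalization, as one step."""
    raw = compute_raw_weights(formula, abundance, catalog, method, once_per_herb)
    return normalize_weights(raw, cfg, label=f"herb-related:{formula.name}")
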