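"""Shared numerical configuration for weighting and integration."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class WeightingConfig:
    """Epsilon constants used throughout score normalization and integration.

    Attributes
    ----------
    epsilon_zero:
        Replaces exact zeros produced by min-max scaling of a quantitative
        evidence source, so that a target at the observed minimum does not
        annihilate the multiplicative consensus score.
    epsilon_missing:
        Imputed score for a target absent from an evidence source (or
        unlisted in a qualitative source). Deliberately many orders of
        magnitude below ``epsilon_zero``: absence is stronger counter-evidence
        than a minimal observed score.
    epsilon_norm:
        Smoothing floor of the modified max-min rescaling that maps raw
        protein weights into (0, 1]; the weakest protein receives exactly
        this value instead of zero so weighted distance sums stay defined.
    """

    epsilon_zero: float = 1e-5
    epsilon_missing: float = 1e-20
    epsilon_norm: float = 1e-6

    def __post_init__(self) -> None:
        for name in ("epsilon_zero", "epsilon_missing", "epsilon_norm"):
            value = getattr(self, name)
            if not (0.0 < value < 1.0):
                raise ValueError(f"{name} must lie in (0, 1); got {value!r}")


DEFAULT_CONFIG = WeightingConfig()
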