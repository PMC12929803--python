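"""Fraction-collection scheme for SEC co-fractionation runs.

A size-exclusion run is collected into equally spaced fractions.  The
default scheme is 60 fractions collected every 19 s starting at 9 min,
i.e. the retention time of fraction ``f`` (1-based) is taken at the
midpoint of its collection window::

    rt(f) = start_s + (f - 0.5) * width_s

so adjacent fractions are exactly ``width_s`` seconds apart.
"""

from __future__ import annotations

from dataclasses import dataclass

from .exceptions import ConfigurationError


@dataclass(frozen=True)
class FractionScheme:
    """Number, start time and width of SEC collection windows."""

    n_fractions: int = 60
    start_s: float = 540.0
    width_s: float = 19.0

    def __post_init__(self) -> None:
        if self.n_fractions < 2:
            raise ConfigurationError("n_fractions must be >= 2")
        if self.width_s <= 0:
            raise ConfigurationError("width_s must be positive")

    def fraction_to_rt(self, f: int | float) -> float:
        """Retention time (seconds) at the midpoint of fraction ``f`` (1-based)."""
        if not 1 <= f <= self.n_fractions:
            raise ConfigurationError(
                f"fraction {f} outside 1..{self.n_fractions}"
            )
        return self.start_s + (f - 0.5) * self.width_s
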