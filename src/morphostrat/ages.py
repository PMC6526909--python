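"""Per-taxon stratigraphic ranges (first/last appearance data, in Ma)."""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError

__all__ = ["AgeTable"]


@dataclass
class AgeTable:
    """Maps taxon → (fad, lad) in Ma before present; fad ≥ lad ≥ 0.

    A point occurrence has fad == lad.  All interval logic downstream
    treats the range as the closed interval [lad, fad]; larger = older.
    """

    ranges: dict[str, tuple[float, float]]

    def __post_init__(self):
        for taxon, (fad, lad) in self.ranges.items():
            if not (fad >= lad >= 0):
                raise ValidationError(
                    f"{taxon}: invalid range fad={fad}, lad={lad} (need fad ≥ lad ≥ 0)"
                )

    def fad(self, taxon: str) -> float:
        return self._get(taxon)[0]

    def lad(self, taxon: str) -> float:
        return self._get(taxon)[1]

    def _get(self, taxon: str) -> tuple[float, float]:
        try:
            return self.ranges[taxon]
        except KeyError:
            raise ValidationError(f"taxon absent from age table: {taxon}") from None

    def __contains__(self, taxon: str) -> bool:
        return taxon in self.ranges

    def __len__(self) -> int:
        return len(self.ranges)

    def taxa(self) -> list[str]:
        return list(self.ranges)
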