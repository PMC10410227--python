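"""Shared data containers: taxon status and the discrete character matrix.

A character matrix is a taxa x characters table of binary scores over
``{0, 1, MISSING}``.  Cells are stored as a small-integer numpy array with
``MISSING`` encoded as -1 so that vectorised arithmetic on scored cells is
cheap and mask construction is a single comparison.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

#: Sentinel cell value for an unscored (missing) character state.
MISSING: int = -1


class TipStatus(str, enum.Enum):
    """Whether a terminal taxon is sampled from the fossil record or living."""

    FOSSIL = "FOSSIL"
    EXTANT = "EXTANT"


@dataclass
class CharacterMatrix:
    """Rectangular table of binary character scores with taxon status.

    Parameters
    ----------
    taxa:
        Ordered, unique taxon labels (rows).
    data:
        ``(n_taxa, n_characters)`` integer array over ``{0, 1, MISSING}``.
    status:
        Per-taxon :class:`TipStatus`, keyed by label.  Taxa absent from the
        mapping are treated as extant.
    characters:
        Ordered character (column) identifiers; generated as ``c0001`` ...
        when omitted.
    provenance:
        Free-text stage tag, e.g. ``"original"`` or
        ``"NONRANDOM_CHARACTERS/rep003/stage2"``.
    """

    taxa: list[str]
    data: np.ndarray
    status: dict[str, TipStatus] = field(default_factory=dict)
    characters: list[str] | None = None
    provenance: str = "original"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.int8)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D taxa x characters array")
        if len(self.taxa) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.taxa)} taxa but {self.data.shape[0]} matrix rows"
            )
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("taxon labels must be unique")
        bad = ~np.isin(self.data, (0, 1, MISSING))
        if bad.any():
            raise ValueError("matrix cells must be 0, 1 or MISSING")
        if self.characters is None:
            width = max(4, len(str(self.data.shape[1])))
            self.characters = [f"c{i + 1:0{width}d}" for i in range(self.data.shape[1])]
        elif len(self.characters) != self.data.shape[1]:
            raise ValueError("characters length does not match matrix width")
        elif len(set(self.characters)) != len(self.characters):
            raise ValueError("character ids must be unique")

    # -- basic geometry -------------------------------------------------
    @property
    def n_taxa(self) -> int:
        return self.data.shape[0]

    @property
    def n_characters(self) -> int:
        return self.data.shape[1]

    @property
    def scored(self) -> np.ndarray:
        """Boolean mask of cells that carry an observed state."""
        return self.data != MISSING

    def status_of(self, label: str) -> TipStatus:
        return self.status.get(label, TipStatus.EXTANT)

    @property
    def fossil_mask(self) -> np.ndarray:
        """Boolean row mask of fossil taxa."""
        return np.array(
            [self.status_of(t) is TipStatus.FOSSIL for t in self.taxa], dtype=bool
        )

    @property
    def fossil_taxa(self) -> list[str]:
        return [t for t in self.taxa if self.status_of(t) is TipStatus.FOSSIL]

    @property
    def extant_taxa(self) -> list[str]:
        return [t for t in self.taxa if self.status_of(t) is TipStatus.EXTANT]

    # -- summaries ------------------------------------------------------
    def missing_fraction(self, scope: str = "ALL") -> float:
        """Fraction of MISSING cells within ``scope`` ("ALL" or "FOSSIL")."""
        if scope == "ALL":
            cells = self.data
        elif scope == "FOSSIL":
            cells = self.data[self.fossil_mask]
        else:
            raise ValueError(f"unknown scope {scope!r}")
        if cells.size == 0:
            return 0.0
        return float(np.mean(cells == MISSING))

    def copy(self, provenance: str | None = None) -> "CharacterMatrix":
        return CharacterMatrix(
            taxa=list(self.taxa),
            data=self.data.copy(),
            status=dict(self.status),
            characters=list(self.characters),
            provenance=self.provenance if provenance is None else provenance,
        )

    def subset_taxa(self, labels: list[str]) -> "CharacterMatrix":
        """Row subset preserving the given label order."""
        index = {t: i for i, t in enumerate(self.taxa)}
        try:
            rows = [index[t] for t in labels]
        except KeyError as exc:
            raise KeyError(f"unknown taxon {exc.args[0]!r}") from None
        return CharacterMatrix(
            taxa=list(labels),
            data=self.data[rows],
            status={t: self.status_of(t) for t in labels},
            characters=list(self.characters),
            provenance=self.provenance,
        )


def round_half_up(x: float) -> int:
    """Round to nearest integer with exact halves rounded up."""
    return int(np.floor(x + 0.5))
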