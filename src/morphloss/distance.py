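"""Pairwise dissimilarity under missing data: Wills' GED and MORD.

The two metrics accommodate missing scores in opposite ways.  The
generalized Euclidean distance (GED, Wills variant) keeps the full
character count and substitutes every incalculable per-character
dissimilarity with the single pooled mean of those that could be
calculated, then takes the Euclidean norm.  The maximum observable
rescaled distance (MORD) drops incomparable characters and rescales the
observed dissimilarity by the maximum attainable over the comparable
ones; for binary data this equals the Gower dissimilarity.  Neither is
guaranteed metric (triangle inequality) once data are missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import MISSING, CharacterMatrix, TipStatus

__all__ = [
    "INCOMPARABLE",
    "DistanceMatrixResult",
    "per_character_dissimilarity",
    "mord",
    "ged_wills",
    "trim_incomparable",
    "sqrt_transform",
]

#: Sentinel returned when a per-character comparison involves a MISSING cell.
INCOMPARABLE = None


def per_character_dissimilarity(a: int, b: int):
    """Binary cladistic dissimilarity: 0/1 when both scored, else INCOMPARABLE."""
    for value in (a, b):
        if value not in (0, 1, MISSING):
            raise ValueError(f"invalid state {value!r}")
    if a == MISSING or b == MISSING:
        return INCOMPARABLE
    return int(a != b)


@dataclass
class DistanceMatrixResult:
    """Symmetric dissimilarities plus per-pair comparable-character counts."""

    taxa: list[str]
    D: np.ndarray
    comparable_counts: np.ndarray
    metric: str  # "ged_wills" | "mord" | "sqrt_mord"
    mean_dissimilarity: float | None = None  # pooled d-bar (GED only)
    cailliez_constant: float | None = None
    status: dict[str, TipStatus] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        n = len(self.taxa)
        if self.D.shape != (n, n):
            raise ValueError("D must be square over taxa")
        if not np.allclose(self.D, self.D.T):
            raise ValueError("D must be symmetric")
        if (self.D < 0).any():
            raise ValueError("distances must be non-negative")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def index_of(self, label: str) -> int:
        try:
            return self.taxa.index(label)
        except ValueError:
            raise KeyError(f"unknown taxon {label!r}") from None

    def subset(self, labels: list[str]) -> "DistanceMatrixResult":
        """Restrict to the given taxa (e.g. dropping extant rows for
        fossil-only analyses)."""
        idx = [self.index_of(t) for t in labels]
        return DistanceMatrixResult(
            taxa=list(labels),
            D=self.D[np.ix_(idx, idx)],
            comparable_counts=self.comparable_counts[np.ix_(idx, idx)],
            metric=self.metric,
            mean_dissimilarity=self.mean_dissimilarity,
            cailliez_constant=self.cailliez_constant,
            status={t: self.status[t] for t in labels if t in self.status},
        )


def _pair_counts(matrix: CharacterMatrix) -> tuple[np.ndarray, np.ndarray]:
    """(comparable counts, differing counts) for every taxon pair."""
    scored = matrix.scored.astype(np.float64)
    values = np.where(matrix.scored, matrix.data, 0).astype(np.float64)
    comp = scored @ scored.T
    # differing = sum over comparable chars of x_i + x_j - 2 x_i x_j
    cross = values @ values.T
    diff = values @ scored.T + scored @ values.T - 2.0 * cross
    return comp, np.maximum(diff, 0.0)


def _zero_comparable_pairs(comp: np.ndarray, taxa: list[str]) -> list[tuple[str, str]]:
    i, j = np.nonzero(np.triu(comp == 0, k=1))
    return [(taxa[a], taxa[b]) for a, b in zip(i, j)]


def mord(matrix: CharacterMatrix) -> DistanceMatrixResult:
    """Maximum observable rescaled distance (= Gower for binary data).

    ``D[i, j]`` is the number of differing comparable characters divided by
    the number of comparable characters.  Raises if any pair shares no
    scored character (trim first with :func:`trim_incomparable`).
    """
    comp, diff = _pair_counts(matrix)
    bad = _zero_comparable_pairs(comp, matrix.taxa)
    if bad:
        raise ValueError(
            f"taxon pairs with no comparable characters: {bad[:10]}"
            + (" ..." if len(bad) > 10 else "")
        )
    with np.errstate(invalid="ignore"):
        D = diff / comp
    np.fill_diagonal(D, 0.0)
    return DistanceMatrixResult(
        taxa=list(matrix.taxa),
        D=D,
        comparable_counts=comp.astype(np.int64),
        metric="mord",
        status={t: matrix.status_of(t) for t in matrix.taxa},
    )


def ged_wills(
    matrix: CharacterMatrix, substitute: str = "global"
) -> DistanceMatrixResult:
    """Generalized Euclidean distance, Wills variant.

    The pooled mean dissimilarity d-bar is taken over every calculable
    per-character comparison across all taxon pairs; each incalculable slot
    contributes d-bar squared, so
    ``D[i, j] = sqrt(diff_ij + (N - comp_ij) * d_bar**2)`` for binary data
    (observed dissimilarities are 0/1, hence square to themselves).

    ``substitute="pair"`` uses each pair's own mean dissimilarity instead
    (falling back to the pooled mean for pairs with nothing calculable);
    the pooled ``"global"`` mean is the default.
    """
    if matrix.n_taxa < 2:
        raise ValueError("GED requires at least two taxa")
    if substitute not in ("global", "pair"):
        raise ValueError(f"unknown substitute {substitute!r}")
    comp, diff = _pair_counts(matrix)
    off = ~np.eye(matrix.n_taxa, dtype=bool)
    total_comp = comp[off].sum() / 2.0
    if total_comp == 0:
        raise ValueError("no per-character dissimilarity is calculable anywhere")
    d_bar = diff[off].sum() / 2.0 / total_comp
    n_chars = matrix.n_characters
    if substitute == "global":
        sub_sq = np.full_like(diff, d_bar**2)
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            pair_mean = np.where(comp > 0, diff / np.maximum(comp, 1), d_bar)
        sub_sq = pair_mean**2
    D = np.sqrt(diff + (n_chars - comp) * sub_sq)
    np.fill_diagonal(D, 0.0)
    return DistanceMatrixResult(
        taxa=list(matrix.taxa),
        D=D,
        comparable_counts=comp.astype(np.int64),
        metric="ged_wills",
        mean_dissimilarity=float(d_bar),
        status={t: matrix.status_of(t) for t in matrix.taxa},
    )


def trim_incomparable(
    matrix: CharacterMatrix,
) -> tuple[CharacterMatrix, list[str]]:
    """Drop taxa until every pair shares at least one scored character.

    While incomparable pairs exist, the taxon with the most MISSING cells
    among those involved in such pairs is removed (ties broken by
    lexicographically first label).  Returns the reduced matrix and the
    removal log.  Raises if trimming would leave fewer than two taxa.
    """
    current = matrix
    removed: list[str] = []
    while True:
        comp, _ = _pair_counts(current)
        bad = _zero_comparable_pairs(comp, current.taxa)
        if not bad:
            return current, removed
        if current.n_taxa <= 2:
            raise ValueError(
                "trimming would leave fewer than two taxa; matrix is too incomplete"
            )
        involved = sorted({t for pair in bad for t in pair})
        missing_counts = {
            t: int((current.data[current.taxa.index(t)] == MISSING).sum())
            for t in involved
        }
        worst = max(missing_counts.values())
        victim = min(t for t, c in missing_counts.items() if c == worst)
        removed.append(victim)
        current = current.subset_taxa([t for t in current.taxa if t != victim])


def sqrt_transform(dm: DistanceMatrixResult) -> DistanceMatrixResult:
    """Element-wise square root of a MORD matrix (pre-ordination transform).

    Square-rooting maps the bounded [0, 1] MORD values onto a scale that
    behaves better under classical scaling; only MORD input is accepted.
    """
    if dm.metric != "mord":
        raise ValueError(f"sqrt transform applies to MORD matrices, got {dm.metric!r}")
    return DistanceMatrixResult(
        taxa=list(dm.taxa),
        D=np.sqrt(dm.D),
        comparable_counts=dm.comparable_counts.copy(),
        metric="sqrt_mord",
        cailliez_constant=dm.cailliez_constant,
        status=dict(dm.status),
    )
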