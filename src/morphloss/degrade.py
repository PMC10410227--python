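"""Taphonomic degradation: staged conversion of character scores to MISSING.

Three regimes emulate how fossilization removes information:

* ``NONRANDOM_CHARACTERS`` - whole characters are knocked out of every
  fossil taxon at once (soft-tissue decay and module loss: the same
  anatomical features are unobservable in all fossils).
* ``RANDOM_SCORES_FOSSIL`` - individual fossil cell scores are lost
  uniformly at random; extant taxa stay complete.
* ``RANDOM_SCORES_ALL`` - cell scores are lost uniformly at random across
  the whole matrix, fossil and extant alike.

All regimes follow the same nested schedule: a soft-tissue stage removing a
fraction p0 of each fossil taxon's scored characters, followed by
increments each removing a fixed fraction of what the soft-tissue stage
left behind.  The default schedule (p0 = 0.43, three 20% increments) takes
nominal fossil missingness through 43%, 54.4%, 65.8% and 77.2%.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING, CharacterMatrix, round_half_up

__all__ = [
    "Regime",
    "DegradationSchedule",
    "DegradedSeries",
    "nominal_missingness",
    "degrade_nonrandom_characters",
    "degrade_random_scores",
    "replicate_series",
    "missingness_audit",
]


class Regime(str, enum.Enum):
    NONRANDOM_CHARACTERS = "NONRANDOM_CHARACTERS"
    RANDOM_SCORES_FOSSIL = "RANDOM_SCORES_FOSSIL"
    RANDOM_SCORES_ALL = "RANDOM_SCORES_ALL"


@dataclass(frozen=True)
class DegradationSchedule:
    """Staged missingness plan applied to fossil character scores.

    ``soft_tissue_fraction`` (p0) is removed first; each of
    ``n_increments`` further stages removes ``increment_fraction`` of the
    scores remaining after the soft-tissue stage, so nominal fossil
    missingness after stage k is ``p0 + k * increment_fraction * (1 - p0)``.
    """

    soft_tissue_fraction: float = 0.43
    n_increments: int = 3
    increment_fraction: float = 0.20

    def __post_init__(self) -> None:
        p0, f = self.soft_tissue_fraction, self.increment_fraction
        if not 0 <= p0 < 1:
            raise ValueError("soft_tissue_fraction must be in [0, 1)")
        if self.n_increments < 0:
            raise ValueError("n_increments must be >= 0")
        if self.n_increments and f <= 0:
            raise ValueError("increment_fraction must be > 0")
        if p0 + self.n_increments * f * (1 - p0) > 1 + 1e-12:
            raise ValueError("schedule exceeds 100% missingness")

    @property
    def n_stages(self) -> int:
        return self.n_increments + 1

    def nominal_fossil_missingness(self, stage: int) -> float:
        """Nominal missing fraction of fossil scores after ``stage`` (0-based)."""
        if not 0 <= stage <= self.n_increments:
            raise ValueError(
                f"stage {stage} outside 0..{self.n_increments}"
            )
        p0 = self.soft_tissue_fraction
        return p0 + stage * self.increment_fraction * (1 - p0)

    @property
    def nominal_sequence(self) -> tuple[float, ...]:
        return tuple(
            self.nominal_fossil_missingness(k) for k in range(self.n_stages)
        )


def nominal_missingness(
    schedule: DegradationSchedule,
    stage: int,
    scope: str = "FOSSIL",
    fossil_share: float = 1.0,
) -> float:
    """Nominal missing fraction at ``stage`` for the given scope.

    ``scope="FOSSIL"`` reports the fraction of fossil scores lost;
    ``scope="ALL"`` dilutes it by ``fossil_share`` (fossil cells / all
    cells), giving the whole-matrix fraction.
    """
    if not 0 <= fossil_share <= 1:
        raise ValueError("fossil_share must be in [0, 1]")
    frac = schedule.nominal_fossil_missingness(stage)
    if scope == "FOSSIL":
        return frac
    if scope == "ALL":
        return frac * fossil_share
    raise ValueError(f"unknown scope {scope!r}")


@dataclass
class DegradedSeries:
    """One replicate's nested four-stage series of degraded matrices."""

    regime: Regime
    replicate_id: int
    seed: int
    stages: list[CharacterMatrix]

    def __post_init__(self) -> None:
        for earlier, later in zip(self.stages, self.stages[1:]):
            early_missing = earlier.data == MISSING
            late_missing = later.data == MISSING
            if (early_missing & ~late_missing).any():
                raise ValueError("stages are not nested: a MISSING cell reappeared")


def _stage_char_counts(schedule: DegradationSchedule, n_characters: int) -> list[int]:
    """Characters blanked by each stage under the non-random regime."""
    c0 = round_half_up(schedule.soft_tissue_fraction * n_characters)
    remaining = n_characters - c0
    inc = round_half_up(schedule.increment_fraction * remaining)
    counts = [c0] + [inc] * schedule.n_increments
    if sum(counts) > n_characters:
        raise ValueError(
            f"schedule requests {sum(counts)} characters but only "
            f"{n_characters} exist"
        )
    return counts


def _require_fossils(matrix: CharacterMatrix) -> np.ndarray:
    fossil_rows = np.flatnonzero(matrix.fossil_mask)
    if fossil_rows.size == 0:
        raise ValueError("matrix has no fossil taxa to degrade")
    return fossil_rows


def degrade_nonrandom_characters(
    matrix: CharacterMatrix,
    schedule: DegradationSchedule,
    seed: int,
    replicate_id: int = 0,
) -> DegradedSeries:
    """Structured loss: the same randomly chosen characters are blanked in
    every fossil taxon, then further characters in each increment.

    Stage 0 blanks ``round(p0 * n_characters)`` characters; each increment
    blanks ``round(increment_fraction * remaining)`` more, where
    ``remaining`` counts characters intact in fossils after stage 0.
    Extant rows are never touched.
    """
    fossil_rows = _require_fossils(matrix)
    counts = _stage_char_counts(schedule, matrix.n_characters)
    rng = np.random.default_rng(seed)
    order = rng.permutation(matrix.n_characters)
    stages: list[CharacterMatrix] = []
    degraded = matrix.data.copy()
    taken = 0
    for k, count in enumerate(counts):
        cols = order[taken : taken + count]
        taken += count
        degraded[np.ix_(fossil_rows, cols)] = MISSING
        stage = matrix.copy(
            provenance=f"{Regime.NONRANDOM_CHARACTERS.value}/rep{replicate_id:03d}/stage{k}"
        )
        stage.data = degraded.copy()
        stages.append(stage)
    return DegradedSeries(Regime.NONRANDOM_CHARACTERS, replicate_id, seed, stages)


def degrade_random_scores(
    matrix: CharacterMatrix,
    schedule: DegradationSchedule,
    scope: str,
    seed: int,
    replicate_id: int = 0,
) -> DegradedSeries:
    """Random loss of individual scores, within fossils or across all taxa.

    Per-stage targets mirror the structured regime: each fossil taxon with
    ``r`` initially scored cells contributes ``round(nominal_k * r)`` lost
    cells by stage k.  With ``scope="FOSSIL"`` each fossil row loses
    exactly its own target; with ``scope="ALL"`` the summed target is
    spread uniformly over every initially scored cell in the matrix.
    Matrices with pre-existing MISSING cells are handled by applying the
    schedule to the scores that remain.
    """
    if scope not in ("FOSSIL", "ALL"):
        raise ValueError(f"unknown scope {scope!r}")
    fossil_rows = _require_fossils(matrix)
    regime = (
        Regime.RANDOM_SCORES_FOSSIL if scope == "FOSSIL" else Regime.RANDOM_SCORES_ALL
    )
    rng = np.random.default_rng(seed)
    scored = matrix.scored
    fossil_scored_counts = scored[fossil_rows].sum(axis=1)
    per_taxon_targets = np.array(
        [
            [
                round_half_up(schedule.nominal_fossil_missingness(k) * r)
                for r in fossil_scored_counts
            ]
            for k in range(schedule.n_stages)
        ]
    )  # (n_stages, n_fossil)
    degraded = matrix.data.copy()
    stages: list[CharacterMatrix] = []
    if scope == "FOSSIL":
        orders = [
            rng.permutation(np.flatnonzero(scored[row])) for row in fossil_rows
        ]
        for k in range(schedule.n_stages):
            for j, row in enumerate(fossil_rows):
                cols = orders[j][: per_taxon_targets[k, j]]
                degraded[row, cols] = MISSING
            stages.append(_stage_copy(matrix, degraded, regime, replicate_id, k))
    else:
        flat_scored = np.flatnonzero(scored.ravel())
        order = rng.permutation(flat_scored)
        totals = per_taxon_targets.sum(axis=1)
        flat = degraded.ravel()
        for k in range(schedule.n_stages):
            flat[order[: totals[k]]] = MISSING
            stages.append(_stage_copy(matrix, degraded, regime, replicate_id, k))
    return DegradedSeries(regime, replicate_id, seed, stages)


def _stage_copy(
    matrix: CharacterMatrix,
    degraded: np.ndarray,
    regime: Regime,
    replicate_id: int,
    stage: int,
) -> CharacterMatrix:
    out = matrix.copy(provenance=f"{regime.value}/rep{replicate_id:03d}/stage{stage}")
    out.data = degraded.copy()
    return out


def degrade(
    matrix: CharacterMatrix,
    regime: Regime,
    schedule: DegradationSchedule,
    seed: int,
    replicate_id: int = 0,
) -> DegradedSeries:
    """Dispatch a single replicate of the requested regime."""
    regime = Regime(regime)
    if regime is Regime.NONRANDOM_CHARACTERS:
        return degrade_nonrandom_characters(matrix, schedule, seed, replicate_id)
    scope = "FOSSIL" if regime is Regime.RANDOM_SCORES_FOSSIL else "ALL"
    return degrade_random_scores(matrix, schedule, scope, seed, replicate_id)


def replicate_series(
    matrix: CharacterMatrix,
    regime: Regime,
    schedule: DegradationSchedule,
    n_replicates: int,
    master_seed: int,
) -> list[DegradedSeries]:
    """Independent degradation replicates with substream seeds from ``master_seed``."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    seeds = np.random.SeedSequence([master_seed, _REGIME_STREAM[Regime(regime)]])
    child_seeds = seeds.generate_state(n_replicates, dtype=np.uint32)
    return [
        degrade(matrix, regime, schedule, int(child_seeds[rep]), replicate_id=rep)
        for rep in range(n_replicates)
    ]


_REGIME_STREAM = {
    Regime.NONRANDOM_CHARACTERS: 1,
    Regime.RANDOM_SCORES_FOSSIL: 2,
    Regime.RANDOM_SCORES_ALL: 3,
}


def missingness_audit(
    series_list: list[DegradedSeries], schedule: DegradationSchedule
) -> pd.DataFrame:
    """Tidy table of nominal vs realized missing fractions per stage."""
    rows = []
    for series in series_list:
        for k, stage in enumerate(series.stages):
            share = stage.fossil_mask.mean()
            for scope in ("FOSSIL", "ALL"):
                rows.append(
                    {
                        "regime": series.regime.value,
                        "replicate": series.replicate_id,
                        "stage": k,
                        "scope": scope,
                        "nominal": nominal_missingness(
                            schedule, k, scope, fossil_share=share
                        ),
                        "realized": stage.missing_fraction(scope),
                    }
                )
    return pd.DataFrame(rows)
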