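"""Synthetic data generation: birth-death trees and homoplasy-matched characters.

The study design calls for a fully bifurcating generating tree carrying both
extinct (fossil) and living (extant) tips, and a binary character matrix
evolved along it under an equal-rates two-state Markov (Mk) model.  To make
the simulated matrix behave like empirical cladistic data, characters are not
taken as they come: candidates are simulated in bulk, their homoplasy is
scored with the consistency index (CI = minimum changes / parsimony changes
on the generating tree), and columns are accepted into per-CI-bin quotas
until the realized CI histogram matches a configurable target.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import dendropy
import numpy as np
from dendropy.simulate import treesim

from .core import CharacterMatrix, TipStatus

__all__ = [
    "SimulationConfig",
    "Phylogeny",
    "simulate_tree",
    "simulate_character",
    "fitch_steps",
    "consistency_index",
    "assemble_matched_matrix",
    "DEFAULT_CI_TARGET",
    "CI_BIN_EDGES",
]

#: CI bin edges: ten half-open bins (0, 0.1], (0.1, 0.2], ..., (0.9, 1.0].
CI_BIN_EDGES: np.ndarray = np.linspace(0.0, 1.0, 11)

#: Placeholder target CI histogram (proportions per bin, low bin first).
#:
#: Empirical morphological matrices carry substantial homoplasy: most
#: characters are clean (CI = 1) or show a single extra step (CI = 0.5),
#: with a tail of more strongly homoplastic characters.  Binary characters
#: can only realise CI = 1/steps, so mass is placed only on reachable bins.
#: This default is a documented placeholder standing in for the homoplasy
#: profile of an "average" empirical dataset and should be replaced by a
#: measured histogram when one is available.
DEFAULT_CI_TARGET: tuple[float, ...] = (
    0.00,  # (0.0, 0.1]
    0.00,  # (0.1, 0.2]
    0.05,  # (0.2, 0.3]  CI = 0.25
    0.12,  # (0.3, 0.4]  CI = 1/3
    0.28,  # (0.4, 0.5]  CI = 0.5
    0.00,  # (0.5, 0.6]
    0.00,  # (0.6, 0.7]
    0.00,  # (0.7, 0.8]
    0.00,  # (0.8, 0.9]
    0.55,  # (0.9, 1.0]  CI = 1 (homoplasy-free)
)

_MIN_BRANCH = 1e-9


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for tree and character simulation.

    Attributes
    ----------
    n_extant, n_fossil:
        Requested tip counts of each status (default 32 + 32 = 64 tips).
    birth_rate, death_rate:
        Birth-death rates per lineage per unit time.  Only the tip counts
        and bifurcation are pinned down by the study design; the rates are
        free parameters with defaults chosen to make extinct-tip counts
        near the requested value reasonably probable.
    char_rate:
        Equal-rates Mk transition rate q (substitutions per unit time).
    n_characters:
        Number of accepted characters in the assembled matrix.
    target_ci_histogram:
        Proportions over the ten CI bins of :data:`CI_BIN_EDGES`; must sum
        to 1 (within 1e-9).
    seed:
        Master seed for tree rejection sampling and character simulation.
    max_attempts:
        Cap on birth-death draws (tree) and on candidate characters
        simulated (matrix assembly) before giving up.
    """

    n_extant: int = 32
    n_fossil: int = 32
    birth_rate: float = 1.0
    death_rate: float = 0.5
    char_rate: float = 0.01
    n_characters: int = 254
    target_ci_histogram: tuple[float, ...] = DEFAULT_CI_TARGET
    seed: int = 0
    max_attempts: int = 2_000_000

    def __post_init__(self) -> None:
        if self.n_extant < 1:
            raise ValueError("n_extant must be >= 1")
        if self.n_fossil < 0:
            raise ValueError("n_fossil must be >= 0")
        if not (0 <= self.death_rate < self.birth_rate):
            raise ValueError("rates must satisfy 0 <= death_rate < birth_rate")
        if self.char_rate <= 0:
            raise ValueError("char_rate must be > 0")
        if self.n_characters < 1:
            raise ValueError("n_characters must be >= 1")
        hist = np.asarray(self.target_ci_histogram, dtype=float)
        if hist.shape != (10,) or (hist < 0).any():
            raise ValueError("target_ci_histogram must be 10 non-negative proportions")
        if abs(hist.sum() - 1.0) > 1e-9:
            raise ValueError("target_ci_histogram must sum to 1")


class Phylogeny:
    """Rooted bifurcating tree with branch lengths and per-tip status.

    Wraps a :class:`dendropy.Tree` and caches flat traversal arrays
    (preorder parents and edge lengths, postorder internal children) so
    that character simulation and Fitch counting vectorise over batches.
    """

    def __init__(self, tree: dendropy.Tree, status: dict[str, TipStatus]):
        self.tree = tree
        nodes = list(tree.preorder_node_iter())
        self._node_index = {id(nd): i for i, nd in enumerate(nodes)}
        self.n_nodes = len(nodes)
        parent = np.full(self.n_nodes, -1, dtype=np.int64)
        length = np.zeros(self.n_nodes, dtype=float)
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                parent[i] = self._node_index[id(nd.parent_node)]
                if nd.edge.length is None:
                    raise ValueError("tree has a branch with no length")
                length[i] = float(nd.edge.length)
        self.preorder_parent = parent
        self.edge_length = length

        tips = [nd for nd in nodes if nd.is_leaf()]
        internal = [nd for nd in nodes if not nd.is_leaf()]
        for nd in internal:
            if len(nd.child_nodes()) != 2:
                raise ValueError("tree must be fully bifurcating")
        self.tip_labels: list[str] = [nd.taxon.label for nd in tips]
        if len(set(self.tip_labels)) != len(self.tip_labels):
            raise ValueError("tip labels must be unique")
        self.tip_node_index = np.array(
            [self._node_index[id(nd)] for nd in tips], dtype=np.int64
        )
        # Postorder over internal nodes with their two children, for Fitch.
        post_internal = [
            nd for nd in tree.postorder_node_iter() if not nd.is_leaf()
        ]
        self.postorder_internal = np.array(
            [self._node_index[id(nd)] for nd in post_internal], dtype=np.int64
        )
        self.internal_children = np.array(
            [
                [self._node_index[id(c)] for c in nd.child_nodes()]
                for nd in post_internal
            ],
            dtype=np.int64,
        )
        self.status = {label: status[label] for label in self.tip_labels}

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def fossil_tips(self) -> list[str]:
        return [t for t in self.tip_labels if self.status[t] is TipStatus.FOSSIL]

    @property
    def extant_tips(self) -> list[str]:
        return [t for t in self.tip_labels if self.status[t] is TipStatus.EXTANT]

    def min_branch_length(self) -> float:
        if self.n_nodes < 2:
            return np.inf
        return float(self.edge_length[1:].min())

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True)


def _draw_birth_death(config: SimulationConfig, rng: random.Random) -> dendropy.Tree:
    gsa = max(config.n_extant + 2, int(np.ceil(config.n_extant * 1.25)))
    return treesim.birth_death_tree(
        birth_rate=config.birth_rate,
        death_rate=config.death_rate,
        num_extant_tips=config.n_extant,
        gsa_ntax=gsa,
        is_retain_extinct_tips=config.n_fossil > 0,
        rng=rng,
    )


def simulate_tree(config: SimulationConfig) -> Phylogeny:
    """Rejection-sample a birth-death tree with the requested tip counts.

    Trees are drawn under the general sampling approach conditioned on the
    extant tip count; draws are rejected until the number of extinct tips
    equals ``config.n_fossil`` and every branch exceeds the zero-length
    tolerance.  Tips are relabelled deterministically in preorder as
    ``extant_NN`` / ``fossil_NN``.

    Raises
    ------
    RuntimeError
        If ``config.max_attempts`` draws fail to satisfy the conditions.
    """
    rng = random.Random(config.seed)
    for _ in range(config.max_attempts):
        try:
            tree = _draw_birth_death(config, rng)
        except Exception:  # total extinction before reaching the target
            continue
        leaves = tree.leaf_nodes()
        if len(leaves) != config.n_extant + config.n_fossil:
            continue
        tree.calc_node_root_distances()
        max_depth = max(l.root_distance for l in leaves)
        extant = [
            l for l in leaves if abs(l.root_distance - max_depth) <= 1e-9 * max_depth
        ]
        if len(extant) != config.n_extant:
            continue
        lengths = [
            nd.edge.length or 0.0
            for nd in tree.preorder_node_iter()
            if nd.parent_node is not None
        ]
        if min(lengths) <= _MIN_BRANCH:
            continue
        extant_ids = {id(l) for l in extant}
        status: dict[str, TipStatus] = {}
        n_e = n_f = 0
        taxon_namespace = dendropy.TaxonNamespace()
        for nd in tree.preorder_node_iter():
            if not nd.is_leaf():
                continue
            if id(nd) in extant_ids:
                n_e += 1
                label = f"extant_{n_e:02d}"
                status[label] = TipStatus.EXTANT
            else:
                n_f += 1
                label = f"fossil_{n_f:02d}"
                status[label] = TipStatus.FOSSIL
            nd.taxon = taxon_namespace.new_taxon(label)
        tree.taxon_namespace = taxon_namespace
        tree.seed_node.edge.length = None  # root edge is not a branch
        return Phylogeny(tree, status)
    raise RuntimeError(
        f"no birth-death draw matched {config.n_extant} extant + "
        f"{config.n_fossil} extinct tips within {config.max_attempts} attempts"
    )


def _simulate_states(
    phy: Phylogeny, q: float, n_characters: int, rng: np.random.Generator
) -> np.ndarray:
    """Evolve ``n_characters`` binary characters; returns (n_tips, n_chars).

    Along a branch of length t the equal-rates two-state chain flips the
    state with probability (1 - exp(-2 q t)) / 2; the root state is drawn
    uniformly (the chain's stationary distribution).
    """
    if q <= 0:
        raise ValueError("rate q must be > 0")
    p_flip = 0.5 * (1.0 - np.exp(-2.0 * q * phy.edge_length))
    states = np.empty((phy.n_nodes, n_characters), dtype=np.int8)
    u = rng.random((phy.n_nodes, n_characters))
    states[0] = rng.integers(0, 2, size=n_characters, dtype=np.int8)
    for i in range(1, phy.n_nodes):
        flip = u[i] < p_flip[i]
        states[i] = states[phy.preorder_parent[i]] ^ flip
    return states[phy.tip_node_index]


def simulate_character(phy: Phylogeny, q: float, seed: int) -> np.ndarray:
    """Simulate one binary character; returns tip states in ``phy.tip_labels`` order."""
    rng = np.random.default_rng(seed)
    return _simulate_states(phy, q, 1, rng)[:, 0]


def _fitch_steps_batch(phy: Phylogeny, tip_states: np.ndarray) -> np.ndarray:
    """Fitch parsimony length for each column of (n_tips, n_chars) states."""
    tip_states = np.asarray(tip_states)
    if tip_states.ndim == 1:
        tip_states = tip_states[:, None]
    if tip_states.shape[0] != phy.n_tips:
        raise ValueError(
            f"{tip_states.shape[0]} state rows for {phy.n_tips} tips"
        )
    if not np.isin(tip_states, (0, 1)).all():
        raise ValueError("tip states must be 0 or 1 (no MISSING)")
    n_chars = tip_states.shape[1]
    # State sets as 2-bit masks: {0} -> 1, {1} -> 2, {0,1} -> 3.
    sets = np.zeros((phy.n_nodes, n_chars), dtype=np.int8)
    sets[phy.tip_node_index] = np.left_shift(1, tip_states.astype(np.int8))
    steps = np.zeros(n_chars, dtype=np.int64)
    for node, (left, right) in zip(phy.postorder_internal, phy.internal_children):
        inter = sets[left] & sets[right]
        empty = inter == 0
        steps += empty
        sets[node] = np.where(empty, sets[left] | sets[right], inter)
    return steps


def fitch_steps(phy: Phylogeny, states) -> int:
    """Minimum number of state changes for one character on the tree.

    ``states`` is either an array aligned with ``phy.tip_labels`` or a
    mapping from tip label to state.
    """
    if isinstance(states, dict):
        missing = [t for t in phy.tip_labels if t not in states]
        if missing:
            raise ValueError(f"states missing for tips {missing}")
        extra = set(states) - set(phy.tip_labels)
        if extra:
            raise ValueError(f"states given for unknown tips {sorted(extra)}")
        states = np.array([states[t] for t in phy.tip_labels])
    return int(_fitch_steps_batch(phy, np.asarray(states))[0])


def consistency_index(states: np.ndarray, steps: int) -> float:
    """CI = (observed states - 1) / parsimony steps; binary variable columns give 1/steps.

    Undefined (raises) for invariant columns, where the minimum number of
    changes is zero.
    """
    states = np.asarray(states)
    m = len(np.unique(states)) - 1
    if m == 0 or steps == 0:
        raise ValueError("consistency index is undefined for invariant characters")
    if steps < m:
        raise ValueError(f"steps={steps} below minimum {m}")
    return m / steps


def _ci_bin(ci: np.ndarray) -> np.ndarray:
    """Map CI values in (0, 1] to bin indices 0..9 over half-open bins (lo, hi]."""
    return np.minimum(np.ceil(np.asarray(ci) * 10.0).astype(int) - 1, 9)


def largest_remainder_quotas(proportions: np.ndarray, total: int) -> np.ndarray:
    """Integer quotas summing exactly to ``total`` by largest-remainder rounding.

    Ties in the fractional remainder are broken in favour of lower bins.
    """
    proportions = np.asarray(proportions, dtype=float)
    raw = proportions * total
    base = np.floor(raw).astype(int)
    short = total - base.sum()
    remainders = raw - base
    # stable sort descending on remainder -> lower index wins ties
    order = np.argsort(-remainders, kind="stable")
    base[order[:short]] += 1
    return base


def assemble_matched_matrix(
    phy: Phylogeny, config: SimulationConfig
) -> tuple[CharacterMatrix, np.ndarray]:
    """Build the 'original matrix' whose CI histogram matches the target.

    Candidate characters are simulated in batches under the Mk model,
    invariant columns are discarded (their CI is undefined), survivors are
    binned by CI, and each bin's quota (largest-remainder rounding of the
    target proportions) is filled in order of arrival.  Returns the matrix
    and the realized per-bin proportions.

    Raises
    ------
    RuntimeError
        If the quotas cannot be filled within ``config.max_attempts``
        simulated candidates (unreachable target for this tree and rate).
    """
    quotas = largest_remainder_quotas(
        np.asarray(config.target_ci_histogram), config.n_characters
    )
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5EED]))
    filled = np.zeros(10, dtype=int)
    accepted: list[np.ndarray] = []
    accepted_bins: list[int] = []
    attempts = 0
    batch = 512
    while filled.sum() < config.n_characters:
        if attempts >= config.max_attempts:
            open_bins = [
                f"({CI_BIN_EDGES[b]:.1f},{CI_BIN_EDGES[b + 1]:.1f}] "
                f"needs {quotas[b] - filled[b]}"
                for b in range(10)
                if filled[b] < quotas[b]
            ]
            raise RuntimeError(
                "CI-matching exhausted "
                f"{config.max_attempts} candidate characters; unfilled bins: "
                + "; ".join(open_bins)
            )
        n = min(batch, config.max_attempts - attempts)
        attempts += n
        tips = _simulate_states(phy, config.char_rate, n, rng)
        variable = (tips.min(axis=0) == 0) & (tips.max(axis=0) == 1)
        tips = tips[:, variable]
        if tips.shape[1] == 0:
            continue
        steps = _fitch_steps_batch(phy, tips)
        bins = _ci_bin(1.0 / steps)
        for j in range(tips.shape[1]):
            b = bins[j]
            if filled[b] < quotas[b]:
                filled[b] += 1
                accepted.append(tips[:, j])
                accepted_bins.append(b)
                if filled.sum() == config.n_characters:
                    break
    data = np.column_stack(accepted).astype(np.int8)
    realized = np.bincount(accepted_bins, minlength=10) / config.n_characters
    matrix = CharacterMatrix(
        taxa=list(phy.tip_labels),
        data=data,
        status=dict(phy.status),
        provenance="original",
    )
    return matrix, realized
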