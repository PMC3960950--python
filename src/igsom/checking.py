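"""Non-mutating calibration and evaluation of a trained model.

The checking pass assigns every acoustic-semantic token to its BMU on both
maps (a calibration in the classic SOM sense), derives per-node density and
mean-distance statistics, and — along the perceiving path only — judges each
solid auditory node's winner link as correct or incorrect against the
corpus pairing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Hashable, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .gsom import GridPosition, GrowingMap
from .links import top_fraction_filter, winner_link

if TYPE_CHECKING:  # pragma: no cover
    from .training import IGsomModel, TrainingToken


@dataclass
class MapSideCheck:
    """BMU assignment and per-node statistics for one map."""

    #: per token, in corpus order: (BMU position, Euclidean distance)
    assignment: list[tuple[GridPosition, float]]
    #: distinct represented items per node (solid nodes only)
    node_items: dict[GridPosition, set[Hashable]]
    #: mean BMU distance over the tokens assigned to each solid node
    node_mean_distance: dict[GridPosition, float]


@dataclass
class MapSummary:
    total_nodes: int
    solid_nodes: int
    boundary_ratio: float
    avg_items_per_solid: float | None
    max_items_per_node: int


@dataclass
class CheckResult:
    """Everything a checking pass establishes about (model, token set)."""

    tokens: Sequence["TrainingToken"]
    audio: MapSideCheck
    semantic: MapSideCheck
    #: syllable ids per auditory node (independent of the realization switch)
    audio_node_syllables: dict[GridPosition, set[Hashable]] = field(default_factory=dict)
    #: per solid auditory node: True = correct winner link
    link_marks: dict[GridPosition, bool] | None = None
    #: correct / marked; None until check_links runs or when nothing is marked
    link_accuracy: float | None = None


def _assign(map_: GrowingMap, vectors: np.ndarray) -> list[tuple[GridPosition, float]]:
    positions, weights = map_.weight_matrix()
    dists = cdist(vectors, weights)
    idx = dists.argmin(axis=1)  # first minimum == lexicographic tie-break
    return [(positions[i], float(dists[t, i])) for t, i in enumerate(idx)]


def _side(
    assignment: list[tuple[GridPosition, float]], items: list[Hashable]
) -> MapSideCheck:
    node_items: dict[GridPosition, set[Hashable]] = {}
    node_dists: dict[GridPosition, list[float]] = {}
    for (pos, dist), item in zip(assignment, items):
        node_items.setdefault(pos, set()).add(item)
        node_dists.setdefault(pos, []).append(dist)
    mean_dist = {pos: float(np.mean(d)) for pos, d in node_dists.items()}
    return MapSideCheck(assignment, node_items, mean_dist)


def check_maps(
    model: "IGsomModel",
    tokens: Sequence["TrainingToken"],
    count_realizations: bool = False,
) -> CheckResult:
    """Assign every token to its BMU on both maps; the model is not modified.

    Auditory density counts distinct syllable ids by default; with
    ``count_realizations`` each (syllable, realization) counts separately.
    Semantic density always counts distinct word ids.
    """
    if not tokens:
        raise ValueError("token list must be non-empty")
    audio_x = np.stack([t.audio_vector for t in tokens])
    sem_x = np.stack([t.semantic_vector for t in tokens])
    audio_assign = _assign(model.auditory_map, audio_x)
    sem_assign = _assign(model.semantic_map, sem_x)
    if count_realizations:
        audio_items: list[Hashable] = [(t.syllable_id, t.realization_index) for t in tokens]
    else:
        audio_items = [t.syllable_id for t in tokens]
    result = CheckResult(
        tokens=tokens,
        audio=_side(audio_assign, audio_items),
        semantic=_side(sem_assign, [t.word_id for t in tokens]),
    )
    syllables: dict[GridPosition, set[Hashable]] = {}
    for (pos, _), tok in zip(audio_assign, tokens):
        syllables.setdefault(pos, set()).add(tok.syllable_id)
    result.audio_node_syllables = syllables
    return result


def check_links(model: "IGsomModel", check: CheckResult, fraction: float = 1.0) -> CheckResult:
    """Mark the winner link of every solid auditory node as correct/incorrect.

    With ``fraction`` < 1 only the top-ranked fraction of link weights is
    eligible (the winner is searched within that filtered view).  A winner
    link is correct iff its target semantic node hosts a word paired with at
    least one syllable represented at the source node; it is incorrect if it
    points at a node hosting no words, at a node hosting only unrelated
    words, or if the source node has no eligible link at all.
    """
    pairing = {t.syllable_id: t.word_id for t in check.tokens}
    eligible = top_fraction_filter(model.registry, fraction)
    by_source: dict[GridPosition, list] = {}
    for link in eligible:
        by_source.setdefault(tuple(link.audio_pos), []).append(link)
    marks: dict[GridPosition, bool] = {}
    for pos in sorted(check.audio_node_syllables):
        expected_words = {pairing[s] for s in check.audio_node_syllables[pos]}
        winner = winner_link(by_source.get(pos, []), pos)
        if winner is None:
            marks[pos] = False
            continue
        hosted = check.semantic.node_items.get(tuple(winner.semantic_pos), set())
        marks[pos] = bool(hosted & expected_words)
    check.link_marks = marks
    check.link_accuracy = (sum(marks.values()) / len(marks)) if marks else None
    return check


def summarize(model: "IGsomModel", check: CheckResult) -> dict[str, MapSummary | float | int | None]:
    """Summary metrics per map plus link figures, after a check_maps pass."""
    out: dict[str, MapSummary | float | int | None] = {}
    for name, map_, side in (
        ("audio", model.auditory_map, check.audio),
        ("semantic", model.semantic_map, check.semantic),
    ):
        solid = len(side.node_items)
        distinct_items = len(set().union(*side.node_items.values())) if solid else 0
        out[name] = MapSummary(
            total_nodes=len(map_),
            solid_nodes=solid,
            boundary_ratio=map_.boundary_ratio(),
            avg_items_per_solid=(distinct_items / solid) if solid else None,
            max_items_per_node=max((len(s) for s in side.node_items.values()), default=0),
        )
    out["link_count"] = len(model.registry)
    out["link_accuracy"] = check.link_accuracy
    return out
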