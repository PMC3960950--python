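"""Associative links between the auditory and semantic maps.

A link joins one auditory-map position to one semantic-map position.  Links
are created (weight 0.1) or reinforced (weight += L = 0.1) whenever the two
BMUs of an acoustic-semantic pair co-activate, and all links decay
multiplicatively at each phase end at a rate given by the relative growth of
the possible-link count N_link = |auditory| * |semantic|.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

from .gsom import GridPosition, GrowingMap

DEFAULT_LINK_INCREMENT = 0.1
DEFAULT_LINK_INIT_WEIGHT = 0.1


@dataclass(frozen=True)
class AssociativeLink:
    """A weighted auditory -> semantic node pairing."""

    audio_pos: GridPosition
    semantic_pos: GridPosition
    weight: float


class LinkRegistry:
    """Store of all associative links plus the forgetting-rate bookkeeping.

    ``previous_possible_count`` holds N_link at the end of the last completed
    training phase (16 for a fresh pair of 2x2 maps).
    """

    def __init__(
        self,
        previous_possible_count: int = 16,
        link_increment: float = DEFAULT_LINK_INCREMENT,
        link_init_weight: float = DEFAULT_LINK_INIT_WEIGHT,
    ) -> None:
        if previous_possible_count < 1:
            raise ValueError("previous_possible_count must be positive")
        if link_increment <= 0 or link_init_weight <= 0:
            raise ValueError("link increment and initial weight must be positive")
        self.previous_possible_count = int(previous_possible_count)
        self.link_increment = float(link_increment)
        self.link_init_weight = float(link_init_weight)
        self._weights: dict[tuple[GridPosition, GridPosition], float] = {}

    def __len__(self) -> int:
        return len(self._weights)

    def weight(self, audio_pos: GridPosition, semantic_pos: GridPosition) -> float | None:
        return self._weights.get((tuple(audio_pos), tuple(semantic_pos)))

    def links(self) -> list[AssociativeLink]:
        """All links, sorted by (audio_pos, semantic_pos)."""
        return [
            AssociativeLink(a, s, w)
            for (a, s), w in sorted(self._weights.items())
        ]

    def reinforce_or_create(
        self,
        audio_pos: GridPosition,
        semantic_pos: GridPosition,
        auditory: GrowingMap | None = None,
        semantic: GrowingMap | None = None,
    ) -> float:
        """Reinforce an existing link by L, or create one at the initial weight.

        When the maps are supplied, both endpoints are validated as occupied.
        Returns the resulting weight.
        """
        audio_pos = tuple(audio_pos)
        semantic_pos = tuple(semantic_pos)
        if auditory is not None and audio_pos not in auditory:
            raise ValueError(f"auditory position {audio_pos} is not occupied")
        if semantic is not None and semantic_pos not in semantic:
            raise ValueError(f"semantic position {semantic_pos} is not occupied")
        key = (audio_pos, semantic_pos)
        if key in self._weights:
            self._weights[key] += self.link_increment
        else:
            self._weights[key] = self.link_init_weight
        return self._weights[key]

    def apply_forgetting(self, rate: float, current_possible_count: int | None = None) -> None:
        """Multiply every link weight by (1 - rate).

        ``current_possible_count``, when given, becomes the new
        ``previous_possible_count`` baseline for the next phase end.
        """
        if not 0.0 <= rate < 1.0:
            raise ValueError("forgetting rate must lie in [0, 1)")
        if rate > 0.0:
            factor = 1.0 - rate
            for key in self._weights:
                self._weights[key] *= factor
        if current_possible_count is not None:
            if current_possible_count < 1:
                raise ValueError("current_possible_count must be positive")
            self.previous_possible_count = int(current_possible_count)


def possible_link_count(auditory: GrowingMap, semantic: GrowingMap) -> int:
    """N_link: every auditory node could in principle link to every semantic node."""
    return len(auditory) * len(semantic)


def forgetting_rate(n_prev: int, n_curr: int) -> float:
    """(N(t) - N(t-1)) / N(t); zero when neither map grew."""
    if n_prev < 1:
        raise ValueError("n_prev must be positive")
    if n_curr < n_prev:
        raise ValueError("possible-link count cannot shrink (maps never lose nodes)")
    return (n_curr - n_prev) / n_curr


def winner_link(
    links: "LinkRegistry | Iterable[AssociativeLink]", audio_pos: GridPosition
) -> AssociativeLink | None:
    """The maximum-weight link leaving ``audio_pos``; ties broken by semantic_pos.

    Returns None when no link originates there.
    """
    audio_pos = tuple(audio_pos)
    if isinstance(links, LinkRegistry):
        links = links.links()
    best: AssociativeLink | None = None
    for link in links:
        if tuple(link.audio_pos) != audio_pos:
            continue
        if (
            best is None
            or link.weight > best.weight
            or (link.weight == best.weight and tuple(link.semantic_pos) < tuple(best.semantic_pos))
        ):
            best = link
    return best


def top_fraction_filter(registry: LinkRegistry, fraction: float) -> list[AssociativeLink]:
    """The ceil(fraction * count) highest-weight links.

    Ties at the cutoff are resolved deterministically by (audio_pos,
    semantic_pos) lexicographic order.  The registry is left untouched.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    all_links = registry.links()
    if not all_links:
        return []
    k = math.ceil(fraction * len(all_links))
    ranked = sorted(
        all_links, key=lambda l: (-l.weight, tuple(l.audio_pos), tuple(l.semantic_pos))
    )
    return ranked[:k]
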