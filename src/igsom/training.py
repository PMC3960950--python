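"""Training regimes: token-level training and the phase schedules.

One token presentation resets the learning rate and neighbourhood size,
finds the BMU once per map, grows at a saturated boundary BMU or otherwise
runs the shrinking-neighbourhood inner loop (weight update + error
accumulation + link reinforcement per iteration, error distribution for a
saturated interior BMU).  Phases present a token list sequentially and end
with link forgetting.  The fundamental schedule is one growing phase plus
cyclical reinforcing (selected tokens) / reviewing (all tokens) phases; the
experiment schedule optionally prepends a reinforcing-by-link phase to each
cycle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import checking
from .gsom import GrowingMap, PhaseParams, decay_learning_rate, decay_neighborhood
from .links import LinkRegistry, forgetting_rate, possible_link_count

logger = logging.getLogger("igsom")


@dataclass
class TrainingToken:
    """One acoustic-semantic pair: a flattened 24xT auditory activation matrix
    coupled with a binary semantic feature vector."""

    audio_vector: np.ndarray
    semantic_vector: np.ndarray
    syllable_id: str
    word_id: str
    realization_index: int = 0

    def __post_init__(self) -> None:
        self.audio_vector = np.asarray(self.audio_vector, dtype=float)
        self.semantic_vector = np.asarray(self.semantic_vector, dtype=float)
        if self.audio_vector.ndim != 1 or self.audio_vector.size == 0:
            raise ValueError("audio_vector must be a non-empty 1-d vector")
        if self.semantic_vector.ndim != 1 or self.semantic_vector.size == 0:
            raise ValueError("semantic_vector must be a non-empty 1-d vector")
        if not np.isin(self.semantic_vector, (0.0, 1.0)).all():
            raise ValueError("semantic_vector components must be 0 or 1")


@dataclass
class IGsomModel:
    """Two growing maps plus the associative-link registry between them."""

    auditory_map: GrowingMap
    semantic_map: GrowingMap
    registry: LinkRegistry

    @classmethod
    def initialize(cls, audio_dim: int, semantic_dim: int, seed: int) -> "IGsomModel":
        ss = np.random.SeedSequence(seed)
        a_rng, s_rng = (np.random.default_rng(c) for c in ss.spawn(2))
        model = cls(
            auditory_map=GrowingMap.initialize(audio_dim, a_rng),
            semantic_map=GrowingMap.initialize(semantic_dim, s_rng),
            registry=LinkRegistry(previous_possible_count=16),
        )
        return model


def _table2(initial_learning_rate: float, growth_threshold: float) -> PhaseParams:
    return PhaseParams(
        initial_learning_rate=initial_learning_rate,
        initial_neighborhood=2.0,
        growth_threshold=growth_threshold,
        alpha=0.9,
        beta=0.9,
        gamma=0.5,
    )


@dataclass
class ScheduleConfig:
    """Per-regime parameters and schedule-level knobs.

    Defaults reproduce the published parameter table: growing/reviewing use
    (R_learn 0.5, sigma 2, T_grow 2, alpha 0.9, beta 0.9, gamma 0.5) and the
    two reinforcing regimes raise R_learn to 0.8 and lower T_grow to 1.
    """

    growing_params: PhaseParams = field(default_factory=lambda: _table2(0.5, 2.0))
    reinforcing_params: PhaseParams = field(default_factory=lambda: _table2(0.8, 1.0))
    reviewing_params: PhaseParams = field(default_factory=lambda: _table2(0.5, 2.0))
    reinforcing_by_link_params: PhaseParams = field(default_factory=lambda: _table2(0.8, 1.0))
    fundamental_cycles: int = 15
    experiment_cycles: int = 15
    with_link_training: bool = False
    density_threshold: int = 4
    distance_threshold: float = 2.5
    link_check_fraction: float = 0.2
    count_realizations: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fundamental_cycles < 1 or self.experiment_cycles < 1:
            raise ValueError("cycle counts must be positive")
        if self.density_threshold < 1 or self.distance_threshold <= 0:
            raise ValueError("selection thresholds must be positive")
        if not 0.0 < self.link_check_fraction <= 1.0:
            raise ValueError("link_check_fraction must lie in (0, 1]")


@dataclass
class PhaseReport:
    kind: str
    n_tokens: int
    node_count_before: dict[str, int]
    node_count_after: dict[str, int]
    growth_events: dict[str, int]
    link_count: int
    forgetting_rate: float


@dataclass
class StepReport:
    step_index: int
    phase_kind: str
    phase: PhaseReport | None  # None when the phase was skipped (empty selection)
    summary: dict
    link_accuracy: float | None


# -- token-level training --------------------------------------------------


def train_token(model: IGsomModel, token: TrainingToken, params: PhaseParams) -> dict[str, list]:
    """Present one acoustic-semantic pair to both maps.

    Returns the positions grown on each map (empty lists when no growth).
    """
    amap, smap = model.auditory_map, model.semantic_map
    a_bmu, _ = amap.find_bmu(token.audio_vector)
    s_bmu, _ = smap.find_bmu(token.semantic_vector)
    t_grow = params.growth_threshold

    grown: dict[str, list] = {"audio": [], "semantic": []}
    inner: list[tuple[str, GrowingMap, tuple, np.ndarray]] = []
    for name, map_, bmu, x in (
        ("audio", amap, a_bmu, token.audio_vector),
        ("semantic", smap, s_bmu, token.semantic_vector),
    ):
        if map_.nodes[bmu].accumulated_error > t_grow and map_.is_boundary(bmu):
            grown[name] = map_.grow(bmu)
        else:
            inner.append((name, map_, bmu, x))

    if inner:
        rates = {name: params.initial_learning_rate for name, *_ in inner}
        sigma = params.initial_neighborhood
        while sigma >= 1.0:
            for name, map_, bmu, x in inner:
                node = map_.nodes[bmu]
                if node.accumulated_error <= t_grow:
                    dist = float(np.linalg.norm(node.weight - x))
                    map_.update_weights(bmu, x, rates[name], sigma)
                    map_.accumulate_error(bmu, dist)
                elif not map_.is_boundary(bmu):
                    map_.distribute_error(bmu, params)
                # a saturated boundary BMU mid-token waits for its growth
                # check at the next presentation
            model.registry.reinforce_or_create(a_bmu, s_bmu, amap, smap)
            for name, map_, _, _ in inner:
                rates[name] = decay_learning_rate(rates[name], map_, params)
            sigma = decay_neighborhood(sigma, params)
    return grown


def run_phase(
    model: IGsomModel,
    tokens: Sequence[TrainingToken],
    params: PhaseParams,
    kind: str = "phase",
) -> PhaseReport:
    """Present tokens sequentially, then apply phase-end link forgetting."""
    if not tokens:
        raise ValueError("token list must be non-empty")
    before = {"audio": len(model.auditory_map), "semantic": len(model.semantic_map)}
    growth = {"audio": 0, "semantic": 0}
    for token in tokens:
        grown = train_token(model, token, params)
        for name in growth:
            if grown[name]:
                growth[name] += 1
    current = possible_link_count(model.auditory_map, model.semantic_map)
    rate = forgetting_rate(model.registry.previous_possible_count, current)
    model.registry.apply_forgetting(rate, current_possible_count=current)
    after = {"audio": len(model.auditory_map), "semantic": len(model.semantic_map)}
    logger.info(
        "%s phase: %d tokens, nodes %s -> %s, %d links, forgetting rate %.4f",
        kind, len(tokens), before, after, len(model.registry), rate,
    )
    return PhaseReport(
        kind=kind,
        n_tokens=len(tokens),
        node_count_before=before,
        node_count_after=after,
        growth_events=growth,
        link_count=len(model.registry),
        forgetting_rate=rate,
    )


# -- token selection -------------------------------------------------------


def _dedup_in_order(tokens: Sequence[TrainingToken], picked: set[int]) -> list[TrainingToken]:
    return [t for i, t in enumerate(tokens) if i in picked]


def select_reinforcing_tokens(
    model: IGsomModel,
    tokens: Sequence[TrainingToken],
    density_threshold: int = 4,
    distance_threshold: float = 2.5,
    count_realizations: bool = False,
) -> list[TrainingToken]:
    """Tokens confused on either map: their BMU hosts more than
    ``density_threshold`` distinct items or sits at a mean represented
    distance above ``distance_threshold``.  Duplicates are removed and the
    original token order is kept."""
    check = checking.check_maps(model, tokens, count_realizations=count_realizations)
    picked: set[int] = set()
    for side in (check.audio, check.semantic):
        flagged = {
            pos
            for pos, items in side.node_items.items()
            if len(items) > density_threshold
            or side.node_mean_distance[pos] > distance_threshold
        }
        for i, (pos, _) in enumerate(side.assignment):
            if pos in flagged:
                picked.add(i)
    return _dedup_in_order(tokens, picked)


def select_link_tokens(
    model: IGsomModel, tokens: Sequence[TrainingToken], fraction: float = 0.2
) -> list[TrainingToken]:
    """Tokens whose auditory BMU carries an incorrect winner link
    (perceiving-path check over the top-``fraction`` links)."""
    check = checking.check_maps(model, tokens)
    check = checking.check_links(model, check, fraction=fraction)
    assert check.link_marks is not None
    incorrect = {pos for pos, ok in check.link_marks.items() if not ok}
    picked = {
        i for i, (pos, _) in enumerate(check.audio.assignment) if pos in incorrect
    }
    return _dedup_in_order(tokens, picked)


# -- schedules -------------------------------------------------------------


def _checked_summary(
    model: IGsomModel, tokens: Sequence[TrainingToken], config: ScheduleConfig, fraction: float
) -> tuple[dict, float | None]:
    check = checking.check_maps(model, tokens, count_realizations=config.count_realizations)
    check = checking.check_links(model, check, fraction=fraction)
    summary = checking.summarize(model, check)
    return summary, check.link_accuracy


def run_fundamental_training(
    model: IGsomModel, tokens: Sequence[TrainingToken], config: ScheduleConfig
) -> list[StepReport]:
    """One basic growing phase then ``fundamental_cycles`` reinforcing/reviewing
    cycles (31 steps at the default 15 cycles), with per-step metrics."""
    reports: list[StepReport] = []

    def record(step: int, kind: str, phase: PhaseReport | None) -> None:
        summary, acc = _checked_summary(model, tokens, config, fraction=1.0)
        reports.append(StepReport(step, kind, phase, summary, acc))

    record_step = 1
    phase = run_phase(model, tokens, config.growing_params, "growing")
    record(record_step, "growing", phase)
    for _ in range(config.fundamental_cycles):
        record_step += 1
        selection = select_reinforcing_tokens(
            model,
            tokens,
            config.density_threshold,
            config.distance_threshold,
            config.count_realizations,
        )
        phase = (
            run_phase(model, selection, config.reinforcing_params, "reinforcing")
            if selection
            else None
        )
        record(record_step, "reinforcing", phase)
        record_step += 1
        phase = run_phase(model, tokens, config.reviewing_params, "reviewing")
        record(record_step, "reviewing", phase)
    return reports


@dataclass
class CycleReport:
    cycle_index: int
    phases: list[PhaseReport]
    summary: dict
    link_accuracy: float | None


def run_experiment(
    model: IGsomModel, tokens: Sequence[TrainingToken], config: ScheduleConfig
) -> list[CycleReport]:
    """Continue training a fundamentally-trained model for
    ``experiment_cycles`` cycles.

    Without link training each cycle is reinforcing + reviewing; with link
    training a reinforcing-by-link phase is prepended: tokens implicated in
    incorrect winner links, judged over the top-``link_check_fraction`` of
    link weights (weak links have no influence on winner selection).  The
    recorded per-cycle link accuracy is always computed unfiltered so the
    curve is comparable across the two experiment arms.
    """
    reports: list[CycleReport] = []
    for cycle in range(1, config.experiment_cycles + 1):
        phases: list[PhaseReport] = []
        if config.with_link_training:
            link_sel = select_link_tokens(model, tokens, fraction=config.link_check_fraction)
            if link_sel:
                phases.append(
                    run_phase(
                        model, link_sel, config.reinforcing_by_link_params, "reinforcing_by_link"
                    )
                )
        selection = select_reinforcing_tokens(
            model,
            tokens,
            config.density_threshold,
            config.distance_threshold,
            config.count_realizations,
        )
        if selection:
            phases.append(run_phase(model, selection, config.reinforcing_params, "reinforcing"))
        phases.append(run_phase(model, tokens, config.reviewing_params, "reviewing"))
        summary, acc = _checked_summary(model, tokens, config, fraction=1.0)
        reports.append(CycleReport(cycle, phases, summary, acc))
    return reports
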