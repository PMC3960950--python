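"""Serialization: model archives, corpora, schedule configs, metrics tables.

The model archive is a versioned JSON container (node tables per map, a link
table, registry scalars) chosen over an opaque binary so that archives stay
diffable and round-trip bit-for-bit through Python's exact float repr.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .gsom import GrowingMap, MapNode, PhaseParams
from .links import LinkRegistry
from .synth import SyntheticConfig, SyntheticCorpus
from .training import (CycleReport, IGsomModel, ScheduleConfig, StepReport,
                       TrainingToken)

ARCHIVE_FORMAT_VERSION = "igsom-model/1"

METRICS_COLUMNS = [
    "step_index",
    "phase_kind",
    "audio_total_nodes",
    "audio_solid_nodes",
    "audio_boundary_ratio",
    "audio_avg_items_per_solid",
    "audio_max_items_per_node",
    "semantic_total_nodes",
    "semantic_solid_nodes",
    "semantic_boundary_ratio",
    "semantic_avg_items_per_solid",
    "semantic_max_items_per_node",
    "link_count",
    "link_accuracy",
]


# -- model archive ---------------------------------------------------------


def _map_to_dict(map_: GrowingMap) -> dict:
    return {
        "input_dimension": map_.input_dimension,
        "nodes": [
            {
                "row": node.position[0],
                "col": node.position[1],
                "weight": node.weight.tolist(),
                "accumulated_error": node.accumulated_error,
            }
            for node in map_
        ],
    }


def _map_from_dict(data: dict) -> GrowingMap:
    m = GrowingMap(data["input_dimension"])
    for rec in data["nodes"]:
        node = m._add_node((rec["row"], rec["col"]), np.array(rec["weight"], dtype=float))
        node.accumulated_error = rec["accumulated_error"]
    return m


def save_model(model: IGsomModel, path: str | Path) -> None:
    archive = {
        "format_version": ARCHIVE_FORMAT_VERSION,
        "auditory_map": _map_to_dict(model.auditory_map),
        "semantic_map": _map_to_dict(model.semantic_map),
        "links": [
            {"audio_pos": list(l.audio_pos), "semantic_pos": list(l.semantic_pos),
             "weight": l.weight}
            for l in model.registry.links()
        ],
        "registry": {
            "previous_possible_count": model.registry.previous_possible_count,
            "link_increment": model.registry.link_increment,
            "link_init_weight": model.registry.link_init_weight,
        },
    }
    Path(path).write_text(json.dumps(archive))


def load_model(path: str | Path) -> IGsomModel:
    archive = json.loads(Path(path).read_text())
    version = archive.get("format_version")
    if version != ARCHIVE_FORMAT_VERSION:
        raise ValueError(
            f"unsupported model archive version {version!r} in {path} "
            f"(expected {ARCHIVE_FORMAT_VERSION!r})"
        )
    reg = LinkRegistry(
        previous_possible_count=archive["registry"]["previous_possible_count"],
        link_increment=archive["registry"]["link_increment"],
        link_init_weight=archive["registry"]["link_init_weight"],
    )
    for rec in archive["links"]:
        reg._weights[(tuple(rec["audio_pos"]), tuple(rec["semantic_pos"]))] = rec["weight"]
    return IGsomModel(
        auditory_map=_map_from_dict(archive["auditory_map"]),
        semantic_map=_map_from_dict(archive["semantic_map"]),
        registry=reg,
    )


# -- metrics ---------------------------------------------------------------


def _summary_row(index: int, kind: str, summary: dict) -> dict:
    row: dict = {"step_index": index, "phase_kind": kind}
    for name in ("audio", "semantic"):
        s = summary[name]
        row[f"{name}_total_nodes"] = s.total_nodes
        row[f"{name}_solid_nodes"] = s.solid_nodes
        row[f"{name}_boundary_ratio"] = s.boundary_ratio
        row[f"{name}_avg_items_per_solid"] = s.avg_items_per_solid
        row[f"{name}_max_items_per_node"] = s.max_items_per_node
    row["link_count"] = summary["link_count"]
    row["link_accuracy"] = summary["link_accuracy"]
    return row


def metrics_frame(reports: Sequence[StepReport | CycleReport], offset: int = 0) -> pd.DataFrame:
    """One metrics row per completed training step / experiment cycle."""
    rows = []
    for rep in reports:
        if isinstance(rep, StepReport):
            rows.append(_summary_row(rep.step_index + offset, rep.phase_kind, rep.summary))
        else:
            kind = "experiment_cycle"
            rows.append(_summary_row(rep.cycle_index + offset, kind, rep.summary))
    return pd.DataFrame(rows, columns=METRICS_COLUMNS)


# -- corpus ----------------------------------------------------------------


def save_corpus(corpus: SyntheticCorpus, out_dir: str | Path) -> None:
    """Write a corpus as plain-text tables: audio matrix (tokens x features),
    semantic 0/1 matrix, pairing table, and a JSON metadata sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    audio = np.stack([t.audio_vector for t in corpus.tokens])
    np.savetxt(out / "audio_matrix.tsv", audio, delimiter="\t", fmt="%.10g")
    np.savetxt(out / "semantic_matrix.tsv", corpus.semantic_matrix, delimiter="\t", fmt="%d")
    pd.DataFrame(
        {
            "syllable_id": [t.syllable_id for t in corpus.tokens],
            "realization_index": [t.realization_index for t in corpus.tokens],
            "word_id": [t.word_id for t in corpus.tokens],
            "category": [corpus.category_of[t.word_id] for t in corpus.tokens],
        }
    ).to_csv(out / "pairing.tsv", sep="\t", index=False)
    time_frames = next(iter(corpus.templates.values())).shape[1]
    meta = {
        "word_ids": corpus.word_ids,
        "audio_dimension": int(audio.shape[1]),
        "semantic_dimension": int(corpus.semantic_matrix.shape[1]),
        "time_frames": int(time_frames),
    }
    (out / "corpus_meta.json").write_text(json.dumps(meta))


def load_corpus_tokens(corpus_dir: str | Path) -> list[TrainingToken]:
    corpus_dir = Path(corpus_dir)
    audio = np.loadtxt(corpus_dir / "audio_matrix.tsv", delimiter="\t", ndmin=2)
    semantic = np.loadtxt(corpus_dir / "semantic_matrix.tsv", delimiter="\t", ndmin=2)
    pairing = pd.read_csv(corpus_dir / "pairing.tsv", sep="\t")
    meta = json.loads((corpus_dir / "corpus_meta.json").read_text())
    word_row = {w: i for i, w in enumerate(meta["word_ids"])}
    tokens = []
    for i, rec in pairing.iterrows():
        tokens.append(
            TrainingToken(
                audio_vector=audio[i],
                semantic_vector=semantic[word_row[rec["word_id"]]],
                syllable_id=str(rec["syllable_id"]),
                word_id=str(rec["word_id"]),
                realization_index=int(rec["realization_index"]),
            )
        )
    return tokens


# -- configuration ---------------------------------------------------------

_PHASE_KEYS = ("growing", "reinforcing", "reviewing", "reinforcing_by_link")


def schedule_config_to_dict(config: ScheduleConfig) -> dict:
    data: dict = {}
    for key in _PHASE_KEYS:
        data[key] = dataclasses.asdict(getattr(config, f"{key}_params"))
    for f in dataclasses.fields(ScheduleConfig):
        if not f.name.endswith("_params"):
            data[f.name] = getattr(config, f.name)
    return data


def schedule_config_from_dict(data: dict) -> ScheduleConfig:
    kwargs: dict = {}
    for key in _PHASE_KEYS:
        if key in data:
            kwargs[f"{key}_params"] = PhaseParams(**data[key])
    for f in dataclasses.fields(ScheduleConfig):
        if not f.name.endswith("_params") and f.name in data:
            kwargs[f.name] = data[f.name]
    return ScheduleConfig(**kwargs)


def load_schedule_config(path: str | Path | None) -> ScheduleConfig:
    if path is None:
        return ScheduleConfig()
    data = yaml.safe_load(Path(path).read_text()) or {}
    return schedule_config_from_dict(data.get("schedule", data))


def load_synthetic_config(path: str | Path | None) -> SyntheticConfig:
    if path is None:
        return SyntheticConfig()
    data = yaml.safe_load(Path(path).read_text()) or {}
    data = data.get("corpus", data)
    names = {f.name for f in dataclasses.fields(SyntheticConfig)}
    return SyntheticConfig(**{k: v for k, v in data.items() if k in names})
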