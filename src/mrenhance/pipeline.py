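"""Composable preprocessing sequences and their ten named presets.

Each preset mirrors one row of the study design: which of Gibbs-artifact
removal, bias-field correction, intensity normalization (z-score or Nyul),
and AHE it applies, and in what order.  A starred bias entry means bias
correction runs *before* Gibbs removal — the distinguishing feature of
sequence 6, the best-performing order, versus sequence 2 which runs Gibbs
removal first.  Sequences 9 and 10 repeat sequence 1's single-stage recipe
on different datasets, so as stage lists they are identical to seq1.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field as dc_field
from typing import Any, Dict, List, Optional, Tuple

import numpy as np
import yaml

from . import __about__
from .biasfield import BiasParams, correct_bias
from .core import Volume3D
from .gibbs import UnringParams, unring_volume
from .intensity import AHEParams, NyulModel, ahe_3d, nyul_apply, nyul_train, zscore_normalize

__all__ = [
    "StageDescriptor",
    "SequenceConfig",
    "RunRecord",
    "PRESET_STAGES",
    "PRESET_FLAGS",
    "preset_sequence",
    "run_sequence",
    "load_config",
]

STAGE_KINDS = ("gibbs", "bias", "zscore", "nyul", "ahe")

#: Stage order of each named preset.
PRESET_STAGES: Dict[str, Tuple[str, ...]] = {
    "seq1": ("gibbs",),
    "seq2": ("gibbs", "bias"),
    "seq3": ("gibbs", "ahe"),
    "seq4": ("gibbs", "bias", "ahe"),
    "seq5": ("gibbs", "zscore"),
    "seq6": ("bias", "gibbs"),
    "seq7": ("bias", "gibbs", "zscore"),
    "seq8": ("bias", "gibbs", "nyul"),
    "seq9": ("gibbs",),
    "seq10": ("gibbs",),
}

#: Check-mark pattern of the design table: (gibbs, bias, normalize, ahe).
#: bias is None / "after-gibbs" (plain check) / "before-gibbs" (starred check).
PRESET_FLAGS: Dict[str, Tuple[bool, Optional[str], Optional[str], bool]] = {
    "seq1": (True, None, None, False),
    "seq2": (True, "after-gibbs", None, False),
    "seq3": (True, None, None, True),
    "seq4": (True, "after-gibbs", None, True),
    "seq5": (True, None, "zscore", False),
    "seq6": (True, "before-gibbs", None, False),
    "seq7": (True, "before-gibbs", "zscore", False),
    "seq8": (True, "before-gibbs", "nyul", False),
    "seq9": (True, None, None, False),
    "seq10": (True, None, None, False),
}


@dataclass
class StageDescriptor:
    """One processing stage: a kind plus its module's parameter record."""

    kind: str
    params: Any = None

    def __post_init__(self) -> None:
        if self.kind not in STAGE_KINDS:
            raise ValueError(f"unknown stage kind {self.kind!r}; valid: {STAGE_KINDS}")
        if self.params is None:
            self.params = _default_params(self.kind)
        expected = _PARAM_TYPES[self.kind]
        if expected is not None and not isinstance(self.params, expected):
            raise ValueError(
                f"stage {self.kind!r} expects params of type {expected.__name__}, "
                f"got {type(self.params).__name__}"
            )


@dataclass
class NyulStageParams:
    """Parameters of the Nyul stage inside a sequence.

    When no trained model is supplied the stage self-trains on the input
    volume (a single-volume model), which standardizes the scale while
    remaining a pure function of the input.
    """

    model: Optional[NyulModel] = None
    model_path: Optional[str] = None


_PARAM_TYPES = {
    "gibbs": UnringParams,
    "bias": BiasParams,
    "zscore": type(None),
    "nyul": NyulStageParams,
    "ahe": AHEParams,
}


def _default_params(kind: str):
    if kind == "gibbs":
        return UnringParams()
    if kind == "bias":
        return BiasParams()
    if kind == "nyul":
        return NyulStageParams()
    if kind == "ahe":
        return AHEParams()
    return None


@dataclass
class SequenceConfig:
    """An ordered, named list of stages."""

    stages: List[StageDescriptor]
    name: str = "custom"

    def kinds(self) -> Tuple[str, ...]:
        return tuple(s.kind for s in self.stages)


@dataclass
class RunRecord:
    """Provenance of one pipeline run: enough to re-run it identically."""

    sequence_name: str
    stage_kinds: Tuple[str, ...]
    stage_params: List[str]
    stage_stats: List[Dict[str, float]]
    toolkit_version: str = __about__.__version__
    input_path: Optional[str] = None
    started: float = 0.0
    finished: float = 0.0

    def as_dict(self) -> Dict[str, Any]:
        return {
            "sequence_name": self.sequence_name,
            "stage_kinds": list(self.stage_kinds),
            "stage_params": self.stage_params,
            "stage_stats": self.stage_stats,
            "toolkit_version": self.toolkit_version,
            "input_path": self.input_path,
            "started": self.started,
            "finished": self.finished,
        }


def preset_sequence(name: str, stage_params: Optional[Dict[str, Any]] = None) -> SequenceConfig:
    """Expand a named preset into an explicit stage list.

    ``stage_params`` optionally overrides the parameter record per stage kind.
    """
    if name not in PRESET_STAGES:
        raise ValueError(f"unknown preset {name!r}; valid presets: {', '.join(PRESET_STAGES)}")
    stage_params = stage_params or {}
    stages = [StageDescriptor(kind=k, params=stage_params.get(k)) for k in PRESET_STAGES[name]]
    return SequenceConfig(stages=stages, name=name)


def _masked_stats(vol: Volume3D) -> Tuple[float, float]:
    m = vol.foreground_mask()
    if not m.any():
        return 0.0, 0.0
    vals = vol.data[m]
    return float(vals.mean()), float(vals.std())


def _apply_stage(vol: Volume3D, stage: StageDescriptor, mask: Optional[np.ndarray]) -> Volume3D:
    if stage.kind == "gibbs":
        return unring_volume(vol, stage.params)
    if stage.kind == "bias":
        return correct_bias(vol, mask, stage.params).corrected
    if stage.kind == "zscore":
        return zscore_normalize(vol, mask)
    if stage.kind == "nyul":
        model = stage.params.model
        if model is None and stage.params.model_path:
            model = NyulModel.load(stage.params.model_path)
        if model is None:
            model = nyul_train([vol], [mask])
        return nyul_apply(vol, model, mask)
    if stage.kind == "ahe":
        return ahe_3d(vol, stage.params)
    raise ValueError(f"unknown stage kind {stage.kind!r}")


def run_sequence(vol: Volume3D, config: SequenceConfig,
                 mask: Optional[np.ndarray] = None,
                 input_path: Optional[str] = None) -> Tuple[Volume3D, RunRecord]:
    """Apply the configured stages strictly in order.

    A failing stage raises with the stage kind and position identified.
    4D handling lives in the CLI; this function is the single-channel core.
    """
    record = RunRecord(
        sequence_name=config.name,
        stage_kinds=config.kinds(),
        stage_params=[repr(s.params) for s in config.stages],
        stage_stats=[],
        input_path=input_path,
        started=time.time(),
    )
    current = vol
    for pos, stage in enumerate(config.stages, start=1):
        before = _masked_stats(current)
        t0 = time.time()
        try:
            current = _apply_stage(current, stage, mask)
        except Exception as exc:
            raise RuntimeError(
                f"stage {pos} ({stage.kind!r}) of sequence {config.name!r} failed: {exc}"
            ) from exc
        after = _masked_stats(current)
        record.stage_stats.append(
            {
                "stage": stage.kind,
                "mean_before": before[0],
                "sd_before": before[1],
                "mean_after": after[0],
                "sd_after": after[1],
                "elapsed_s": time.time() - t0,
            }
        )
    record.finished = time.time()
    return current, record


def load_config(path) -> SequenceConfig:
    """Build a SequenceConfig from a YAML stage list or a preset reference.

    Accepted forms::

        preset: seq6

    or an explicit stage list with optional per-stage parameter blocks::

        name: my-pipeline
        stages:
          - kind: bias
            params: {max_iterations: 30}
          - kind: gibbs
            params: {num_shifts: 20, min_window: 1, max_window: 3}
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: config must be a mapping")
    if "preset" in doc:
        return preset_sequence(doc["preset"])
    stages = []
    for entry in doc.get("stages", []):
        kind = entry["kind"]
        pblock = entry.get("params") or {}
        ptype = _PARAM_TYPES[kind] if kind in _PARAM_TYPES else None
        if kind == "zscore":
            params = None
        elif kind == "nyul":
            params = NyulStageParams(model_path=pblock.get("model_path"))
        else:
            params = ptype(**pblock)
        stages.append(StageDescriptor(kind=kind, params=params))
    if not stages:
        raise ValueError(f"{path}: no stages defined")
    return SequenceConfig(stages=stages, name=doc.get("name", "custom"))
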