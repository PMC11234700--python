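"""Model configuration loading/saving and tabular result serialisation.

A model file is YAML (or JSON) with top-level keys ``parameters``, ``tree``
and ``settings``; the schema is enforced on load by the pydantic domain
models and published as a versioned JSON-schema document shipped with the
package.  Machine-readable result files are comma-separated, dot-decimal,
UTF-8, without thousands separators; full float precision is kept wherever a
file is meant to round-trip, and only the human-facing CEA table applies
display rounding (currency to 2 decimals, QALYs to 6).
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import List, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .cea import CEATable
from .engine import StrategyOutcome
from .errors import ModelError
from .psa import CEACCurve, PSASampleSet
from .sensitivity import ThresholdResult, TornadoEntry
from .tree_model import AnalysisSettings, DecisionTree, Parameter, ParameterSet

CONFIG_SCHEMA_VERSION = 1

#: name of the calibrated ACL model configuration shipped with the package
BUNDLED_ACL_CONFIG = "acl_indonesia.yaml"


class ModelConfig(BaseModel):
    """Top-level schema of a model configuration file."""

    model_config = ConfigDict(extra="forbid")

    schema_version: int = Field(default=CONFIG_SCHEMA_VERSION)
    parameters: List[Parameter]
    tree: DecisionTree
    settings: AnalysisSettings = Field(default_factory=AnalysisSettings)


ModelBundle = Tuple[DecisionTree, ParameterSet, AnalysisSettings]


def loads_config(text: str) -> ModelBundle:
    """Parse a YAML/JSON model configuration from a string."""
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ModelError(f"cannot parse model configuration: {exc}") from exc
    if not isinstance(raw, dict):
        raise ModelError("model configuration must be a mapping with keys "
                         "'parameters', 'tree', 'settings'")
    try:
        cfg = ModelConfig.model_validate(raw)
    except Exception as exc:  # pydantic.ValidationError
        raise ModelError(f"invalid model configuration:\n{exc}") from exc
    if cfg.schema_version != CONFIG_SCHEMA_VERSION:
        raise ModelError(
            f"unsupported schema_version {cfg.schema_version} "
            f"(this package reads version {CONFIG_SCHEMA_VERSION})"
        )
    return cfg.tree, ParameterSet(cfg.parameters), cfg.settings


def load_config(path: Union[str, Path]) -> ModelBundle:
    """Load and validate a model configuration file."""
    p = Path(path)
    if not p.exists():
        raise ModelError(f"model file not found: {p}")
    return loads_config(p.read_text(encoding="utf-8"))


def dumps_config(tree: DecisionTree, params: ParameterSet,
                 settings: AnalysisSettings) -> str:
    """Serialise a model to YAML (full float precision, stable key order)."""
    cfg = ModelConfig(schema_version=CONFIG_SCHEMA_VERSION,
                      parameters=params.parameters, tree=tree, settings=settings)
    payload = cfg.model_dump(mode="json", exclude_none=True)
    return yaml.safe_dump(payload, sort_keys=False, width=100)


def save_config(path: Union[str, Path], tree: DecisionTree, params: ParameterSet,
                settings: AnalysisSettings) -> None:
    Path(path).write_text(dumps_config(tree, params, settings), encoding="utf-8")


def config_json_schema() -> dict:
    """JSON schema of the configuration format (also shipped as a data file)."""
    schema = ModelConfig.model_json_schema()
    schema["$id"] = f"ceatree-model-config-v{CONFIG_SCHEMA_VERSION}"
    return schema


def bundled_config_path() -> Path:
    """Filesystem path of the calibrated ACL model shipped with the package."""
    return Path(resources.files("ceatree").joinpath("data", BUNDLED_ACL_CONFIG))


def load_bundled_acl_model() -> ModelBundle:
    return load_config(bundled_config_path())


# --------------------------------------------------------------------------
# Result writers
# --------------------------------------------------------------------------


def outcomes_frame(outcomes: Sequence[StrategyOutcome]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"strategy": o.strategy, "cost": o.cost, "effect": o.effect} for o in outcomes]
    )


def write_outcomes(outcomes: Sequence[StrategyOutcome], path: Union[str, Path]) -> None:
    outcomes_frame(outcomes).to_csv(path, index=False)


def cea_table_frame(table: CEATable, display: bool = True) -> pd.DataFrame:
    """CEA table as a DataFrame; ``display=True`` applies report rounding."""
    frame = table.to_frame()
    if display:
        for col in ("cost", "incr_cost", "nmb"):
            frame[col] = frame[col].map(lambda v: None if pd.isna(v) else round(float(v), 2))
        for col in ("effect", "incr_effect"):
            frame[col] = frame[col].map(lambda v: None if pd.isna(v) else round(float(v), 6))
        frame["icer"] = frame["icer"].map(
            lambda v: v if v is None or isinstance(v, str) or pd.isna(v) else round(float(v), 2)
        )
    return frame


def write_cea_table(table: CEATable, path: Union[str, Path]) -> None:
    cea_table_frame(table).to_csv(path, index=False)


def write_psa_samples(samples: PSASampleSet, path: Union[str, Path]) -> None:
    samples.data.to_csv(path, index=False)


def read_psa_samples(path: Union[str, Path], seed: int = -1) -> PSASampleSet:
    data = pd.read_csv(path)
    draws = int(data["draw"].nunique())
    return PSASampleSet(draws=draws, seed=seed, data=data)


def write_ceac(curve: CEACCurve, path: Union[str, Path]) -> None:
    long = curve.probabilities.reset_index().melt(
        id_vars="wtp", var_name="strategy", value_name="probability"
    )
    long.to_csv(path, index=False)


def write_oneway(results: Sequence[Tuple[float, float]], name: str, output: str,
                 path: Union[str, Path]) -> None:
    pd.DataFrame(results, columns=[name, output]).to_csv(path, index=False)


def write_twoway(matrix: np.ndarray, grid_a: Sequence[float], grid_b: Sequence[float],
                 name_a: str, name_b: str, path: Union[str, Path]) -> None:
    frame = pd.DataFrame(matrix, index=pd.Index(grid_a, name=name_a),
                         columns=pd.Index(grid_b, name=name_b))
    frame.to_csv(path)


def write_tornado(entries: Sequence[TornadoEntry], path: Union[str, Path]) -> None:
    pd.DataFrame(
        [
            {
                "parameter": e.parameter,
                "low": e.low,
                "high": e.high,
                "output_low": e.output_low,
                "output_high": e.output_high,
                "spread": e.spread,
            }
            for e in entries
        ]
    ).to_csv(path, index=False)


def write_threshold(result: ThresholdResult, path: Union[str, Path]) -> None:
    payload = {
        "parameter": result.parameter,
        "threshold": result.threshold,
        "direction": result.direction,
        "converged": result.converged,
        "iterations": result.iterations,
        "value_at_threshold": result.value_at_threshold,
        "value_lo": result.value_lo,
        "value_hi": result.value_hi,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")
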