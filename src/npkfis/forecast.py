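"""Domain layer: the packaged default NPK system and user-facing forecasts.

The default system interprets soil-test readings in ppm.  Input universes
are nitrogen 0-100, phosphorus 0-150 and potassium 0-1500 ppm, each split
into LOW / ADEQUATE / HIGH / EXCESSIVE bands per standard soil-test
interpretation charts.  The four outputs — required N, required P, required
K and soil fertility — live on a converted 0-100 scale, soil fertility
explicitly a percentage.  (Whether the 0-100 required-potassium scale is
ppm or an index is ambiguous in the source charts; values are reported
as-is on 0-100.)
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd

from .errors import ConfigError, InvalidInputError
from .inference import (
    DEFAULT_RESOLUTION,
    FiringRecord,
    FuzzySystem,
    InferenceResult,
    infer,
)
from .membership import (
    InputLevel,
    Level,
    LinguisticVariable,
    OutputLevel,
    fuzzify,
    variables_from_json,
)
from .rulebase import (
    ANTECEDENT_VARS,
    CONSEQUENT_VARS,
    generate_rule_base,
    parse_rules,
)

__all__ = [
    "SoilSample",
    "Forecast",
    "default_system",
    "forecast",
    "classify_crisp",
    "read_samples_csv",
    "write_samples_csv",
    "forecast_frame",
    "run_batch",
]

_CSV_COLUMNS = ("n_ppm", "p_ppm", "k_ppm")


@dataclass(frozen=True)
class SoilSample:
    """One soil-test reading: N, P, K in parts per million, optional
    crisp fertility label (LOW / AVERAGE / HIGH)."""

    n_ppm: float
    p_ppm: float
    k_ppm: float
    label: Optional[str] = None

    def __post_init__(self) -> None:
        for name, v in (("n_ppm", self.n_ppm), ("p_ppm", self.p_ppm), ("k_ppm", self.k_ppm)):
            if not isinstance(v, (int, float)) or not math.isfinite(v):
                raise InvalidInputError(f"{name} must be finite, got {v!r}")
            if v < 0:
                raise InvalidInputError(f"{name} must be >= 0 ppm, got {v}")
        if self.label is not None and self.label not in OutputLevel.__members__:
            raise InvalidInputError(
                f"label must be one of {list(OutputLevel.__members__)}, got {self.label!r}"
            )

    def as_inputs(self) -> dict[str, float]:
        return {"N": self.n_ppm, "P": self.p_ppm, "K": self.k_ppm}


@dataclass(frozen=True)
class Forecast:
    """Crisp forecast for one sample.

    ``fertility_pct`` is the soil-fertility percentage (0-100);
    ``required_*`` are on the 0-100 recommendation scale.  ``labels`` maps
    each output to the linguistic level of maximal membership at its crisp
    value, and ``trace`` lists every rule that fired with its strength.
    """

    fertility_pct: float
    required_n: float
    required_p: float
    required_k: float
    labels: dict[str, str]
    trace: tuple[FiringRecord, ...]
    nil_defaults: frozenset[str]

    @property
    def fertility_label(self) -> str:
        return self.labels["S.F"]

    def to_dict(self, include_trace: bool = False) -> dict:
        d = {
            "fertility_pct": self.fertility_pct,
            "required_n": self.required_n,
            "required_p": self.required_p,
            "required_k": self.required_k,
            "labels": dict(self.labels),
        }
        if include_trace:
            d["trace"] = InferenceResult(
                values={}, trace=self.trace, nil_defaults=self.nil_defaults
            ).trace_json()
        return d

    def to_json(self, include_trace: bool = False) -> str:
        return json.dumps(self.to_dict(include_trace=include_trace), indent=2)


def _read_packaged(name: str) -> str:
    return (resources.files("npkfis") / "data" / name).read_text(encoding="utf-8")


def default_system(
    config_path: Union[str, Path, None] = None,
    rules_path: Union[str, Path, None] = None,
    resolution: int = DEFAULT_RESOLUTION,
) -> FuzzySystem:
    """Build (and validate) the packaged default system, optionally
    overriding the variable config JSON and/or the rule DSL file."""
    if config_path is None:
        config_text = _read_packaged("system_default.json")
    else:
        config_text = Path(config_path).read_text(encoding="utf-8")
    if rules_path is None:
        rules_text = _read_packaged("rules_default.txt")
    else:
        rules_text = Path(rules_path).read_text(encoding="utf-8")

    variables = variables_from_json(config_text)
    missing = [v for v in (*ANTECEDENT_VARS, *CONSEQUENT_VARS) if v not in variables]
    if missing:
        raise ConfigError(f"system config missing variables {missing}")
    system = FuzzySystem(
        inputs={v: variables[v] for v in ANTECEDENT_VARS},
        outputs={v: variables[v] for v in CONSEQUENT_VARS},
        rules=parse_rules(rules_text),
        resolution=resolution,
    )
    system.validate()
    return system


def _argmax_level(var: LinguisticVariable, x: float) -> Level:
    degrees = fuzzify(var, x)
    return max(degrees, key=lambda lvl: (degrees[lvl], -lvl.order))


def forecast(
    sample: SoilSample,
    system: Optional[FuzzySystem] = None,
    resolution: Optional[int] = None,
) -> Forecast:
    """Forecast soil fertility and required NPK for one sample."""
    if system is None:
        system = default_system()
    result = infer(system, sample.as_inputs(), resolution=resolution)
    labels = {
        name: _argmax_level(system.outputs[name], value).name
        for name, value in result.values.items()
    }
    return Forecast(
        fertility_pct=result.values["S.F"],
        required_n=result.values["R.N"],
        required_p=result.values["R.P"],
        required_k=result.values["R.K"],
        labels=labels,
        trace=result.trace,
        nil_defaults=result.nil_defaults,
    )


def classify_crisp(var: LinguisticVariable, x: float) -> Level:
    """Crisp-interval classification against the printed interval table.

    The value (clipped to the domain) falls in the unique printed band,
    with each boundary belonging to the lower band (a nitrogen reading of
    exactly 20 ppm is LOW, 20.1 is ADEQUATE) and the final band closed.
    """
    if not isinstance(x, (int, float)) or not math.isfinite(x):
        raise InvalidInputError(f"{var.name}: crisp value must be finite, got {x!r}")
    xc = var.clip(float(x))
    for band in var.bands[:-1]:
        if xc <= band.hi:
            return band.level
    return var.bands[-1].level


# ---------------------------------------------------------------------------
# CSV batch interface
# ---------------------------------------------------------------------------

def read_samples_csv(path: Union[str, Path]) -> list[SoilSample]:
    """Read samples from CSV with columns n_ppm, p_ppm, k_ppm[, label]."""
    df = pd.read_csv(path)
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigError(f"{path}: missing required columns {missing}")
    has_label = "label" in df.columns
    samples = []
    for row in df.itertuples(index=False):
        label = getattr(row, "label") if has_label else None
        if label is not None and (not isinstance(label, str) or not label):
            label = None
        samples.append(
            SoilSample(float(row.n_ppm), float(row.p_ppm), float(row.k_ppm), label)
        )
    return samples


def write_samples_csv(samples: Iterable[SoilSample], path: Union[str, Path]) -> None:
    rows = [
        {"n_ppm": s.n_ppm, "p_ppm": s.p_ppm, "k_ppm": s.k_ppm, "label": s.label}
        for s in samples
    ]
    df = pd.DataFrame(rows)
    if df["label"].isna().all():
        df = df.drop(columns=["label"])
    df.to_csv(path, index=False)


def forecast_frame(
    samples: Iterable[SoilSample],
    system: Optional[FuzzySystem] = None,
) -> pd.DataFrame:
    """Forecast a batch; returns the input columns with forecast columns
    appended (fertility_pct, required_n/p/k, *_label)."""
    if system is None:
        system = default_system()
    rows = []
    for s in samples:
        fc = forecast(s, system)
        row = {"n_ppm": s.n_ppm, "p_ppm": s.p_ppm, "k_ppm": s.k_ppm}
        if s.label is not None:
            row["label"] = s.label
        row.update(
            fertility_pct=fc.fertility_pct,
            required_n=fc.required_n,
            required_p=fc.required_p,
            required_k=fc.required_k,
            fertility_label=fc.labels["S.F"],
            required_n_label=fc.labels["R.N"],
            required_p_label=fc.labels["R.P"],
            required_k_label=fc.labels["R.K"],
        )
        rows.append(row)
    return pd.DataFrame(rows)


def run_batch(
    in_path: Union[str, Path],
    out_path: Union[str, Path],
    system: Optional[FuzzySystem] = None,
) -> pd.DataFrame:
    """Forecast every row of ``in_path`` and write the result CSV."""
    df = forecast_frame(read_samples_csv(in_path), system)
    df.to_csv(out_path, index=False)
    return df
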