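"""Synthetic labelled NPK panels.

Emulates a labelled soil-test panel — triples of (N, P, K) readings in ppm
with a crisp fertility class — so the forecaster and its metrics can be
exercised without any field data.  Ground-truth labels come from the same
crisp interpretation the rule base encodes: each nutrient is classified
against its printed interval table and the fertility class is the minimum
per-nutrient adequacy.  This is the only self-consistent labelling oracle
available without real annotated samples; panels therefore probe the
fuzzy pipeline's fidelity to its own crisp semantics, not real-world
accuracy.

Sampling modes:

- ``uniform``: readings uniform over each nutrient's full domain;
- ``stratified``: at least one sample per each of the 64 level cells,
  uniform within the cell's printed intervals;
- ``prototype-jitter``: cell prototypes (printed-interval midpoints) plus
  Gaussian noise of standard deviation sigma ppm, clipped to the domain.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from itertools import product
from pathlib import Path
from typing import Callable, Optional, Union

import numpy as np
import pandas as pd

from .errors import PanelSpecError
from .forecast import SoilSample, write_samples_csv
from .inference import FuzzySystem
from .membership import InputLevel, LevelBand
from .rulebase import ANTECEDENT_VARS, fertility_consequent

__all__ = ["SamplingMode", "PanelSpec", "generate_panel", "panel_frame", "write_panel_csv"]


class SamplingMode(str, Enum):
    UNIFORM = "uniform"
    STRATIFIED = "stratified"
    PROTOTYPE_JITTER = "prototype-jitter"


LabelRule = Callable[[InputLevel, InputLevel, InputLevel], str]


def _crisp_label(n: InputLevel, p: InputLevel, k: InputLevel) -> str:
    return fertility_consequent(n, p, k).name


@dataclass(frozen=True)
class PanelSpec:
    """Specification of a synthetic panel.

    ``sigma`` (ppm) is the jitter for prototype-jitter mode; ``label_rule``
    defaults to the crisp adequacy map shared with the rule base.
    """

    count: int
    seed: Optional[int] = None
    mode: SamplingMode = SamplingMode.UNIFORM
    sigma: float = 0.0
    label_rule: LabelRule = _crisp_label

    def __post_init__(self) -> None:
        if self.count < 1:
            raise PanelSpecError(f"count must be >= 1, got {self.count}")
        if self.sigma < 0:
            raise PanelSpecError(f"sigma must be >= 0, got {self.sigma}")
        if self.mode is SamplingMode.STRATIFIED and self.count < len(_cells()):
            raise PanelSpecError(
                f"stratified mode needs count >= {len(_cells())} "
                f"(one per level cell), got {self.count}"
            )


def _cells() -> list[tuple[InputLevel, InputLevel, InputLevel]]:
    return list(product(InputLevel, repeat=3))


def _band(system: FuzzySystem, var: str, level: InputLevel) -> LevelBand:
    return system.inputs[var].band(level)


def _classify(system: FuzzySystem, sample: tuple[float, float, float]):
    # crisp per-nutrient classification (upper-inclusive printed bands)
    from .forecast import classify_crisp

    return tuple(
        classify_crisp(system.inputs[v], x) for v, x in zip(ANTECEDENT_VARS, sample)
    )


def generate_panel(spec: PanelSpec, system: Optional[FuzzySystem] = None) -> list[SoilSample]:
    """Generate a reproducible labelled panel under ``spec``."""
    if system is None:
        from .forecast import default_system

        system = default_system()
    rng = np.random.default_rng(spec.seed)
    cells = _cells()
    triples: list[tuple[float, float, float]] = []

    if spec.mode is SamplingMode.UNIFORM:
        for _ in range(spec.count):
            triples.append(
                tuple(
                    float(rng.uniform(*system.inputs[v].domain)) for v in ANTECEDENT_VARS
                )
            )
    elif spec.mode is SamplingMode.STRATIFIED:
        for i in range(spec.count):
            cell = cells[i % len(cells)]
            triple = []
            for var, level in zip(ANTECEDENT_VARS, cell):
                band = _band(system, var, level)
                lo = max(band.lo, system.inputs[var].domain[0])
                triple.append(float(rng.uniform(lo, band.hi)))
            triples.append(tuple(triple))
    elif spec.mode is SamplingMode.PROTOTYPE_JITTER:
        for i in range(spec.count):
            cell = cells[i % len(cells)]
            triple = []
            for var, level in zip(ANTECEDENT_VARS, cell):
                band = _band(system, var, level)
                mid = (band.lo + band.hi) / 2.0
                value = mid + (float(rng.normal(0.0, spec.sigma)) if spec.sigma > 0 else 0.0)
                lo_d, hi_d = system.inputs[var].domain
                triple.append(float(min(max(value, lo_d), hi_d)))
            triples.append(tuple(triple))
    else:  # pragma: no cover - enum is exhaustive
        raise PanelSpecError(f"unknown sampling mode {spec.mode!r}")

    samples = []
    for triple in triples:
        levels = _classify(system, triple)
        samples.append(SoilSample(*triple, label=spec.label_rule(*levels)))
    return samples


def panel_frame(samples: list[SoilSample]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"n_ppm": s.n_ppm, "p_ppm": s.p_ppm, "k_ppm": s.k_ppm, "label": s.label}
            for s in samples
        ]
    )


def write_panel_csv(samples: list[SoilSample], path: Union[str, Path]) -> None:
    write_samples_csv(samples, path)
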