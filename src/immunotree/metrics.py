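"""Expression metrics: percent change vs baseline and the DC infiltration index.

Percent change of a molecule is ((D/C) - 1) * 100 where C is the steady-state
concentration (µM) in the non-tumorigenic baseline network and D the
concentration in the patient-specific disease-state network.  The
dendritic-cell infiltration index summarises the 9 chemokine percent changes
as a weighted sum with nonnegative weights normalised to 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, NamedTuple

from .cohort import CHEMOKINE_NAMES, ISM_NAMES, PatientRecord

__all__ = [
    "BaselinePair",
    "ChemokineWeights",
    "percent_change",
    "dc_infiltration_index",
    "max_ism_excess",
    "load_weights",
]

_WEIGHT_SUM_TOL = 1e-9
_WEIGHT_RENORM_TOL = 1e-6


class BaselinePair(NamedTuple):
    """Baseline (control, C) and disease (D) concentrations of one molecule."""

    control_value: float
    disease_value: float


def percent_change(pair: BaselinePair | tuple[float, float]) -> float:
    """Percent change of the disease state relative to baseline.

    Computes ``((D / C) - 1) * 100``; the sign is preserved and no clamping
    is applied.  Raises :class:`ValueError` for a nonpositive baseline, for
    which the ratio is undefined as an expression change.
    """
    control, disease = pair
    if control <= 0:
        raise ValueError(
            f"baseline control concentration must be positive, got {control}"
        )
    return (disease / control - 1.0) * 100.0


@dataclass(frozen=True)
class ChemokineWeights:
    """Nonnegative per-chemokine weights normalised to sum to 1."""

    weights: Mapping[str, float]

    def __post_init__(self) -> None:
        got = set(self.weights)
        if got != set(CHEMOKINE_NAMES):
            raise ValueError(
                "weights must cover exactly the 9 canonical chemokines; "
                f"missing={sorted(set(CHEMOKINE_NAMES) - got)}, "
                f"extra={sorted(got - set(CHEMOKINE_NAMES))}"
            )
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("chemokine weights must be nonnegative")
        total = sum(self.weights.values())
        if abs(total - 1.0) > _WEIGHT_SUM_TOL:
            raise ValueError(
                f"chemokine weights must sum to 1 (got {total!r})"
            )

    @classmethod
    def uniform(cls) -> "ChemokineWeights":
        return cls({c: 1.0 / len(CHEMOKINE_NAMES) for c in CHEMOKINE_NAMES})


def load_weights(path: Path | str) -> ChemokineWeights:
    """Load a chemokine-weight configuration from JSON or YAML.

    A weight vector whose sum deviates from 1 by at most 1e-6 is
    renormalised; a larger deviation is rejected.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        import yaml

        raw = yaml.safe_load(text)
    else:
        raw = json.loads(text)
    if not isinstance(raw, dict):
        raise ValueError(f"weights file {path} must map chemokine -> weight")
    weights = {str(k): float(v) for k, v in raw.items()}
    total = sum(weights.values())
    if abs(total - 1.0) > _WEIGHT_RENORM_TOL:
        raise ValueError(
            f"weights in {path} sum to {total!r}; "
            f"deviation from 1 exceeds {_WEIGHT_RENORM_TOL}"
        )
    if total > 0:
        weights = {k: v / total for k, v in weights.items()}
    return ChemokineWeights(weights)


def dc_infiltration_index(
    chemokine_pct: Mapping[str, float],
    weights: ChemokineWeights | None = None,
) -> float:
    """Weighted dendritic-cell infiltration index.

    Returns the sum over the 9 chemokines of percent change times weight.
    With the default uniform weights this is the arithmetic mean of the
    chemokine percent changes.
    """
    if weights is None:
        weights = ChemokineWeights.uniform()
    missing = [c for c in CHEMOKINE_NAMES if c not in chemokine_pct]
    if missing:
        raise KeyError(
            f"chemokine percent map is missing {missing[0]!r} "
            f"(all of {missing} absent)"
        )
    return sum(
        chemokine_pct[c] * weights.weights[c] for c in CHEMOKINE_NAMES
    )


def max_ism_excess(
    record: PatientRecord, margin: float = 5.0
) -> tuple[list[str], float]:
    """Immunosuppressive molecules exceeding PD-L1 by more than ``margin``.

    Returns the list of ISM names whose percent change exceeds the patient's
    PD-L1 percent change by strictly more than ``margin`` percentage points
    (in canonical order), together with the maximum excess
    ``ism_pct - pdl1_pct`` over all 14 molecules.
    """
    excesses = {m: record.ism_pct[m] - record.pdl1_pct for m in ISM_NAMES}
    names = [m for m in ISM_NAMES if excesses[m] > margin]
    return names, max(excesses.values())
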