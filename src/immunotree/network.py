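"""Reduced ODE model of PD-L1 regulatory signaling.

A declarative reaction network is integrated to a homeostatic steady state
with a stiff implicit solver (Radau), once for the unperturbed baseline and
once with a patient's mutation profile applied, and molecule readouts are
reported as percent change of the perturbed steady state over the baseline.

The packaged network encodes the canonical PD-L1 regulation arms — the
RAS/RAF/MEK/ERK cascade converging on AP-1, the PI3K/AKT/mTOR/STAT3 arm, and
the IFN-γ/STAT1/IRF1 arm — whose activation factors drive PD-L1
transcription, together with a wild-type TP53 inhibitory arm and the
STK11/AMPK and KEAP1 positive regulatory links relevant to KRAS co-mutation
subgroups.  The 14 immunosuppressive molecules and 9 chemokines are modelled
as lumped transcriptional targets of the same activation factors.

Kinetics are Michaelis–Menten or mass action.  Rates:

* ``michaelis_menten``: ``Vmax * S / (Km + S)`` over the (consumed)
  substrate when one is declared, times saturating activator factors
  ``A / (Ka + A)`` and inhibitor factors ``Ki / (Ki + I)``.  A reaction with
  no substrate is a regulated synthesis term driven entirely by its
  modifiers.
* ``mass_action``: ``k`` times the product of substrate concentrations,
  times the same modifier factors.

Mutation perturbations act on the network specification, never on solver
state: a gain of function scales the rate parameters of every reaction the
gene drives (and sharpens its inhibitory constants); a loss of function
applies the reciprocal scaling; amplification and deletion act on the
gene's basal synthesis rate.
"""

from __future__ import annotations

import copy
import enum
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy.integrate import solve_ivp

from .metrics import BaselinePair, percent_change

__all__ = [
    "Species",
    "Modifier",
    "Reaction",
    "NetworkSpec",
    "MutationEffect",
    "MutationPerturbation",
    "SteadyState",
    "SimulationResult",
    "michaelis_menten_rate",
    "load_network",
    "load_mutations",
    "bundled_network",
    "apply_perturbations",
    "simulate_to_steady_state",
    "predict_profile",
    "DEFAULT_MAGNITUDES",
]

#: Default perturbation multipliers: clearly separated effect sizes for
#: activity gain, activity loss (reciprocal), and copy-number changes.
DEFAULT_MAGNITUDES = {
    "oncogene_gof": 5.0,
    "tsg_lof": 10.0,  # activity is divided by this factor
    "amplification": 5.0,
}


class NetworkSchemaError(ValueError):
    """The network specification violates its schema or invariants."""


def michaelis_menten_rate(substrate: float, vmax: float, km: float) -> float:
    """Michaelis–Menten rate ``Vmax * S / (Km + S)``."""
    if km <= 0:
        raise ValueError(f"Km must be positive, got {km}")
    if substrate < 0:
        raise ValueError(f"substrate concentration must be >= 0, got {substrate}")
    return vmax * substrate / (km + substrate)


@dataclass
class Species:
    name: str
    baseline_synthesis_rate: float = 0.0
    degradation_rate: float = 1.0
    initial_concentration: float = 0.0

    def validate(self) -> None:
        if self.baseline_synthesis_rate < 0 or self.degradation_rate < 0:
            raise NetworkSchemaError(
                f"species {self.name!r}: rates must be nonnegative"
            )
        if self.initial_concentration < 0:
            raise NetworkSchemaError(
                f"species {self.name!r}: initial concentration must be >= 0"
            )


@dataclass
class Modifier:
    """An activator (half-saturation ``ka``) or inhibitor (constant ``ki``)."""

    species: str
    constant: float  # Ka for activators, Ki for inhibitors

    def validate(self, role: str, reaction_id: str) -> None:
        if self.constant <= 0:
            raise NetworkSchemaError(
                f"reaction {reaction_id!r}: {role} constant for "
                f"{self.species!r} must be positive"
            )


@dataclass
class Reaction:
    id: str
    kind: str  # "michaelis_menten" | "mass_action"
    products: list[str]
    substrates: list[str] = field(default_factory=list)
    activators: list[Modifier] = field(default_factory=list)
    inhibitors: list[Modifier] = field(default_factory=list)
    parameters: dict[str, float] = field(default_factory=dict)

    def rate_parameter_name(self) -> str:
        return "Vmax" if self.kind == "michaelis_menten" else "k"

    def validate(self, species_names: set[str]) -> None:
        if self.kind not in ("michaelis_menten", "mass_action"):
            raise NetworkSchemaError(
                f"reaction {self.id!r}: unknown kind {self.kind!r}"
            )
        for name in self.substrates + self.products:
            if name not in species_names:
                raise NetworkSchemaError(
                    f"reaction {self.id!r} references undeclared species "
                    f"{name!r}"
                )
        for mod in self.activators:
            mod.validate("activator", self.id)
            if mod.species not in species_names:
                raise NetworkSchemaError(
                    f"reaction {self.id!r} references undeclared species "
                    f"{mod.species!r}"
                )
        for mod in self.inhibitors:
            mod.validate("inhibitor", self.id)
            if mod.species not in species_names:
                raise NetworkSchemaError(
                    f"reaction {self.id!r} references undeclared species "
                    f"{mod.species!r}"
                )
        rate_name = self.rate_parameter_name()
        if rate_name not in self.parameters:
            raise NetworkSchemaError(
                f"reaction {self.id!r}: missing parameter {rate_name!r}"
            )
        if self.parameters[rate_name] < 0:
            raise NetworkSchemaError(
                f"reaction {self.id!r}: {rate_name} must be nonnegative"
            )
        if self.kind == "michaelis_menten":
            km = self.parameters.get("Km")
            if km is None or km <= 0:
                raise NetworkSchemaError(
                    f"reaction {self.id!r}: Michaelis-Menten Km must be "
                    f"positive, got {km}"
                )

    def drivers(self) -> list[str]:
        """Species whose activity drives this reaction forward."""
        return list(self.substrates) + [m.species for m in self.activators]


@dataclass
class NetworkSpec:
    species: list[Species]
    reactions: list[Reaction]
    outputs: list[str]
    name: str = ""

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        names = [s.name for s in self.species]
        if len(names) != len(set(names)):
            raise NetworkSchemaError("duplicate species names in network")
        name_set = set(names)
        for sp in self.species:
            sp.validate()
        for rxn in self.reactions:
            rxn.validate(name_set)
        for out in self.outputs:
            if out not in name_set:
                raise NetworkSchemaError(
                    f"output {out!r} is not a declared species"
                )
        if "PDL1" not in self.outputs:
            raise NetworkSchemaError("outputs must include PDL1")

    def species_names(self) -> list[str]:
        return [s.name for s in self.species]


class MutationEffect(str, enum.Enum):
    ONCOGENE_GOF = "oncogene_gof"
    TSG_LOF = "tsg_lof"
    AMPLIFICATION = "amplification"
    DELETION = "deletion"


@dataclass(frozen=True)
class MutationPerturbation:
    gene: str
    effect: MutationEffect
    magnitude: float | None = None

    def resolved_magnitude(self) -> float:
        if self.effect == MutationEffect.DELETION:
            return 0.0
        if self.magnitude is not None:
            if self.magnitude <= 0:
                raise ValueError(
                    f"perturbation magnitude must be positive, "
                    f"got {self.magnitude}"
                )
            return self.magnitude
        return DEFAULT_MAGNITUDES[self.effect.value]


def _as_modifiers(raw: object, reaction_id: str, role: str) -> list[Modifier]:
    mods = []
    for entry in raw or []:
        if not isinstance(entry, Mapping) or "species" not in entry:
            raise NetworkSchemaError(
                f"reaction {reaction_id!r}: each {role} needs a 'species' key"
            )
        mods.append(
            Modifier(str(entry["species"]), float(entry.get("constant", 1.0)))
        )
    return mods


def _spec_from_mapping(raw: Mapping, name: str = "") -> NetworkSpec:
    species = [
        Species(
            name=str(s["name"]),
            baseline_synthesis_rate=float(s.get("baseline_synthesis_rate", 0.0)),
            degradation_rate=float(s.get("degradation_rate", 1.0)),
            initial_concentration=float(s.get("initial_concentration", 0.0)),
        )
        for s in raw.get("species", [])
    ]
    reactions = []
    for r in raw.get("reactions", []):
        rid = str(r.get("id", f"rxn{len(reactions)}"))
        reactions.append(
            Reaction(
                id=rid,
                kind=str(r.get("kind", "michaelis_menten")),
                products=[str(p) for p in r.get("products", [])],
                substrates=[str(s) for s in r.get("substrates", [])],
                activators=_as_modifiers(r.get("activators"), rid, "activator"),
                inhibitors=_as_modifiers(r.get("inhibitors"), rid, "inhibitor"),
                parameters={k: float(v) for k, v in (r.get("parameters") or {}).items()},
            )
        )
    return NetworkSpec(
        species=species,
        reactions=reactions,
        outputs=[str(o) for o in raw.get("outputs", [])],
        name=str(raw.get("name", name)),
    )


def load_network(path: Path | str) -> NetworkSpec:
    """Load and validate a reaction-network specification from YAML/JSON."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"network file not found: {path}")
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, Mapping):
        raise NetworkSchemaError(f"network file {path} must be a mapping")
    return _spec_from_mapping(raw, name=path.stem)


def bundled_network() -> NetworkSpec:
    """The packaged reduced PD-L1 regulation network."""
    ref = resources.files("immunotree.data").joinpath("pdl1_network.yaml")
    with resources.as_file(ref) as path:
        return load_network(path)


def load_mutations(path: Path | str) -> list[MutationPerturbation]:
    """Read a mutation profile (TSV with columns gene, effect[, magnitude])."""
    import pandas as pd

    frame = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("gene", "effect"):
        if col not in frame.columns:
            raise NetworkSchemaError(
                f"mutation file {path} is missing column {col!r}"
            )
    muts = []
    for _, row in frame.iterrows():
        magnitude = None
        if "magnitude" in frame.columns and isinstance(row.get("magnitude"), str):
            magnitude = float(row["magnitude"])
        muts.append(
            MutationPerturbation(
                gene=str(row["gene"]).strip(),
                effect=MutationEffect(str(row["effect"]).strip()),
                magnitude=magnitude,
            )
        )
    return muts


def apply_perturbations(
    network: NetworkSpec, mutations: Sequence[MutationPerturbation]
) -> NetworkSpec:
    """Return a new network with the mutation profile applied.

    Activity-level effects (gain/loss of function) rescale the rate
    parameter of every reaction the gene drives — as substrate or activator
    — and the gene's inhibition constants where it acts as inhibitor (a
    gain sharpens inhibition, a loss relaxes it).  Expression-level effects
    (amplification/deletion) rescale or zero the gene's basal synthesis.
    The input specification is never modified.
    """
    perturbed = copy.deepcopy(network)
    valid = set(perturbed.species_names())
    for mut in mutations:
        if mut.gene not in valid:
            raise KeyError(
                f"unknown gene {mut.gene!r}; network species are "
                f"{sorted(valid)}"
            )
        if mut.effect in (MutationEffect.AMPLIFICATION, MutationEffect.DELETION):
            factor = mut.resolved_magnitude()
            for sp in perturbed.species:
                if sp.name == mut.gene:
                    sp.baseline_synthesis_rate *= factor
            continue
        magnitude = mut.resolved_magnitude()
        if mut.effect == MutationEffect.ONCOGENE_GOF:
            drive_factor, ki_factor = magnitude, 1.0 / magnitude
        else:  # TSG_LOF: activity approaches loss
            drive_factor, ki_factor = 1.0 / magnitude, magnitude
        for rxn in perturbed.reactions:
            if mut.gene in rxn.drivers():
                rate_name = rxn.rate_parameter_name()
                rxn.parameters[rate_name] *= drive_factor
            for mod in rxn.inhibitors:
                if mod.species == mut.gene:
                    mod.constant *= ki_factor
    perturbed.validate()
    return perturbed


@dataclass
class SteadyState:
    state: dict[str, float]
    converged: bool
    residual: float
    time_elapsed: float


def _rhs_factory(network: NetworkSpec):
    names = network.species_names()
    index = {n: i for i, n in enumerate(names)}
    synthesis = np.array([s.baseline_synthesis_rate for s in network.species])
    degradation = np.array([s.degradation_rate for s in network.species])

    compiled = []
    for rxn in network.reactions:
        compiled.append(
            (
                rxn.kind,
                rxn.parameters["Vmax" if rxn.kind == "michaelis_menten" else "k"],
                rxn.parameters.get("Km", 1.0),
                [index[s] for s in rxn.substrates],
                [(index[m.species], m.constant) for m in rxn.activators],
                [(index[m.species], m.constant) for m in rxn.inhibitors],
                [index[p] for p in rxn.products],
            )
        )

    def rhs(_t, y):
        conc = np.maximum(y, 0.0)
        dydt = synthesis - degradation * conc
        for kind, rate_const, km, subs, acts, inhs, prods in compiled:
            if kind == "michaelis_menten":
                rate = rate_const
                if subs:
                    s = conc[subs[0]]
                    rate *= s / (km + s)
            else:
                rate = rate_const
                for i in subs:
                    rate *= conc[i]
            for i, ka in acts:
                rate *= conc[i] / (ka + conc[i])
            for i, ki in inhs:
                rate *= ki / (ki + conc[i])
            for i in subs:
                dydt[i] -= rate
            for i in prods:
                dydt[i] += rate
        return dydt

    return rhs, names


def simulate_to_steady_state(
    network: NetworkSpec,
    tol_abs: float = 1e-9,
    tol_rel: float = 1e-8,
    horizon: float = 5e4,
    window: float = 500.0,
) -> SteadyState:
    """Integrate the network ODEs until a homeostatic steady state.

    The system is advanced with the implicit Radau method in windows of
    ``window`` time units; integration stops once the maximum absolute time
    derivative falls below ``tol_abs`` (µM per time unit) or the relative
    state change over a window falls below ``tol_rel``, or the time horizon
    is exhausted (in which case ``converged`` is False).
    """
    rhs, names = _rhs_factory(network)
    y = np.array([s.initial_concentration for s in network.species])
    t = 0.0
    converged = False
    residual = float(np.max(np.abs(rhs(0.0, y)))) if len(y) else 0.0
    if len(y) == 0:
        return SteadyState({}, True, 0.0, 0.0)
    while t < horizon:
        sol = solve_ivp(
            rhs,
            (t, t + window),
            y,
            method="Radau",
            rtol=1e-8,
            atol=1e-10,
        )
        if not sol.success:
            raise RuntimeError(
                f"ODE integration failed at t={t}: {sol.message}"
            )
        y_new = sol.y[:, -1]
        if (y_new < -1e-6).any():
            raise RuntimeError(
                "integration produced negative concentrations beyond "
                "solver tolerance"
            )
        y_new = np.maximum(y_new, 0.0)
        residual = float(np.max(np.abs(rhs(0.0, y_new))))
        scale = np.maximum(np.abs(y_new), 1e-12)
        rel_change = float(np.max(np.abs(y_new - y) / scale))
        t += window
        y = y_new
        if residual < tol_abs or rel_change < tol_rel:
            converged = True
            break
    return SteadyState(dict(zip(names, y)), converged, residual, t)


@dataclass
class SimulationResult:
    baseline_state: dict[str, float]
    perturbed_state: dict[str, float]
    percent_changes: dict[str, float]
    converged: bool
    residual: float


def predict_profile(
    network: NetworkSpec,
    mutations: Sequence[MutationPerturbation],
    baseline: SteadyState | None = None,
    **solver_kwargs,
) -> SimulationResult:
    """Simulate baseline and mutated steady states and report percent changes.

    ``baseline`` may be supplied to reuse a precomputed unperturbed steady
    state when scoring many mutation profiles on the same network.
    """
    if baseline is None:
        baseline = simulate_to_steady_state(network, **solver_kwargs)
    perturbed_spec = apply_perturbations(network, mutations)
    perturbed = simulate_to_steady_state(perturbed_spec, **solver_kwargs)
    changes = {}
    for out in network.outputs:
        control = baseline.state[out]
        disease = perturbed.state[out]
        changes[out] = percent_change(BaselinePair(control, disease))
    return SimulationResult(
        baseline_state=dict(baseline.state),
        perturbed_state=dict(perturbed.state),
        percent_changes=changes,
        converged=baseline.converged and perturbed.converged,
        residual=max(baseline.residual, perturbed.residual),
    )
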