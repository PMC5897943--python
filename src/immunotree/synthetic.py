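"""Synthetic patient cohorts with known ground-truth decision labels.

Two generation modes:

* ``parametric`` — per-molecule percent changes drawn from configured
  Gaussian location/scale pairs, with a configurable correlation between
  PD-L1 and its co-regulated molecules (TGFB1, IL6) so that step-3
  decisions are non-trivial; the DC infiltration index is computed from the
  drawn chemokine values with uniform weights.
* ``mechanistic`` — mutation profiles sampled over a driver-gene panel and
  pushed through the packaged signaling network simulator.

Each patient's *true* label is the decision tree applied to the noiseless
profile; the recorded clinical response is that label flipped independently
with probability ``label_flip_rate`` — the simplest generative stand-in for
all unmodeled biology separating prediction from outcome (the reference
cohort's mismatch fraction is 4/29 ≈ 0.14).  Observation noise, when
enabled, perturbs the stored profile but not the true label.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, replace

import numpy as np

from .classifier import DecisionTrace, Thresholds, classify_patient
from .cohort import (
    CHEMOKINE_NAMES,
    ISM_NAMES,
    Cohort,
    Dataset,
    PatientRecord,
    Response,
    bundled_fixture,
)
from .metrics import ChemokineWeights, dc_infiltration_index
from .network import (
    MutationEffect,
    MutationPerturbation,
    NetworkSpec,
    bundled_network,
    predict_profile,
    simulate_to_steady_state,
)

__all__ = [
    "GeneratorConfig",
    "CohortGenerator",
    "generate_cohort",
    "table1_like_preset",
    "DEFAULT_GENE_PANEL",
]

_PROFILE_MOLECULES = ("PDL1",) + ISM_NAMES + CHEMOKINE_NAMES

#: Driver-gene panel for mechanistic sampling: (gene, effect, weight).
#: Weights are marginal inclusion probabilities per patient.
DEFAULT_GENE_PANEL: tuple[tuple[str, str, float], ...] = (
    ("KRAS", "oncogene_gof", 0.35),
    ("BRAF", "oncogene_gof", 0.10),
    ("MEK", "oncogene_gof", 0.10),
    ("EGFR", "oncogene_gof", 0.15),
    ("PIK3CA", "oncogene_gof", 0.10),
    ("MTOR", "oncogene_gof", 0.05),
    ("TP53", "tsg_lof", 0.40),
    ("STK11", "tsg_lof", 0.15),
    ("KEAP1", "tsg_lof", 0.10),
    ("CDKN2A", "tsg_lof", 0.15),
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration of the synthetic-cohort generator.

    ``effect_distributions`` maps molecule name to (location, scale) of a
    Gaussian over percent change (parametric mode).  ``label_flip_rate``
    emulates the clinical/predicted mismatch fraction; ``dataset_split`` is
    the fraction of patients assigned to the discovery dataset.
    """

    n_patients: int = 29
    seed: int = 0
    mode: str = "parametric"
    effect_distributions: dict[str, tuple[float, float]] = field(
        default_factory=dict
    )
    mutation_weights: tuple[tuple[str, str, float], ...] = DEFAULT_GENE_PANEL
    noise_sd: float = 0.0
    label_flip_rate: float = 4.0 / 29.0
    dataset_split: float = 13.0 / 29.0
    pdl1_correlation: float = 0.6

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if self.mode not in ("parametric", "mechanistic"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not 0.0 <= self.label_flip_rate <= 1.0:
            raise ValueError("label_flip_rate must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not 0.0 < self.dataset_split < 1.0:
            raise ValueError("dataset_split must lie strictly in (0, 1)")
        if not -1.0 < self.pdl1_correlation < 1.0:
            raise ValueError("pdl1_correlation must lie in (-1, 1)")


#: Default parametric effect distributions: percent-change location/scale
#: chosen so cohorts spread across all five decision-tree terminals.
_DEFAULT_DISTRIBUTIONS: dict[str, tuple[float, float]] = {
    "PDL1": (50.0, 45.0),
    **{m: (20.0, 25.0) for m in ISM_NAMES},
    "FASLG": (-4.0, 4.0),
    **{c: (30.0, 60.0) for c in CHEMOKINE_NAMES},
}


class CohortGenerator:
    """Deterministic cohort sampler for a given configuration and seed."""

    def __init__(self, config: GeneratorConfig | None = None,
                 network: NetworkSpec | None = None) -> None:
        self.config = config or GeneratorConfig()
        self._network = network
        self._baseline = None

    # -- public API --------------------------------------------------------

    def generate(self) -> tuple[Cohort, dict[str, DecisionTrace]]:
        """Draw a cohort and its ground-truth decision traces."""
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        ids = self._draw_ids(rng, cfg.n_patients)
        n_discovery = int(round(cfg.dataset_split * cfg.n_patients))

        records: list[PatientRecord] = []
        truth: dict[str, DecisionTrace] = {}
        for i, sid in enumerate(ids):
            profile = self._draw_profile(rng)
            trace = self._true_trace(profile)
            truth[sid] = trace
            observed = self._observe(profile, rng)
            clinical = trace.label
            if rng.random() < cfg.label_flip_rate:
                clinical = (
                    Response.RESPONDER
                    if clinical == Response.NON_RESPONDER
                    else Response.NON_RESPONDER
                )
            chemokines = {c: observed[c] for c in CHEMOKINE_NAMES}
            records.append(
                PatientRecord(
                    study_id=sid,
                    dataset=(
                        Dataset.DISCOVERY
                        if i < n_discovery
                        else Dataset.VALIDATION
                    ),
                    clinical_response=clinical,
                    pdl1_pct=observed["PDL1"],
                    ism_pct={m: observed[m] for m in ISM_NAMES},
                    dc_index_pct=dc_infiltration_index(
                        chemokines, ChemokineWeights.uniform()
                    ),
                    chemokine_pct=chemokines,
                )
            )
        return Cohort(records, name=f"synthetic-{cfg.mode}"), truth

    # -- internals ---------------------------------------------------------

    @staticmethod
    def _draw_ids(rng: np.random.Generator, n: int) -> list[str]:
        alphabet = np.array(list(string.ascii_uppercase + string.digits))
        ids: list[str] = []
        seen: set[str] = set()
        while len(ids) < n:
            sid = "".join(rng.choice(alphabet, size=6))
            if sid not in seen:
                seen.add(sid)
                ids.append(sid)
        return ids

    def _distributions(self) -> dict[str, tuple[float, float]]:
        dists = dict(_DEFAULT_DISTRIBUTIONS)
        dists.update(self.config.effect_distributions)
        return dists

    def _draw_profile(self, rng: np.random.Generator) -> dict[str, float]:
        if self.config.mode == "mechanistic":
            return self._draw_mechanistic(rng)
        dists = self._distributions()
        profile: dict[str, float] = {}
        # correlated block: PDL1 with TGFB1 and IL6
        rho = self.config.pdl1_correlation
        cov = np.array(
            [[1.0, rho, rho], [rho, 1.0, rho * rho], [rho, rho * rho, 1.0]]
        )
        z = rng.multivariate_normal(np.zeros(3), cov, method="cholesky")
        for name, zi in zip(("PDL1", "TGFB1", "IL6"), z):
            loc, scale = dists[name]
            profile[name] = loc + scale * zi
        for name in _PROFILE_MOLECULES:
            if name in profile:
                continue
            loc, scale = dists[name]
            profile[name] = rng.normal(loc, scale)
        return profile

    def _draw_mechanistic(self, rng: np.random.Generator) -> dict[str, float]:
        if self._network is None:
            self._network = bundled_network()
        if self._baseline is None:
            self._baseline = simulate_to_steady_state(self._network)
        mutations: list[MutationPerturbation] = []
        while not mutations:
            for gene, effect, weight in self.config.mutation_weights:
                if rng.random() < weight:
                    mutations.append(
                        MutationPerturbation(gene, MutationEffect(effect))
                    )
        result = predict_profile(
            self._network, mutations, baseline=self._baseline
        )
        return dict(result.percent_changes)

    def _true_trace(self, profile: dict[str, float]) -> DecisionTrace:
        record = self._profile_to_record("TRUTH0", profile)
        return classify_patient(record, Thresholds())

    def _observe(
        self, profile: dict[str, float], rng: np.random.Generator
    ) -> dict[str, float]:
        if self.config.noise_sd == 0:
            return dict(profile)
        return {
            name: value + rng.normal(0.0, self.config.noise_sd)
            for name, value in profile.items()
        }

    @staticmethod
    def _profile_to_record(sid: str, profile: dict[str, float]) -> PatientRecord:
        chemokines = {c: profile[c] for c in CHEMOKINE_NAMES}
        return PatientRecord(
            study_id=sid,
            dataset=Dataset.DISCOVERY,
            clinical_response=Response.NON_RESPONDER,  # placeholder label
            pdl1_pct=profile["PDL1"],
            ism_pct={m: profile[m] for m in ISM_NAMES},
            dc_index_pct=dc_infiltration_index(
                chemokines, ChemokineWeights.uniform()
            ),
            chemokine_pct=chemokines,
        )


def generate_cohort(
    config: GeneratorConfig,
) -> tuple[Cohort, dict[str, DecisionTrace]]:
    """Generate a synthetic cohort plus its ground-truth trace map."""
    return CohortGenerator(config).generate()


def table1_like_preset(n_patients: int = 29, seed: int = 0) -> GeneratorConfig:
    """A parametric configuration moment-matched to the reference cohort.

    Per-molecule locations and scales equal the empirical mean/SD of the
    corresponding fixture columns.  Chemokine values are not printed in the
    reference table, so each chemokine is given location equal to the DC
    index mean and scale equal to 3x the DC index SD — under uniform 1/9
    weights the resulting index then matches the fixture's DC index moments.
    The label flip rate is the observed mismatch fraction (4/29) and the
    discovery split is 13/29.
    """
    fixture = bundled_fixture()
    frame = fixture.to_frame()
    dists: dict[str, tuple[float, float]] = {}
    for molecule in ("PDL1",) + ISM_NAMES:
        col = frame[molecule].astype(float)
        dists[molecule] = (float(col.mean()), float(col.std(ddof=1)))
    dc = frame["DC_index"].astype(float)
    n_chemo = len(CHEMOKINE_NAMES)
    chemo_scale = float(dc.std(ddof=1)) * np.sqrt(n_chemo)
    for chemokine in CHEMOKINE_NAMES:
        dists[chemokine] = (float(dc.mean()), chemo_scale)
    return GeneratorConfig(
        n_patients=n_patients,
        seed=seed,
        mode="parametric",
        effect_distributions=dists,
        label_flip_rate=4.0 / 29.0,
        dataset_split=13.0 / 29.0,
    )
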