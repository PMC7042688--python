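"""Synthetic data generation for the full estimation pipeline.

Realizes a parameter bundle (:class:`SyntheticScenario`) into a prey
library, calibration coefficients, a predator cohort with known true diets,
and an annual ice-index table, so that every downstream stage can be tested
without external data.

Signature noise is logistic-normal (normal perturbation in log space,
closed back to the simplex), which keeps components strictly positive and
allows covariance injection; diet proportions are Dirichlet.  All
randomness flows from one root seed through named substreams, so each
component is independently reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .signatures import (
    SEX_AGE_CLASSES,
    CalibrationCoefficients,
    FattyAcidSet,
    IceIndexTable,
    PredatorRecord,
    PreyLibrary,
    Signature,
    SignatureValidationError,
)
from .qfasa_core import alpha_to_pi, species_means

__all__ = [
    "SyntheticScenario",
    "substream",
    "gen_prey_library",
    "gen_calibration",
    "gen_predator_cohort",
    "gen_fa_set",
]

DEFAULT_LABELS = ("ringed_seal", "bearded_seal", "beluga", "bowhead", "seabird")


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, independent random substream derived from one root seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(name.encode())])
    )


@dataclass(frozen=True)
class SyntheticScenario:
    """Parameter bundle the generators realize with a seed.

    Defaults mirror the structure of a multi-year polar bear study: five
    prey species with uneven specimen counts, four predator sex/age
    classes, a 13-year span, and a diet dominated by one species.
    """

    labels: tuple[str, ...] = DEFAULT_LABELS
    n_specimens: tuple[int, ...] = (89, 20, 29, 64, 23)
    n_fatty_acids: int = 20
    species_means: np.ndarray | None = None
    #: log-space scale separating species mean signatures from one another
    mean_separation: float = 1.0
    #: within-species logistic-normal dispersion (log-space SD)
    dispersion: float = 0.15
    lipid_fractions: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0, 0.10)
    #: log-normal SD of calibration coefficients around 1
    cc_spread: float = 0.3
    n_predators: int = 125
    years: tuple[int, ...] = tuple(range(2004, 2017))
    class_probs: tuple[float, ...] = (0.35, 0.35, 0.15, 0.15)
    #: mean of the diet-generating Dirichlet, in species order
    diet_base_mean: tuple[float, ...] = (0.45, 0.20, 0.05, 0.15, 0.15)
    #: Dirichlet precision; larger = less between-bear diet variation
    diet_concentration: float = 40.0
    #: per-class multiplicative tweaks of the diet mean, e.g.
    #: {"AM": {"ringed_seal": 0.6, "bowhead": 1.6}}
    class_effects: Mapping[str, Mapping[str, float]] | None = None
    #: SD of a yearly multiplicative log-normal jitter on the diet mean
    year_effect_scale: float = 0.0
    #: logistic-normal noise added to each predator signature (log-space SD)
    predator_noise: float = 0.05
    #: ice index model: value = intercept + slope * (year - first) + N(0, sd)
    ice_params: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "ifd50": (60.0, 3.0, 6.0),
            "ifd15": (40.0, 2.5, 6.0),
            "melt_season": (100.0, 2.0, 8.0),
        }
    )
    seed: int = 0

    def __post_init__(self):
        k = len(self.labels)
        if len(self.n_specimens) != k or len(self.lipid_fractions) != k:
            raise SignatureValidationError("per-species fields must match labels")
        if len(self.diet_base_mean) != k:
            raise SignatureValidationError("diet_base_mean must match labels")
        if any(n < 1 for n in self.n_specimens) or self.n_fatty_acids < 2:
            raise SignatureValidationError("counts must be positive")
        if self.dispersion < 0 or self.predator_noise < 0 or self.cc_spread < 0:
            raise SignatureValidationError("noise scales must be >= 0")
        if self.diet_concentration <= 0:
            raise SignatureValidationError("diet_concentration must be > 0")
        if abs(sum(self.class_probs) - 1.0) > 1e-9 or len(self.class_probs) != 4:
            raise SignatureValidationError("class_probs must be 4 probabilities summing to 1")

    def with_(self, **kwargs) -> "SyntheticScenario":
        return replace(self, **kwargs)


def gen_fa_set(n_fatty_acids: int) -> FattyAcidSet:
    """Plausible shorthand labels for a synthetic fatty acid set."""
    base = [
        "14:0", "16:0", "16:1n7", "18:0", "18:1n9", "18:1n7", "18:2n6",
        "18:3n3", "18:4n3", "20:0", "20:1n9", "20:1n7", "20:4n6", "20:4n3",
        "20:5n3", "22:1n11", "22:1n9", "22:5n3", "22:6n3", "24:1n9",
    ]
    if n_fatty_acids <= len(base):
        return FattyAcidSet(base[:n_fatty_acids])
    extra = [f"x{i}:0" for i in range(n_fatty_acids - len(base))]
    return FattyAcidSet(base + extra)


def _scenario_means(scenario: SyntheticScenario) -> np.ndarray:
    """Species mean signatures: shared base profile times per-species
    log-normal displacement scaled by ``mean_separation``."""
    if scenario.species_means is not None:
        m = np.asarray(scenario.species_means, dtype=float)
        if m.shape != (len(scenario.labels), scenario.n_fatty_acids):
            raise SignatureValidationError(f"species_means has shape {m.shape}")
        return m / m.sum(axis=1, keepdims=True)
    rng = substream(scenario.seed, "means")
    base = rng.dirichlet(np.full(scenario.n_fatty_acids, 5.0))
    z = rng.normal(size=(len(scenario.labels), scenario.n_fatty_acids))
    m = base * np.exp(scenario.mean_separation * z)
    return m / m.sum(axis=1, keepdims=True)


def _logistic_normal(rng, center: np.ndarray, sd: float, n: int) -> np.ndarray:
    """n draws around a simplex center: perturb in log space, re-close."""
    z = rng.normal(scale=sd, size=(n, center.size)) if sd > 0 else np.zeros((n, center.size))
    v = center * np.exp(z)
    return v / v.sum(axis=1, keepdims=True)


def gen_prey_library(scenario: SyntheticScenario) -> PreyLibrary:
    """Generate a seeded prey library from the scenario."""
    means = _scenario_means(scenario)
    rng = substream(scenario.seed, "library")
    species = {}
    for i, label in enumerate(scenario.labels):
        species[label] = _logistic_normal(
            rng, means[i], scenario.dispersion, scenario.n_specimens[i]
        )
    return PreyLibrary(
        fa_set=gen_fa_set(scenario.n_fatty_acids),
        species=species,
        lipid_fractions=dict(zip(scenario.labels, scenario.lipid_fractions)),
    )


def gen_calibration(
    n_fatty_acids: int, spread: float = 0.3, seed: int = 0,
    fa_set: FattyAcidSet | None = None,
) -> CalibrationCoefficients:
    """Log-normal calibration coefficients around 1 with the given spread."""
    if spread < 0:
        raise SignatureValidationError("cc spread must be >= 0")
    rng = substream(seed, "cc")
    if fa_set is None:
        fa_set = gen_fa_set(n_fatty_acids)
    values = np.exp(rng.normal(scale=spread, size=n_fatty_acids)) if spread > 0 \
        else np.ones(n_fatty_acids)
    return CalibrationCoefficients(fa_set, values)


def _diet_mean_for(scenario: SyntheticScenario, klass: str, year_jitter: np.ndarray) -> np.ndarray:
    mean = np.asarray(scenario.diet_base_mean, dtype=float)
    if scenario.class_effects and klass in scenario.class_effects:
        mult = np.array(
            [scenario.class_effects[klass].get(sp, 1.0) for sp in scenario.labels]
        )
        mean = mean * mult
    mean = mean * year_jitter
    return mean / mean.sum()


def gen_predator_cohort(
    scenario: SyntheticScenario,
    lib: PreyLibrary,
    cc: CalibrationCoefficients | None = None,
) -> tuple[list[PredatorRecord], pd.DataFrame, IceIndexTable]:
    """Generate predators with known true diets plus an ice-index table.

    Each predator: class and year from scenario proportions; a true biomass
    diet ``pi`` from the class/year Dirichlet; fatty-acid-space coefficients
    ``alpha_k ∝ pi_k * f_k``; a signature mixed from the library's species
    means, distorted into predator space by the calibration coefficients,
    with logistic-normal noise.  Returns the records, a true-diet table
    (``id``, ``class``, ``year``, one column per species) and the ice table.
    """
    if tuple(lib.labels) != tuple(scenario.labels):
        raise SignatureValidationError("library species do not match scenario labels")
    k = len(scenario.labels)
    rng_cov = substream(scenario.seed, "covariates")
    rng_diet = substream(scenario.seed, "diets")
    rng_noise = substream(scenario.seed, "noise")
    rng_ice = substream(scenario.seed, "ice")

    means = species_means(lib)
    f = lib.lipid_vector()
    classes = rng_cov.choice(SEX_AGE_CLASSES, size=scenario.n_predators,
                             p=scenario.class_probs)
    years = rng_cov.choice(scenario.years, size=scenario.n_predators)

    year_jitter = {
        y: (
            np.exp(rng_diet.normal(scale=scenario.year_effect_scale, size=k))
            if scenario.year_effect_scale > 0
            else np.ones(k)
        )
        for y in scenario.years
    }

    records, truth = [], []
    for i in range(scenario.n_predators):
        klass, year = str(classes[i]), int(years[i])
        mean = _diet_mean_for(scenario, klass, year_jitter[year])
        pi = rng_diet.dirichlet(scenario.diet_concentration * mean)
        alpha = pi * f
        alpha = alpha / alpha.sum()
        sig_vals = alpha @ means
        sig_vals = sig_vals / sig_vals.sum()
        if cc is not None:
            sig_vals = sig_vals * cc.values
            sig_vals = sig_vals / sig_vals.sum()
        sig_vals = _logistic_normal(rng_noise, sig_vals, scenario.predator_noise, 1)[0]
        bear_id = f"bear_{i:04d}"
        records.append(
            PredatorRecord(
                id=bear_id,
                sex_age_class=klass,
                capture_year=year,
                signature=Signature(lib.fa_set, sig_vals),
            )
        )
        truth.append({"id": bear_id, "class": klass, "year": year,
                      **dict(zip(scenario.labels, pi))})

    ice_rows = []
    y0 = min(scenario.years)
    for y in sorted(scenario.years):
        row = {"year": y}
        for name, (b0, b1, sd) in scenario.ice_params.items():
            val = b0 + b1 * (y - y0) + (rng_ice.normal(scale=sd) if sd > 0 else 0.0)
            row[name] = float(np.clip(val, 0.0, 366.0))
        ice_rows.append(row)

    return records, pd.DataFrame(truth), IceIndexTable(pd.DataFrame(ice_rows))
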