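"""Model-adequacy simulations for the diet estimator.

Two diagnostics:

* **prey-on-prey** — repeatedly split each species' specimens into a test
  ("predator") half and a reduced library, estimate each test specimen's
  diet against the reduced library, and score how much of the estimate is
  attributed back to the specimen's own species.
* **pseudo-predator** — build predators from a known ("true") diet by
  fat-weighted mixing of bootstrap-resampled species means, distort them
  into predator space with the calibration coefficients, and score how well
  the estimator recovers the generating diet.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .signatures import (
    DEFAULT_ZERO_EPS,
    CalibrationCoefficients,
    FattyAcidSet,
    PreyLibrary,
    Signature,
    SignatureValidationError,
    apply_calibration,
)
from .qfasa_core import alpha_to_pi, estimate_diet, species_means
from .synthetic_data import substream

__all__ = ["PreyOnPreyResult", "PseudoPredatorResult", "prey_on_prey", "pseudo_predator"]


@dataclass(frozen=True)
class PreyOnPreyResult:
    """Per-species correct-identification summary plus full attributions.

    ``attributions`` holds one row per (replicate, test specimen): the
    replicate index, the specimen's true species, and the estimated diet
    proportion assigned to every species.  ``summary`` pools replicates
    into per-species mean ± SD percent correct.
    """

    summary: pd.DataFrame = field(repr=False)
    attributions: pd.DataFrame = field(repr=False)
    n_reps: int
    seed: int
    metric: str


@dataclass(frozen=True)
class PseudoPredatorResult:
    """Recovered-diet summary for a known generating diet."""

    true_diet: np.ndarray
    species: tuple[str, ...]
    estimates: pd.DataFrame = field(repr=False)
    summary: pd.DataFrame = field(repr=False)
    n_runs: int
    seed: int


def _reduced_library(lib: PreyLibrary, keep_idx: Mapping[str, np.ndarray]) -> PreyLibrary:
    return PreyLibrary(
        fa_set=lib.fa_set,
        species={k: lib.species[k][keep_idx[k]] for k in lib.labels},
        lipid_fractions=dict(lib.lipid_fractions),
    )


def prey_on_prey(
    lib: PreyLibrary,
    cc: CalibrationCoefficients | None = None,
    fa_subset: FattyAcidSet | Sequence[str] | None = None,
    *,
    split_fraction: float = 0.5,
    n_reps: int = 100,
    seed: int = 0,
    metric: str = "proportion",
    zero_eps: float = DEFAULT_ZERO_EPS,
) -> PreyOnPreyResult:
    """Prey-on-prey identification simulation.

    Per replicate, each species' specimens are split at ``split_fraction``
    (test-set size rounds down) into test specimens and a reduced library.
    Test specimens are distorted into predator space with ``cc`` and run
    through the estimator against the reduced library.  "Correct
    identification" is, under ``metric="proportion"``, the estimated diet
    share of the specimen's own species; ``metric="argmax"`` scores a hard
    classification (1 if own species tops the estimate) instead.

    Species with a single specimen cannot be split and are excluded with a
    warning.
    """
    if not (0.0 < split_fraction < 1.0):
        raise SignatureValidationError("split_fraction must be in (0, 1)")
    if metric not in ("proportion", "argmax"):
        raise SignatureValidationError(f"unknown metric {metric!r}")
    singletons = [k for k in lib.labels if lib.n_specimens(k) < 2]
    if singletons:
        warnings.warn(
            f"species with < 2 specimens excluded from prey-on-prey: {singletons}",
            stacklevel=2,
        )
        lib = lib.subset_species([k for k in lib.labels if k not in singletons])
    if lib.n_species < 2:
        raise SignatureValidationError("need >= 2 usable species")

    rng = substream(seed, "prey_on_prey")
    rows = []
    for rep in range(n_reps):
        test_idx, keep_idx = {}, {}
        for k in lib.labels:
            n = lib.n_specimens(k)
            n_test = max(1, int(n * split_fraction)) if n > 1 else 0
            n_test = min(n_test, n - 1)  # keep the reduced library non-empty
            perm = rng.permutation(n)
            test_idx[k] = perm[:n_test]
            keep_idx[k] = perm[n_test:]
        reduced = _reduced_library(lib, keep_idx)
        for k in lib.labels:
            for j in test_idx[k]:
                sig = Signature(lib.fa_set, lib.species[k][j])
                if cc is not None:
                    sig = apply_calibration(sig, cc, "prey_to_predator")
                est = estimate_diet(
                    sig, reduced, cc, fa_subset, zero_eps=zero_eps, seed=seed
                )
                rows.append({"rep": rep, "true_species": k,
                             **dict(zip(reduced.labels, est.pi))})
    attributions = pd.DataFrame(rows)

    summary_rows = []
    for k in lib.labels:
        sub = attributions.loc[attributions["true_species"] == k, list(lib.labels)]
        if metric == "proportion":
            scores = sub[k].to_numpy(dtype=float) * 100.0
        else:
            scores = (sub.to_numpy(dtype=float).argmax(axis=1)
                      == list(lib.labels).index(k)).astype(float) * 100.0
        summary_rows.append(
            {
                "species": k,
                "correct_id_mean": float(scores.mean()),
                "correct_id_sd": float(scores.std(ddof=1)) if scores.size > 1 else 0.0,
                "n_scored": int(scores.size),
            }
        )
    return PreyOnPreyResult(
        summary=pd.DataFrame(summary_rows),
        attributions=attributions,
        n_reps=n_reps,
        seed=seed,
        metric=metric,
    )


def pseudo_predator(
    true_diet,
    lib: PreyLibrary,
    cc: CalibrationCoefficients | None = None,
    fa_subset: FattyAcidSet | Sequence[str] | None = None,
    lipid_overrides: Mapping[str, float] | None = None,
    *,
    n_runs: int = 100,
    seed: int = 0,
    zero_eps: float = DEFAULT_ZERO_EPS,
) -> PseudoPredatorResult:
    """Pseudo-predator diet-recovery simulation.

    Per run: bootstrap-resample specimens within each species, form the
    resampled species means, combine them with fat-weighted coefficients
    ``alpha_k ∝ pi_k * f_k``, distort into predator space with ``cc``, and
    estimate the diet against the full library.  Returns per-run estimates
    and a per-species mean ± SD summary (percent scale).
    """
    pi_true = np.asarray(true_diet, dtype=float)
    if pi_true.shape != (lib.n_species,):
        raise SignatureValidationError(
            f"true diet length {pi_true.size} does not match {lib.n_species} species"
        )
    if np.any(pi_true < 0) or abs(pi_true.sum() - 1.0) > 1e-6:
        raise SignatureValidationError("true diet must be on the simplex")
    if n_runs < 1:
        raise SignatureValidationError("n_runs must be >= 1")

    f = lib.lipid_vector(lipid_overrides)
    alpha = pi_true * f
    alpha = alpha / alpha.sum()
    rng = substream(seed, "pseudo_predator")

    rows = []
    for run in range(n_runs):
        boot = {}
        for k in lib.labels:
            n = lib.n_specimens(k)
            boot[k] = lib.species[k][rng.integers(0, n, size=n)]
        boot_lib = PreyLibrary(lib.fa_set, boot, dict(lib.lipid_fractions))
        means = species_means(boot_lib, fa_subset, zero_eps)
        sig_vals = alpha @ means
        sig_vals = sig_vals / sig_vals.sum()
        fa = boot_lib.fa_set if fa_subset is None else FattyAcidSet(
            fa_subset.names if isinstance(fa_subset, FattyAcidSet) else fa_subset
        )
        sig = Signature(fa, sig_vals)
        if cc is not None:
            cc_used = cc if fa_subset is None else CalibrationCoefficients(
                fa, cc.values[cc.fa_set.indices_of(fa)]
            )
            sig = apply_calibration(sig, cc_used, "prey_to_predator")
        else:
            cc_used = None
        est = estimate_diet(
            sig, lib, cc_used, fa_subset, lipid_overrides,
            zero_eps=zero_eps, seed=seed,
        )
        rows.append({"run": run, **dict(zip(lib.labels, est.pi))})
    estimates = pd.DataFrame(rows)

    summary_rows = []
    for i, k in enumerate(lib.labels):
        vals = estimates[k].to_numpy(dtype=float) * 100.0
        summary_rows.append(
            {
                "species": k,
                "true_pct": float(pi_true[i] * 100.0),
                "estimate_mean": float(vals.mean()),
                "estimate_sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
            }
        )
    return PseudoPredatorResult(
        true_diet=pi_true,
        species=lib.labels,
        estimates=estimates,
        summary=pd.DataFrame(summary_rows),
        n_runs=n_runs,
        seed=seed,
    )
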