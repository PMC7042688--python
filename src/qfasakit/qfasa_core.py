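"""Diet estimation engine.

Estimates the prey mixture whose mean signature is closest — under a
symmetrized Kullback-Leibler distance — to a calibration-corrected predator
signature, by constrained minimization on the probability simplex, then
converts the fatty-acid-space mixing coefficients ``alpha`` into biomass
diet proportions ``pi`` using per-species lipid fractions::

    pi_k = (alpha_k / f_k) / sum_j (alpha_j / f_j)

With equal lipid fractions across species, ``pi == alpha`` exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .signatures import (
    DEFAULT_ZERO_EPS,
    CalibrationCoefficients,
    FattyAcidSet,
    PredatorRecord,
    PreyLibrary,
    Signature,
    SignatureValidationError,
    apply_calibration,
    replace_zeros,
    restrict,
)

__all__ = [
    "DietEstimate",
    "kl_distance",
    "mixture",
    "species_means",
    "prepare_predator",
    "alpha_to_pi",
    "estimate_diet",
    "batch_estimate",
    "summarize_diet",
]

SIMPLEX_TOL = 1e-6
#: Two starts "agree" when their optimum distances differ by less than this.
START_AGREEMENT_TOL = 1e-6


@dataclass(frozen=True)
class DietEstimate:
    """Result of a single-predator estimation.

    ``alpha`` are fatty-acid-space mixing coefficients, ``pi`` the
    lipid-converted biomass proportions (both on the simplex over the prey
    species, in library order).
    """

    species: tuple[str, ...]
    alpha: np.ndarray
    pi: np.ndarray
    optimum_distance: float
    converged: bool
    n_starts_agreeing: int

    def __post_init__(self):
        for name in ("alpha", "pi"):
            v = np.asarray(getattr(self, name), dtype=float)
            if np.any(v < -SIMPLEX_TOL) or abs(v.sum() - 1.0) > SIMPLEX_TOL:
                raise ValueError(f"{name} is not on the simplex: {v}")
            object.__setattr__(self, name, v)
        if self.optimum_distance < 0:
            raise ValueError("optimum_distance must be >= 0")


def kl_distance(a, b) -> float:
    """Symmetrized Kullback-Leibler distance ``sum((a-b) * ln(a/b))``.

    Symmetric, nonnegative and zero iff ``a == b``.  Inputs must be
    strictly positive compositions of equal length (apply zero replacement
    first).
    """
    av = a.values if isinstance(a, Signature) else np.asarray(a, dtype=float)
    bv = b.values if isinstance(b, Signature) else np.asarray(b, dtype=float)
    if av.shape != bv.shape:
        raise SignatureValidationError("signatures have different lengths")
    if np.any(av <= 0) or np.any(bv <= 0):
        raise SignatureValidationError(
            "kl_distance requires strictly positive components; replace zeros first"
        )
    return float(np.sum((av - bv) * np.log(av / bv)))


def mixture(alpha, prey_means: np.ndarray) -> np.ndarray:
    """Convex combination of per-species mean signatures, renormalized.

    ``prey_means`` has one row per species; ``alpha`` is a simplex vector
    over species.
    """
    a = np.asarray(alpha, dtype=float)
    m = np.asarray(prey_means, dtype=float)
    if m.ndim != 2 or a.shape != (m.shape[0],):
        raise SignatureValidationError(
            f"alpha length {a.shape} does not match prey mean matrix {m.shape}"
        )
    v = a @ m
    s = v.sum()
    if s <= 0:
        raise SignatureValidationError("mixture has zero total mass")
    return v / s


def species_means(
    lib: PreyLibrary,
    fa_subset: FattyAcidSet | Sequence[str] | None = None,
    zero_eps: float = DEFAULT_ZERO_EPS,
) -> np.ndarray:
    """Per-species mean signatures (rows, in library order).

    Each specimen is zero-replaced and restricted to ``fa_subset`` (with
    renormalization) before averaging; the mean is then closed to sum 1.
    """
    rows = []
    for label in lib.labels:
        mat = lib.species[label]
        specs = []
        for v in mat:
            sig = replace_zeros(Signature(lib.fa_set, v), zero_eps)
            if fa_subset is not None:
                sig = restrict(sig, fa_subset)
            specs.append(sig.values)
        mean = np.mean(specs, axis=0)
        rows.append(mean / mean.sum())
    return np.vstack(rows)


def prepare_predator(
    sig: Signature,
    cc: CalibrationCoefficients | None,
    fa_subset: FattyAcidSet | Sequence[str] | None = None,
    zero_eps: float = DEFAULT_ZERO_EPS,
) -> np.ndarray:
    """Calibration-correct, restrict and zero-replace a predator signature."""
    if cc is not None:
        sig = apply_calibration(sig, cc, "predator_to_prey")
    if fa_subset is not None:
        sig = restrict(sig, fa_subset)
    return replace_zeros(sig, zero_eps).values


def alpha_to_pi(alpha: np.ndarray, lipid_fractions: np.ndarray) -> np.ndarray:
    """Convert mixing coefficients to biomass proportions via lipid fractions."""
    a = np.asarray(alpha, dtype=float)
    f = np.asarray(lipid_fractions, dtype=float)
    if a.shape != f.shape:
        raise SignatureValidationError("alpha and lipid fractions differ in length")
    if np.any(f <= 0):
        raise SignatureValidationError("lipid fractions must be > 0")
    if np.all(f == f[0]):
        # equal lipid content: pi is exactly alpha (avoid rounding drift)
        return a / a.sum()
    w = a / f
    return w / w.sum()


def _objective_and_grad(y: np.ndarray, means: np.ndarray):
    """KL distance between ``y`` and ``mixture(alpha, means)`` with gradient."""
    log_y = np.log(y)

    def fun(alpha):
        v = alpha @ means
        s = v.sum()
        m = v / s
        # clip guards transient negative iterates inside the solver
        m = np.clip(m, 1e-300, None)
        log_m = np.log(m)
        f = float(np.sum((y - m) * (log_y - log_m)))
        dfdm = -(log_y - log_m) - (y - m) / m
        # d m_i / d alpha_j = (means_ji - m_i * rowsum_j) / s
        rowsum = means.sum(axis=1)
        grad = (means @ dfdm - (m @ dfdm) * rowsum) / s
        return f, grad

    return fun


def _starts(n_species: int, n_random: int, seed) -> np.ndarray:
    """Multi-start points: barycenter first, then vertices, then random.

    The barycenter leads so that flat (degenerate) objectives resolve to the
    symmetric solution under the lowest-start-index tie break.
    """
    rng = np.random.default_rng(seed)
    pts = [np.full(n_species, 1.0 / n_species)]
    pts.extend(np.eye(n_species))
    for _ in range(n_random):
        pts.append(rng.dirichlet(np.ones(n_species)))
    return np.vstack(pts)


def estimate_diet(
    pred: Signature | PredatorRecord,
    lib: PreyLibrary,
    cc: CalibrationCoefficients | None = None,
    fa_subset: FattyAcidSet | Sequence[str] | None = None,
    lipid_overrides: Mapping[str, float] | None = None,
    *,
    zero_eps: float = DEFAULT_ZERO_EPS,
    n_random_starts: int = 5,
    seed: int = 0,
    tol: float = 1e-8,
) -> DietEstimate:
    """Estimate one predator's diet against a prey library.

    Minimizes the symmetrized KL distance between the corrected predator
    signature and the convex mixture of species mean signatures, over the
    simplex, from multiple starts (barycenter + vertices + seeded random);
    the best optimum wins, ties broken by lowest start index.  Failure of
    every start is flagged via ``converged=False`` rather than raised.
    """
    if isinstance(pred, PredatorRecord):
        pred = pred.signature
    if lib.n_species < 2:
        raise SignatureValidationError("need >= 2 prey species")
    y = prepare_predator(pred, cc, fa_subset, zero_eps)
    means = species_means(lib, fa_subset, zero_eps)
    if means.shape[1] != y.size:
        raise SignatureValidationError("predator and prey fatty acid sets differ")

    k = lib.n_species
    fun = _objective_and_grad(y, means)
    constraints = [{"type": "eq", "fun": lambda a: a.sum() - 1.0,
                    "jac": lambda a: np.ones_like(a)}]
    bounds = [(0.0, 1.0)] * k

    results = []  # (fval, start_index, alpha, success)
    for idx, x0 in enumerate(_starts(k, n_random_starts, seed)):
        res = minimize(
            fun, x0, jac=True, method="SLSQP", bounds=bounds,
            constraints=constraints, options={"ftol": tol, "maxiter": 500},
        )
        a = np.clip(res.x, 0.0, None)
        s = a.sum()
        if s <= 0:
            continue
        a = a / s
        fval, _ = fun(a)
        results.append((fval, idx, a, bool(res.success)))
    if not results:
        # pathological: every start collapsed; return flagged barycenter
        a = np.full(k, 1.0 / k)
        fval, _ = fun(a)
        results.append((fval, -1, a, False))

    # best optimum wins; ties (within numerical noise) by lowest start index,
    # so degenerate flat objectives resolve to the barycenter start
    fmin = min(r[0] for r in results)
    best = min((r for r in results if r[0] <= fmin + 1e-12), key=lambda r: r[1])
    n_agree = sum(1 for r in results if r[0] <= best[0] + START_AGREEMENT_TOL)

    fval, _, alpha, success = best
    f = lib.lipid_vector(lipid_overrides)
    return DietEstimate(
        species=lib.labels,
        alpha=alpha,
        pi=alpha_to_pi(alpha, f),
        optimum_distance=max(fval, 0.0),
        converged=success,
        n_starts_agreeing=n_agree,
    )


def batch_estimate(
    predators: Sequence[PredatorRecord],
    lib: PreyLibrary,
    cc: CalibrationCoefficients | None = None,
    fa_subset: FattyAcidSet | Sequence[str] | None = None,
    lipid_overrides: Mapping[str, float] | None = None,
    *,
    zero_eps: float = DEFAULT_ZERO_EPS,
    seed: int = 0,
    n_random_starts: int = 5,
) -> pd.DataFrame:
    """Estimate diets for a predator cohort.

    Returns one row per predator: ``id``, ``class``, ``year``, one ``pi``
    column per species, ``optimum_distance`` and ``converged``.
    Deterministic for a given seed (random starts are seeded per call).
    """
    if not predators:
        raise SignatureValidationError("empty predator list")
    rows = []
    for rec in predators:
        est = estimate_diet(
            rec.signature, lib, cc, fa_subset, lipid_overrides,
            zero_eps=zero_eps, n_random_starts=n_random_starts, seed=seed,
        )
        rows.append(
            {
                "id": rec.id,
                "class": rec.sex_age_class,
                "year": rec.capture_year,
                **dict(zip(lib.labels, est.pi)),
                "optimum_distance": est.optimum_distance,
                "converged": est.converged,
            }
        )
    return pd.DataFrame(rows)


def summarize_diet(diet_table: pd.DataFrame, species: Sequence[str]) -> pd.DataFrame:
    """Per-species mean and standard error of ``pi``, on the percent scale.

    Mirrors the "mean ± SE %" reporting convention (one decimal place in the
    ``display`` column).
    """
    out = []
    n = len(diet_table)
    for sp in species:
        vals = diet_table[sp].to_numpy(dtype=float) * 100.0
        mean = float(vals.mean())
        se = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        out.append(
            {
                "species": sp,
                "mean_pct": mean,
                "se_pct": se,
                "n": n,
                "display": f"{mean:.1f} ± {se:.1f}%",
            }
        )
    return pd.DataFrame(out)
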