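"""Fatty acid signature data model, validation and tabular I/O.

A *signature* is a composition over a named set of fatty acids (shorthand
labels such as ``"16:0"`` or ``"22:6n3"``), stored internally as proportions
on the unit simplex.  External files may carry either proportions or mass
percentages (rows summing to ~100); rows are closed to sum 1 on read.

The module also holds the calibration-coefficient model: a strictly positive
per-fatty-acid factor describing how a predator's metabolism distorts dietary
fatty acid proportions.  Mapping a predator signature into prey space divides
by the coefficients and renormalizes; the multiplicative inverse direction is
used when simulating predators from prey.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SignatureValidationError",
    "FattyAcidSet",
    "Signature",
    "CalibrationCoefficients",
    "PredatorRecord",
    "PreyLibrary",
    "IceIndexTable",
    "SEX_AGE_CLASSES",
    "normalize",
    "replace_zeros",
    "apply_calibration",
    "restrict",
    "read_predator_table",
    "read_prey_table",
    "read_lipid_table",
    "read_cc_table",
    "read_ice_table",
    "write_predator_table",
    "write_prey_table",
    "write_table",
]

#: Independent-bear demographic classes: adult/subadult crossed with sex.
#: Dependent young are excluded from analysis (nursing distorts signatures).
SEX_AGE_CLASSES = ("AF", "AM", "SF", "SM")

#: Row sums above this are taken to be on the 0-100 percent scale.
PERCENT_SCALE_THRESHOLD = 1.5

#: Default replacement for structural zeros ahead of log-based distances.
DEFAULT_ZERO_EPS = 1e-5

CLOSURE_TOL = 1e-9


class SignatureValidationError(ValueError):
    """Raised when a signature, table row or coefficient fails validation."""


@dataclass(frozen=True)
class FattyAcidSet:
    """Ordered, unique collection of fatty acid labels."""

    names: tuple[str, ...]

    def __init__(self, names: Iterable[str]):
        names = tuple(str(n) for n in names)
        if not names:
            raise SignatureValidationError("fatty acid set must be non-empty")
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise SignatureValidationError(f"duplicate fatty acid labels: {dupes}")
        object.__setattr__(self, "names", names)

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self):
        return iter(self.names)

    def __contains__(self, name: str) -> bool:
        return name in self.names

    def indices_of(self, subset: "FattyAcidSet | Sequence[str]") -> np.ndarray:
        """Positions of ``subset`` labels within this set (order of subset)."""
        labels = subset.names if isinstance(subset, FattyAcidSet) else tuple(subset)
        missing = [n for n in labels if n not in self.names]
        if missing:
            raise SignatureValidationError(
                f"fatty acids not in set: {missing}; no imputation is performed"
            )
        pos = {n: i for i, n in enumerate(self.names)}
        return np.array([pos[n] for n in labels], dtype=int)


def _as_vector(values, n: int | None = None) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise SignatureValidationError(f"expected 1-D vector, got shape {v.shape}")
    if n is not None and v.size != n:
        raise SignatureValidationError(f"expected length {n}, got {v.size}")
    return v


@dataclass(frozen=True)
class Signature:
    """A closed composition (sums to 1) aligned to a :class:`FattyAcidSet`."""

    fa_set: FattyAcidSet
    values: np.ndarray

    def __post_init__(self):
        v = _as_vector(self.values, len(self.fa_set))
        if np.any(v < 0):
            raise SignatureValidationError("signature has negative components")
        if abs(v.sum() - 1.0) > CLOSURE_TOL:
            raise SignatureValidationError(
                f"signature not closed: sum={v.sum()!r} (use normalize())"
            )
        v = v.copy()
        v.flags.writeable = False
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.fa_set)


@dataclass(frozen=True)
class CalibrationCoefficients:
    """Strictly positive per-fatty-acid predator:prey distortion factors."""

    fa_set: FattyAcidSet
    values: np.ndarray

    def __post_init__(self):
        v = _as_vector(self.values, len(self.fa_set))
        if np.any(v <= 0) or not np.all(np.isfinite(v)):
            raise SignatureValidationError("calibration coefficients must be finite and > 0")
        v = v.copy()
        v.flags.writeable = False
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class PredatorRecord:
    """One sampled predator: identity, demography and adipose signature."""

    id: str
    sex_age_class: str
    capture_year: int
    signature: Signature

    def __post_init__(self):
        if self.sex_age_class not in SEX_AGE_CLASSES:
            raise SignatureValidationError(
                f"predator {self.id!r}: unknown sex/age class "
                f"{self.sex_age_class!r} (expected one of {SEX_AGE_CLASSES})"
            )


@dataclass(frozen=True)
class PreyLibrary:
    """Per-species specimen signatures plus lipid fractions.

    Parameters
    ----------
    fa_set : FattyAcidSet
        Shared fatty acid set for every specimen.
    species : mapping of label -> (n_specimens, n_fatty_acids) array
        Each row a closed composition.
    lipid_fractions : mapping of label -> float in (0, 1]
        Proportion of consumed prey mass that is lipid.
    """

    fa_set: FattyAcidSet
    species: Mapping[str, np.ndarray]
    lipid_fractions: Mapping[str, float]

    def __post_init__(self):
        if len(self.species) < 2:
            raise SignatureValidationError("prey library needs >= 2 species")
        clean: dict[str, np.ndarray] = {}
        for label, mat in self.species.items():
            m = np.asarray(mat, dtype=float)
            if m.ndim != 2 or m.shape[1] != len(self.fa_set):
                raise SignatureValidationError(
                    f"species {label!r}: specimen matrix shape {m.shape} "
                    f"does not match {len(self.fa_set)} fatty acids"
                )
            if m.shape[0] < 1:
                raise SignatureValidationError(f"species {label!r}: no specimens")
            if np.any(m < 0):
                raise SignatureValidationError(f"species {label!r}: negative values")
            if np.any(np.abs(m.sum(axis=1) - 1.0) > CLOSURE_TOL):
                raise SignatureValidationError(
                    f"species {label!r}: specimens not closed to sum 1"
                )
            m = m.copy()
            m.flags.writeable = False
            clean[label] = m
        object.__setattr__(self, "species", clean)
        lf = {}
        for label in clean:
            if label not in self.lipid_fractions:
                raise SignatureValidationError(f"missing lipid fraction for {label!r}")
            f = float(self.lipid_fractions[label])
            if not (0.0 < f <= 1.0):
                raise SignatureValidationError(
                    f"lipid fraction for {label!r} must be in (0, 1], got {f}"
                )
            lf[label] = f
        object.__setattr__(self, "lipid_fractions", lf)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.species.keys())

    @property
    def n_species(self) -> int:
        return len(self.species)

    def n_specimens(self, label: str) -> int:
        return self.species[label].shape[0]

    def lipid_vector(self, overrides: Mapping[str, float] | None = None) -> np.ndarray:
        """Lipid fractions as a vector in species order, with overrides applied."""
        f = dict(self.lipid_fractions)
        if overrides:
            unknown = set(overrides) - set(f)
            if unknown:
                raise SignatureValidationError(f"lipid override for unknown species: {sorted(unknown)}")
            f.update({k: float(v) for k, v in overrides.items()})
        vec = np.array([f[k] for k in self.labels], dtype=float)
        if np.any(vec <= 0) or np.any(vec > 1):
            raise SignatureValidationError("lipid fractions must be in (0, 1]")
        return vec

    def subset_species(self, keep: Sequence[str]) -> "PreyLibrary":
        return PreyLibrary(
            fa_set=self.fa_set,
            species={k: self.species[k] for k in keep},
            lipid_fractions={k: self.lipid_fractions[k] for k in keep},
        )


@dataclass(frozen=True)
class IceIndexTable:
    """Annual sea-ice indices: ice-free days at two thresholds, melt season."""

    data: pd.DataFrame = field(repr=False)

    COLUMNS = ("year", "ifd50", "ifd15", "melt_season")

    def __post_init__(self):
        df = pd.DataFrame(self.data)
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise SignatureValidationError(f"ice index table missing columns: {missing}")
        df = df.loc[:, list(self.COLUMNS)].copy()
        df["year"] = df["year"].astype(int)
        if df["year"].duplicated().any():
            raise SignatureValidationError("ice index table has duplicated years")
        for c in self.COLUMNS[1:]:
            df[c] = df[c].astype(float)
            bad = df.loc[(df[c] < 0) | (df[c] > 366), "year"].tolist()
            if bad:
                raise SignatureValidationError(
                    f"{c} outside [0, 366] for years {bad}"
                )
        object.__setattr__(self, "data", df.reset_index(drop=True))

    def index_for_years(self, years: Sequence[int], index: str) -> np.ndarray:
        if index not in self.COLUMNS[1:]:
            raise SignatureValidationError(
                f"unknown ice index {index!r}; choose from {self.COLUMNS[1:]}"
            )
        lookup = dict(zip(self.data["year"], self.data[index]))
        missing = sorted({int(y) for y in years if int(y) not in lookup})
        if missing:
            raise SignatureValidationError(f"years missing from ice table: {missing}")
        return np.array([lookup[int(y)] for y in years], dtype=float)


# ---------------------------------------------------------------------------
# Core compositional operations
# ---------------------------------------------------------------------------

def normalize(raw, fa_set: FattyAcidSet | Sequence[str], *, label: str | None = None) -> Signature:
    """Close a nonnegative vector to sum 1 and wrap as a :class:`Signature`.

    Proportionality to the input is preserved.  All-zero or negative input
    raises :class:`SignatureValidationError` naming ``label`` if given.
    """
    if not isinstance(fa_set, FattyAcidSet):
        fa_set = FattyAcidSet(fa_set)
    who = f" for {label!r}" if label else ""
    v = _as_vector(raw, len(fa_set))
    if not np.all(np.isfinite(v)):
        raise SignatureValidationError(f"non-finite signature values{who}")
    if np.any(v < 0):
        raise SignatureValidationError(f"negative signature values{who}")
    s = v.sum()
    if s <= 0:
        raise SignatureValidationError(f"signature sums to zero{who}")
    return Signature(fa_set, v / s)


def replace_zeros(sig: Signature, eps: float = DEFAULT_ZERO_EPS) -> Signature:
    """Replace zero components with ``eps`` and renormalize.

    KL-type distances are undefined at zero; a small positive replacement
    followed by closure is the conventional remedy.
    """
    if eps <= 0:
        raise SignatureValidationError("zero-replacement eps must be > 0")
    v = np.where(sig.values <= 0, eps, sig.values)
    return Signature(sig.fa_set, v / v.sum())


def apply_calibration(
    sig: Signature,
    cc: CalibrationCoefficients,
    direction: str = "predator_to_prey",
) -> Signature:
    """Calibration-correct a signature.

    ``"predator_to_prey"`` divides each component by its coefficient and
    renormalizes (the correction applied before diet estimation);
    ``"prey_to_predator"`` multiplies and renormalizes (used to distort
    simulated predators).  The two directions are exact inverses.
    """
    if sig.fa_set.names != cc.fa_set.names:
        raise SignatureValidationError("signature and coefficients use different fatty acid sets")
    if direction == "predator_to_prey":
        v = sig.values / cc.values
    elif direction == "prey_to_predator":
        v = sig.values * cc.values
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return Signature(sig.fa_set, v / v.sum())


def restrict(sig: Signature, subset: FattyAcidSet | Sequence[str]) -> Signature:
    """Restrict a signature to a fatty acid subset and renormalize."""
    if not isinstance(subset, FattyAcidSet):
        subset = FattyAcidSet(subset)
    idx = sig.fa_set.indices_of(subset)
    v = sig.values[idx]
    s = v.sum()
    if s <= 0:
        raise SignatureValidationError("signature has zero mass on requested subset")
    return Signature(subset, v / s)


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

def _sniff_sep(path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            return "\t" if "\t" in line else ","
    raise SignatureValidationError(f"{path}: empty file")


def _read_delimited(path) -> pd.DataFrame:
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, comment="#", dtype=str, skipinitialspace=True)
    df.columns = [str(c).strip() for c in df.columns]
    return df


def _numeric_block(df: pd.DataFrame, cols: Sequence[str], path) -> np.ndarray:
    block = df.loc[:, list(cols)].apply(pd.to_numeric, errors="coerce")
    bad = block.isna().any(axis=1)
    if bad.any():
        # +2: header line plus 1-based indexing
        rows = [int(i) + 2 for i in np.flatnonzero(bad.to_numpy())]
        raise SignatureValidationError(
            f"{path}: non-numeric fatty acid values on line(s) {rows}"
        )
    return block.to_numpy(dtype=float)


def _close_rows(mat: np.ndarray, path, row_labels: Sequence[str]) -> np.ndarray:
    """Close each row to sum 1; percent-scale rows (sum > 1.5) rescale too."""
    sums = mat.sum(axis=1)
    errs = []
    for i, s in enumerate(sums):
        if s <= 0 or np.any(mat[i] < 0):
            errs.append(f"line {i + 2} ({row_labels[i]})")
    if errs:
        raise SignatureValidationError(
            f"{path}: rows with nonpositive totals or negative values: {errs}"
        )
    return mat / sums[:, None]


def read_predator_table(path) -> list[PredatorRecord]:
    """Read a predator signature file.

    Expected columns: ``id``, ``class``, ``year``, then one column per fatty
    acid.  Values may be proportions or percentages; each row is closed to
    sum 1.  Unknown class codes (e.g. dependent young) are an error.
    """
    df = _read_delimited(path)
    meta = ["id", "class", "year"]
    missing = [c for c in meta if c not in df.columns]
    if missing:
        raise SignatureValidationError(f"{path}: missing required columns {missing}")
    fa_cols = [c for c in df.columns if c not in meta]
    if not fa_cols:
        raise SignatureValidationError(f"{path}: no fatty acid columns found")
    fa_set = FattyAcidSet(fa_cols)
    mat = _numeric_block(df, fa_cols, path)
    mat = _close_rows(mat, path, df["id"].tolist())

    records = []
    for i, row in df.iterrows():
        klass = str(row["class"]).strip()
        if klass not in SEX_AGE_CLASSES:
            raise SignatureValidationError(
                f"{path}: line {int(i) + 2}: unknown sex/age class {klass!r} "
                f"(expected one of {SEX_AGE_CLASSES}; dependent young are excluded)"
            )
        try:
            year = int(float(row["year"]))
        except (TypeError, ValueError):
            raise SignatureValidationError(
                f"{path}: line {int(i) + 2}: non-integer year {row['year']!r}"
            ) from None
        records.append(
            PredatorRecord(
                id=str(row["id"]).strip(),
                sex_age_class=klass,
                capture_year=year,
                signature=Signature(fa_set, mat[i]),
            )
        )
    return records


def read_lipid_table(path) -> dict[str, float]:
    """Read a two-column (species, lipid_fraction) file."""
    df = _read_delimited(path)
    missing = [c for c in ("species", "lipid_fraction") if c not in df.columns]
    if missing:
        raise SignatureValidationError(f"{path}: missing required columns {missing}")
    out = {}
    for i, row in df.iterrows():
        try:
            out[str(row["species"]).strip()] = float(row["lipid_fraction"])
        except (TypeError, ValueError):
            raise SignatureValidationError(
                f"{path}: line {int(i) + 2}: non-numeric lipid fraction"
            ) from None
    return out


def read_prey_table(path, lipids: Mapping[str, float] | str | None = None) -> PreyLibrary:
    """Read a prey signature file (columns: ``species`` then fatty acids).

    ``lipids`` may be a mapping or a path to a lipid file; if omitted every
    species defaults to a lipid fraction of 1.0 (whole-blubber assumption).
    """
    df = _read_delimited(path)
    if "species" not in df.columns:
        raise SignatureValidationError(f"{path}: missing required column ['species']")
    fa_cols = [c for c in df.columns if c != "species"]
    if not fa_cols:
        raise SignatureValidationError(f"{path}: no fatty acid columns found")
    fa_set = FattyAcidSet(fa_cols)
    mat = _numeric_block(df, fa_cols, path)
    labels = [str(s).strip() for s in df["species"]]
    mat = _close_rows(mat, path, labels)

    species: dict[str, list[np.ndarray]] = {}
    for lab, row in zip(labels, mat):
        species.setdefault(lab, []).append(row)

    if isinstance(lipids, (str, bytes)) or hasattr(lipids, "__fspath__"):
        lipids = read_lipid_table(lipids)
    if lipids is None:
        lipids = {lab: 1.0 for lab in species}

    return PreyLibrary(
        fa_set=fa_set,
        species={lab: np.vstack(rows) for lab, rows in species.items()},
        lipid_fractions=dict(lipids),
    )


def read_cc_table(path, fa_set: FattyAcidSet | None = None) -> CalibrationCoefficients:
    """Read a two-column (fatty_acid, cc) file, optionally aligned to ``fa_set``."""
    df = _read_delimited(path)
    missing = [c for c in ("fatty_acid", "cc") if c not in df.columns]
    if missing:
        raise SignatureValidationError(f"{path}: missing required columns {missing}")
    mapping = {}
    for i, row in df.iterrows():
        try:
            mapping[str(row["fatty_acid"]).strip()] = float(row["cc"])
        except (TypeError, ValueError):
            raise SignatureValidationError(
                f"{path}: line {int(i) + 2}: non-numeric calibration coefficient"
            ) from None
    if fa_set is None:
        fa_set = FattyAcidSet(mapping.keys())
    missing_fa = [n for n in fa_set.names if n not in mapping]
    if missing_fa:
        raise SignatureValidationError(
            f"{path}: calibration coefficients missing for {missing_fa}"
        )
    return CalibrationCoefficients(fa_set, np.array([mapping[n] for n in fa_set.names]))


def read_ice_table(path) -> IceIndexTable:
    df = _read_delimited(path)
    for c in df.columns:
        df[c] = pd.to_numeric(df[c], errors="coerce")
    if df.isna().any().any():
        raise SignatureValidationError(f"{path}: non-numeric entries in ice index table")
    return IceIndexTable(df)


def _provenance_header(meta: Mapping[str, object] | None) -> str:
    from . import __version__

    parts = [f"qfasakit v{__version__}"]
    if meta:
        parts += [f"{k}={v}" for k, v in meta.items()]
    return "# " + " ".join(parts) + "\n"


def write_table(df: pd.DataFrame, path, *, meta: Mapping[str, object] | None = None,
                sep: str = ",") -> None:
    """Write a table with a provenance header comment line.

    Floats are written with 17 significant digits so that write-then-read
    round-trips reproduce values exactly.
    """
    buf = io.StringIO()
    buf.write(_provenance_header(meta))
    df.to_csv(buf, sep=sep, index=False, float_format="%.17g")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())


def write_predator_table(records: Sequence[PredatorRecord], path, *,
                         meta: Mapping[str, object] | None = None, sep: str = ",") -> None:
    if not records:
        raise SignatureValidationError("no predator records to write")
    fa_set = records[0].signature.fa_set
    rows = []
    for r in records:
        if r.signature.fa_set.names != fa_set.names:
            raise SignatureValidationError("records use different fatty acid sets")
        rows.append([r.id, r.sex_age_class, r.capture_year, *r.signature.values])
    df = pd.DataFrame(rows, columns=["id", "class", "year", *fa_set.names])
    write_table(df, path, meta=meta, sep=sep)


def write_prey_table(lib: PreyLibrary, path, *,
                     meta: Mapping[str, object] | None = None, sep: str = ",") -> None:
    rows = []
    for label, mat in lib.species.items():
        for spec in mat:
            rows.append([label, *spec])
    df = pd.DataFrame(rows, columns=["species", *lib.fa_set.names])
    write_table(df, path, meta=meta, sep=sep)
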