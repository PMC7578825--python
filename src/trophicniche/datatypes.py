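"""Domain types for gut-content and stable-isotope trophic niche analysis.

The tabular inputs (diet records, isotope samples, source signatures,
gut-fullness observations) are thin, validated wrappers around pandas
DataFrames; the result types are plain dataclasses that serialize losslessly
to JSON/CSV via :mod:`trophicniche.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd


class TrophicError(Exception):
    """Base class for all validation and computation errors in this package."""


class SchemaError(TrophicError):
    """A required column is missing or has the wrong dtype."""


class ValidationError(TrophicError):
    """A row violates a type invariant; the message names the row."""


class InsufficientDataError(TrophicError):
    """Too few samples/individuals for the requested metric."""


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing column(s) {missing!r}")


@dataclass
class DietMatrix:
    """Per-individual prey-resource use (counts and masses) with group labels.

    ``data`` columns: individual_id, group, prey_taxon, count, mass.
    Counts are numbers of prey items; masses are grams. Either count or mass
    may be missing (NaN) for a record — the record simply does not contribute
    to metrics needing the missing field. Duplicate (individual, taxon) rows
    are summed on construction.
    """

    data: pd.DataFrame

    COLUMNS = ("individual_id", "group", "prey_taxon", "count", "mass")

    def __post_init__(self) -> None:
        _require_columns(self.data, self.COLUMNS, "DietMatrix")
        df = self.data.copy()
        for col in ("count", "mass"):
            vals = pd.to_numeric(df[col], errors="coerce")
            bad = vals.notna() & (vals < 0)
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise ValidationError(f"DietMatrix: negative {col} at row {row}")
            if col == "count":
                nonint = vals.notna() & (vals != np.floor(vals))
                if nonint.any():
                    row = int(np.flatnonzero(nonint.to_numpy())[0])
                    raise ValidationError(f"DietMatrix: non-integer count at row {row}")
            inf = vals.notna() & ~np.isfinite(vals.fillna(0.0))
            if inf.any():
                row = int(np.flatnonzero(inf.to_numpy())[0])
                raise ValidationError(f"DietMatrix: non-finite {col} at row {row}")
            df[col] = vals
        # duplicate (individual, taxon) rows are summed; NaN stays NaN only
        # if every duplicate was NaN
        df = (
            df.groupby(["individual_id", "group", "prey_taxon"], sort=False)[["count", "mass"]]
            .sum(min_count=1)
            .reset_index()
        )
        self.data = df

    @property
    def taxa(self) -> list[str]:
        """Shared prey vocabulary, in order of first appearance."""
        return list(dict.fromkeys(self.data["prey_taxon"]))

    @property
    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.data["group"]))

    def individuals(self, group: str | None = None) -> list:
        df = self.data if group is None else self.data[self.data["group"] == group]
        return list(dict.fromkeys(df["individual_id"]))

    def pivot(self, group: str, basis: str = "count") -> pd.DataFrame:
        """Individuals x taxa matrix of the chosen basis for one group.

        Rows with a missing value on the chosen basis contribute zero.
        """
        if basis not in ("count", "mass"):
            raise ValueError(f"basis must be 'count' or 'mass', got {basis!r}")
        df = self.data[self.data["group"] == group]
        if df.empty:
            raise InsufficientDataError(f"no individuals in group {group!r}")
        mat = df.pivot_table(
            index="individual_id", columns="prey_taxon", values=basis, aggfunc="sum"
        ).fillna(0.0)
        # preserve first-appearance order on both axes
        mat = mat.reindex(index=self.individuals(group))
        mat = mat.reindex(columns=[t for t in self.taxa if t in mat.columns])
        return mat


@dataclass
class IsotopeTable:
    """Per-sample (δ13C, δ15N) in ‰, with group label and optional standard length (mm)."""

    data: pd.DataFrame

    COLUMNS = ("sample_id", "group", "d13C", "d15N")

    def __post_init__(self) -> None:
        _require_columns(self.data, self.COLUMNS, "IsotopeTable")
        df = self.data.copy()
        for col in ("d13C", "d15N"):
            vals = pd.to_numeric(df[col], errors="coerce")
            bad = ~np.isfinite(vals.to_numpy(dtype=float))
            if bad.any():
                row = int(np.flatnonzero(bad)[0])
                raise ValidationError(f"IsotopeTable: non-finite {col} at row {row}")
            df[col] = vals
        if "SL" in df.columns:
            sl = pd.to_numeric(df["SL"], errors="coerce")
            bad = sl.notna() & (sl <= 0)
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise ValidationError(f"IsotopeTable: non-positive SL at row {row}")
            df["SL"] = sl
        self.data = df

    @property
    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.data["group"]))

    def xy(self, group: str | None = None) -> np.ndarray:
        """(n, 2) array of (δ13C, δ15N) for one group (or all samples)."""
        df = self.data if group is None else self.data[self.data["group"] == group]
        return df[["d13C", "d15N"]].to_numpy(dtype=float)


@dataclass
class SourceSet:
    """Per-source isotopic signatures and trophic enrichment factors.

    Arrays are (n_sources, n_tracers); tracer order is shared by all sources.
    """

    names: list[str]
    tracers: list[str]
    mean: np.ndarray
    sd: np.ndarray
    tef_mean: np.ndarray
    tef_sd: np.ndarray

    def __post_init__(self) -> None:
        k, j = len(self.names), len(self.tracers)
        if k < 1:
            raise ValidationError("SourceSet: need at least one source")
        for attr in ("mean", "sd", "tef_mean", "tef_sd"):
            arr = np.asarray(getattr(self, attr), dtype=float)
            if arr.shape != (k, j):
                raise ValidationError(
                    f"SourceSet: {attr} has shape {arr.shape}, expected ({k}, {j})"
                )
            setattr(self, attr, arr)
        if (self.sd < 0).any() or (self.tef_sd < 0).any():
            raise ValidationError("SourceSet: negative SD")

    @property
    def n_sources(self) -> int:
        return len(self.names)


@dataclass
class FullnessTable:
    """Ordinal gut-fullness observations with time-of-day/season/group covariates.

    ``ff`` is the visual fullness level 0 (empty intestine) … 5 (distension);
    Wt/Wgut/Wg are body, gut and gonad wet masses in grams.
    """

    data: pd.DataFrame

    COLUMNS = ("individual_id", "group", "season", "time_h", "ff")

    def __post_init__(self) -> None:
        _require_columns(self.data, self.COLUMNS, "FullnessTable")
        df = self.data.copy()
        ff = pd.to_numeric(df["ff"], errors="coerce")
        bad = ~ff.isin(range(6))
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(f"FullnessTable: ff outside 0-5 at row {row}")
        df["ff"] = ff.astype(int)
        for col in ("Wt", "Wgut", "Wg"):
            if col in df.columns:
                df[col] = pd.to_numeric(df[col], errors="coerce")
        if "Wt" in df.columns:
            for col in ("Wgut", "Wg"):
                if col in df.columns:
                    bad = df[col].notna() & df["Wt"].notna() & (df[col] > df["Wt"])
                    if bad.any():
                        row = int(np.flatnonzero(bad.to_numpy())[0])
                        raise ValidationError(
                            f"FullnessTable: {col} exceeds Wt at row {row}"
                        )
        self.data = df


# ---------------------------------------------------------------------------
# result types


@dataclass
class DietProfile:
    """A diet-proportion vector on the shared prey vocabulary.

    ``basis`` records whether proportions derive from mass (%W/100) or
    count (%N/100) data. Proportions within 1e-9 of a simplex are accepted;
    otherwise they are renormalized (printed tables often omit minor items).
    """

    labels: list[str]
    proportions: np.ndarray
    basis: str = "mass"

    def __post_init__(self) -> None:
        p = np.asarray(self.proportions, dtype=float)
        if (p < 0).any():
            raise ValidationError("DietProfile: negative proportion")
        total = p.sum()
        if total <= 0:
            raise ValidationError("DietProfile: zero-vector profile")
        if abs(total - 1.0) > 1e-9:
            p = p / total
        self.proportions = p

    def as_series(self) -> pd.Series:
        return pd.Series(self.proportions, index=self.labels)


@dataclass
class NicheMetrics:
    """The seven bivariate isotope-niche metrics for one group (‰ / ‰²)."""

    nr: float
    cr: float
    cd: float
    mnnd_mean: float
    mnnd_sd: float
    ta: float
    sea: float
    seac: float
    n: int
    degenerate: bool = False


@dataclass
class SpecializationResult:
    """Roughgarden Shannon-entropy niche decomposition (nats)."""

    tnw: float
    wic: float
    bic: float
    wic_over_tnw: float
    mean_diet_similarity: float | None = None
    degenerate: bool = False


@dataclass
class MixResult:
    """Posterior summary of dietary source proportions."""

    sources: list[str]
    posterior_mean: np.ndarray
    ci95_low: np.ndarray
    ci95_high: np.ndarray
    diagnostics: dict = field(default_factory=dict)
    draws: np.ndarray | None = None

    def __post_init__(self) -> None:
        for attr in ("posterior_mean", "ci95_low", "ci95_high"):
            setattr(self, attr, np.asarray(getattr(self, attr), dtype=float))


@dataclass
class Ellipse:
    """A covariance ellipse in (δ13C, δ15N) space.

    ``coverage`` is the bivariate-normal probability mass the drawn/overlapped
    ellipse encloses; 0.3935 corresponds to the 1-SD standard ellipse.
    """

    center: np.ndarray
    covariance: np.ndarray
    coverage: float = 0.3935

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        cov = np.asarray(self.covariance, dtype=float)
        if cov.shape != (2, 2) or not np.allclose(cov, cov.T):
            raise ValidationError("Ellipse: covariance must be symmetric 2x2")
        if np.linalg.eigvalsh(cov).min() <= 0:
            raise ValidationError("Ellipse: covariance must be positive definite")
        self.covariance = cov


@dataclass
class RegressionFit:
    """OLS fit of an isotope tracer on standard length."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    slope_se: float = float("nan")


@dataclass
class TestResult:
    """Outcome of a two-sample or correlation test."""

    statistic: float
    p_value: float
    method: str
    n1: int = 0
    n2: int = 0
    permutations: int | None = None
    seed: int | None = None


@dataclass
class LmmFit:
    """ML fit of the gut-fullness linear mixed model (season random intercept)."""

    formula: str
    fixed_effects: dict
    fixed_effects_se: dict
    season_variance: float
    residual_variance: float
    log_likelihood: float
    n_fixed_params: int
    converged: bool = True
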