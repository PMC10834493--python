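"""Data model and I/O for dissolution profiles and studies.

A dissolution profile records the cumulative percent of label claim
released at each sampling time, for one product, across replicate
vessels.  A study couples one reference (innovator) profile with one or
more test (generic) profiles on an identical time grid, which is what
the model-independent f1/f2 comparison requires.

Profiles come in two flavours:

* **replicate** profiles hold the full time x replicate matrix; per-time
  mean and SD are derived.
* **summary-only** profiles hold only per-time mean and SD (and the
  replicate count n), the way published dissolution tables report them.
  They are first-class citizens because a mean-profile comparison needs
  nothing more.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, GridMismatchError, ParseError

#: Hard ceiling on percent released; values above this almost always mean
#: a unit error (fraction vs percent) rather than a real supersaturation.
MAX_PERCENT = 120.0

#: Default CV screening policy: <= 20 % at the first sampling time,
#: <= 10 % at every later one (the usual prerequisite for a mean-based
#: f2 comparison).
DEFAULT_CV_POLICY = (20.0, 10.0)


@dataclass(frozen=True)
class TimeGrid:
    """Ordered sampling times in minutes."""

    times: tuple[float, ...]

    def __init__(self, times: Sequence[float]) -> None:
        t = tuple(float(x) for x in times)
        if len(t) < 3:
            raise ValueError(f"a time grid needs at least 3 points, got {len(t)}")
        arr = np.asarray(t)
        if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
            raise ValueError("sampling times must be finite and > 0")
        if np.any(np.diff(arr) <= 0):
            raise ValueError(f"sampling times must be strictly increasing: {t}")
        object.__setattr__(self, "times", t)

    def __len__(self) -> int:
        return len(self.times)

    def __iter__(self):
        return iter(self.times)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.times, dtype=float)


@dataclass
class DissolutionProfile:
    """One product's percent-released series over a time grid.

    Exactly one of ``replicates`` or (``mean``, ``sd``) is the source of
    truth.  ``replicates`` has shape (n_times, n_reps).  For summary-only
    profiles ``sd`` entries may be NaN when the SD is unknown (n = 1).
    """

    product_label: str
    grid: TimeGrid
    replicates: np.ndarray | None = None
    mean: np.ndarray | None = None
    sd: np.ndarray | None = None
    n_reps: int | None = None
    #: "raise" rejects values above the plausibility ceiling; "flag"
    #: keeps them and records a boolean mask in ``implausible`` (used by
    #: quantitation, where a high cell is a data-quality flag, not fatal).
    on_implausible: str = "raise"
    implausible: np.ndarray | None = None

    def __post_init__(self) -> None:
        nt = len(self.grid)
        if self.replicates is not None:
            rep = np.atleast_2d(np.asarray(self.replicates, dtype=float))
            if rep.shape[0] != nt:
                # allow a 1-D series to be passed either way round
                if rep.shape == (1, nt):
                    rep = rep.T
                else:
                    raise ValueError(
                        f"replicate matrix has {rep.shape[0]} rows for "
                        f"{nt} time points ({self.product_label})"
                    )
            self.implausible = _check_percent(
                rep, self.product_label, self.on_implausible)
            self.replicates = rep
            self.n_reps = rep.shape[1]
        else:
            if self.mean is None:
                raise ValueError("profile needs replicates or a mean series")
            m = np.asarray(self.mean, dtype=float)
            if m.shape != (nt,):
                raise ValueError(
                    f"mean series length {m.size} != grid length {nt} "
                    f"({self.product_label})"
                )
            self.implausible = _check_percent(
                m, self.product_label, self.on_implausible)
            self.mean = m
            if self.sd is not None:
                s = np.asarray(self.sd, dtype=float)
                if s.shape != (nt,):
                    raise ValueError("sd series length does not match grid")
                with np.errstate(invalid="ignore"):
                    if np.any(s[np.isfinite(s)] < 0):
                        raise ValueError("SDs must be >= 0")
                self.sd = s

    @property
    def summary_only(self) -> bool:
        return self.replicates is None

    def means(self) -> np.ndarray:
        """Per-time-point mean percent released."""
        if self.replicates is not None:
            return self.replicates.mean(axis=1)
        return np.asarray(self.mean, dtype=float)

    def sds(self) -> np.ndarray:
        """Per-time-point sample SD (n-1 denominator); NaN when n = 1 or unknown."""
        if self.replicates is not None:
            if self.replicates.shape[1] < 2:
                return np.full(len(self.grid), np.nan)
            return self.replicates.std(axis=1, ddof=1)
        if self.sd is None:
            return np.full(len(self.grid), np.nan)
        return np.asarray(self.sd, dtype=float)


def _check_percent(
    values: np.ndarray, label: str, on_implausible: str = "raise"
) -> np.ndarray | None:
    if not np.all(np.isfinite(values)):
        raise ValueError(f"non-finite percent-released value in {label!r}")
    if np.any(values < 0):
        raise ValueError(f"negative percent-released value in {label!r}")
    high = values > MAX_PERCENT
    if high.any():
        if on_implausible != "flag":
            raise ValueError(
                f"percent released > {MAX_PERCENT:g} in {label!r}; "
                "check units (fraction vs percent)"
            )
        return high
    return None


@dataclass
class Study:
    """A reference profile plus test profiles on a shared time grid."""

    reference: DissolutionProfile
    tests: list[DissolutionProfile]
    method: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        grids = {p.grid.times for p in [self.reference, *self.tests]}
        if len(grids) > 1:
            labels = sorted(
                p.product_label
                for p in [self.reference, *self.tests]
                if p.grid.times != self.reference.grid.times
            )
            raise GridMismatchError(
                "profiles do not share the reference time grid: "
                + ", ".join(labels)
            )
        labels = [p.product_label for p in self.tests]
        if self.reference.product_label in labels:
            raise ValueError(
                f"reference label {self.reference.product_label!r} also "
                "appears among the test products"
            )
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate test product labels")

    @property
    def grid(self) -> TimeGrid:
        return self.reference.grid

    def all_profiles(self) -> list[DissolutionProfile]:
        return [self.reference, *self.tests]


# ---------------------------------------------------------------------------
# summarising and variability screening
# ---------------------------------------------------------------------------

def summarize(profile: DissolutionProfile) -> pd.DataFrame:
    """Per-time-point mean and sample SD for one profile.

    Summary-only profiles pass their stored values through unchanged.
    A single-replicate profile reports SD as NaN (absent), never zero.
    """
    return pd.DataFrame(
        {
            "time_min": profile.grid.as_array(),
            "mean": profile.means(),
            "sd": profile.sds(),
        }
    )


@dataclass(frozen=True)
class VariabilityReport:
    """Outcome of CV screening for one profile."""

    product_label: str
    cv_percent: np.ndarray  # per time point, NaN where not computable
    limits: np.ndarray      # the CV limit applied at each time point
    assessable: bool
    passed: bool | None     # None when not assessable

    def to_frame(self, grid: TimeGrid) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_min": grid.as_array(),
                "cv_percent": self.cv_percent,
                "cv_limit": self.limits,
            }
        )


def screen_variability(
    profile: DissolutionProfile,
    policy: tuple[float, float] = DEFAULT_CV_POLICY,
) -> VariabilityReport:
    """Screen per-time-point coefficients of variation against a policy.

    ``policy`` is (limit at the first time point, limit thereafter), in
    percent.  CV = 100 * SD / mean.  A summary-only profile with stored
    SDs is screened from those; with no SDs the report is flagged as not
    assessable instead of silently passing.
    """
    first_limit, later_limit = policy
    means = profile.means()
    sds = profile.sds()
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = 100.0 * sds / means
    limits = np.full(len(profile.grid), float(later_limit))
    limits[0] = float(first_limit)
    if np.all(np.isnan(cv)):
        return VariabilityReport(profile.product_label, cv, limits, False, None)
    ok = bool(np.all(cv[np.isfinite(cv)] <= limits[np.isfinite(cv)]))
    return VariabilityReport(profile.product_label, cv, limits, True, ok)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

LONG_COLUMNS = ["product", "time_min", "replicate", "pct_released"]
SUMMARY_COLUMNS = ["product", "time_min", "mean", "sd", "n"]

#: Separator between product and replicate in wide-layout column names.
WIDE_SEP = ":"


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )


def _numeric(df: pd.DataFrame, column: str, path) -> pd.Series:
    out = pd.to_numeric(df[column], errors="coerce")
    bad = out.isna() & df[column].notna()
    if bad.any():
        row = int(bad.idxmax()) + 2  # +1 header, +1 zero-index
        raise ParseError(
            f"{path}: non-numeric value {df.loc[bad.idxmax(), column]!r} "
            f"in column {column!r} at line {row}"
        )
    if out.isna().any():
        row = int(out.isna().idxmax()) + 2
        raise ParseError(f"{path}: empty cell in column {column!r} at line {row}")
    return out


def load_study(
    path: str | Path,
    reference: str,
    layout: str = "long",
    method: Mapping[str, object] | None = None,
) -> Study:
    """Read a study from CSV.

    Layouts:

    * ``long``: columns product, time_min, replicate, pct_released.
    * ``summary``: columns product, time_min, mean, sd, n (sd may be blank).
    * ``wide``: a time_min column plus one column per product-replicate,
      named ``<product>:<replicate>`` (a bare product name means a single
      replicate).

    ``reference`` designates the reference product by label; it is never
    inferred from label text.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: no profiles parsed (file is empty)") from None
    if df.empty:
        raise FormatError(f"{path}: no profiles parsed (no data rows)")

    if layout == "long":
        profiles = _parse_long(df, path)
    elif layout == "summary":
        profiles = _parse_summary(df, path)
    elif layout == "wide":
        profiles = _parse_wide(df, path)
    else:
        raise ValueError(f"unknown layout {layout!r}")

    if reference not in profiles:
        raise FormatError(
            f"{path}: reference label {reference!r} not found "
            f"(products: {', '.join(sorted(profiles))})"
        )
    ref = profiles.pop(reference)
    tests = [profiles[k] for k in profiles]  # dict preserves input order
    return Study(reference=ref, tests=tests, method=dict(method or {}))


def _parse_long(df: pd.DataFrame, path) -> dict[str, DissolutionProfile]:
    _require_columns(df, LONG_COLUMNS, path)
    df = df.copy()
    df["time_min"] = _numeric(df, "time_min", path)
    df["pct_released"] = _numeric(df, "pct_released", path)
    profiles: dict[str, DissolutionProfile] = {}
    for product, g in df.groupby("product", sort=False):
        wide = g.pivot_table(
            index="time_min", columns="replicate", values="pct_released",
            sort=True,
        )
        if wide.isna().any().any():
            raise GridMismatchError(
                f"{path}: product {product!r} has unequal sampling times "
                "across replicates"
            )
        grid = TimeGrid(wide.index.to_numpy())
        profiles[str(product)] = DissolutionProfile(
            product_label=str(product), grid=grid, replicates=wide.to_numpy()
        )
    _check_shared_grid(profiles, path)
    return profiles


def _parse_summary(df: pd.DataFrame, path) -> dict[str, DissolutionProfile]:
    _require_columns(df, SUMMARY_COLUMNS, path)
    df = df.copy()
    df["time_min"] = _numeric(df, "time_min", path)
    df["mean"] = _numeric(df, "mean", path)
    sd = pd.to_numeric(df["sd"], errors="coerce")  # blanks allowed -> NaN
    n = pd.to_numeric(df["n"], errors="coerce")
    profiles: dict[str, DissolutionProfile] = {}
    for product, g in df.groupby("product", sort=False):
        g = g.sort_values("time_min")
        grid = TimeGrid(g["time_min"].to_numpy())
        n_vals = n.loc[g.index].dropna().unique()
        profiles[str(product)] = DissolutionProfile(
            product_label=str(product),
            grid=grid,
            mean=g["mean"].to_numpy(),
            sd=sd.loc[g.index].to_numpy(),
            n_reps=int(n_vals[0]) if len(n_vals) == 1 else None,
        )
    _check_shared_grid(profiles, path)
    return profiles


def _parse_wide(df: pd.DataFrame, path) -> dict[str, DissolutionProfile]:
    _require_columns(df, ["time_min"], path)
    df = df.copy()
    df["time_min"] = _numeric(df, "time_min", path)
    df = df.sort_values("time_min")
    grid = TimeGrid(df["time_min"].to_numpy())
    by_product: dict[str, list[np.ndarray]] = {}
    for col in df.columns:
        if col == "time_min":
            continue
        product = col.split(WIDE_SEP, 1)[0] if WIDE_SEP in col else col
        by_product.setdefault(product, []).append(
            _numeric(df, col, path).to_numpy()
        )
    if not by_product:
        raise FormatError(f"{path}: no product columns beside time_min")
    return {
        p: DissolutionProfile(
            product_label=p, grid=grid, replicates=np.column_stack(cols)
        )
        for p, cols in by_product.items()
    }


def _check_shared_grid(profiles: dict[str, DissolutionProfile], path) -> None:
    grids = {p.grid.times for p in profiles.values()}
    if len(grids) > 1:
        ref_grid = max(grids, key=lambda g: sum(
            1 for p in profiles.values() if p.grid.times == g
        ))
        offenders = sorted(
            lbl for lbl, p in profiles.items() if p.grid.times != ref_grid
        )
        raise GridMismatchError(
            f"{path}: products on a different time grid than the majority: "
            + ", ".join(offenders)
        )


def write_study(study: Study, path: str | Path, layout: str = "long") -> None:
    """Write a study back to CSV; numeric cells round-trip at full precision."""
    path = Path(path)
    rows = []
    if layout == "long":
        for p in study.all_profiles():
            if p.summary_only:
                raise ValueError(
                    f"{p.product_label!r} is summary-only; use layout='summary'"
                )
            for i, t in enumerate(p.grid):
                for r in range(p.replicates.shape[1]):
                    rows.append((p.product_label, t, r + 1, p.replicates[i, r]))
        out = pd.DataFrame(rows, columns=LONG_COLUMNS)
    elif layout == "summary":
        for p in study.all_profiles():
            m, s = p.means(), p.sds()
            for i, t in enumerate(p.grid):
                rows.append((p.product_label, t, m[i],
                             s[i] if np.isfinite(s[i]) else "",
                             p.n_reps if p.n_reps else ""))
        out = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    else:
        raise ValueError(f"unknown layout {layout!r}")
    out.to_csv(path, index=False)
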