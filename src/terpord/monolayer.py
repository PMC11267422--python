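"""Langmuir-monolayer analysis: mean molecular areas, the condensation
effect, excess free energy of mixing, and regression-based group comparison.

A compression isotherm records surface pressure Π (mN/m) against mean
molecular area A (Å²/molecule) for a lipid film at the air-water interface.
For a binary film of components 1 and 2 at mole fractions X₁, X₂, the
condensation effect at a pressure Π is

    c = 100 · (1 − A₀ / (X₁A₁ + X₂A₂))   [%]

where A₀ is the measured mixture MMA and X₁A₁ + X₂A₂ the ideal-mixing
area. Positive c means the film packs tighter than an ideal mixture — the
diagnostic signature of ordering by a sterol or hopanoid.

The excess free energy of mixing at a target pressure Π* integrates the
excess area over the compression path,

    ΔG_exc(Π*) = N_A ∫ [A_mix(Π) − (X₁A₁(Π) + X₂A₂(Π))] dΠ ,

converted to J/mol (1 mN/m · Å²/molecule = 1e-23 J/molecule). Negative
values indicate favourable lipid-lipid interaction.

All uncertainty propagation is first order (delta method) with independent
errors.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegeneracyError, FormatError, RangeError, TerpordError

logger = logging.getLogger(__name__)

#: 1 (mN/m)·(Å²/molecule) = 1e-3 N/m · 1e-20 m² = 1e-23 J/molecule
AVOGADRO = 6.02214076e23
MNM_A2_TO_J_PER_MOL = 1e-23 * AVOGADRO  # = 6.02214076 J/mol

GAS_CONSTANT = 8.314462618  # J/(mol K)

DEFAULT_DG_TARGETS = (5.0, 10.0, 15.0, 20.0, 25.0)
DEFAULT_FIT_WINDOW = (10.0, 30.0)

PRESSURE_COLUMN = "pressure_mN_per_m"
AREA_COLUMN = "area_A2_per_molecule"


@dataclass(frozen=True)
class MixtureSpec:
    """Component identities and mole fractions of a film or bilayer."""

    components: tuple[str, ...]
    fractions: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.components) not in (1, 2):
            raise TerpordError("a film has one or two components")
        if len(self.components) != len(self.fractions):
            raise TerpordError("one mole fraction per component")
        fr = np.asarray(self.fractions, dtype=float)
        if np.any(fr <= 0) or np.any(fr > 1):
            raise TerpordError(f"mole fractions must lie in (0, 1]: {self.fractions}")
        if abs(fr.sum() - 1.0) > 1e-9:
            raise TerpordError(f"mole fractions must sum to 1: {self.fractions}")

    @property
    def x1(self) -> float:
        return self.fractions[0]

    @property
    def x2(self) -> float:
        return self.fractions[1] if len(self.fractions) > 1 else 0.0

    def label(self) -> str:
        return "+".join(
            f"{c}({x:g})" for c, x in zip(self.components, self.fractions)
        )


@dataclass
class Isotherm:
    """One film's pressure-area curve, sorted by increasing pressure.

    ``area_sd`` is per-point standard deviation (zeros for a single
    replicate, populated by :func:`mean_isotherm`).
    """

    pressures: np.ndarray  # mN/m, strictly increasing
    areas: np.ndarray  # Å²/molecule
    replicate_id: str = ""
    composition: MixtureSpec | None = None
    temperature: float = 20.0  # °C
    area_sd: np.ndarray | None = None
    n_replicates: int = 1

    def __post_init__(self) -> None:
        self.pressures = np.asarray(self.pressures, dtype=float)
        self.areas = np.asarray(self.areas, dtype=float)
        if self.pressures.ndim != 1 or self.pressures.shape != self.areas.shape:
            raise TerpordError("pressures and areas must be 1-d and equal length")
        if len(self.pressures) < 3:
            raise TerpordError(
                f"isotherm needs at least 3 points, got {len(self.pressures)}"
            )
        if np.any(np.diff(self.pressures) <= 0):
            raise TerpordError("pressures must be strictly increasing")
        if np.any(self.areas <= 0):
            raise TerpordError("areas must be strictly positive")
        if self.area_sd is None:
            self.area_sd = np.zeros_like(self.areas)
        else:
            self.area_sd = np.asarray(self.area_sd, dtype=float)
            if self.area_sd.shape != self.areas.shape:
                raise TerpordError("area_sd must match areas in length")
            if np.any(self.area_sd < 0):
                raise TerpordError("area_sd must be non-negative")
        if np.any(np.diff(self.areas) > 0):
            warnings.warn(
                f"isotherm {self.replicate_id or '<unnamed>'}: area is not "
                "monotone non-increasing with pressure (noise?)",
                stacklevel=2,
            )

    def __len__(self) -> int:
        return len(self.pressures)

    @property
    def pressure_range(self) -> tuple[float, float]:
        return float(self.pressures[0]), float(self.pressures[-1])


@dataclass(frozen=True)
class MeasuredArea:
    """A mean molecular area at one surface pressure, with uncertainty."""

    value: float  # Å²/molecule
    sd: float  # Å²/molecule
    pressure: float  # mN/m
    n_replicates: int = 1

    def __post_init__(self) -> None:
        if not self.value > 0:
            raise TerpordError(f"area must be positive, got {self.value}")
        if self.sd < 0:
            raise TerpordError("sd must be non-negative")


@dataclass(frozen=True)
class CondensationResult:
    """Percent condensation of a binary film relative to ideal mixing."""

    c: float  # percent
    sd: float  # percent
    pressure: float  # mN/m
    mixture: MixtureSpec


@dataclass(frozen=True)
class MixingFreeEnergy:
    """Excess free energy of mixing at a set of target pressures."""

    target_pressures: tuple[float, ...]  # mN/m
    values: tuple[float, ...]  # J/mol
    sds: tuple[float, ...]  # J/mol
    includes_ideal_term: bool = False
    lower_bound: float = float("nan")  # mN/m, integration lower limit


@dataclass(frozen=True)
class IsothermFitCoefficients:
    """OLS line A = β₀ + β₁Π over a pressure window."""

    coefficients: tuple[float, float]  # (intercept Å², slope Å²·m/mN)
    fit_window: tuple[float, float]  # mN/m
    r_squared: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise TerpordError(f"R² out of [0,1]: {self.r_squared}")


@dataclass(frozen=True)
class ManovaResult:
    statistic_name: str
    statistic_value: float
    F: float
    p: float
    df: tuple[float, float]  # (numerator, denominator)


# ---------------------------------------------------------------------------
# I/O


def read_isotherm(
    path: str | Path,
    *,
    sep: str = ",",
    composition: MixtureSpec | None = None,
    temperature: float = 20.0,
) -> Isotherm:
    """Read a delimited isotherm table into an :class:`Isotherm`.

    The header must contain a pressure column and an area column (any
    header containing ``pressure`` / ``area``, case-insensitive; the
    canonical names are ``pressure_mN_per_m`` and ``area_A2_per_molecule``).
    Rows sharing a pressure are averaged with a warning; rows are sorted by
    pressure.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=sep, comment="#")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"{path}: cannot parse delimited table: {exc}") from exc

    pcol = _find_column(df, "pressure", path)
    acol = _find_column(df, "area", path)

    for col in (pcol, acol):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise FormatError(
                f"{path}: non-numeric value in column {col!r} at data row "
                f"{int(bad[0]) + 1}: {df.loc[bad[0], col]!r}"
            )
        df[col] = coerced
    df = df.dropna(subset=[pcol, acol])
    if len(df) < 3:
        raise FormatError(f"{path}: need at least 3 numeric rows, got {len(df)}")

    if df[pcol].duplicated().any():
        warnings.warn(f"{path}: duplicated pressures averaged", stacklevel=2)
        df = df.groupby(pcol, as_index=False)[[acol]].mean()
    df = df.sort_values(pcol)

    return Isotherm(
        pressures=df[pcol].to_numpy(),
        areas=df[acol].to_numpy(),
        replicate_id=path.stem,
        composition=composition,
        temperature=temperature,
    )


def _find_column(df: pd.DataFrame, keyword: str, path: Path) -> str:
    matches = [c for c in df.columns if keyword in str(c).lower()]
    if not matches:
        raise FormatError(
            f"{path}: no column matching {keyword!r} in header {list(df.columns)}"
        )
    return matches[0]


def write_isotherm(iso: Isotherm, path: str | Path) -> None:
    """Write an isotherm as the canonical two-column CSV."""
    pd.DataFrame(
        {PRESSURE_COLUMN: iso.pressures, AREA_COLUMN: iso.areas}
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Replicate averaging and MMA extraction


def mean_isotherm(replicates: Sequence[Isotherm]) -> Isotherm:
    """Pointwise mean ± sd of replicate isotherms on a common grid.

    Replicates are interpolated linearly onto the pressure grid of the
    first replicate, restricted to the pressure range common to all.
    """
    if len(replicates) < 2:
        raise TerpordError("need at least 2 replicates to average")
    comps = {r.composition for r in replicates}
    if len(comps) > 1:
        raise TerpordError(f"replicates have mixed compositions: {comps}")
    lo = max(r.pressures[0] for r in replicates)
    hi = min(r.pressures[-1] for r in replicates)
    if lo >= hi:
        raise TerpordError("replicate pressure ranges are disjoint")
    first = replicates[0]
    grid = first.pressures[(first.pressures >= lo) & (first.pressures <= hi)]
    if len(grid) < 3:
        raise TerpordError("fewer than 3 grid points in the common pressure range")
    stack = np.vstack([np.interp(grid, r.pressures, r.areas) for r in replicates])
    return Isotherm(
        pressures=grid,
        areas=stack.mean(axis=0),
        area_sd=stack.std(axis=0, ddof=1),
        replicate_id="mean",
        composition=first.composition,
        temperature=first.temperature,
        n_replicates=len(replicates),
    )


def mma_at_pressure(
    iso: Isotherm, pressure: float, *, round_down: bool = False
) -> MeasuredArea:
    """Mean molecular area at a surface pressure, by linear interpolation.

    With ``round_down=True`` the query snaps to the nearest recorded
    pressure at or below the target instead of interpolating.
    """
    lo, hi = iso.pressure_range
    if not (lo <= pressure <= hi):
        raise RangeError(
            f"pressure {pressure} mN/m outside recorded range [{lo}, {hi}]; "
            "extrapolation refused"
        )
    if round_down:
        idx = int(np.searchsorted(iso.pressures, pressure, side="right") - 1)
        return MeasuredArea(
            value=float(iso.areas[idx]),
            sd=float(iso.area_sd[idx]),
            pressure=float(iso.pressures[idx]),
            n_replicates=iso.n_replicates,
        )
    value = float(np.interp(pressure, iso.pressures, iso.areas))
    sd = float(np.interp(pressure, iso.pressures, iso.area_sd))
    return MeasuredArea(
        value=value, sd=sd, pressure=float(pressure), n_replicates=iso.n_replicates
    )


# ---------------------------------------------------------------------------
# Condensation effect (ideal mixing rule + percent deviation)


def ideal_mixing_area(
    a1: MeasuredArea, a2: MeasuredArea, mix: MixtureSpec
) -> MeasuredArea:
    """Ideal-mixing MMA X₁A₁ + X₂A₂ with first-order error propagation."""
    if abs(a1.pressure - a2.pressure) > 1e-9:
        raise TerpordError(
            f"component areas at different pressures: {a1.pressure} vs {a2.pressure}"
        )
    x1, x2 = mix.x1, mix.x2
    value = x1 * a1.value + x2 * a2.value
    sd = float(np.hypot(x1 * a1.sd, x2 * a2.sd))
    return MeasuredArea(
        value=value,
        sd=sd,
        pressure=a1.pressure,
        n_replicates=min(a1.n_replicates, a2.n_replicates),
    )


def condensation_effect(
    a0: MeasuredArea, a1: MeasuredArea, a2: MeasuredArea, mix: MixtureSpec
) -> CondensationResult:
    """Percent condensation c = 100·(1 − A₀/(X₁A₁+X₂A₂)).

    c > 0: the mixed film packs tighter than ideal (condensation);
    c < 0: expansion. Uncertainty by the delta method over A₀, A₁, A₂.
    """
    if not (abs(a0.pressure - a1.pressure) < 1e-9 and abs(a0.pressure - a2.pressure) < 1e-9):
        raise TerpordError("all three areas must be taken at the same pressure")
    x1, x2 = mix.x1, mix.x2
    denom = x1 * a1.value + x2 * a2.value
    if denom <= 0:
        raise TerpordError(f"ideal area must be positive, got {denom}")
    c = 100.0 * (1.0 - a0.value / denom)
    # dc/dA0 = -100/D ; dc/dAi = 100 A0 Xi / D²
    dc_da0 = -100.0 / denom
    dc_da1 = 100.0 * a0.value * x1 / denom**2
    dc_da2 = 100.0 * a0.value * x2 / denom**2
    sd = float(
        np.sqrt((dc_da0 * a0.sd) ** 2 + (dc_da1 * a1.sd) ** 2 + (dc_da2 * a2.sd) ** 2)
    )
    return CondensationResult(c=float(c), sd=sd, pressure=a0.pressure, mixture=mix)


# ---------------------------------------------------------------------------
# Excess area and excess free energy of mixing


def excess_area_curve(
    mix_iso: Isotherm,
    pure1: Isotherm,
    pure2: Isotherm,
    mix: MixtureSpec,
    grid: Sequence[float],
) -> pd.DataFrame:
    """Excess area ΔA(Π) = A_mix − (X₁A₁ + X₂A₂) on a pressure grid.

    Returns a DataFrame with columns ``pressure``, ``excess_area``, ``sd``.
    """
    grid = np.asarray(grid, dtype=float)
    for iso, name in ((mix_iso, "mixture"), (pure1, "pure1"), (pure2, "pure2")):
        lo, hi = iso.pressure_range
        out = grid[(grid < lo) | (grid > hi)]
        if len(out):
            raise RangeError(
                f"grid points {out.tolist()} outside the {name} isotherm "
                f"range [{lo}, {hi}]"
            )
    rows = []
    for p in grid:
        am = mma_at_pressure(mix_iso, p)
        ideal = ideal_mixing_area(
            mma_at_pressure(pure1, p), mma_at_pressure(pure2, p), mix
        )
        rows.append(
            (p, am.value - ideal.value, float(np.hypot(am.sd, ideal.sd)))
        )
    return pd.DataFrame(rows, columns=["pressure", "excess_area", "sd"])


def _trapezoid_weights(p: np.ndarray) -> np.ndarray:
    """Weights w such that trapz(y, p) = w · y."""
    w = np.zeros_like(p)
    dp = np.diff(p)
    w[:-1] += dp / 2.0
    w[1:] += dp / 2.0
    return w


def excess_free_energy(
    excess: pd.DataFrame,
    targets: Sequence[float] = DEFAULT_DG_TARGETS,
    *,
    include_ideal: bool = False,
    mix: MixtureSpec | None = None,
    temperature: float = 20.0,
) -> MixingFreeEnergy:
    """ΔG_exc(Π*) by trapezoidal integration of the excess-area table.

    Integration runs from the lowest tabulated pressure of ``excess`` up to
    each target; no extrapolation below the table. With ``include_ideal``
    the ideal entropy of mixing RT(X₁lnX₁ + X₂lnX₂) is added (requires
    ``mix``; ``temperature`` in °C).
    """
    p = excess["pressure"].to_numpy(dtype=float)
    da = excess["excess_area"].to_numpy(dtype=float)
    sd = excess["sd"].to_numpy(dtype=float) if "sd" in excess else np.zeros_like(da)
    order = np.argsort(p)
    p, da, sd = p[order], da[order], sd[order]
    lower = float(p[0])

    ideal_term = 0.0
    if include_ideal:
        if mix is None or len(mix.fractions) != 2:
            raise TerpordError("include_ideal requires a binary MixtureSpec")
        t_kelvin = temperature + 273.15
        ideal_term = GAS_CONSTANT * t_kelvin * (
            mix.x1 * np.log(mix.x1) + mix.x2 * np.log(mix.x2)
        )

    values, sds = [], []
    for target in targets:
        if target < lower - 1e-12:
            raise RangeError(
                f"target pressure {target} mN/m below the lowest tabulated "
                f"pressure {lower}"
            )
        if target > p[-1] + 1e-12:
            raise RangeError(
                f"target pressure {target} mN/m above the highest tabulated "
                f"pressure {p[-1]}"
            )
        # clip the table at the target, interpolating the end point
        mask = p <= target + 1e-12
        pp = p[mask]
        yy = da[mask]
        ss = sd[mask]
        if pp[-1] < target - 1e-12:
            yy = np.append(yy, np.interp(target, p, da))
            ss = np.append(ss, np.interp(target, p, sd))
            pp = np.append(pp, target)
        w = _trapezoid_weights(pp)
        integral = float(w @ yy)  # mN/m · Å²/molecule
        sigma = float(np.sqrt(np.sum((w * ss) ** 2)))
        values.append(integral * MNM_A2_TO_J_PER_MOL + ideal_term)
        sds.append(sigma * MNM_A2_TO_J_PER_MOL)
    return MixingFreeEnergy(
        target_pressures=tuple(float(t) for t in targets),
        values=tuple(values),
        sds=tuple(sds),
        includes_ideal_term=include_ideal,
        lower_bound=lower,
    )


# ---------------------------------------------------------------------------
# Regression + MANOVA group comparison


def fit_isotherm_regression(
    iso: Isotherm, window: tuple[float, float] = DEFAULT_FIT_WINDOW
) -> IsothermFitCoefficients:
    """OLS line A = β₀ + β₁Π over a pressure window."""
    lo, hi = window
    mask = (iso.pressures >= lo) & (iso.pressures <= hi)
    if mask.sum() < 3:
        raise TerpordError(
            f"need at least 3 points in window [{lo}, {hi}], got {int(mask.sum())}"
        )
    x = iso.pressures[mask]
    y = iso.areas[mask]
    res = stats.linregress(x, y)
    # guard against the degenerate flat case where rvalue is nan
    r2 = 0.0 if np.isnan(res.rvalue) else float(res.rvalue**2)
    return IsothermFitCoefficients(
        coefficients=(float(res.intercept), float(res.slope)),
        fit_window=(float(lo), float(hi)),
        r_squared=r2,
    )


def manova_isotherm_groups(
    groups: Mapping[str, Sequence[IsothermFitCoefficients]],
    *,
    statistic: str = "pillai",
) -> ManovaResult:
    """One-way MANOVA on the (intercept, slope) coefficient vectors.

    ``statistic`` selects Pillai's trace (default) or Wilks' lambda.
    """
    from statsmodels.multivariate.manova import MANOVA

    if len(groups) < 2:
        raise TerpordError("MANOVA needs at least 2 groups")
    rows = []
    for label, fits in groups.items():
        if len(fits) < 2:
            raise TerpordError(f"group {label!r} needs at least 2 replicates")
        for f in fits:
            rows.append({"group": label, "b0": f.coefficients[0], "b1": f.coefficients[1]})
    df = pd.DataFrame(rows)
    if (df.groupby("group")[["b0", "b1"]].std(ddof=1) < 1e-14).all(axis=None):
        raise DegeneracyError(
            "within-group covariance is singular (identical replicates)"
        )
    try:
        mv = MANOVA.from_formula("b0 + b1 ~ group", data=df)
        table = mv.mv_test().results["group"]["stat"]
    except np.linalg.LinAlgError as exc:
        raise DegeneracyError(f"MANOVA failed on singular covariance: {exc}") from exc
    name = {"pillai": "Pillai's trace", "wilks": "Wilks' lambda"}.get(statistic)
    if name is None:
        raise TerpordError(f"unknown MANOVA statistic {statistic!r}")
    row = table.loc[name]
    return ManovaResult(
        statistic_name=name,
        statistic_value=float(row["Value"]),
        F=float(row["F Value"]),
        p=float(row["Pr > F"]),
        df=(float(row["Num DF"]), float(row["Den DF"])),
    )
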