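"""Cellular assay reductions: growth rate from phenol-red OD curves,
lysis fraction from anchored propidium-iodide fluorescence, and one-way
ANOVA with Tukey's post hoc test for group comparison.

Phenol-red media acidify as a culture grows, so absorbance at 562 nm falls
with time; the growth rate is the negative of the OLS slope of OD on time
within the dye's indicative range (OD562 0.75 down to 0.4 by default).

The hypoosmotic-lysis readout normalizes each well's fluorescence to two
anchors on the same plate: the 0 % wash-buffer well (pure water, full
lysis) and the 100 % wash-buffer well (isotonic, intact cells):

    f = (F_q − F_intact) / (F_lysed − F_intact)

clamped to [0, 1]; replicates are averaged after normalization.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegeneracyError, FormatError, TerpordError

DEFAULT_OD_WINDOW = (0.4, 0.75)
DEFAULT_QUERY_FRACTION = 80.0  # % wash buffer


@dataclass
class GrowthCurve:
    """A phenol-red growth trace: time (h) vs. OD562 (10 mm path)."""

    times: np.ndarray  # hours, strictly increasing
    od562: np.ndarray  # absorbance, >= 0
    diet: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od562 = np.asarray(self.od562, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.od562.shape:
            raise TerpordError("times and od562 must be 1-d and equal length")
        if np.any(np.diff(self.times) <= 0):
            raise TerpordError("times must be strictly increasing")
        if np.any(self.od562 < 0):
            raise TerpordError("od562 must be non-negative")


@dataclass
class LysisSeries:
    """One replicate's propidium-iodide wells over wash-buffer dilutions."""

    buffer_fractions: np.ndarray  # % wash buffer, 0-100
    fluorescence: np.ndarray  # arbitrary units
    replicate_id: str = ""

    def __post_init__(self) -> None:
        self.buffer_fractions = np.asarray(self.buffer_fractions, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.buffer_fractions.shape != self.fluorescence.shape:
            raise TerpordError("buffer_fractions and fluorescence must match")
        for anchor in (0.0, 100.0):
            if not np.any(np.isclose(self.buffer_fractions, anchor)):
                raise TerpordError(
                    f"series {self.replicate_id!r} lacks the {anchor:g}% anchor well"
                )

    def at(self, pct: float) -> float:
        mask = np.isclose(self.buffer_fractions, pct)
        if not mask.any():
            raise TerpordError(
                f"buffer fraction {pct:g}% not measured in {self.replicate_id!r}"
            )
        return float(self.fluorescence[mask].mean())


@dataclass(frozen=True)
class GrowthRateResult:
    rate: float  # 1/h, negative of the fitted OD slope
    stderr: float
    r_squared: float
    n_points: int
    window: tuple[float, float]


@dataclass(frozen=True)
class LysisResult:
    fraction: float  # clamped to [0, 1]
    raw_fraction: float  # unclamped mean of per-replicate fractions
    query_fraction: float  # % wash buffer
    n_replicates: int


@dataclass(frozen=True)
class AnovaResult:
    F: float
    p: float
    pairwise: pd.DataFrame  # columns: group1, group2, diff, p_adj


# ---------------------------------------------------------------------------
# I/O


def read_growth_curve(path: str | Path, *, sep: str = ",") -> GrowthCurve:
    """Read a ``time_h,od562`` table."""
    path = Path(path)
    df = pd.read_csv(path, sep=sep, comment="#")
    cols = {c.lower(): c for c in df.columns}
    tcol = next((cols[c] for c in cols if "time" in c), None)
    ocol = next((cols[c] for c in cols if "od" in c), None)
    if tcol is None or ocol is None:
        raise FormatError(f"{path}: need time and OD columns, got {list(df.columns)}")
    df = df.sort_values(tcol)
    return GrowthCurve(
        times=pd.to_numeric(df[tcol]).to_numpy(),
        od562=pd.to_numeric(df[ocol]).to_numpy(),
        diet=path.stem,
    )


def read_lysis_series(path: str | Path, *, sep: str = ",") -> list[LysisSeries]:
    """Read a ``buffer_pct,fluorescence[,replicate]`` table into replicates."""
    path = Path(path)
    df = pd.read_csv(path, sep=sep, comment="#")
    cols = {c.lower(): c for c in df.columns}
    bcol = next((cols[c] for c in cols if "buffer" in c), None)
    fcol = next((cols[c] for c in cols if "fluor" in c), None)
    if bcol is None or fcol is None:
        raise FormatError(
            f"{path}: need buffer and fluorescence columns, got {list(df.columns)}"
        )
    rcol = next((cols[c] for c in cols if "replicate" in c), None)
    if rcol is None:
        df = df.assign(_rep="rep1")
        rcol = "_rep"
    out = []
    for rep, sub in df.groupby(rcol, sort=True):
        out.append(
            LysisSeries(
                buffer_fractions=pd.to_numeric(sub[bcol]).to_numpy(),
                fluorescence=pd.to_numeric(sub[fcol]).to_numpy(),
                replicate_id=str(rep),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Reductions


def growth_rate(
    curve: GrowthCurve, window: tuple[float, float] = DEFAULT_OD_WINDOW
) -> GrowthRateResult:
    """Growth rate = −(OLS slope of OD562 on time) over the OD window.

    Window membership is the closed interval on measured OD values.
    """
    lo, hi = min(window), max(window)
    mask = (curve.od562 >= lo) & (curve.od562 <= hi)
    if mask.sum() < 3:
        raise TerpordError(
            f"need at least 3 points with OD in [{lo}, {hi}], got {int(mask.sum())}"
        )
    res = stats.linregress(curve.times[mask], curve.od562[mask])
    r2 = 0.0 if np.isnan(res.rvalue) else float(res.rvalue**2)
    return GrowthRateResult(
        rate=float(-res.slope),
        stderr=float(res.stderr) if np.isfinite(res.stderr) else 0.0,
        r_squared=r2,
        n_points=int(mask.sum()),
        window=(lo, hi),
    )


def lysis_fraction(
    series: LysisSeries | Sequence[LysisSeries],
    query_fraction: float = DEFAULT_QUERY_FRACTION,
) -> LysisResult:
    """Fraction of cells lysed at a wash-buffer dilution.

    Each replicate is normalized to its own anchors — 0 % buffer (fully
    lysed) and 100 % buffer (intact) — then the normalized fractions are
    averaged and clamped to [0, 1].
    """
    reps = [series] if isinstance(series, LysisSeries) else list(series)
    if not reps:
        raise TerpordError("no lysis series given")
    fractions = []
    for rep in reps:
        f_lysed = rep.at(0.0)
        f_intact = rep.at(100.0)
        if abs(f_lysed - f_intact) < 1e-12:
            raise DegeneracyError(
                f"series {rep.replicate_id!r}: anchor wells are equal"
            )
        f_q = rep.at(query_fraction)
        fractions.append((f_q - f_intact) / (f_lysed - f_intact))
    raw = float(np.mean(fractions))
    return LysisResult(
        fraction=float(np.clip(raw, 0.0, 1.0)),
        raw_fraction=raw,
        query_fraction=float(query_fraction),
        n_replicates=len(reps),
    )


def anova_tukey(groups: Mapping[str, Sequence[float]]) -> AnovaResult:
    """One-way ANOVA omnibus F/p plus Tukey HSD adjusted pairwise p-values."""
    if len(groups) < 2:
        raise TerpordError("ANOVA needs at least 2 groups")
    labels = list(groups)
    samples = []
    for label in labels:
        vals = np.asarray(groups[label], dtype=float)
        if len(vals) < 2:
            raise TerpordError(f"group {label!r} needs at least 2 values")
        samples.append(vals)
    F, p = stats.f_oneway(*samples)
    tk = stats.tukey_hsd(*samples)
    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            rows.append(
                {
                    "group1": labels[i],
                    "group2": labels[j],
                    "diff": float(samples[i].mean() - samples[j].mean()),
                    "p_adj": float(tk.pvalue[i, j]),
                }
            )
    return AnovaResult(F=float(F), p=float(p), pairwise=pd.DataFrame(rows))
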