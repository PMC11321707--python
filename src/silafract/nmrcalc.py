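"""NMR-derived observables for peptide self-assembly and silicification.

Covers chemical shift perturbations (CSP) between correlation spectra,
intensity ratios and residual dissolved fractions, per-residue exponential
decay rates from real-time silicification traces with surface/core
classification, transverse relaxation rates, and DOSY diffusion fitting with
Stokes-Einstein conversion to hydrodynamic radii.

All fits are deterministic given the data: initial values come from
closed-form linearizations plus a fixed multistart grid, never from random
initialization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from lmfit import Model

from .structio import read_table, write_table

__all__ = [
    "PeakTable",
    "DosySeries",
    "KineticTraces",
    "RateResult",
    "DosyFit",
    "GAMMA_1H",
    "BOLTZMANN_J_PER_K",
    "WATER_VISCOSITY_25C",
    "CSP_WEIGHTS",
    "chemical_shift_perturbation",
    "intensity_ratio",
    "residual_fraction",
    "fit_exponential_decay",
    "classify_residue_kinetics",
    "fit_stejskal_tanner",
    "stokes_einstein_radius",
    "fit_relaxation_rate",
]

GAMMA_1H = 2.6752218744e8  # rad s^-1 T^-1
BOLTZMANN_J_PER_K = 1.380649e-23
WATER_VISCOSITY_25C = 8.937e-4  # Pa s at 298.15 K

#: per-nucleus-pair weights (w_a, w_b) for the weighted-Euclidean CSP
CSP_WEIGHTS: dict[str, tuple[float, float]] = {
    "H-N": (1.0, 0.14),
    "C-N": (0.30, 0.14),
    "H-P": (1.0, 0.14),
}


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class PeakTable:
    """Per-residue peak list: two chemical shifts (ppm) and an intensity.

    ``nucleus_pair`` tags which correlation the two shift columns belong to
    (``H-N``, ``C-N`` or ``H-P``); it selects the CSP weighting.
    """

    df: pd.DataFrame
    nucleus_pair: str = "H-N"

    def __post_init__(self) -> None:
        required = {"resid", "resname", "shift_a", "shift_b", "intensity"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"peak table missing columns {sorted(missing)}")
        if self.df["resid"].duplicated().any():
            raise ValueError("residue indices must be unique")
        if (self.df["intensity"] < 0).any():
            raise ValueError("intensities must be non-negative")
        if self.nucleus_pair not in CSP_WEIGHTS:
            raise ValueError(f"unknown nucleus pair {self.nucleus_pair!r}")
        self.df = self.df.reset_index(drop=True)

    @classmethod
    def from_csv(cls, path: str | Path, nucleus_pair: str = "H-N") -> "PeakTable":
        return cls(read_table(path, "peaks"), nucleus_pair=nucleus_pair)

    def to_csv(self, path: str | Path) -> Path:
        return write_table(self.df, path, "peaks")

    def indexed(self) -> pd.DataFrame:
        return self.df.set_index("resid")


@dataclass
class DosySeries:
    """Pulsed-field-gradient decay: integrals vs gradient strength.

    gradient in T/m (strictly increasing, >= 5 points), delta = gradient
    pulse length (s), big_delta = diffusion delay (s), gamma in rad/s/T.
    Temperature (K) and viscosity (Pa s) ride along for the Stokes-Einstein
    step.
    """

    gradient: np.ndarray
    integral: np.ndarray
    delta: float
    big_delta: float
    gamma: float = GAMMA_1H
    temperature: float = 298.15
    viscosity: float = WATER_VISCOSITY_25C

    def __post_init__(self) -> None:
        self.gradient = np.asarray(self.gradient, dtype=float)
        self.integral = np.asarray(self.integral, dtype=float)
        if len(self.gradient) != len(self.integral):
            raise ValueError("gradient and integral lengths differ")
        if len(self.gradient) < 5:
            raise ValueError("DOSY series needs at least 5 points")
        if np.any(self.gradient < 0) or np.any(np.diff(self.gradient) <= 0):
            raise ValueError("gradients must be non-negative and strictly increasing")
        if not 0 < self.delta < self.big_delta:
            raise ValueError("need 0 < delta < big_delta")

    def b_values(self) -> np.ndarray:
        """Stejskal-Tanner b factors: γ² g² δ² (Δ − δ/3), in s/m²."""
        return (
            self.gamma**2
            * self.gradient**2
            * self.delta**2
            * (self.big_delta - self.delta / 3.0)
        )

    @classmethod
    def from_csv(cls, path: str | Path, delta: float, big_delta: float, **kw) -> "DosySeries":
        df = read_table(path, "dosy")
        return cls(
            gradient=df["gradient"].to_numpy(),
            integral=df["integral"].to_numpy(),
            delta=delta,
            big_delta=big_delta,
            **kw,
        )

    def to_csv(self, path: str | Path) -> Path:
        return write_table(
            pd.DataFrame({"gradient": self.gradient, "integral": self.integral}),
            path,
            "dosy",
        )


@dataclass
class KineticTraces:
    """Real-time silicification traces: time grid x per-residue intensities."""

    time: np.ndarray
    intensities: np.ndarray  # (n_residues, n_times)
    resids: np.ndarray
    resnames: np.ndarray | None = None
    surface_flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        self.resids = np.asarray(self.resids, dtype=int)
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if self.intensities.shape != (len(self.resids), len(self.time)):
            raise ValueError("intensities must be (n_residues, n_times)")

    @classmethod
    def from_csv(cls, path: str | Path, normalize: bool = True) -> "KineticTraces":
        df = read_table(path, "kinetics")
        pivot = df.pivot_table(index="resid", columns="time", values="intensity")
        pivot = pivot.sort_index().sort_index(axis=1)
        mat = pivot.to_numpy()
        if normalize:
            mat = mat / mat[:, :1]
        return cls(
            time=pivot.columns.to_numpy(dtype=float),
            intensities=mat,
            resids=pivot.index.to_numpy(dtype=int),
        )

    def to_csv(self, path: str | Path) -> Path:
        long = pd.DataFrame(
            {
                "time": np.tile(self.time, len(self.resids)),
                "resid": np.repeat(self.resids, len(self.time)),
                "intensity": self.intensities.ravel(),
            }
        )
        return write_table(long, path, "kinetics")


@dataclass
class RateResult:
    """One fitted exponential decay: I(t) = A exp(-k t) + B."""

    resid: int | None
    k: float
    plateau: float
    k_stderr: float = float("nan")
    plateau_stderr: float = float("nan")
    converged: bool = True
    classification: str | None = None
    message: str = ""


@dataclass
class DosyFit:
    """Stejskal-Tanner fit result."""

    D: float  # m²/s
    I0: float
    D_stderr: float = float("nan")
    I0_stderr: float = float("nan")
    converged: bool = True
    message: str = ""


# ---------------------------------------------------------------------------
# CSP / intensity observables
# ---------------------------------------------------------------------------

def _matched(reference: PeakTable, perturbed: PeakTable) -> pd.DataFrame:
    a = reference.indexed()
    b = perturbed.indexed()
    return a.join(b, how="outer", lsuffix="_ref", rsuffix="_pert")


def chemical_shift_perturbation(
    reference: PeakTable,
    perturbed: PeakTable,
    weights: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Weighted-Euclidean CSP per residue (ppm).

    CSP_r = sqrt((w_a Δδ_a)² + (w_b Δδ_b)²) with the weights selected by the
    tables' nucleus pair (H-N: 1/0.14; C-N: 0.30/0.14) unless overridden.
    Residues present in only one table are kept with ``absent=True`` and a
    NaN CSP rather than a zero.
    """
    if reference.nucleus_pair != perturbed.nucleus_pair:
        raise ValueError(
            f"nucleus pair mismatch: {reference.nucleus_pair!r} vs {perturbed.nucleus_pair!r}"
        )
    w_a, w_b = weights if weights is not None else CSP_WEIGHTS[reference.nucleus_pair]
    j = _matched(reference, perturbed)
    da = j["shift_a_pert"] - j["shift_a_ref"]
    db = j["shift_b_pert"] - j["shift_b_ref"]
    csp = np.sqrt((w_a * da) ** 2 + (w_b * db) ** 2)
    out = pd.DataFrame(
        {
            "resid": j.index,
            "resname": j["resname_ref"].fillna(j["resname_pert"]),
            "csp": csp.to_numpy(),
            "absent": (j["shift_a_ref"].isna() | j["shift_a_pert"].isna()).to_numpy(),
        }
    ).reset_index(drop=True)
    return out


def intensity_ratio(
    reference: PeakTable,
    perturbed: PeakTable,
    detection_floor: float | None = None,
) -> pd.DataFrame:
    """Per-residue I/I0 between perturbed (I) and reference (I0) tables.

    Residues whose perturbed intensity falls below ``detection_floor`` are
    reported with ``below_detection=True`` and a NaN ratio; I0 = 0 yields an
    ``undefined`` flag.
    """
    j = _matched(reference, perturbed)
    i0 = j["intensity_ref"]
    i1 = j["intensity_pert"]
    ratio = i1 / i0.replace(0.0, np.nan)
    undefined = (i0 == 0.0).fillna(False)
    below = pd.Series(False, index=j.index)
    if detection_floor is not None:
        below = (i1 < detection_floor).fillna(False)
    ratio = ratio.where(~below)
    out = pd.DataFrame(
        {
            "resid": j.index,
            "ratio": ratio.to_numpy(),
            "absent": (i0.isna() | i1.isna()).to_numpy(),
            "below_detection": below.to_numpy(),
            "undefined": undefined.to_numpy(),
        }
    ).reset_index(drop=True)
    return out


def residual_fraction(
    reference: PeakTable,
    perturbed: PeakTable,
    detection_floor: float | None = None,
) -> float:
    """Overall dissolved fraction: arithmetic mean of detected I/I0 ratios."""
    ratios = intensity_ratio(reference, perturbed, detection_floor=detection_floor)
    valid = ratios["ratio"].dropna()
    if valid.empty:
        raise ValueError("no matched, detected residues to average")
    return float(valid.mean())


# ---------------------------------------------------------------------------
# exponential decay fitting
# ---------------------------------------------------------------------------

def _exp_plateau(t: np.ndarray, amplitude: float, rate: float, plateau: float) -> np.ndarray:
    return amplitude * np.exp(-rate * t) + plateau


def fit_exponential_decay(
    time: np.ndarray,
    trace: np.ndarray,
    model: str = "plateau",
    resid: int | None = None,
) -> RateResult:
    """Nonlinear least-squares fit of I(t) = A exp(-k t) + B.

    ``model="no-plateau"`` fixes B = 0.  Initialization uses a log-linear
    estimate plus a fixed multistart grid over the rate; the fit is
    deterministic.  Non-convergence is reported on the result, not raised.
    """
    t = np.asarray(time, dtype=float)
    y = np.asarray(trace, dtype=float)
    if len(t) < 5:
        raise ValueError("need at least 5 time points")
    if model not in ("plateau", "no-plateau"):
        raise ValueError("model must be 'plateau' or 'no-plateau'")
    scale = max(abs(float(np.max(y))), abs(float(np.min(y))), 1e-30)
    if np.ptp(y) <= 1e-10 * scale:  # constant trace: zero decay rate
        b = float(y[0]) if model == "plateau" else 0.0
        return RateResult(resid=resid, k=0.0, plateau=b, k_stderr=0.0, plateau_stderr=0.0)

    b0 = float(np.min(y)) if model == "plateau" else 0.0
    amp0 = float(y[0] - b0)
    # log-linear rate estimate over the decaying part
    pos = (y - b0) > 0.05 * max(amp0, 1e-30)
    if pos.sum() >= 2:
        slope = np.polyfit(t[pos], np.log(y[pos] - b0 + 1e-30), 1)[0]
        k0 = max(-slope, 1e-12)
    else:
        k0 = 1.0 / (t[-1] - t[0] + 1e-30)

    m = Model(_exp_plateau)
    params = m.make_params(amplitude=amp0, rate=k0, plateau=b0)
    params["rate"].set(min=0.0)
    if model == "no-plateau":
        params["plateau"].set(value=0.0, vary=False)

    best = None
    for factor in (1.0, 0.3, 3.0, 0.1, 10.0):
        params["rate"].set(value=k0 * factor)
        try:
            res = m.fit(y, params, t=t)
        except Exception:  # pragma: no cover - lmfit failures become flags
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res
    if best is None or not best.success:
        return RateResult(
            resid=resid, k=float("nan"), plateau=float("nan"),
            converged=False, message="fit did not converge",
        )
    p = best.params
    return RateResult(
        resid=resid,
        k=float(p["rate"].value),
        plateau=float(p["plateau"].value),
        k_stderr=float(p["rate"].stderr) if p["rate"].stderr else float("nan"),
        plateau_stderr=float(p["plateau"].stderr) if p["plateau"].stderr else float("nan"),
    )


def fit_kinetic_traces(traces: KineticTraces, model: str = "plateau") -> list[RateResult]:
    """Fit every residue trace; failed fits are flagged, not raised."""
    return [
        fit_exponential_decay(traces.time, traces.intensities[i], model=model,
                              resid=int(traces.resids[i]))
        for i in range(len(traces.resids))
    ]


def classify_residue_kinetics(
    rates: Sequence[RateResult],
    mad_scale: float = 1.4826,
    stderr_guard: float = 3.0,
) -> list[RateResult]:
    """Label residues as surface / core / undetermined by their decay rates.

    Rule: with med the median rate over converged fits and
    band = max(``mad_scale`` x MAD, ``stderr_guard`` x median fit stderr),
    rates above med + band are *surface* (they empty fastest, sitting next
    to the silica nucleation sites), rates within med +- band are *core*,
    and rates below the band or from failed fits are *undetermined*.  The
    stderr guard keeps the band meaningful when most rates coincide and the
    raw MAD collapses to fit noise.
    """
    ok = [r for r in rates if r.converged and np.isfinite(r.k)]
    if not ok:
        raise ValueError("all fits failed; nothing to classify")
    if len(ok) < 3:
        raise ValueError("need at least 3 converged fits to classify")
    ks = np.asarray([r.k for r in ok])
    med = float(np.median(ks))
    mad = float(np.median(np.abs(ks - med)))
    se = np.asarray([r.k_stderr for r in ok])
    se_med = float(np.nanmedian(se)) if np.any(np.isfinite(se)) else 0.0
    band = max(mad_scale * mad, stderr_guard * se_med, 1e-30)
    out = []
    for r in rates:
        if not (r.converged and np.isfinite(r.k)):
            label = "undetermined"
        elif r.k > med + band:
            label = "surface"
        elif r.k >= med - band:
            label = "core"
        else:
            label = "undetermined"
        out.append(
            RateResult(
                resid=r.resid, k=r.k, plateau=r.plateau, k_stderr=r.k_stderr,
                plateau_stderr=r.plateau_stderr, converged=r.converged,
                classification=label, message=r.message,
            )
        )
    return out


def fit_relaxation_rate(delays: np.ndarray, intensities: np.ndarray) -> RateResult:
    """Mono-exponential transverse relaxation fit I(τ) = I0 exp(-R2 τ).

    Same engine as :func:`fit_exponential_decay` with the plateau fixed at
    zero; the returned ``k`` is R2 in the inverse units of ``delays``.
    """
    d = np.asarray(delays, dtype=float)
    if len(d) < 4:
        raise ValueError("need at least 4 relaxation delays")
    if len(d) == 4:  # the fitting engine wants 5+ points; pad is not allowed,
        # so fall back to the exact log-linear solution for 4 points
        y = np.asarray(intensities, dtype=float)
        if np.ptp(y) <= 1e-10 * max(abs(y).max(), 1e-30):
            return RateResult(resid=None, k=0.0, plateau=0.0, k_stderr=0.0)
        slope, _ = np.polyfit(d, np.log(np.clip(y, 1e-300, None)), 1)
        return RateResult(resid=None, k=float(max(-slope, 0.0)), plateau=0.0)
    return fit_exponential_decay(d, intensities, model="no-plateau")


# ---------------------------------------------------------------------------
# DOSY
# ---------------------------------------------------------------------------

def _st_decay(b: np.ndarray, I0: float, D: float) -> np.ndarray:
    return I0 * np.exp(-D * b)


def fit_stejskal_tanner(series: DosySeries) -> DosyFit:
    """Fit I(g) = I0 exp(-D γ² g² δ² (Δ - δ/3)) for the diffusion coefficient.

    A linearized ln(I) vs b slope seeds the nonlinear fit.  Constant data
    yield D = 0; systematically increasing data are flagged non-converged.
    """
    b = series.b_values()
    y = series.integral
    scale = max(abs(float(np.max(y))), 1e-30)
    if np.ptp(y) <= 1e-12 * scale:
        return DosyFit(D=0.0, I0=float(y[0]), D_stderr=0.0, I0_stderr=0.0)
    pos = y > 0
    if pos.sum() >= 3:
        slope, logi0 = np.polyfit(b[pos], np.log(y[pos]), 1)
    else:
        slope, logi0 = -1e-10, np.log(scale)
    if slope >= 0:
        return DosyFit(
            D=float("nan"), I0=float("nan"), converged=False,
            message="non-decaying data: no diffusion attenuation",
        )
    d0 = -slope
    m = Model(_st_decay)
    best = None
    for factor in (1.0, 0.3, 3.0):
        params = m.make_params(I0=np.exp(logi0), D=d0 * factor)
        params["D"].set(min=0.0)
        try:
            res = m.fit(y, params, b=b)
        except Exception:  # pragma: no cover
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res
    if best is None or not best.success:
        return DosyFit(D=float("nan"), I0=float("nan"), converged=False,
                       message="fit did not converge")
    p = best.params
    return DosyFit(
        D=float(p["D"].value),
        I0=float(p["I0"].value),
        D_stderr=float(p["D"].stderr) if p["D"].stderr else float("nan"),
        I0_stderr=float(p["I0"].stderr) if p["I0"].stderr else float("nan"),
    )


def stokes_einstein_radius(
    D: float,
    temperature: float = 298.15,
    viscosity: float = WATER_VISCOSITY_25C,
) -> float:
    """Hydrodynamic radius in nm from a diffusion coefficient in m²/s.

    Rh = k_B T / (6 π η D), the spherical Stokes-Einstein model.
    """
    if D <= 0 or temperature <= 0 or viscosity <= 0:
        raise ValueError("D, temperature and viscosity must be positive")
    rh_m = BOLTZMANN_J_PER_K * temperature / (6.0 * np.pi * viscosity * D)
    return float(rh_m * 1e9)


def dosy_to_radius(series: DosySeries) -> tuple[DosyFit, float]:
    """Convenience: fit the series and convert to Rh (nm) with its own T, η."""
    fit = fit_stejskal_tanner(series)
    if not fit.converged or not np.isfinite(fit.D) or fit.D <= 0:
        return fit, float("nan")
    return fit, stokes_einstein_radius(fit.D, series.temperature, series.viscosity)
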