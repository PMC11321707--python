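"""Small-angle scattering from bead assemblies: Debye curves, Guinier and
one-level Beaucage unified fits.

The Debye sum I(q) = Σᵢⱼ fᵢfⱼ sin(q rᵢⱼ)/(q rᵢⱼ) gives the orientationally
averaged intensity of a rigid bead model (unit form factors by default — the
coarse-grained beads carry no element contrast).  Guinier analysis recovers
Rg from the low-q limit ln I ≈ ln I₀ − q²Rg²/3; the Beaucage unified
function adds a structurally limited power law and fits Guinier and
power-law regimes simultaneously.  q is in nm⁻¹ throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from lmfit import Model
from scipy.spatial.distance import pdist
from scipy.special import erf

from .structio import AssemblyFrame

__all__ = [
    "XRAY_WAVELENGTH_NM",
    "ScatteringCurve",
    "GuinierFit",
    "BeaucageFit",
    "debye_curve",
    "guinier_fit",
    "beaucage_fit",
    "beaucage_intensity",
]

XRAY_WAVELENGTH_NM = 0.1542  # Cu Kα


@dataclass
class ScatteringCurve:
    """Scattering intensity on a strictly increasing positive q grid (nm⁻¹)."""

    q: np.ndarray
    intensity: np.ndarray
    wavelength: float = XRAY_WAVELENGTH_NM
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if len(self.q) != len(self.intensity):
            raise ValueError("q and intensity lengths differ")
        if np.any(self.q <= 0) or np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be positive and strictly increasing")
        if np.any(self.intensity <= 0):
            raise ValueError("intensities must be positive")


@dataclass
class GuinierFit:
    rg: float  # nm
    i0: float
    n_points: int
    q_max_used: float
    converged: bool = True
    message: str = ""


@dataclass
class BeaucageFit:
    """One-level unified-fit parameters: Guinier prefactor G, Rg (nm),
    power-law prefactor B and exponent P."""

    G: float
    rg: float
    B: float
    P: float
    residual: float
    converged: bool = True
    message: str = ""


# ---------------------------------------------------------------------------
# Debye curve
# ---------------------------------------------------------------------------

def debye_curve(
    frame: AssemblyFrame,
    q: np.ndarray,
    form_factor: str = "unit",
) -> ScatteringCurve:
    """Debye scattering intensity of a bead frame on a q grid (nm⁻¹).

    ``form_factor="unit"`` weighs every bead equally; ``"mass"`` uses the
    bead masses.  Positions (Å) are converted to nm; the qr → 0 limit of the
    sinc kernel is 1, so I(q→0) = (Σf)².
    """
    q = np.asarray(q, dtype=float)
    if np.any(q <= 0):
        raise ValueError("q values must be positive")
    if frame.n_beads < 2:
        raise ValueError("need at least 2 beads")
    if form_factor == "unit":
        f = np.ones(frame.n_beads)
    elif form_factor == "mass":
        f = frame.mass.astype(float)
    else:
        raise ValueError("form_factor must be 'unit' or 'mass'")
    pos_nm = frame.positions / 10.0
    d = pdist(pos_nm)
    iu, ju = np.triu_indices(frame.n_beads, k=1)
    w = f[iu] * f[ju]
    self_term = float(np.sum(f**2))
    # np.sinc(x) = sin(pi x)/(pi x); sin(qd)/(qd) = np.sinc(qd/pi)
    intensity = np.empty(len(q))
    for k, qk in enumerate(q):
        intensity[k] = self_term + 2.0 * float(np.sum(w * np.sinc(qk * d / np.pi)))
    return ScatteringCurve(q=q, intensity=intensity, metadata={"form_factor": form_factor})


def restrict_above_background(
    curve: ScatteringCurve, background: float, factor: float = 5.0
) -> ScatteringCurve:
    """Keep only the q range where the intensity dominates a flat background.

    Point-bead Debye curves flatten to the self-term (I → N for unit form
    factors) at high q, the analogue of the incoherent background an
    experimentalist subtracts before model fitting; shape fits should only
    see the coherent window above it.
    """
    keep = curve.intensity >= factor * background
    if keep.sum() < 5:
        raise ValueError("fewer than 5 points above the background level")
    return ScatteringCurve(
        q=curve.q[keep], intensity=curve.intensity[keep],
        wavelength=curve.wavelength, metadata=dict(curve.metadata),
    )


# ---------------------------------------------------------------------------
# Guinier
# ---------------------------------------------------------------------------

def guinier_fit(curve: ScatteringCurve, qrg_max: float = 1.3, min_points: int = 5) -> GuinierFit:
    """Iterative Guinier fit: slope of ln I vs q² over the window q·Rg ≤ qrg_max.

    Starts from the lowest-q decade and shrinks the window until
    q_max · Rg ≤ qrg_max.  A non-negative slope flags the absence of a
    Guinier regime instead of returning a radius.
    """
    q, i = curve.q, curve.intensity

    def finish(rg: float, intercept: float, idx: np.ndarray) -> GuinierFit:
        q_max = float(q[idx].max())
        if q_max * rg > qrg_max * 1.05:
            # even the smallest allowed window violates the qRg limit: the
            # curve has no resolvable Guinier knee (e.g. a pure power law)
            return GuinierFit(
                rg=float("nan"), i0=float("nan"), n_points=int(idx.sum()),
                q_max_used=q_max, converged=False,
                message="no Guinier regime: window cannot satisfy the qRg limit",
            )
        return GuinierFit(rg=rg, i0=float(np.exp(intercept)),
                          n_points=int(idx.sum()), q_max_used=q_max)

    n = max(min_points, len(q) // 4)
    idx = np.arange(len(q)) < n
    rg_prev = None
    for _ in range(60):
        if idx.sum() < min_points:
            return GuinierFit(
                rg=float("nan"), i0=float("nan"), n_points=int(idx.sum()),
                q_max_used=float("nan"), converged=False,
                message="fewer than the minimum points in the Guinier window",
            )
        slope, intercept = np.polyfit(q[idx] ** 2, np.log(i[idx]), 1)
        if slope >= 0:
            return GuinierFit(
                rg=float("nan"), i0=float("nan"), n_points=int(idx.sum()),
                q_max_used=float(q[idx].max()), converged=False,
                message="no Guinier regime: non-negative low-q slope",
            )
        rg = float(np.sqrt(-3.0 * slope))
        new_idx = q * rg <= qrg_max
        if new_idx.sum() < min_points:
            new_idx = np.arange(len(q)) < min_points
        if rg_prev is not None and abs(rg - rg_prev) <= 1e-9 * rg:
            return finish(rg, intercept, idx)
        if new_idx.sum() == idx.sum() and np.all(new_idx == idx):
            return finish(rg, intercept, idx)
        rg_prev = rg
        idx = new_idx
    return GuinierFit(
        rg=rg, i0=float(np.exp(intercept)), n_points=int(idx.sum()),
        q_max_used=float(q[idx].max()), converged=False,
        message="window iteration did not settle",
    )


# ---------------------------------------------------------------------------
# Beaucage unified fit
# ---------------------------------------------------------------------------

def beaucage_intensity(q: np.ndarray, G: float, rg: float, B: float, P: float) -> np.ndarray:
    """One-level Beaucage unified function:
    I(q) = G exp(−q²Rg²/3) + B [erf(qRg/√6)]³ᴾ / qᴾ."""
    q = np.asarray(q, dtype=float)
    guinier = G * np.exp(-(q**2) * rg**2 / 3.0)
    qstar = erf(q * rg / np.sqrt(6.0))
    power = B * qstar ** (3.0 * P) / q**P
    return guinier + power


def _log_beaucage(q: np.ndarray, logG: float, rg: float, logB: float, P: float) -> np.ndarray:
    return np.log(beaucage_intensity(q, np.exp(logG), rg, np.exp(logB), P) + 1e-300)


def beaucage_fit(curve: ScatteringCurve, p_starts=(1.0, 2.0, 3.0, 4.0)) -> BeaucageFit:
    """Least-squares one-level Beaucage fit (in log intensity, so both the
    Guinier knee and the power-law tail carry weight).

    Requires at least a decade in q.  Initialization: G and Rg from
    :func:`guinier_fit` (falling back to a coarse low-q estimate), B from
    the high-q tail, multistart over the exponent P.  P is bounded to
    [1, 4.5]: below 1 the power-law term degenerates into a flat pedestal
    under the Guinier knee and corrupts Rg.
    """
    q, i = curve.q, curve.intensity
    if q.max() / q.min() < 10.0:
        raise ValueError("curve must span at least one decade in q")
    gui = guinier_fit(curve)
    if gui.converged and np.isfinite(gui.rg):
        rg0, g0 = gui.rg, gui.i0
    else:
        rg0, g0 = 1.0 / q[len(q) // 4], float(i[0])

    m = Model(_log_beaucage)
    best = None
    for p0 in p_starts:
        b0 = float(i[-1] * q[-1] ** p0)
        params = m.make_params(
            logG=np.log(max(g0, 1e-30)), rg=rg0, logB=np.log(max(b0, 1e-30)), P=p0
        )
        params["rg"].set(min=1e-6)
        params["P"].set(min=1.0, max=4.5)
        try:
            res = m.fit(np.log(i), params, q=q)
        except Exception:  # pragma: no cover
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res
    if best is None or not best.success:
        return BeaucageFit(
            G=float("nan"), rg=float("nan"), B=float("nan"), P=float("nan"),
            residual=float("nan"), converged=False, message="unified fit did not converge",
        )
    p = best.params
    return BeaucageFit(
        G=float(np.exp(p["logG"].value)),
        rg=float(p["rg"].value),
        B=float(np.exp(p["logB"].value)),
        P=float(p["P"].value),
        residual=float(np.sqrt(best.chisqr / len(q))),
    )
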