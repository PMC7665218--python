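"""INEPT polarization-transfer signal model and disorder quantification.

In solid-state NMR of fibrils, scalar-coupling-driven (INEPT) 1H-13C
polarization transfer only yields signal from segments undergoing
large-amplitude sub-microsecond motion, so INEPT peak areas report on
dynamically disordered residues.  For transfer delays tau1 and tau2 the
Calpha peak area is proportional to::

    sin(2 pi J tau1) sin(2 pi k J tau2) exp(-2 tau1 / T2H) exp(-2 tau2 / T2C)

with J the 1Ha-13Ca scalar coupling (~140 Hz), k the number of attached
alpha protons (2 for Gly, 1 otherwise), and T2H/T2C the 1H/13C
transverse relaxation times.  The ideal maximum (no relaxation, optimal
delays) is 1, which normalizes the relaxation-induced reduction factors.

Setting the delay derivative of the amplitude to zero gives closed forms
for the relaxation times from the observed maxima::

    T2H = tan(2 pi J tau1_max) / (pi J)
    T2C = tan(2 pi k J tau2_max) / (k pi J)

Delays are in milliseconds throughout; J is in Hz, and the phase
argument 2*pi*J*tau carries an explicit ms->s conversion.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_J",
    "K_BY_CLASS",
    "INEPTModelParams",
    "inept_amplitude",
    "t2_from_tau_max",
    "tau_max_from_t2",
    "reduction_factor",
    "fit_tau_max",
    "disorder_ratio",
    "disordered_fraction",
    "DisorderEstimate",
    "INEPTExperiment",
    "INEPTResults",
    "INEPTClassFit",
    "read_inept_csv",
]

#: Default one-bond 1Ha-13Ca scalar coupling, Hz.
DEFAULT_J = 140.0

#: Attached alpha-proton count by residue class.
K_BY_CLASS = {"Gly": 2, "other": 1}

_MS = 1.0e-3  # delays are ms; J is Hz


@dataclass(frozen=True)
class INEPTModelParams:
    """Signal-model parameters: J (Hz), k in {1,2,3}, T2 values in ms.

    ``math.inf`` for a T2 is the no-relaxation limit.
    """

    J: float = DEFAULT_J
    k: int = 1
    T2H: float = math.inf
    T2C: float = math.inf

    def __post_init__(self) -> None:
        if self.J <= 0:
            raise ValueError("J must be positive")
        if self.k not in (1, 2, 3):
            raise ValueError("k must be 1, 2 or 3")
        if self.T2H <= 0 or self.T2C <= 0:
            raise ValueError("T2 values must be positive (or math.inf)")


def inept_amplitude(tau1_ms, tau2_ms, params: INEPTModelParams):
    """INEPT Calpha amplitude at delays (tau1, tau2), ideal maximum = 1.

    Accepts scalars or numpy arrays for the delays.
    """
    t1 = np.asarray(tau1_ms, dtype=float) * _MS
    t2 = np.asarray(tau2_ms, dtype=float) * _MS
    if np.any(t1 < 0) or np.any(t2 < 0):
        raise ValueError("delays must be non-negative")
    amp = (
        np.sin(2.0 * np.pi * params.J * t1)
        * np.sin(2.0 * np.pi * params.k * params.J * t2)
        * np.exp(-2.0 * t1 / (params.T2H * _MS))
        * np.exp(-2.0 * t2 / (params.T2C * _MS))
    )
    return float(amp) if amp.ndim == 0 else amp


def t2_from_tau_max(
    tau_max_ms: float, J: float = DEFAULT_J, k: int = 1, channel: str = "H"
) -> float:
    """Transverse relaxation time (ms) from the signal-maximizing delay.

    For the 1H channel: T2H = tan(2 pi J tau)/(pi J); for the 13C
    channel the k attached protons enter: T2C = tan(2 pi k J tau)/(k pi J).
    Valid only on the first tangent branch, 2 pi (k) J tau < pi/2.
    """
    if channel not in ("H", "C"):
        raise ValueError("channel must be 'H' or 'C'")
    keff = k if channel == "C" else 1
    phase = 2.0 * math.pi * keff * J * tau_max_ms * _MS
    if not 0.0 < phase < math.pi / 2.0:
        raise ValueError(
            "tau_max on or beyond the quarter-period singularity: "
            "no physical maximum on the first tangent branch"
        )
    return math.tan(phase) / (keff * math.pi * J) / _MS


def tau_max_from_t2(
    t2_ms: float, J: float = DEFAULT_J, k: int = 1, channel: str = "H"
) -> float:
    """Delay (ms) maximizing the amplitude for a given T2; inverse of
    :func:`t2_from_tau_max`."""
    keff = k if channel == "C" else 1
    if math.isinf(t2_ms):
        return 1.0 / (4.0 * keff * J) / _MS
    return math.atan(keff * math.pi * J * t2_ms * _MS) / (2.0 * math.pi * keff * J) / _MS


def reduction_factor(
    tau1_max_ms: float,
    tau2_max_ms: float,
    params: INEPTModelParams | None = None,
    *,
    J: float = DEFAULT_J,
    k: int = 1,
) -> float:
    """Relaxation-induced reduction of the maximum signal vs the ideal unit maximum.

    If ``params`` omits T2 values (infinite), they are inferred from the
    stated maxima via :func:`t2_from_tau_max`.  If finite T2 values are
    supplied that are inconsistent with the given maxima, a warning is
    emitted and the supplied values are used.
    """
    if params is None:
        params = INEPTModelParams(J=J, k=k)
    if math.isinf(params.T2H):
        params = replace(params, T2H=t2_from_tau_max(tau1_max_ms, params.J, params.k, "H"))
    elif abs(tau_max_from_t2(params.T2H, params.J, params.k, "H") - tau1_max_ms) > 0.05:
        warnings.warn("supplied T2H is not maximal at tau1_max", stacklevel=2)
    if math.isinf(params.T2C):
        params = replace(params, T2C=t2_from_tau_max(tau2_max_ms, params.J, params.k, "C"))
    elif abs(tau_max_from_t2(params.T2C, params.J, params.k, "C") - tau2_max_ms) > 0.05:
        warnings.warn("supplied T2C is not maximal at tau2_max", stacklevel=2)
    return inept_amplitude(tau1_max_ms, tau2_max_ms, params)


def _quadratic_peak(x: np.ndarray, y: np.ndarray) -> float:
    """Vertex abscissa of the parabola through the top three points of a scan."""
    order = np.argsort(x)
    x, y = x[order], y[order]
    if len(x) < 3:
        raise ValueError("need at least 3 points along a scanned delay")
    i = int(np.argmax(y))
    if i == 0 or i == len(x) - 1:
        raise ValueError("maximum lies on the grid boundary (unbracketed)")
    a, b, c = np.polyfit(x[i - 1 : i + 2], y[i - 1 : i + 2], 2)
    if a >= 0:
        raise ValueError("top three points do not bracket a maximum")
    return float(-b / (2.0 * a))


def fit_tau_max(curve: pd.DataFrame) -> tuple[float, float]:
    """Sub-grid (tau1_max, tau2_max) in ms from a two-scan peak-area table.

    ``curve`` has columns ``tau1_ms``, ``tau2_ms``, ``area``.  The tau1
    scan is the largest group of rows sharing a tau2 value (and vice
    versa); each scan's maximum is located by quadratic interpolation
    through its top three points, so coarse experimental grids still
    yield sub-grid maxima.
    """
    required = {"tau1_ms", "tau2_ms", "area"}
    if not required.issubset(curve.columns):
        raise ValueError(f"curve must have columns {sorted(required)}")

    def scan(var: str, fixed: str) -> float:
        groups = [g for _, g in curve.groupby(fixed) if g[var].nunique() >= 3]
        if not groups:
            raise ValueError(f"no {var} scan with >= 3 points at fixed {fixed}")
        g = max(groups, key=len)
        agg = g.groupby(var, as_index=False)["area"].mean()  # repeated delays
        return _quadratic_peak(agg[var].to_numpy(float), agg["area"].to_numpy(float))

    return scan("tau1_ms", "tau2_ms"), scan("tau2_ms", "tau1_ms")


def disorder_ratio(
    observed_ratio: float, reduction_gly: float, reduction_other: float
) -> float:
    """Relaxation-corrected Gly:non-Gly disordered-residue ratio.

    ``observed_ratio * reduction_other / reduction_gly`` -- the observed
    maximum-signal ratio rescaled by the two reduction factors.
    """
    if min(observed_ratio, reduction_gly, reduction_other) <= 0:
        raise ValueError("all inputs must be positive")
    return observed_ratio * reduction_other / reduction_gly


def disordered_fraction(ratio: float) -> float:
    """Percentage of disordered residues that are Gly: 100 * r / (1 + r)."""
    if ratio < 0:
        raise ValueError("ratio must be non-negative")
    return 100.0 * ratio / (1.0 + ratio)


@dataclass(frozen=True)
class DisorderEstimate:
    observed_ratio: float
    reduction_gly: float
    reduction_other: float
    corrected_ratio: float
    gly_fraction: float  # percent


# ---------------------------------------------------------------------------
# Model / Results interface


@dataclass(frozen=True)
class INEPTClassFit:
    residue_class: str
    k: int
    tau1_max_ms: float
    tau2_max_ms: float
    T2H_ms: float
    T2C_ms: float
    reduction: float


def read_inept_csv(path) -> pd.DataFrame:
    """Read an INEPT peak-area table (tau1_ms, tau2_ms, area[, residue_class])."""
    df = pd.read_csv(path)
    missing = {"tau1_ms", "tau2_ms", "area"} - set(df.columns)
    if missing:
        raise ValueError(f"missing columns {sorted(missing)}")
    return df


class INEPTExperiment:
    """Delay-dependence experiment: peak areas on a (tau1, tau2) grid.

    The table has columns ``tau1_ms``, ``tau2_ms``, ``area`` and
    optionally ``residue_class`` ("Gly" or "other"); without the class
    column all rows are fitted as one class with the given ``k``.
    """

    def __init__(self, curve: pd.DataFrame, J: float = DEFAULT_J, k: int = 1):
        self.curve = curve.copy()
        if "residue_class" not in self.curve.columns:
            self.curve["residue_class"] = "Gly" if k == 2 else "other"
        self.J = float(J)

    @classmethod
    def from_csv(cls, path, J: float = DEFAULT_J) -> "INEPTExperiment":
        return cls(read_inept_csv(path), J=J)

    def fit(self) -> "INEPTResults":
        fits: dict[str, INEPTClassFit] = {}
        for cls_name, group in self.curve.groupby("residue_class"):
            k = K_BY_CLASS.get(str(cls_name), 1)
            tau1, tau2 = fit_tau_max(group)
            t2h = t2_from_tau_max(tau1, self.J, k, "H")
            t2c = t2_from_tau_max(tau2, self.J, k, "C")
            red = inept_amplitude(
                tau1, tau2, INEPTModelParams(J=self.J, k=k, T2H=t2h, T2C=t2c)
            )
            fits[str(cls_name)] = INEPTClassFit(
                str(cls_name), k, tau1, tau2, t2h, t2c, red
            )
        return INEPTResults(self, fits)


class INEPTResults:
    """Fitted delay maxima, relaxation times and reduction factors per class."""

    def __init__(self, model: INEPTExperiment, fits: dict[str, INEPTClassFit]):
        self.model = model
        self.fits = fits

    def __getitem__(self, residue_class: str) -> INEPTClassFit:
        return self.fits[residue_class]

    def disorder_estimate(self, observed_ratio: float) -> DisorderEstimate:
        """Chain the fitted reduction factors into a disordered-Gly share.

        ``observed_ratio`` is the measured ratio of maximum Gly to
        non-Gly 1D INEPT signals.
        """
        gly = self.fits["Gly"].reduction
        other = self.fits["other"].reduction
        corrected = disorder_ratio(observed_ratio, gly, other)
        return DisorderEstimate(
            observed_ratio, gly, other, corrected, disordered_fraction(corrected)
        )

    def summary(self) -> str:
        lines = [
            "INEPT delay-dependence fit",
            f"  J = {self.model.J:.1f} Hz",
            f"  {'class':<8}{'k':>3}{'tau1max/ms':>12}{'tau2max/ms':>12}"
            f"{'T2H/ms':>9}{'T2C/ms':>9}{'reduction':>11}",
        ]
        for f in self.fits.values():
            lines.append(
                f"  {f.residue_class:<8}{f.k:>3}{f.tau1_max_ms:>12.2f}"
                f"{f.tau2_max_ms:>12.2f}{f.T2H_ms:>9.1f}{f.T2C_ms:>9.1f}"
                f"{f.reduction:>11.2f}"
            )
        return "\n".join(lines)

    def plot(self, ax=None):
        """Peak areas vs each scanned delay, with the fitted maxima marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for cls_name, group in self.model.curve.groupby("residue_class"):
            f = self.fits[str(cls_name)]
            for var, mark in (("tau1_ms", f.tau1_max_ms), ("tau2_ms", f.tau2_max_ms)):
                scans = [g for _, g in group.groupby("tau2_ms" if var == "tau1_ms" else "tau1_ms")
                         if g[var].nunique() >= 3]
                if not scans:
                    continue
                g = max(scans, key=len).sort_values(var)
                ax.plot(g[var], g["area"], "o-", label=f"{cls_name} {var}")
                ax.axvline(mark, ls=":", lw=0.8)
        ax.set_xlabel("delay (ms)")
        ax.set_ylabel("peak area")
        ax.legend(fontsize="small")
        return ax
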