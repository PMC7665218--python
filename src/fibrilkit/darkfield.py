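"""Mass-per-length (MPL) from dark-field TEM intensities with TMV calibration.

Dark-field image intensities integrated over 100 nm x 60 nm boxes centred
on fibril segments (``I_center``) are background-corrected using two
flanking boxes (``I_B1``, ``I_B2``) and converted to MPL counts against
tobacco mosaic virus (TMV) rods as an internal standard of 131 kDa/nm::

    MPL = (I_F / I_TMV) * 131,   I_F = I_center - (I_B1 + I_B2)/2

where ``I_TMV`` is the average background-corrected intensity over many
TMV rods.  The error model evaluates the same statistic on background
boxes: E = sqrt(3/2) * (I_B - I_B_ave)/I_TMV * 131, whose distribution is
centred at zero with the width the three-box arithmetic implies.

The table schema (CSV columns) is ``segment_id, kind, I_center, I_B1,
I_B2`` with ``kind`` in {"fibril", "TMV", "background"}.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "TMV_MPL",
    "read_darkfield_csv",
    "validate_table",
    "subtracted_intensity",
    "tmv_calibration",
    "Calibration",
    "mpl_count",
    "background_error",
    "fit_gaussian_histogram",
    "GaussianFit",
    "MassPerLengthModel",
    "MPLResults",
]

#: MPL of tobacco mosaic virus, kDa/nm (the internal calibration standard).
TMV_MPL = 131.0

_COLUMNS = ("segment_id", "kind", "I_center", "I_B1", "I_B2")
_KINDS = {"fibril", "TMV", "background"}


def read_darkfield_csv(path) -> pd.DataFrame:
    return validate_table(pd.read_csv(path))


def validate_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = set(_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"missing columns {sorted(missing)}")
    bad = set(table["kind"]) - _KINDS
    if bad:
        raise ValueError(f"unknown kind values {sorted(bad)}")
    return table


def subtracted_intensity(table: pd.DataFrame) -> pd.Series:
    """Background-corrected intensity I_center - (I_B1 + I_B2)/2 per row.

    A row missing one background box reuses the other (with a warning);
    the published procedure always has both flanking boxes.
    """
    b1 = table["I_B1"].to_numpy(float)
    b2 = table["I_B2"].to_numpy(float)
    only_one = np.isnan(b1) ^ np.isnan(b2)
    if only_one.any():
        warnings.warn(
            f"{int(only_one.sum())} row(s) missing one background box; "
            "reusing the other",
            stacklevel=2,
        )
        b1 = np.where(np.isnan(b1), b2, b1)
        b2 = np.where(np.isnan(b2), b1, b2)
    if np.isnan(b1).any():
        raise ValueError("row(s) with no background intensity at all")
    return pd.Series(
        table["I_center"].to_numpy(float) - 0.5 * (b1 + b2), index=table.index
    )


class Calibration(NamedTuple):
    I_TMV: float
    n_rods: int


def tmv_calibration(table: pd.DataFrame) -> Calibration:
    """Mean background-corrected TMV intensity (the calibration constant)."""
    tmv = table[table["kind"] == "TMV"]
    if len(tmv) == 0:
        raise ValueError("no TMV rows: cannot calibrate")
    value = float(subtracted_intensity(tmv).mean())
    if value <= 0:
        raise ValueError("non-positive TMV calibration (miscalibrated data)")
    return Calibration(value, len(tmv))


def mpl_count(
    rows: pd.DataFrame | pd.Series, I_TMV: float, tmv_mpl: float = TMV_MPL
):
    """MPL count(s) (I_F / I_TMV) * 131 kDa/nm for fibril row(s).

    Negative I_F is allowed (the count is negative) -- such counts are
    meaningful for the error distribution.
    """
    if I_TMV <= 0:
        raise ValueError("I_TMV must be positive")
    if isinstance(rows, pd.Series):
        rows = rows.to_frame().T
    i_f = subtracted_intensity(rows)
    out = i_f / I_TMV * tmv_mpl
    return float(out.iloc[0]) if len(out) == 1 else out


def background_error(I_B, I_B_ave: float, I_TMV: float, tmv_mpl: float = TMV_MPL):
    """Error statistic sqrt(3/2) * (I_B - I_B_ave)/I_TMV * 131 kDa/nm."""
    if I_TMV <= 0:
        raise ValueError("I_TMV must be positive")
    out = np.sqrt(1.5) * (np.asarray(I_B, dtype=float) - I_B_ave) / I_TMV * tmv_mpl
    return float(out) if out.ndim == 0 else out


class GaussianFit(NamedTuple):
    mean: float
    sd: float
    amplitude: float
    sample_mean: float
    sample_sd: float
    n: int


def fit_gaussian_histogram(
    values, bin_width: float = 2.0, min_values: int = 10
) -> GaussianFit:
    """Least-squares Gaussian fit to a binned histogram of MPL counts.

    Counts are binned at fixed ``bin_width`` and a Gaussian
    ``A exp(-(x-mu)^2 / (2 sigma^2))`` is fitted on the bin centres.
    Sample mean/SD are reported alongside for comparison.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < min_values:
        raise ValueError(f"need at least {min_values} values")
    if np.ptp(v) == 0:
        raise ValueError("degenerate (all-equal) values")
    lo = np.floor(v.min() / bin_width) * bin_width
    nbins = int(np.ceil((v.max() - lo) / bin_width)) + 1
    edges = lo + bin_width * np.arange(nbins + 1)
    counts, _ = np.histogram(v, bins=edges)
    centers = edges[:-1] + bin_width / 2.0

    def gauss(x, a, mu, sigma):
        return a * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))

    p0 = (float(counts.max()), float(v.mean()), max(float(v.std()), bin_width / 2))
    popt, _ = curve_fit(gauss, centers, counts, p0=p0, maxfev=10000)
    a, mu, sigma = popt
    return GaussianFit(
        mean=float(mu),
        sd=abs(float(sigma)),
        amplitude=float(a),
        sample_mean=float(v.mean()),
        sample_sd=float(v.std(ddof=1)),
        n=len(v),
    )


class MassPerLengthModel:
    """Dark-field MPL analysis of an intensity table.

    Parameters
    ----------
    table : DataFrame with columns segment_id, kind, I_center, I_B1, I_B2
    tmv_mpl : MPL of the calibration standard (131 kDa/nm for TMV)
    """

    def __init__(self, table: pd.DataFrame, tmv_mpl: float = TMV_MPL):
        self.table = validate_table(table)
        self.tmv_mpl = float(tmv_mpl)

    @classmethod
    def from_csv(cls, path, tmv_mpl: float = TMV_MPL) -> "MassPerLengthModel":
        return cls(read_darkfield_csv(path), tmv_mpl)

    def fit(
        self, bin_width: float = 2.0, exclude_negative: bool = False
    ) -> "MPLResults":
        cal = tmv_calibration(self.table)
        fibrils = self.table[self.table["kind"] == "fibril"]
        per_segment = pd.Series(
            np.atleast_1d(mpl_count(fibrils, cal.I_TMV, self.tmv_mpl)),
            index=fibrils["segment_id"].to_numpy(),
            name="mpl_kda_per_nm",
        )
        values = per_segment.to_numpy(float)
        if exclude_negative:
            values = values[values > 0]
        hist_fit = fit_gaussian_histogram(values, bin_width)
        bg = self.table[self.table["kind"] == "background"]
        errors = None
        if len(bg):
            # pure-background boxes: the error statistic uses raw box intensities
            raw = bg["I_center"].to_numpy(float)
            errors = background_error(raw, float(raw.mean()), cal.I_TMV, self.tmv_mpl)
        return MPLResults(self, cal, per_segment, hist_fit, errors, bin_width)


class MPLResults:
    """Per-segment MPL counts, calibration, and Gaussian histogram fit."""

    def __init__(
        self,
        model: MassPerLengthModel,
        calibration: Calibration,
        per_segment: pd.Series,
        fit: GaussianFit,
        errors,
        bin_width: float,
    ):
        self.model = model
        self.calibration = calibration
        self.per_segment = per_segment
        self.fit = fit
        self.errors = errors
        self.bin_width = bin_width

    @property
    def mean(self) -> float:
        return self.fit.mean

    @property
    def sd(self) -> float:
        return self.fit.sd

    @property
    def n(self) -> int:
        return self.fit.n

    def subunit_count(self, mass_model):
        """Cross-beta subunit count implied by the fitted mean MPL."""
        from .helix import subunit_count_from_mpl

        return subunit_count_from_mpl(self.mean, mass_model)

    def summary(self) -> str:
        f = self.fit
        lines = [
            "Dark-field MPL analysis",
            f"  calibration: I_TMV = {self.calibration.I_TMV:.4g} "
            f"({self.calibration.n_rods} TMV rods, {self.model.tmv_mpl:g} kDa/nm)",
            f"  fibril segments: n = {f.n}",
            f"  Gaussian fit:   {f.mean:.1f} +/- {f.sd:.1f} kDa/nm "
            f"(bin width {self.bin_width:g})",
            f"  sample moments: {f.sample_mean:.1f} +/- {f.sample_sd:.1f} kDa/nm",
        ]
        if self.errors is not None:
            lines.append(
                f"  background error: mean {np.mean(self.errors):+.2f}, "
                f"sd {np.std(self.errors):.2f} kDa/nm ({len(self.errors)} boxes)"
            )
        return "\n".join(lines)

    def plot_histogram(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        v = self.per_segment.to_numpy(float)
        lo = np.floor(v.min() / self.bin_width) * self.bin_width
        edges = lo + self.bin_width * np.arange(
            int(np.ceil((v.max() - lo) / self.bin_width)) + 2
        )
        ax.hist(v, bins=edges, alpha=0.6, label="MPL counts")
        x = np.linspace(edges[0], edges[-1], 300)
        f = self.fit
        ax.plot(
            x,
            f.amplitude * np.exp(-((x - f.mean) ** 2) / (2 * f.sd**2)),
            label=f"fit {f.mean:.1f} +/- {f.sd:.1f}",
        )
        ax.set_xlabel("MPL (kDa/nm)")
        ax.set_ylabel("count")
        ax.legend()
        return ax
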