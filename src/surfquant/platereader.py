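"""Bulk GFP/OD measurements to molecules per cell, molarity and fitness.

The calibration chain: GFP intensity is divided by OD600 (``GFP_corr``),
expressed relative to a non-fluorescent control (``GFP_norm``), regressed
against known reference-strain abundances in log10-log10 space, and the
fitted line is inverted to predict molecules/cell for new strains. A stated
cell density converts molecules/cell to molar enzyme concentration, and the
displayed fraction from the imaging pipeline scales total abundance to
surface abundance.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator

AVOGADRO = 6.02214076e23


class PlateReaderError(ValueError):
    pass


def gfp_corr(gfp: float, od600: float) -> float:
    """GFP intensity corrected for cell mass (divided by OD600)."""
    od600 = np.asarray(od600, dtype=float)
    if (od600 <= 0).any():
        raise PlateReaderError("od600 must be > 0")
    return np.asarray(gfp, dtype=float) / od600


def gfp_norm(gfp_corr_strain: float, gfp_corr_control: float) -> float:
    """GFP_corr of a strain as a ratio to the negative-control GFP_corr."""
    control = np.asarray(gfp_corr_control, dtype=float)
    if (control <= 0).any():
        raise PlateReaderError("control GFP_corr must be > 0")
    return np.asarray(gfp_corr_strain, dtype=float) / control


class GfpCalibration(BaseEstimator):
    """Log-log regression of normalized GFP on known molecules/cell.

    ``fit`` performs OLS of log10(GFP_norm) on log10(abundance) over the
    reference strains (at least three distinct abundances, all positive);
    ``predict`` inverts the line to map GFP_norm readings of unknown strains
    to molecules/cell. Predictions outside the fitted GFP_norm range carry an
    extrapolation flag (``predict_abundance``). A linear-space fit is
    available for sensitivity analysis (``log_space=False``).

    Attributes (after ``fit``): ``slope_``, ``intercept_``, ``r_squared_``,
    ``n_strains_``, ``abundance_domain_``, ``gfp_norm_domain_``.
    """

    def __init__(self, log_space: bool = True):
        self.log_space = log_space

    def fit(self, molecules_per_cell, gfp_norm_values):
        a = np.asarray(molecules_per_cell, dtype=float)
        g = np.asarray(gfp_norm_values, dtype=float)
        if a.shape != g.shape or a.ndim != 1:
            raise PlateReaderError("abundances and GFP_norm must be 1-D and aligned")
        if (a <= 0).any() or (g <= 0).any():
            raise PlateReaderError("abundances and GFP_norm must be positive")
        if np.unique(a).size < 3:
            raise PlateReaderError(
                "calibration needs >= 3 distinct reference abundances"
            )
        x, y = (np.log10(a), np.log10(g)) if self.log_space else (a, g)
        res = sm.OLS(y, sm.add_constant(x)).fit()
        self.intercept_, self.slope_ = map(float, res.params)
        if self.slope_ == 0:
            raise PlateReaderError("degenerate calibration: zero slope")
        self.r_squared_ = float(res.rsquared)
        self.slope_se_ = float(res.bse[1])
        self.slope_ci_ = tuple(map(float, res.conf_int()[1]))
        self.n_strains_ = int(np.unique(a).size)
        self.abundance_domain_ = (float(a.min()), float(a.max()))
        self.gfp_norm_domain_ = (float(g.min()), float(g.max()))
        return self

    def predict(self, gfp_norm_values):
        g = np.asarray(gfp_norm_values, dtype=float)
        if (g <= 0).any():
            raise PlateReaderError("GFP_norm must be positive")
        if self.log_space:
            return 10.0 ** ((np.log10(g) - self.intercept_) / self.slope_)
        return (g - self.intercept_) / self.slope_

    def predict_abundance(self, gfp_norm_values):
        """Molecules/cell plus a boolean extrapolation flag per reading."""
        g = np.asarray(gfp_norm_values, dtype=float)
        lo, hi = self.gfp_norm_domain_
        return self.predict(g), (g < lo) | (g > hi)

    def to_dict(self) -> dict:
        return {
            "log_space": self.log_space,
            "slope": self.slope_,
            "intercept": self.intercept_,
            "r_squared": self.r_squared_,
            "n_strains": self.n_strains_,
            "abundance_domain": list(self.abundance_domain_),
            "gfp_norm_domain": list(self.gfp_norm_domain_),
        }


def fit_calibration(molecules_per_cell, gfp_norm_values, **kwargs) -> GfpCalibration:
    return GfpCalibration(**kwargs).fit(molecules_per_cell, gfp_norm_values)


def predict_abundance(model: GfpCalibration, gfp_norm_values):
    return model.predict_abundance(gfp_norm_values)


def molarity(molecules_per_cell, cell_density: float) -> float:
    """Molar concentration (nM) of ``molecules_per_cell`` at ``cell_density``
    cells/mL: molecules/cell x cells/L / Avogadro, in nanomolar."""
    mpc = np.asarray(molecules_per_cell, dtype=float)
    if (mpc < 0).any() or cell_density < 0:
        raise PlateReaderError("inputs must be non-negative")
    mol_per_litre = mpc * cell_density * 1.0e3 / AVOGADRO
    out = mol_per_litre * 1.0e9
    return float(out) if out.ndim == 0 else out


def displayed_abundance(
    total_molecules_per_cell: float, displayed_fraction: float,
    cell_density: float = 1.0e8,
) -> tuple[float, float]:
    """Surface abundance (molecules/cell) and its molarity (nM) at the
    stated cell density, from total abundance x displayed fraction."""
    frac = np.asarray(displayed_fraction, dtype=float)
    if ((frac < 0) | (frac > 1)).any():
        raise PlateReaderError("displayed fraction must lie in [0, 1]")
    displayed = np.asarray(total_molecules_per_cell, dtype=float) * frac
    return displayed, molarity(displayed, cell_density)


def growth_rate(time_min, od600, window: int = 5) -> float:
    """Maximum specific growth rate (1/h): the steepest ``window``-point
    sliding-window slope of ln(OD600) against time."""
    t = np.asarray(time_min, dtype=float) / 60.0
    od = np.asarray(od600, dtype=float)
    if t.shape != od.shape or t.ndim != 1:
        raise PlateReaderError("time and OD series must be 1-D and aligned")
    if t.size < 8:
        raise PlateReaderError(f"need >= 8 time points, got {t.size}")
    if (od <= 0).any():
        raise PlateReaderError("OD600 values must be > 0")
    if window < 2 or window > t.size:
        raise PlateReaderError("invalid window size")
    ln_od = np.log(od)
    slopes = [
        np.polyfit(t[i : i + window], ln_od[i : i + window], 1)[0]
        for i in range(t.size - window + 1)
    ]
    return float(max(slopes))


def fitness_ratio(mu_strain: float, mu_reference: float) -> float:
    """Growth rate of the experimental strain over that of the parental."""
    if mu_reference <= 0:
        raise PlateReaderError("reference growth rate must be > 0")
    return float(mu_strain / mu_reference)


@dataclasses.dataclass(frozen=True)
class AbundanceRecord:
    """Resolved abundance chain for one strain at a stated cell density."""

    strain_id: str
    gfp_corr: float
    gfp_norm: float
    molecules_per_cell: float
    concentration_nM: float
    cell_density: float
    displayed_fraction: float | None = None
    displayed_molecules_per_cell: float | None = None
    displayed_concentration_nM: float | None = None
    extrapolated: bool = False

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def abundance_record(
    strain_id: str,
    gfp: float,
    od600: float,
    control_gfp: float,
    control_od600: float,
    calibration: GfpCalibration,
    cell_density: float = 1.0e8,
    displayed_fraction: float | None = None,
) -> AbundanceRecord:
    """Run one strain through the full abundance chain."""
    corr = gfp_corr(gfp, od600)
    norm = gfp_norm(corr, gfp_corr(control_gfp, control_od600))
    mpc, flag = calibration.predict_abundance(norm)
    mpc = float(mpc)
    rec = dict(
        strain_id=strain_id,
        gfp_corr=float(corr),
        gfp_norm=float(norm),
        molecules_per_cell=mpc,
        concentration_nM=molarity(mpc, cell_density),
        cell_density=cell_density,
        extrapolated=bool(flag),
    )
    if displayed_fraction is not None:
        disp, disp_nm = displayed_abundance(mpc, displayed_fraction, cell_density)
        rec.update(
            displayed_fraction=float(displayed_fraction),
            displayed_molecules_per_cell=float(disp),
            displayed_concentration_nM=float(disp_nm),
        )
    return AbundanceRecord(**rec)


def two_sample_ttest(a, b) -> tuple[float, float]:
    """Thin unpaired two-sample comparison (t statistic, p value)."""
    res = stats.ttest_ind(np.asarray(a, float), np.asarray(b, float))
    return float(res.statistic), float(res.pvalue)
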