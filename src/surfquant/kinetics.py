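"""Absorbance to product, Michaelis-Menten fitting, and whole-cell catalytic
constants.

Released para-nitrophenol (pNP) is quantified by Beer-Lambert from endpoint
A405 readings after subtracting the paired substrate-autohydrolysis control,
using a pH-dependent molar extinction coefficient modelled by
Henderson-Hasselbalch ionization. Initial rates over the fixed incubation
are fitted with v = Vmax * S / (Km + S); k_cat = Vmax / [E] uses the enzyme
concentration from the abundance chain (molecules/cell x displayed fraction
x cell density), with its provenance recorded.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import warnings

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator


class KineticsError(ValueError):
    pass


class FitConvergenceError(KineticsError):
    """Nonlinear fit failed; carries the last parameter iterate."""

    def __init__(self, message: str, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


def load_pnp_extinction_reference() -> pd.DataFrame:
    """Packaged pNP extinction-coefficient reference table (pH, epsilon).

    The shipped table is a synthetic stand-in generated from the
    Henderson-Hasselbalch model with literature pKa and epsilon_max (see the
    file header); pass your own (pH, epsilon) pairs to
    :class:`PnpExtinctionModel` to use measured values.
    """
    path = importlib.resources.files("surfquant.data") / "pnp_extinction_synthetic.csv"
    with importlib.resources.as_file(path) as p:
        return pd.read_csv(p, comment="#")


def _henderson_hasselbalch(ph, epsilon_max, pka):
    return epsilon_max / (1.0 + 10.0 ** (pka - ph))


class PnpExtinctionModel(BaseEstimator):
    """epsilon(pH) = epsilon_max / (1 + 10^(pKa - pH)) fitted by least squares.

    Requires at least four reference points spanning the pKa. Attributes
    after ``fit``: ``epsilon_max_`` (1/(M cm)), ``pka_``. ``wavelength_nm``
    tags the wavelength the coefficients refer to.
    """

    def __init__(self, epsilon_max0: float = 18000.0, pka0: float = 7.15,
                 wavelength_nm: float = 405.0):
        self.epsilon_max0 = epsilon_max0
        self.pka0 = pka0
        self.wavelength_nm = wavelength_nm

    def fit(self, ph, epsilon):
        ph = np.asarray(ph, dtype=float)
        eps = np.asarray(epsilon, dtype=float)
        if ph.size < 4:
            raise KineticsError("need >= 4 (pH, epsilon) reference points")
        try:
            popt, pcov = curve_fit(
                _henderson_hasselbalch, ph, eps,
                p0=(self.epsilon_max0, self.pka0), maxfev=10000,
            )
        except RuntimeError as exc:
            raise FitConvergenceError(f"extinction model did not converge: {exc}") from exc
        self.epsilon_max_, self.pka_ = map(float, popt)
        if not ph.min() < self.pka_ < ph.max():
            raise KineticsError(
                f"reference pH range [{ph.min()}, {ph.max()}] does not span the "
                f"fitted pKa {self.pka_:.2f}"
            )
        self.param_se_ = tuple(np.sqrt(np.diag(pcov)).astype(float))
        return self

    def predict(self, ph):
        out = _henderson_hasselbalch(np.asarray(ph, dtype=float), self.epsilon_max_, self.pka_)
        return float(out) if out.ndim == 0 else out

    @classmethod
    def from_reference(cls, **kwargs) -> "PnpExtinctionModel":
        ref = load_pnp_extinction_reference()
        return cls(**kwargs).fit(ref["pH"], ref["epsilon_M_cm"])


def fit_epsilon_model(ph, epsilon, **kwargs) -> PnpExtinctionModel:
    return PnpExtinctionModel(**kwargs).fit(ph, epsilon)


def pnp_concentration(
    a405, a405_autohydrolysis_control, epsilon: float, pathlength: float
):
    """Released pNP (uM) by Beer-Lambert after subtracting the paired
    autohydrolysis control; negative net absorbance floors at 0 with a
    warning."""
    if epsilon <= 0 or pathlength <= 0:
        raise KineticsError("epsilon and pathlength must be > 0")
    net = np.asarray(a405, dtype=float) - np.asarray(a405_autohydrolysis_control, dtype=float)
    if (net < 0).any():
        warnings.warn("negative net absorbance floored at 0", stacklevel=2)
        net = np.clip(net, 0.0, None)
    out = net / (epsilon * pathlength) * 1.0e6
    return float(out) if out.ndim == 0 else out


def initial_rate(product_uM, duration_min: float):
    """Endpoint product over incubation time (uM/min, single-endpoint design)."""
    if duration_min <= 0:
        raise KineticsError("duration must be > 0")
    out = np.asarray(product_uM, dtype=float) / duration_min
    return float(out) if out.ndim == 0 else out


def _mm(s, vmax, km):
    return vmax * s / (km + s)


class MichaelisMenten(BaseEstimator):
    """Unweighted nonlinear least-squares fit of v = Vmax * S / (Km + S).

    Replicate points are fitted individually (no averaging). Initial guesses:
    Vmax = max(v), Km = S nearest half of max(v). Attributes after ``fit``:
    ``vmax_``, ``km_``, ``vmax_se_``, ``km_se_``, ``rss_``.
    """

    def __init__(self, min_distinct_s: int = 5):
        self.min_distinct_s = min_distinct_s

    def fit(self, substrate_uM, rate):
        s = np.asarray(substrate_uM, dtype=float)
        v = np.asarray(rate, dtype=float)
        if s.shape != v.shape or s.ndim != 1:
            raise KineticsError("substrate and rate must be 1-D and aligned")
        if np.unique(s).size < self.min_distinct_s:
            raise KineticsError(
                f"need >= {self.min_distinct_s} distinct substrate concentrations"
            )
        if not (v > 0).any():
            raise KineticsError("all rates are non-positive; nothing to fit")
        vmax0 = float(v.max())
        km0 = float(s[np.argmin(np.abs(v - vmax0 / 2.0))])
        p0 = (vmax0, max(km0, 1e-9))
        try:
            popt, pcov = curve_fit(
                _mm, s, v, p0=p0, bounds=([0.0, 0.0], [np.inf, np.inf]), maxfev=10000
            )
        except RuntimeError as exc:
            raise FitConvergenceError(
                f"Michaelis-Menten fit did not converge: {exc}", last_iterate=p0
            ) from exc
        self.vmax_, self.km_ = map(float, popt)
        self.vmax_se_, self.km_se_ = np.sqrt(np.diag(pcov)).astype(float)
        self.rss_ = float(np.sum((v - _mm(s, *popt)) ** 2))
        self.n_points_ = int(s.size)
        return self

    def predict(self, substrate_uM):
        out = _mm(np.asarray(substrate_uM, dtype=float), self.vmax_, self.km_)
        return float(out) if out.ndim == 0 else out

    def diagnostics(self) -> dict:
        return {
            "vmax_se": float(self.vmax_se_),
            "km_se": float(self.km_se_),
            "rss": self.rss_,
            "n_points": self.n_points_,
        }


def fit_michaelis_menten(substrate_uM, rate) -> tuple[float, float, dict]:
    """(Vmax, Km, diagnostics) from a nonlinear Michaelis-Menten fit."""
    est = MichaelisMenten().fit(substrate_uM, rate)
    return est.vmax_, est.km_, est.diagnostics()


_VMAX_TO_M_PER_S = {"uM/min": 1.0e-6 / 60.0, "nM/s": 1.0e-9, "M/s": 1.0}


def catalytic_constants(
    vmax: float,
    enzyme_concentration_nM: float,
    km_uM: float,
    *,
    vmax_unit: str = "uM/min",
    provenance: str = "displayed",
) -> tuple[float, float]:
    """Turnover number k_cat (1/s) and efficiency k_cat/Km (1/(M s)).

    ``enzyme_concentration_nM`` should come from the abundance chain
    (molecules/cell x displayed fraction x cell density) for whole-cell
    catalysts; ``provenance`` records whether it is the displayed, total or
    purified enzyme concentration.
    """
    if enzyme_concentration_nM <= 0:
        raise KineticsError("enzyme concentration must be > 0")
    if km_uM <= 0:
        raise KineticsError("Km must be > 0")
    if provenance not in ("displayed", "total", "purified"):
        raise KineticsError(f"unknown enzyme-concentration provenance {provenance!r}")
    vmax_M_s = vmax * _VMAX_TO_M_PER_S[vmax_unit]
    kcat = vmax_M_s / (enzyme_concentration_nM * 1.0e-9)
    return float(kcat), float(kcat / (km_uM * 1.0e-6))


def normalize_activity(
    rate: float, cell_density: float, reference_density: float = 1.0e8
):
    """Rescale an activity measured at ``cell_density`` (cells/mL) to the
    reference density (default 1e8 cells/mL)."""
    if cell_density <= 0:
        raise KineticsError("cell density must be > 0")
    out = np.asarray(rate, dtype=float) * reference_density / cell_density
    return float(out) if out.ndim == 0 else out


@dataclasses.dataclass(frozen=True)
class KineticsFit:
    """Michaelis-Menten parameters with the enzyme-concentration provenance."""

    strain_id: str
    vmax_uM_min: float
    km_uM: float
    kcat_per_s: float
    efficiency_per_M_s: float
    enzyme_nM: float
    provenance: str
    diagnostics: dict

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def fit_assay(
    assay: pd.DataFrame,
    epsilon: float,
    pathlength: float,
    duration_min: float,
    enzyme_nM: float,
    *,
    strain_id: str = "",
    provenance: str = "displayed",
) -> KineticsFit:
    """Full assay-table route: paired-control subtraction, Beer-Lambert,
    initial rates, MM fit, catalytic constants.

    ``assay`` needs columns substrate_uM, replicate, is_control, a405.
    """
    required = {"substrate_uM", "replicate", "is_control", "a405"}
    if not required <= set(assay.columns):
        raise KineticsError(f"assay table lacks columns {sorted(required - set(assay.columns))}")
    controls = (
        assay[assay["is_control"]]
        .set_index(["substrate_uM", "replicate"])["a405"]
    )
    reactions = assay[~assay["is_control"]].copy()
    ctrl = reactions.set_index(["substrate_uM", "replicate"]).index.map(controls)
    if pd.isna(ctrl).any():
        raise KineticsError("missing paired autohydrolysis-control rows")
    product = pnp_concentration(
        reactions["a405"].to_numpy(), np.asarray(ctrl, dtype=float), epsilon, pathlength
    )
    rates = initial_rate(product, duration_min)
    est = MichaelisMenten().fit(reactions["substrate_uM"].to_numpy(), rates)
    kcat, eff = catalytic_constants(
        est.vmax_, enzyme_nM, est.km_, provenance=provenance
    )
    return KineticsFit(
        strain_id=strain_id,
        vmax_uM_min=est.vmax_,
        km_uM=est.km_,
        kcat_per_s=kcat,
        efficiency_per_M_s=eff,
        enzyme_nM=enzyme_nM,
        provenance=provenance,
        diagnostics=est.diagnostics(),
    )
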