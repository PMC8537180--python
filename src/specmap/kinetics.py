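"""Michaelis-Menten fitting of initial-rate data.

Rates are specific activities in U/mg (1 U = 1 umol substrate per
minute), substrate concentrations in mM.  The turnover number follows
from the specific activity and the enzyme's molar mass:

    k_cat [1/s] = V_max [umol min^-1 mg^-1] * MW [kDa] / 60,

since 1 kDa = 1 mg/umol.  Fitting is unweighted nonlinear least
squares of v = V_max * S / (K_M + S), started from a Hanes-Woolf
linearization (S/v regressed on S), with both parameters bounded
positive.  Identifiability is checked explicitly: a design that never
leaves saturation (or never approaches it) cannot pin down K_M and
raises :class:`FitError` rather than returning a spurious estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import DimensionError, FitError

DEFAULT_MW_KDA = 73.7  # synthetic reference: kojibiose hydrolase-sized monomer
DEFAULT_ENZYME_MG_PER_ML = 0.005  # 5 ug/mL assay concentration
#: nine-point dilution series spanning 0.25-10 mM
DEFAULT_CONCENTRATIONS_MM = (0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 3.5, 5.0, 10.0)


@dataclass
class RateDataset:
    """Initial-rate measurements for one enzyme/substrate pair."""

    concentrations_mM: np.ndarray
    rates_U_per_mg: np.ndarray
    enzyme_mg_per_ml: float = DEFAULT_ENZYME_MG_PER_ML
    mw_kda: float = DEFAULT_MW_KDA

    def __post_init__(self):
        s = np.asarray(self.concentrations_mM, dtype=float)
        v = np.asarray(self.rates_U_per_mg, dtype=float)
        if s.shape != v.shape:
            raise DimensionError("concentration and rate vectors differ in length")
        if np.any(s <= 0):
            raise ValueError("substrate concentrations must be strictly positive")
        if np.any(v < 0):
            raise ValueError("rates must be non-negative")
        if self.mw_kda <= 0 or self.enzyme_mg_per_ml <= 0:
            raise ValueError("enzyme concentration and MW must be positive")
        object.__setattr__(self, "concentrations_mM", s)
        object.__setattr__(self, "rates_U_per_mg", v)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "concentration_mM": self.concentrations_mM,
                "rate_U_per_mg": self.rates_U_per_mg,
            }
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(
        cls,
        path: str | Path,
        enzyme_mg_per_ml: float = DEFAULT_ENZYME_MG_PER_ML,
        mw_kda: float = DEFAULT_MW_KDA,
    ) -> "RateDataset":
        df = pd.read_csv(path, sep="\t")
        return cls(
            concentrations_mM=df["concentration_mM"].to_numpy(),
            rates_U_per_mg=df["rate_U_per_mg"].to_numpy(),
            enzyme_mg_per_ml=enzyme_mg_per_ml,
            mw_kda=mw_kda,
        )


@dataclass
class MMFit:
    """Fitted Michaelis-Menten parameters and derived quantities."""

    km_mM: float
    vmax_U_per_mg: float
    kcat_per_s: float
    se_km: float
    se_vmax: float
    se_kcat: float
    kcat_over_km: float  # mM^-1 s^-1
    n_points: int
    converged: bool = True


def _mm(s, vmax, km):
    return vmax * s / (km + s)


def kcat_from_vmax(vmax_U_per_mg: float, mw_kda: float) -> float:
    return vmax_U_per_mg * mw_kda / 60.0


def fit_michaelis_menten(data: RateDataset) -> MMFit:
    """Unweighted least-squares Michaelis-Menten fit.

    Requires at least 4 distinct concentrations.  Raises
    :class:`FitError` when the optimizer fails or when K_M is
    unidentifiable from the design (rates flat across the measured
    range, or K_M pushed far outside it with an unbounded standard
    error).
    """
    s = data.concentrations_mM
    v = data.rates_U_per_mg
    if len(np.unique(s)) < 4:
        raise FitError("need at least 4 distinct substrate concentrations")
    if np.allclose(v, 0):
        raise FitError("all rates are zero; nothing to fit")

    # Hanes-Woolf start: S/v = S/Vmax + Km/Vmax, linear in S
    ok = v > 0
    slope, intercept = np.polyfit(s[ok], s[ok] / v[ok], 1)
    vmax0 = 1.0 / slope if slope > 0 else float(v.max())
    km0 = intercept * vmax0 if intercept > 0 and slope > 0 else float(np.median(s))
    vmax0 = max(vmax0, 1e-12)
    km0 = min(max(km0, 1e-9), 1e6)

    try:
        popt, pcov = curve_fit(
            _mm, s, v, p0=(vmax0, km0),
            bounds=((1e-12, 1e-12), (np.inf, np.inf)),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise FitError(f"Michaelis-Menten fit did not converge: {exc}") from exc
    vmax, km = float(popt[0]), float(popt[1])
    perr = np.sqrt(np.diag(pcov))
    se_vmax, se_km = float(perr[0]), float(perr[1])

    # identifiability: Km far outside the measured range (above it the
    # curve never bends, below it every point is saturated), or a
    # standard error swamping the estimate, means the design carries no
    # information on Km
    if (
        not np.isfinite(se_km)
        or km > 100 * s.max()
        or km < s.min() / 100
        or (se_km > 10 * km and se_km > s.max())
    ):
        raise FitError(
            f"K_M is not identifiable from this design "
            f"(K_M={km:.3g} mM, SE={se_km:.3g}, max S={s.max():.3g} mM)"
        )
    kcat = kcat_from_vmax(vmax, data.mw_kda)
    se_kcat = kcat_from_vmax(se_vmax, data.mw_kda)
    return MMFit(
        km_mM=km,
        vmax_U_per_mg=vmax,
        kcat_per_s=kcat,
        se_km=se_km,
        se_vmax=se_vmax,
        se_kcat=se_kcat,
        kcat_over_km=kcat / km,
        n_points=len(s),
    )


def round_sig(x: float, sig: int = 2) -> float:
    if x == 0:
        return 0.0
    from math import floor, log10
    return round(x, -int(floor(log10(abs(x)))) + (sig - 1))


def catalytic_efficiency(fit: MMFit) -> tuple[float, float]:
    """(raw, 2-significant-figure) catalytic efficiency in mM^-1 s^-1."""
    raw = fit.kcat_per_s / fit.km_mM
    return raw, round_sig(raw, 2)
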