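"""Core FRET algebra.

Distance <-> efficiency conversion, averaging-regime conversions between the
different distance observables (mean interdye distance ``<R_DA>``, FRET-averaged
distance ``<R_DA>_E`` and mean-position distance ``R_mp``), the corrected
proximity ratio used in plate-reader titrations, and sigmoidal fitting of
salt-titration curves.

All distances are in Angstrom, concentrations in mM NaCl, lifetimes in ns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import lmfit

__all__ = [
    "FretPair",
    "CorrectionSet",
    "efficiency_from_distance",
    "distance_from_efficiency",
    "DistancePolynomial",
    "MEAN_TO_FRET_AVERAGED",
    "mean_to_fret_averaged",
    "proximity_ratio",
    "normalize_titration",
    "TitrationFit",
    "fit_titration",
]


@dataclass(frozen=True)
class FretPair:
    """A donor/acceptor dye pair.

    Parameters
    ----------
    R0 : float
        Foerster radius in Angstrom (e.g. 55.6 for Alexa488-Alexa594,
        52.0 for Alexa488-Cy5).
    kappa2 : float
        Orientation factor; 2/3 for the isotropic dynamic average.
    tau_D0 : float
        Donor-only fluorescence lifetime in ns.
    """

    R0: float
    kappa2: float = 2.0 / 3.0
    tau_D0: float = 4.0

    def __post_init__(self) -> None:
        if self.R0 <= 0:
            raise ValueError("R0 must be positive")
        if self.tau_D0 <= 0:
            raise ValueError("tau_D0 must be positive")


@dataclass(frozen=True)
class CorrectionSet:
    """Intensity correction factors for FRET observables.

    gamma   -- detection-efficiency / quantum-yield ratio (red over green).
    alpha   -- spectral crosstalk: fraction of donor fluorescence detected in
               the red channel ("leakage").
    bg_green, bg_red -- background count rates in kHz per channel.
    de      -- direct acceptor excitation expressed as a fraction of the
               acceptor-excitation intensity to subtract from the red signal.
    """

    gamma: float = 1.0
    alpha: float = 0.0
    bg_green: float = 0.0
    bg_red: float = 0.0
    de: float = 0.0

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if not 0.0 <= self.alpha < 1.0:
            raise ValueError("alpha must be in [0, 1)")


def efficiency_from_distance(R, pair: FretPair):
    """FRET efficiency E = 1 / (1 + (R/R0)^6) for distance(s) ``R`` in A."""
    R = np.asarray(R, dtype=float)
    if np.any(R <= 0):
        raise ValueError("distance must be positive")
    out = 1.0 / (1.0 + (R / pair.R0) ** 6)
    return out if out.ndim else float(out)


def distance_from_efficiency(E, pair: FretPair):
    """Invert the Foerster relation: R = R0 * (1/E - 1)^(1/6).

    Exact algebraic inverse of :func:`efficiency_from_distance`; E must lie
    strictly inside (0, 1).
    """
    E = np.asarray(E, dtype=float)
    if np.any(E <= 0.0) or np.any(E >= 1.0):
        raise ValueError("efficiency must be strictly inside (0, 1)")
    out = pair.R0 * (1.0 / E - 1.0) ** (1.0 / 6.0)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class DistancePolynomial:
    """Cubic conversion between distance observables.

    Evaluates ``c0 + c1 r + c2 r^2 + c3 r^3``.  The default instance
    :data:`MEAN_TO_FRET_AVERAGED` converts the species-averaged mean interdye
    distance ``<R_DA>`` into the FRET-averaged distance ``<R_DA>_E``; other
    coefficient sets (e.g. R_mp -> <R_DA>_E) plug into the same mechanism.
    """

    coefficients: tuple = (15.3230, 0.592830, 0.00175370, -0.0000032013)
    valid_range: tuple = (20.0, 120.0)
    name: str = "mean_to_fret_averaged"

    def __call__(self, r, strict: bool = False):
        r = np.asarray(r, dtype=float)
        lo, hi = self.valid_range
        outside = (r < lo) | (r > hi)
        if np.any(outside):
            import warnings

            msg = (
                f"{self.name}: input outside calibrated range "
                f"[{lo}, {hi}] A; extrapolating"
            )
            if strict:
                raise ValueError(msg)
            warnings.warn(msg, stacklevel=2)
        c0, c1, c2, c3 = self.coefficients
        out = c0 + c1 * r + c2 * r**2 + c3 * r**3
        return out if out.ndim else float(out)


MEAN_TO_FRET_AVERAGED = DistancePolynomial()


def mean_to_fret_averaged(r_mean, strict: bool = False):
    """Convert ``<R_DA>`` (A) to ``<R_DA>_E`` (A) with the calibrated cubic."""
    return MEAN_TO_FRET_AVERAGED(r_mean, strict=strict)


def proximity_ratio(i_a_dex, i_d_dex, i_a_aex=0.0, corr: CorrectionSet | None = None):
    """Corrected proximity ratio P from plate-reader intensities.

    ``P = (I_A^Dex)_corr / ((I_D^Dex)_corr + (I_A^Dex)_corr)`` where the
    corrected intensities account for background (already-integrated counts;
    here the ``bg_*`` rates are interpreted as constant offsets in the same
    units as the intensities), donor leakage into the acceptor channel
    (``alpha``) and direct acceptor excitation estimated from the
    acceptor-excitation scan (``de * I_A^Aex``).
    """
    if corr is None:
        corr = CorrectionSet()
    i_a_dex = np.asarray(i_a_dex, dtype=float)
    i_d_dex = np.asarray(i_d_dex, dtype=float)
    i_a_aex = np.asarray(i_a_aex, dtype=float)
    if np.any(i_a_dex < 0) or np.any(i_d_dex < 0) or np.any(i_a_aex < 0):
        raise ValueError("intensities must be non-negative")
    f_d = i_d_dex - corr.bg_green
    f_a = i_a_dex - corr.bg_red - corr.alpha * f_d - corr.de * i_a_aex
    f_a = f_a / corr.gamma
    denom = f_d + f_a
    if np.any(denom <= 0):
        raise ValueError("corrected total intensity is non-positive; P undefined")
    out = f_a / denom
    return out if out.ndim else float(out)


def normalize_titration(concentration_mM, P, ref_concentration: float = 100.0):
    """Scale a titration curve to its value at the reference salt concentration.

    The curve is divided by the proximity ratio at the concentration closest
    to ``ref_concentration`` (100 mM NaCl by convention), mapping the fully
    assembled plateau to ~1.
    """
    c = np.asarray(concentration_mM, dtype=float)
    P = np.asarray(P, dtype=float)
    ref = P[np.argmin(np.abs(c - ref_concentration))]
    if ref <= 0:
        raise ValueError("reference proximity ratio must be positive")
    return P / ref


@dataclass
class TitrationFit:
    """Result of a sigmoidal salt-titration fit.

    c_half/b are the transition midpoint and logistic half-width in mM;
    plateaus are the high- and low-salt asymptotes of the proximity ratio.
    """

    c_half: float
    c_half_stderr: float
    b: float
    b_stderr: float
    p_hi: float
    p_lo: float
    chi2_red: float
    residuals: np.ndarray = field(repr=False)
    lmfit_result: lmfit.minimizer.MinimizerResult = field(repr=False, default=None)

    def __call__(self, c):
        c = np.asarray(c, dtype=float)
        return self.p_lo + (self.p_hi - self.p_lo) / (
            1.0 + np.exp((c - self.c_half) / self.b)
        )

    def summary(self) -> str:
        lines = [
            "Sigmoidal titration fit",
            "-" * 38,
            f"c_1/2      {self.c_half:10.2f} +/- {self.c_half_stderr:.2f} mM",
            f"b          {self.b:10.2f} +/- {self.b_stderr:.2f} mM",
            f"P(high)    {self.p_hi:10.4f}",
            f"P(low)     {self.p_lo:10.4f}",
            f"chi2_red   {self.chi2_red:10.3f}",
        ]
        return "\n".join(lines)


def fit_titration(
    concentration_mM,
    P,
    se=None,
    c_half0: float | None = None,
    b0: float = 120.0,
) -> TitrationFit:
    """Weighted least-squares fit of a logistic decay to a salt titration.

    Model: ``P(c) = P_lo + (P_hi - P_lo) / (1 + exp((c - c_1/2) / b))`` with
    b > 0, so P decreases with added salt.  Requires at least 5 points and a
    resolvable transition (the fitted amplitude must exceed 3x its standard
    error, otherwise the curve is flat within noise and the fit refuses).
    """
    c = np.asarray(concentration_mM, dtype=float)
    P = np.asarray(P, dtype=float)
    if c.ndim != 1 or c.size < 5:
        raise ValueError("need at least 5 titration points")
    if np.any(np.diff(c) <= 0):
        raise ValueError("concentrations must be strictly increasing")
    if se is None:
        weights = np.ones_like(P)
    else:
        se = np.asarray(se, dtype=float)
        weights = 1.0 / np.where(se > 0, se, np.nanmin(se[se > 0]))

    params = lmfit.Parameters()
    params.add("c_half", value=c_half0 if c_half0 is not None else float(np.median(c)))
    params.add("b", value=b0, min=1e-3)
    params.add("p_hi", value=float(np.max(P)))
    params.add("p_lo", value=float(np.min(P)))

    def resid(pars):
        v = pars.valuesdict()
        model = v["p_lo"] + (v["p_hi"] - v["p_lo"]) / (
            1.0 + np.exp((c - v["c_half"]) / v["b"])
        )
        return (P - model) * weights

    result = lmfit.minimize(resid, params, method="leastsq")
    if not result.success:
        raise RuntimeError(
            "titration fit did not converge; residuals: "
            f"{np.asarray(result.residual)}"
        )
    v = result.params
    amplitude = v["p_hi"].value - v["p_lo"].value
    amp_err = np.sqrt(
        (v["p_hi"].stderr or 0.0) ** 2 + (v["p_lo"].stderr or 0.0) ** 2
    )
    if amp_err == 0.0:
        amp_err = float(np.std(P - np.mean(P))) or 1e-12
    if abs(amplitude) < 3.0 * amp_err or v["c_half"].stderr is None:
        raise RuntimeError(
            "no resolvable transition in the sampled concentration range "
            f"(amplitude {amplitude:.3g} +/- {amp_err:.3g})"
        )
    ndata = c.size
    nfree = max(ndata - result.nvarys, 1)
    return TitrationFit(
        c_half=float(v["c_half"].value),
        c_half_stderr=float(v["c_half"].stderr or np.nan),
        b=float(v["b"].value),
        b_stderr=float(v["b"].stderr or np.nan),
        p_hi=float(v["p_hi"].value),
        p_lo=float(v["p_lo"].value),
        chi2_red=float(np.sum(np.asarray(result.residual) ** 2) / nfree),
        residuals=np.asarray(result.residual),
        lmfit_result=result,
    )
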