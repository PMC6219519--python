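"""Nucleosome disassembly kinetics.

The microsecond opening of the dimer:tetramer interface is modelled as fast
two-state exchange between a closed (mid-FRET, MF*) and an open (high-FRET,
HF) conformation, present in parallel in the octasome O (both H2A-H2B dimers
bound) and in the hexasome H (one dimer lost).  The slow release/uptake of a
free H2A-H2B dimer couples the two fast equilibria:

    O_st  <=>  O_cl  <=>  O_op
                ..fast..   |
                           |  dimer off/on (K_dis)
                           v
               H_cl  <=>  H_op   ( -> tetrasome, very slow, outside the
                ..fast..           steady-state solved here)

The module provides the closed-form identities (relaxation time, equilibrium
constant, mean dynamic efficiency, free-dimer bookkeeping), the steady-state
forward model for the concentration dependence of the apparent exchange
rates, and weighted global fits of concentration and salt series.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import lmfit

from .fret import FretPair, efficiency_from_distance

__all__ = [
    "FourStateScheme",
    "TABLE_150MM",
    "SaltResponse",
    "relaxation_time",
    "equilibrium_constant",
    "mean_dyn_efficiency",
    "free_dimer_concentration",
    "steady_state",
    "apparent_exchange",
    "ConcentrationSeriesResults",
    "fit_concentration_series",
    "SaltSeriesResults",
    "fit_salt_series",
]

STATES = ("O_st", "O_cl", "O_op", "H_cl", "H_op")


def relaxation_time(k_f: float, k_b: float) -> float:
    """Two-state relaxation time t_R = 1 / (k_f + k_b) (units of 1/k)."""
    if k_f < 0 or k_b < 0:
        raise ValueError("rates must be non-negative")
    if k_f + k_b == 0:
        raise ValueError("both rates zero: relaxation time undefined")
    return 1.0 / (k_f + k_b)


def equilibrium_constant(k_f: float, k_b: float) -> float:
    """K = k_f / k_b = x_open / x_closed for a reversible two-state step."""
    if k_b <= 0:
        raise ValueError("backward rate must be positive")
    return k_f / k_b


def mean_dyn_efficiency(x_closed: float, x_open: float, e_closed: float, e_open: float) -> float:
    """Population-weighted mean FRET efficiency of the exchanging pair."""
    if not np.isclose(x_closed + x_open, 1.0):
        raise ValueError("state fractions must sum to 1")
    return x_closed * e_closed + x_open * e_open


def free_dimer_concentration(c_total: float, x_hexasome: float, x_tetrasome: float = 0.0) -> float:
    """Free H2A-H2B concentration from mass balance.

    One dimer is released per hexasome and two per tetrasome, so
    ``[D] = c_total * (x_H + 2 x_T)``.  Concentrations in molar.
    """
    if x_hexasome < 0 or x_tetrasome < 0 or x_hexasome + x_tetrasome > 1 + 1e-12:
        raise ValueError("invalid species fractions")
    return c_total * (x_hexasome + 2.0 * x_tetrasome)


@dataclass(frozen=True)
class FourStateScheme:
    """Rate constants of the stepwise disassembly scheme.

    Units: first-order rates in s^-1, the dimer re-binding rate ``k_H_O`` in
    M^-1 s^-1 and the dissociation constant ``K_dis_OH`` in M.  Entries that
    the experiment only bounds (steps I, III and V) default to values
    compatible with the published bounds; fits treat them as box constraints.
    """

    # step I: static <-> closed octasome (slow, ms and above)
    k_Ost_Ocl: float = 0.019e3
    k_Ocl_Ost: float = 0.317e3
    # step II: closed <-> open octasome (tens of microseconds)
    k_Ocl_Oop: float = 13e3
    k_Oop_Ocl: float = 8e3
    # step III: dimer release / uptake coupling O and H
    k_O_H: float = 4e-3
    k_H_O: float = 1e8
    # step IV: closed <-> open hexasome
    k_Hcl_Hop: float = 54e3
    k_Hop_Hcl: float = 17e3
    # step V: hexasome -> tetrasome (excluded from the steady state)
    k_Hop_T: float = 1.8e-5
    k_T_Hop: float = 1e7

    def __post_init__(self):
        for name, v in self.__dict__.items():
            if v < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def K_st_cl(self) -> float:
        return equilibrium_constant(self.k_Ost_Ocl, self.k_Ocl_Ost)

    @property
    def K_cl_op_O(self) -> float:
        return equilibrium_constant(self.k_Ocl_Oop, self.k_Oop_Ocl)

    @property
    def K_cl_op_H(self) -> float:
        return equilibrium_constant(self.k_Hcl_Hop, self.k_Hop_Hcl)

    @property
    def K_dis_OH(self) -> float:
        """Dimer dissociation constant [H][D]/[O_op] in molar."""
        if self.k_H_O <= 0:
            raise ValueError("k_H_O is zero: K_dis undefined")
        return self.k_O_H / self.k_H_O


#: Parameter set at 150 mM NaCl.  Point values where directly determined;
#: the bounded entries (steps I, III, V) are stored alongside as box bounds.
TABLE_150MM = FourStateScheme(
    k_Ost_Ocl=0.019e3,   # < 0.02e3 s^-1
    k_Ocl_Ost=0.317e3,   # < 0.32e3 s^-1 (ratio fixed by K_st/cl = 0.06)
    k_Ocl_Oop=13e3,
    k_Oop_Ocl=8e3,
    k_O_H=3.9e-3 * 1.0,  # consistent with K_dis = 39 pM at k_H_O = 1e8
    k_H_O=1e8,           # > 1e8 M^-1 s^-1
    k_Hcl_Hop=54e3,
    k_Hop_Hcl=17e3,
    k_Hop_T=1.8e-5,
    k_T_Hop=1e7,
)

#: Bounds for entries Table-style experiments can only bound, as
#: (lower, upper) in the same units as the scheme fields.
TABLE_150MM_BOUNDS = {
    "k_Ost_Ocl": (0.0, 0.02e3),
    "k_Ocl_Ost": (0.0, 0.32e3),
    "k_O_H": (4e-3, np.inf),
    "k_H_O": (1e8, np.inf),
    "k_Hop_T": (0.0, 1.8e-5),
    "k_T_Hop": (0.0, 1e7),
}


def steady_state(scheme: FourStateScheme, c_total: float, tol: float = 1e-12, max_iter: int = 10_000):
    """Equilibrium populations of {O_st, O_cl, O_op, H_cl, H_op}.

    The chain is reversible, so the populations follow detailed balance with
    relative Boltzmann weights; the dimer-release step couples octasome and
    hexasome weights through the free-dimer concentration, which is solved
    self-consistently by damped fixed-point iteration:

        [D] = c_total * x_H,   w(H_cl) = w(O_op) * K_dis / [D].

    Returns ``(fractions: dict, free_dimer: float)``.
    """
    if c_total <= 0:
        raise ValueError("total nucleosome concentration must be positive")
    if scheme.k_Ocl_Ost <= 0 or scheme.k_Oop_Ocl <= 0 or scheme.k_Hop_Hcl <= 0:
        raise ValueError("backward rates of reversible steps must be positive")
    k1 = scheme.K_st_cl
    k2 = scheme.K_cl_op_O
    k4 = scheme.K_cl_op_H
    if scheme.k_H_O == 0:
        # irreversible dimer loss: all nucleosomes end as hexasomes
        x_h = 1.0 if scheme.k_O_H > 0 else 0.0
        if x_h:
            w = np.array([0.0, 0.0, 0.0, 1.0, k4])
        else:
            w = np.array([1.0, k1, k1 * k2, 0.0, 0.0])
        w /= w.sum()
        frac = dict(zip(STATES, w))
        return frac, c_total * (w[3] + w[4])
    kdis = scheme.K_dis_OH

    x_h = 0.5
    for _ in range(max_iter):
        d = max(c_total * x_h, 1e-300)
        w_o = np.array([1.0, k1, k1 * k2])
        w_h = w_o[2] * kdis / d * np.array([1.0, k4])
        total = w_o.sum() + w_h.sum()
        x_h_new = w_h.sum() / total
        if abs(x_h_new - x_h) < tol:
            x_h = x_h_new
            break
        x_h = 0.5 * (x_h + x_h_new)
    else:
        raise RuntimeError("free-dimer fixed point did not converge")
    d = c_total * x_h
    w = np.concatenate([w_o, w_o[2] * kdis / max(d, 1e-300) * np.array([1.0, k4])])
    w /= w.sum()
    frac = dict(zip(STATES, w))
    return frac, d


def apparent_exchange(
    scheme: FourStateScheme,
    c_total: float,
    pair: FretPair | None = None,
    r_closed: float = 61.2,
    r_open: float = 46.7,
):
    """Apparent MF*<->HF exchange observables at total concentration ``c_total``.

    The dynamic subpopulation comprises {O_cl, O_op, H_cl, H_op}.  With equal
    brightness of the exchanging states the apparent forward (opening) rate
    is the closed-state-population-weighted mean of the two opening rate
    constants; the backward rate is weighted over the open states.  The mean
    dynamic efficiency uses the closed/open state efficiencies computed from
    ``r_closed``/``r_open`` (A).

    Returns ``(k_app_forward, k_app_backward, mean_E_dyn)`` in s^-1.
    """
    if pair is None:
        pair = FretPair(R0=55.6, tau_D0=4.0)
    frac, _ = steady_state(scheme, c_total)
    x_ocl, x_oop = frac["O_cl"], frac["O_op"]
    x_hcl, x_hop = frac["H_cl"], frac["H_op"]
    x_cl = x_ocl + x_hcl
    x_op = x_oop + x_hop
    if x_cl <= 0 or x_op <= 0:
        raise ValueError("degenerate scheme: no dynamic subpopulation")
    k_f = (x_ocl * scheme.k_Ocl_Oop + x_hcl * scheme.k_Hcl_Hop) / x_cl
    k_b = (x_oop * scheme.k_Oop_Ocl + x_hop * scheme.k_Hop_Hcl) / x_op
    e_cl = efficiency_from_distance(r_closed, pair)
    e_op = efficiency_from_distance(r_open, pair)
    x_dyn = x_cl + x_op
    e_dyn = (x_cl * e_cl + x_op * e_op) / x_dyn
    return k_f, k_b, e_dyn


@dataclass
class ConcentrationSeriesResults:
    """Fitted subset of the four-state scheme from a concentration series."""

    scheme: FourStateScheme
    stderr: dict
    chi2_red: float
    lmfit_result: lmfit.minimizer.MinimizerResult

    def summary(self) -> str:
        lines = ["Four-state concentration-series fit", "-" * 44]
        for name in ("k_Ocl_Oop", "k_Oop_Ocl", "k_Hcl_Hop", "k_Hop_Hcl"):
            err = self.stderr.get(name, np.nan)
            lines.append(
                f"{name:12s} {getattr(self.scheme, name)/1e3:9.2f} +/- "
                f"{(err or np.nan)/1e3:7.2f} x10^3 s^-1"
            )
        kd = self.scheme.K_dis_OH
        lines.append(f"K_dis        {kd*1e12:9.1f} pM")
        lines.append(f"chi2_red     {self.chi2_red:9.3f}")
        return "\n".join(lines)


def fit_concentration_series(
    c_total,
    k_app_f,
    k_app_b,
    e_dyn,
    errors=None,
    start: FourStateScheme | None = None,
    pair: FretPair | None = None,
    r_closed: float = 61.2,
    r_open: float = 46.7,
    vary_kdis: bool = True,
) -> ConcentrationSeriesResults:
    """Weighted global fit of the four-state model to a concentration series.

    Observations are ``(k_app_forward, k_app_backward, <E>_dyn)`` at each
    total nucleosome concentration (molar).  Free parameters are the two
    opening/closing rate pairs and the dimer dissociation constant; the slow
    step-I rates are kept at their bounded values.  ``errors`` may be a tuple
    of per-observable error arrays; defaults to 5% relative errors.

    Raises if the requested parameter set is structurally unidentifiable
    (``k_H_O = 0`` decouples the series from K_dis).
    """
    c_total = np.asarray(c_total, dtype=float)
    if c_total.size < 4:
        raise ValueError("need at least 4 concentrations")
    k_app_f = np.asarray(k_app_f, dtype=float)
    k_app_b = np.asarray(k_app_b, dtype=float)
    e_dyn = np.asarray(e_dyn, dtype=float)
    if start is None:
        start = TABLE_150MM
    if start.k_H_O == 0:
        raise ValueError(
            "k_H_O = 0: apparent rates are independent of concentration, "
            "K_dis_OH is unidentifiable"
        )
    if vary_kdis and np.ptp(k_app_f) < 1e-9 * np.max(k_app_f):
        raise ValueError(
            "apparent rates show no concentration dependence; "
            "K_dis_OH is unidentifiable"
        )
    if errors is None:
        errors = (0.05 * k_app_f, 0.05 * k_app_b, 0.05 * np.abs(e_dyn) + 1e-3)
    err_f, err_b, err_e = (np.asarray(e, dtype=float) for e in errors)

    params = lmfit.Parameters()
    params.add("k_Ocl_Oop", value=start.k_Ocl_Oop, min=1e2, max=1e6)
    params.add("k_Oop_Ocl", value=start.k_Oop_Ocl, min=1e2, max=1e6)
    params.add("k_Hcl_Hop", value=start.k_Hcl_Hop, min=1e2, max=1e6)
    params.add("k_Hop_Hcl", value=start.k_Hop_Hcl, min=1e2, max=1e6)
    params.add("log10_kdis", value=np.log10(start.K_dis_OH), min=-14, max=-6,
               vary=vary_kdis)

    def build(pars):
        v = pars.valuesdict()
        return replace(
            start,
            k_Ocl_Oop=v["k_Ocl_Oop"],
            k_Oop_Ocl=v["k_Oop_Ocl"],
            k_Hcl_Hop=v["k_Hcl_Hop"],
            k_Hop_Hcl=v["k_Hop_Hcl"],
            k_O_H=10.0 ** v["log10_kdis"] * start.k_H_O,
        )

    def resid(pars):
        scheme = build(pars)
        model = np.array(
            [apparent_exchange(scheme, c, pair, r_closed, r_open) for c in c_total]
        )
        return np.concatenate(
            [
                (model[:, 0] - k_app_f) / err_f,
                (model[:, 1] - k_app_b) / err_b,
                (model[:, 2] - e_dyn) / err_e,
            ]
        )

    result = lmfit.minimize(resid, params, method="leastsq")
    scheme = build(result.params)
    stderr = {}
    for lm_name, name in [
        ("k_Ocl_Oop", "k_Ocl_Oop"),
        ("k_Oop_Ocl", "k_Oop_Ocl"),
        ("k_Hcl_Hop", "k_Hcl_Hop"),
        ("k_Hop_Hcl", "k_Hop_Hcl"),
    ]:
        stderr[name] = result.params[lm_name].stderr
    ndata = 3 * c_total.size
    chi2_red = float(np.sum(result.residual**2) / max(ndata - result.nvarys, 1))
    return ConcentrationSeriesResults(scheme, stderr, chi2_red, result)


@dataclass(frozen=True)
class SaltResponse:
    """Sigmoidal NaCl dependence of one rate or fraction."""

    hi: float
    lo: float
    c_half: float
    b: float

    def __call__(self, c):
        c = np.asarray(c, dtype=float)
        out = self.lo + (self.hi - self.lo) / (1.0 + np.exp((c - self.c_half) / self.b))
        return out if out.ndim else float(out)


def constrained_fractions(x_lf, x_mf, K_cl_op):
    """Species fractions of the exchanging pair given the static fractions.

    The dynamic population is what is left after the static LF and MF
    species; the closed/open equilibrium constant splits it exactly:
    ``x_MF* = (1 - x_LF - x_MF) / (1 + K)`` and
    ``x_HF  = (1 - x_LF - x_MF) * K / (1 + K)``.
    """
    x_lf = np.asarray(x_lf, dtype=float)
    x_mf = np.asarray(x_mf, dtype=float)
    K = np.asarray(K_cl_op, dtype=float)
    dyn = 1.0 - x_lf - x_mf
    return dyn / (1.0 + K), dyn * K / (1.0 + K)


@dataclass
class SaltSeriesResults:
    """Joint sigmoidal fit of the exchange rates across a salt series."""

    forward: SaltResponse
    backward: SaltResponse
    c_half_stderr: float
    chi2_red: float
    lmfit_result: lmfit.minimizer.MinimizerResult

    @property
    def c_half(self) -> float:
        return self.forward.c_half

    def equilibrium_constant(self, c):
        return self.forward(c) / self.backward(c)

    def fractions(self, c, x_lf, x_mf):
        return constrained_fractions(x_lf, x_mf, self.equilibrium_constant(c))

    def summary(self) -> str:
        return "\n".join(
            [
                "Salt-series global fit (shared c_1/2)",
                "-" * 44,
                f"c_1/2        {self.c_half:9.1f} +/- {self.c_half_stderr:.1f} mM",
                f"b (forward)  {self.forward.b:9.1f} mM",
                f"b (backward) {self.backward.b:9.1f} mM",
                f"k_f plateaus {self.forward.hi/1e3:.1f} -> {self.forward.lo/1e3:.1f} x10^3 s^-1",
                f"k_b plateaus {self.backward.hi/1e3:.1f} -> {self.backward.lo/1e3:.1f} x10^3 s^-1",
                f"chi2_red     {self.chi2_red:9.3f}",
            ]
        )


def fit_salt_series(
    concentration_mM,
    k_forward,
    k_backward,
    err_forward=None,
    err_backward=None,
) -> SaltSeriesResults:
    """Global sigmoid fit of forward/backward exchange rates vs NaCl.

    Both rates share the transition midpoint ``c_1/2`` (the experiment
    reports a single global midpoint for the rate pair) but have individual
    plateaus and half-widths.  The forward (opening) rate decreases with
    salt, the backward rate increases: the backward response uses the
    mirrored sigmoid so both are parameterized with b > 0.
    """
    c = np.asarray(concentration_mM, dtype=float)
    kf = np.asarray(k_forward, dtype=float)
    kb = np.asarray(k_backward, dtype=float)
    if c.size < 5:
        raise ValueError("need at least 5 salt points")
    wf = 1.0 / np.asarray(err_forward, dtype=float) if err_forward is not None else np.ones_like(kf)
    wb = 1.0 / np.asarray(err_backward, dtype=float) if err_backward is not None else np.ones_like(kb)

    params = lmfit.Parameters()
    params.add("c_half", value=float(np.median(c)))
    params.add("b_f", value=120.0, min=1.0)
    params.add("b_b", value=120.0, min=1.0)
    params.add("kf_hi", value=float(np.max(kf)))
    params.add("kf_lo", value=float(np.min(kf)), min=0.0)
    params.add("kb_lo", value=float(np.min(kb)), min=0.0)
    params.add("kb_hi", value=float(np.max(kb)))

    def resid(pars):
        v = pars.valuesdict()
        mf = v["kf_lo"] + (v["kf_hi"] - v["kf_lo"]) / (
            1.0 + np.exp((c - v["c_half"]) / v["b_f"])
        )
        mb = v["kb_lo"] + (v["kb_hi"] - v["kb_lo"]) / (
            1.0 + np.exp(-(c - v["c_half"]) / v["b_b"])
        )
        return np.concatenate([(kf - mf) * wf, (kb - mb) * wb])

    result = lmfit.minimize(resid, params, method="leastsq")
    if not result.success:
        raise RuntimeError("salt-series fit did not converge")
    v = result.params
    forward = SaltResponse(hi=v["kf_hi"].value, lo=v["kf_lo"].value,
                           c_half=v["c_half"].value, b=v["b_f"].value)
    # backward increases with salt: same logistic with plateaus swapped
    # (hi/lo are the low-salt/high-salt plateaus respectively)
    backward = SaltResponse(hi=v["kb_lo"].value, lo=v["kb_hi"].value,
                            c_half=v["c_half"].value, b=v["b_b"].value)
    ndata = 2 * c.size
    chi2_red = float(np.sum(result.residual**2) / max(ndata - result.nvarys, 1))
    return SaltSeriesResults(
        forward=forward,
        backward=backward,
        c_half_stderr=float(v["c_half"].stderr or np.nan),
        chi2_red=chi2_red,
        lmfit_result=result,
    )
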