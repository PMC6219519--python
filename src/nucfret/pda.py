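"""Dynamic photon distribution analysis (dynPDA).

Photon-count histograms of fixed time windows carry more information than
their mean: the shape of the proxy-efficiency histogram encodes shot noise,
background, static heterogeneity and -- through the window-averaged
occupancy of an exchanging pair -- microsecond rate constants.  This module
computes the analytic photon distributions for static Gaussian-distance
species and for a two-state exchanging pair, and fits multi-window
histograms to recover species fractions, interdye distances and the
forward/backward rate constants.

The two-state occupancy-time distribution over a window of length T has two
atoms (paths without any transition) and a continuous part expressible with
modified Bessel functions; the window's apparent efficiency is the
occupancy-weighted average of the two state efficiencies, and the photon
split of each window is conditionally binomial, convolved with the Poisson
backgrounds of both spectral channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import lmfit
from scipy.special import gammaln, ive
from scipy.stats import poisson

from .fret import FretPair, CorrectionSet, efficiency_from_distance
from .simulate import ExchangingPair, FretSpecies, PhotonStream
from .bursts import select_bursts

__all__ = [
    "OccupancyDensity",
    "occupancy_density",
    "PdaHistogram",
    "make_histograms",
    "static_species_pmf",
    "dynamic_pmf",
    "DynamicPDA",
    "DynamicPDAResults",
]


# --------------------------------------------------------------------------
# occupancy-time distribution of a stationary two-state Markov process
# --------------------------------------------------------------------------

@dataclass
class OccupancyDensity:
    """Distribution of the fractional time x spent in state_a over a window.

    Mixed distribution: ``atom_a`` at x = 1 (no transition out of a),
    ``atom_b`` at x = 0, and a continuous density on (0, 1) sampled on
    ``grid`` with trapezoid ``weights`` normalized to 1 - atom_a - atom_b.
    """

    k_ab: float
    k_ba: float
    T: float
    atom_a: float
    atom_b: float
    grid: np.ndarray
    density: np.ndarray
    weights: np.ndarray

    @property
    def p_a(self) -> float:
        return self.k_ba / (self.k_ab + self.k_ba)

    def mean(self) -> float:
        """Closed form: E[x] = p_a (stationarity)."""
        return self.p_a

    def var(self) -> float:
        """Closed form from the exponential occupancy autocovariance."""
        k = self.k_ab + self.k_ba
        pa = self.p_a
        vT1 = 2.0 * pa * (1 - pa) * (self.T / k - (1.0 - np.exp(-k * self.T)) / k**2)
        return vT1 / self.T**2

    def numeric_moments(self):
        m1 = self.atom_a + np.sum(self.weights * self.grid)
        m2 = self.atom_a + np.sum(self.weights * self.grid**2)
        return m1, m2 - m1**2

    def total_mass(self) -> float:
        return self.atom_a + self.atom_b + float(np.sum(self.weights))


def _occupancy_logdensity(x, k1, k2, T):
    """log of the continuous occupancy density g(x), x = T1/T in (0, 1)."""
    t1 = x * T
    t2 = (1.0 - x) * T
    p1 = k2 / (k1 + k2)
    p2 = k1 / (k1 + k2)
    z = 2.0 * np.sqrt(k1 * k2 * t1 * t2)
    # ive = Iv(z) * exp(-z): exponentially scaled for large arguments
    i0 = ive(0, z)
    i1 = ive(1, z)
    term = (
        (p1 * k1 + p2 * k2) * i0
        + (p1 * np.sqrt(k1 * k2 * t1 / t2) + p2 * np.sqrt(k1 * k2 * t2 / t1)) * i1
    )
    return -k1 * t1 - k2 * t2 + z + np.log(np.maximum(term, 1e-300)) + np.log(T)


def occupancy_density(
    pair: ExchangingPair, T: float, n_grid: int = 240
) -> OccupancyDensity:
    """Mixed distribution of the state_a occupancy fraction over [0, T].

    Starts from the equilibrium state probabilities.  The no-transition
    paths give atoms p_a exp(-k_ab T) at x = 1 and p_b exp(-k_ba T) at
    x = 0; the paths with >= 1 transition give a continuous Bessel-function
    density, evaluated on an adaptive grid concentrated around the mean when
    the exchange is fast, and renormalized to the exact continuous mass.
    """
    if T <= 0:
        raise ValueError("window length must be positive")
    k1, k2 = pair.k_ab, pair.k_ba
    if k1 == 0 and k2 == 0:
        raise ValueError("both rates zero: occupancy distribution undefined")
    pa, pb = pair.p_a, pair.p_b
    atom_a = pa * np.exp(-k1 * T)
    atom_b = pb * np.exp(-k2 * T)
    if k1 == 0 or k2 == 0:
        # absorbing state: no continuous part (any transition is one-way,
        # but with one rate zero the process started in the absorbing state
        # never leaves; started in the other it switches once)
        grid = np.linspace(1e-6, 1 - 1e-6, n_grid)
        dens = np.zeros_like(grid)
        if k1 > 0:  # a -> b absorbing in b: T1 = first dwell in a
            dens = pa * k1 * T * np.exp(-k1 * grid * T)
        elif k2 > 0:
            dens = pb * k2 * T * np.exp(-k2 * (1 - grid) * T)
        w = _trapezoid_weights(grid) * dens
        target = 1.0 - atom_a - atom_b
        s = w.sum()
        if s > 0:
            w *= target / s
        return OccupancyDensity(k1, k2, T, atom_a, atom_b, grid, dens, w)

    mean = pa
    k = k1 + k2
    std = np.sqrt(2.0 * pa * pb * (T / k - (1 - np.exp(-k * T)) / k**2)) / T
    lo = max(1e-6, mean - 10 * std)
    hi = min(1.0 - 1e-6, mean + 10 * std)
    grid = np.unique(
        np.concatenate(
            [np.linspace(1e-6, 1 - 1e-6, max(41, n_grid // 4)),
             np.linspace(lo, hi, n_grid)]
        )
    )
    dens = np.exp(_occupancy_logdensity(grid, k1, k2, T))
    w = _trapezoid_weights(grid) * dens
    target = 1.0 - atom_a - atom_b
    s = w.sum()
    if s > 0:
        w *= target / s
    return OccupancyDensity(k1, k2, T, atom_a, atom_b, grid, dens, w)


def _trapezoid_weights(x: np.ndarray) -> np.ndarray:
    w = np.zeros_like(x)
    dx = np.diff(x)
    w[:-1] += 0.5 * dx
    w[1:] += 0.5 * dx
    return w


# --------------------------------------------------------------------------
# time windows and histograms
# --------------------------------------------------------------------------

@dataclass
class PdaHistogram:
    """Observed proxy-efficiency histogram for one time-window length.

    ``counts`` over ``bin_edges`` sum to ``n_windows``; ``f_values`` and
    ``f_weights`` are the (compressed) background-corrected fluorescence
    count distribution P(F) of the same windows, reused by the model.
    """

    time_window: float
    bin_edges: np.ndarray
    counts: np.ndarray
    n_windows: int
    f_values: np.ndarray
    f_weights: np.ndarray
    bg_green_counts: float
    bg_red_counts: float

    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"proxy_e_lo": self.bin_edges[:-1], "proxy_e_hi": self.bin_edges[1:],
             "count": self.counts}
        )


def slice_windows(stream: PhotonStream, time_window: float, bursts=None,
                  min_photons_burst: int = 60, max_gap: float = 100e-6):
    """Cut bursts into non-overlapping windows of ``time_window`` seconds.

    Windows start at the burst start; the trailing remainder is dropped.
    Returns an (n_windows, 2) array of (n_green, n_red) detected counts.
    """
    if bursts is None:
        bursts = select_bursts(stream, min_photons=min_photons_burst, max_gap=max_gap)
    out = []
    for b in bursts:
        sl = b.slice()
        t = stream.macrotime[sl]
        green = stream.channel[sl] <= 1
        t0 = t[0]
        n_win = int((t[-1] - t0) // time_window)
        if n_win < 1:
            continue
        idx = np.floor((t - t0) / time_window).astype(int)
        for w in range(n_win):
            m = idx == w
            out.append((int(np.sum(m & green)), int(np.sum(m & ~green))))
    return np.asarray(out, dtype=int).reshape(-1, 2)


def make_histograms(
    stream: PhotonStream,
    time_windows,
    corrections: CorrectionSet | None = None,
    n_bins: int = 40,
    e_range=(-0.1, 1.1),
    min_photons_window: int = 20,
    max_f_support: int = 60,
    bursts=None,
):
    """Build PdaHistograms for each requested window length.

    The proxy axis is the raw red fraction after subtraction of the mean
    background counts per window; windows with fewer than
    ``min_photons_window`` photons are discarded.  The empirical
    fluorescence count distribution P(F) (total counts minus mean
    background) is compressed to at most ``max_f_support`` support points.
    """
    if corrections is None:
        corrections = CorrectionSet()
    hists = []
    for tw in np.atleast_1d(time_windows):
        counts = slice_windows(stream, tw, bursts=bursts)
        bg_g = corrections.bg_green * 1e3 * tw
        bg_r = corrections.bg_red * 1e3 * tw
        if counts.size == 0:
            raise ValueError(f"no windows of length {tw*1e3:.2f} ms")
        total = counts.sum(axis=1)
        keep = total >= min_photons_window
        counts = counts[keep]
        total = total[keep]
        proxy = (counts[:, 1] - bg_r) / (total - bg_g - bg_r)
        edges = np.linspace(*e_range, n_bins + 1)
        hist, _ = np.histogram(np.clip(proxy, *e_range), bins=edges)
        f = np.maximum(np.round(total - bg_g - bg_r).astype(int), 1)
        f_vals, f_cnt = np.unique(f, return_counts=True)
        if f_vals.size > max_f_support:
            q = np.linspace(0, 1, max_f_support + 1)
            qe = np.unique(np.quantile(f, q).astype(int))
            idx = np.clip(np.searchsorted(qe, f, side="right") - 1, 0, qe.size - 1)
            f_vals = np.array([int(round(f[idx == i].mean())) for i in range(qe.size)
                               if np.any(idx == i)])
            f_cnt = np.array([np.sum(idx == i) for i in range(qe.size)
                              if np.any(idx == i)])
        hists.append(
            PdaHistogram(
                time_window=float(tw),
                bin_edges=edges,
                counts=hist.astype(float),
                n_windows=int(total.size),
                f_values=f_vals,
                f_weights=f_cnt / f_cnt.sum(),
                bg_green_counts=bg_g,
                bg_red_counts=bg_r,
            )
        )
    return hists


# --------------------------------------------------------------------------
# analytic photon distributions
# --------------------------------------------------------------------------

def _p_red(E, corr: CorrectionSet):
    E = np.asarray(E, dtype=float)
    p = corr.gamma * E / (corr.gamma * E + 1.0 - E)
    return p + (1.0 - p) * corr.alpha


class _HistogramKernel:
    """Precomputed pieces of the pmf of one histogram.

    For each support point F of the fluorescence count distribution the
    matrix ``M_F`` maps a binomial red-count vector to proxy-efficiency bin
    mass, with the Poisson backgrounds of both channels convolved in
    (truncation at the 0.9999 quantile).  The binomial split probability is
    evaluated on a fixed fine grid in p; continuous weight is assigned to
    the two neighbouring grid points by linear interpolation.
    """

    def __init__(self, hist: PdaHistogram, n_pgrid: int = 301):
        self.hist = hist
        self.pgrid = np.linspace(0.0, 1.0, n_pgrid)
        self._logp = np.log(np.clip(self.pgrid, 1e-12, None))
        self._log1mp = np.log(np.clip(1.0 - self.pgrid, 1e-12, None))
        edges = hist.bin_edges
        lam_r = hist.bg_red_counts
        lam_g = hist.bg_green_counts
        br_max = int(poisson.ppf(0.9999, lam_r)) if lam_r > 0 else 0
        bg_max = int(poisson.ppf(0.9999, lam_g)) if lam_g > 0 else 0
        w_br = poisson.pmf(np.arange(br_max + 1), lam_r) if lam_r > 0 else np.array([1.0])
        w_bg = poisson.pmf(np.arange(bg_max + 1), lam_g) if lam_g > 0 else np.array([1.0])
        w_br /= w_br.sum()
        w_bg /= w_bg.sum()
        self.matrices = {}
        nb = edges.size - 1
        for F in hist.f_values:
            F = int(F)
            M = np.zeros((F + 1, nb))
            k = np.arange(F + 1)
            for br, wr in enumerate(w_br):
                for bgr, wg in enumerate(w_bg):
                    n_tot = F + br + bgr
                    proxy = (k + br - lam_r) / (n_tot - lam_r - lam_g)
                    proxy = np.clip(proxy, edges[0], edges[-1] - 1e-12)
                    bins = np.clip(np.digitize(proxy, edges) - 1, 0, nb - 1)
                    np.add.at(M, (k, bins), wr * wg)
            self.matrices[F] = M

    def binom_matrix(self, F: int) -> np.ndarray:
        k = np.arange(F + 1)
        lc = gammaln(F + 1) - gammaln(k + 1) - gammaln(F - k + 1)
        logpmf = lc[None, :] + k[None, :] * self._logp[:, None] \
            + (F - k)[None, :] * self._log1mp[:, None]
        return np.exp(logpmf)

    def mixture_pmf(self, p_nodes, w_nodes) -> np.ndarray:
        """pmf over proxy bins for a mixture of split probabilities."""
        p_nodes = np.asarray(p_nodes, dtype=float)
        w_nodes = np.asarray(w_nodes, dtype=float)
        gw = np.zeros_like(self.pgrid)
        p = np.clip(p_nodes, 0.0, 1.0)
        pos = p * (self.pgrid.size - 1)
        i0 = np.clip(pos.astype(int), 0, self.pgrid.size - 2)
        frac = pos - i0
        np.add.at(gw, i0, w_nodes * (1.0 - frac))
        np.add.at(gw, i0 + 1, w_nodes * frac)
        out = np.zeros(self.hist.bin_edges.size - 1)
        for F, wf in zip(self.hist.f_values, self.hist.f_weights):
            B = self.binom_matrix(int(F))
            out += wf * (gw @ B @ self.matrices[int(F)])
        return out


def _gauss_hermite_distance_nodes(center, sigma, n):
    x, w = np.polynomial.hermite_e.hermegauss(n)
    r = center + sigma * x
    w = w / np.sqrt(2.0 * np.pi)
    keep = r > 1.0
    return r[keep], w[keep] / w[keep].sum()


def static_species_pmf(
    species: FretSpecies,
    hist: PdaHistogram,
    corr: CorrectionSet,
    pair: FretPair,
    n_quad: int = 16,
    _kernel: _HistogramKernel | None = None,
) -> np.ndarray:
    """Proxy-efficiency pmf of a static Gaussian-distance species.

    The fluorescence photons of each window split binomially at the
    apparent red probability p_R(E'), integrated over the species' Gaussian
    distance distribution by Gauss-Hermite quadrature and convolved with the
    channel backgrounds.  Sums to 1 over the proxy bins.
    """
    kern = _kernel or _HistogramKernel(hist)
    if species.sigma > 0:
        r, w = _gauss_hermite_distance_nodes(species.rda_e, species.sigma, n_quad)
    else:
        r, w = np.array([species.rda_e]), np.array([1.0])
    p = _p_red(efficiency_from_distance(r, pair), corr)
    return kern.mixture_pmf(p, w)


def donor_only_pmf(hist, corr, pair, _kernel=None) -> np.ndarray:
    kern = _kernel or _HistogramKernel(hist)
    return kern.mixture_pmf([corr.alpha], [1.0])


def dynamic_pmf(
    pair_exch: ExchangingPair,
    hist: PdaHistogram,
    corr: CorrectionSet,
    pair: FretPair,
    n_occ: int = 220,
    n_quad_sigma: int = 5,
    _kernel: _HistogramKernel | None = None,
) -> np.ndarray:
    """Proxy-efficiency pmf of a two-state exchanging pair.

    Mixture over the occupancy-time distribution: a window spending the
    fraction x in state_a has apparent efficiency
    ``E_app = x E_a + (1-x) E_b`` (equal brightness), split binomially at
    p_R(E_app); the no-transition atoms contribute pure state_a / state_b
    windows.  Each state's interdye distance carries its own Gaussian
    half-width, integrated with a small Gauss-Hermite rule.
    """
    kern = _kernel or _HistogramKernel(hist)
    occ = occupancy_density(pair_exch, hist.time_window, n_grid=n_occ)
    ra, wa = (
        _gauss_hermite_distance_nodes(pair_exch.state_a.rda_e, pair_exch.state_a.sigma, n_quad_sigma)
        if pair_exch.state_a.sigma > 0
        else (np.array([pair_exch.state_a.rda_e]), np.array([1.0]))
    )
    rb, wb = (
        _gauss_hermite_distance_nodes(pair_exch.state_b.rda_e, pair_exch.state_b.sigma, n_quad_sigma)
        if pair_exch.state_b.sigma > 0
        else (np.array([pair_exch.state_b.rda_e]), np.array([1.0]))
    )
    ea = efficiency_from_distance(ra, pair)
    eb = efficiency_from_distance(rb, pair)
    # tensor nodes: occupancy grid x distance quadratures
    x = occ.grid[:, None, None]
    e_app = x * ea[None, :, None] + (1.0 - x) * eb[None, None, :]
    w = occ.weights[:, None, None] * wa[None, :, None] * wb[None, None, :]
    p_nodes = _p_red(e_app.ravel(), corr)
    w_nodes = w.ravel()
    # atoms: whole window in one state
    p_atom_a = _p_red(ea, corr)
    p_atom_b = _p_red(eb, corr)
    p_nodes = np.concatenate([p_nodes, p_atom_a, p_atom_b])
    w_nodes = np.concatenate([w_nodes, occ.atom_a * wa, occ.atom_b * wb])
    return kern.mixture_pmf(p_nodes, w_nodes)


# --------------------------------------------------------------------------
# the fitted model
# --------------------------------------------------------------------------

@dataclass
class DynamicPDAResults:
    """Estimates and diagnostics of a dynPDA fit.

    Rates in s^-1, distances in A.  ``params`` is the lmfit parameter set
    (with stderr from the covariance of the weighted least squares),
    ``chi2_red`` the Poisson-weighted reduced chi-square over all histogram
    bins, ``residuals`` the per-bin weighted residuals per time window.
    """

    model: "DynamicPDA"
    params: lmfit.Parameters
    chi2_red: float
    residuals: list
    expected: list
    lmfit_result: lmfit.minimizer.MinimizerResult = field(repr=False, default=None)

    def value(self, name: str) -> float:
        return float(self.params[name].value)

    def stderr(self, name: str):
        return self.params[name].stderr

    @property
    def k_open(self) -> float:
        """Forward (closed -> open, MF* -> HF) rate constant in s^-1."""
        return 10.0 ** self.value("log10_k_open")

    @property
    def k_close(self) -> float:
        return 10.0 ** self.value("log10_k_close")

    @property
    def relaxation_time(self) -> float:
        return 1.0 / (self.k_open + self.k_close)

    def rate_stderr(self, which: str = "open"):
        p = self.params[f"log10_k_{which}"]
        if p.stderr is None:
            return None
        k = 10.0 ** p.value
        return k * np.log(10.0) * p.stderr

    def summary(self) -> str:
        lines = ["Dynamic photon distribution analysis", "-" * 44]
        for name, par in self.params.items():
            err = f" +/- {par.stderr:.3g}" if par.stderr else ""
            fixed = "" if par.vary else "  (fixed)"
            lines.append(f"{name:14s} {par.value:10.4g}{err}{fixed}")
        if self.model.dynamic is not None:
            lines.append(
                f"k_open  = {self.k_open/1e3:.1f} x10^3 s^-1, "
                f"k_close = {self.k_close/1e3:.1f} x10^3 s^-1, "
                f"t_R = {self.relaxation_time*1e6:.1f} us"
            )
        lines.append(f"chi2_red       {self.chi2_red:10.3f}")
        return "\n".join(lines)

    def report(self) -> dict:
        """Structured fit report: parameter, value, error, vary flag."""
        out = {
            name: dict(value=par.value, stderr=par.stderr, vary=par.vary)
            for name, par in self.params.items()
        }
        out["chi2_red"] = self.chi2_red
        return out


class DynamicPDA:
    """dynPDA model: static species + donor-only + one exchanging pair.

    Built from one or more :class:`PdaHistogram` (different time-window
    lengths constrain the rates jointly) and a model specification in terms
    of :class:`FretSpecies` / :class:`ExchangingPair`.  ``fit`` returns a
    :class:`DynamicPDAResults`.

    Parameters named in ``vary`` are free; everything else is fixed at the
    construction values.  Available parameter names: ``x_<species>`` for
    each static species fraction, ``x_donor_only``, ``r_<species>`` for
    each static species distance, ``r_dyn_a``/``r_dyn_b`` for the
    exchanging-state distances, and ``log10_k_open``/``log10_k_close``.
    The dynamic fraction is 1 minus all other fractions.  When
    ``share_mf_distance`` the closed exchanging state reuses the first
    static species' distance (the joint Gaussian treatment of the two
    mid-FRET species).
    """

    def __init__(
        self,
        histograms,
        static_species,
        donor_only_fraction: float = 0.1,
        dynamic: ExchangingPair | None = None,
        corrections: CorrectionSet | None = None,
        pair: FretPair | None = None,
        share_mf_distance: bool = True,
    ):
        self.histograms = list(histograms)
        if not self.histograms:
            raise ValueError("need at least one histogram")
        self.static_species = list(static_species)
        self.donor_only_fraction = donor_only_fraction
        self.dynamic = dynamic
        self.corrections = corrections or CorrectionSet()
        self.pair = pair or FretPair(R0=55.6, tau_D0=4.0)
        self.share_mf_distance = share_mf_distance and dynamic is not None
        self._kernels = [_HistogramKernel(h) for h in self.histograms]

    # -- parameter plumbing -------------------------------------------------

    def make_params(self, vary=()) -> lmfit.Parameters:
        vary = set(vary)
        params = lmfit.Parameters()
        for sp in self.static_species:
            params.add(f"x_{sp.name}", value=sp.fraction, min=0.0, max=1.0,
                       vary=f"x_{sp.name}" in vary)
            params.add(f"r_{sp.name}", value=sp.rda_e, min=20.0, max=150.0,
                       vary=f"r_{sp.name}" in vary)
        params.add("x_donor_only", value=self.donor_only_fraction, min=0.0,
                   max=1.0, vary="x_donor_only" in vary)
        if self.dynamic is not None:
            params.add("r_dyn_a", value=self.dynamic.state_a.rda_e, min=20.0,
                       max=150.0,
                       vary=("r_dyn_a" in vary) and not self.share_mf_distance)
            params.add("r_dyn_b", value=self.dynamic.state_b.rda_e, min=20.0,
                       max=150.0, vary="r_dyn_b" in vary)
            params.add("log10_k_open", value=np.log10(self.dynamic.k_ab),
                       min=2.0, max=7.0, vary="log10_k_open" in vary)
            params.add("log10_k_close", value=np.log10(self.dynamic.k_ba),
                       min=2.0, max=7.0, vary="log10_k_close" in vary)
        self._check_identifiable(params)
        return params

    def _check_identifiable(self, params: lmfit.Parameters) -> None:
        if self.dynamic is None:
            return
        rates_free = params["log10_k_open"].vary or params["log10_k_close"].vary
        dist_free = params["r_dyn_b"].vary or any(
            params[f"r_{sp.name}"].vary for sp in self.static_species
        )
        if rates_free and dist_free and len(self.histograms) < 2:
            raise ValueError(
                "non-identifiable fit: exchanging rates (log10_k_open/"
                "log10_k_close) and distances cannot float together with a "
                "single time window; add a second window length or fix the "
                "distances"
            )

    # -- forward model ------------------------------------------------------

    def expected_pmf(self, params: lmfit.Parameters):
        """Model pmf over proxy bins for every histogram."""
        v = params.valuesdict()
        fractions = {sp.name: v[f"x_{sp.name}"] for sp in self.static_species}
        x_d0 = v["x_donor_only"]
        x_dyn = 1.0 - sum(fractions.values()) - x_d0
        out = []
        for hist, kern in zip(self.histograms, self._kernels):
            pmf = x_d0 * donor_only_pmf(hist, self.corrections, self.pair, _kernel=kern)
            for sp in self.static_species:
                sp_now = FretSpecies(sp.name, v[f"r_{sp.name}"], sp.sigma, 1.0)
                pmf = pmf + fractions[sp.name] * static_species_pmf(
                    sp_now, hist, self.corrections, self.pair, _kernel=kern
                )
            if self.dynamic is not None and x_dyn > 1e-12:
                r_a = v[f"r_{self.static_species[0].name}"] if self.share_mf_distance \
                    else v["r_dyn_a"]
                dyn_now = ExchangingPair(
                    FretSpecies("a", r_a, self.dynamic.state_a.sigma),
                    FretSpecies("b", v["r_dyn_b"], self.dynamic.state_b.sigma),
                    10.0 ** v["log10_k_open"],
                    10.0 ** v["log10_k_close"],
                )
                pmf = pmf + x_dyn * dynamic_pmf(
                    dyn_now, hist, self.corrections, self.pair, _kernel=kern
                )
            out.append(pmf)
        return out

    def _residuals(self, params):
        res = []
        penalty = 0.0
        v = params.valuesdict()
        x_dyn = 1.0 - sum(v[f"x_{sp.name}"] for sp in self.static_species) \
            - v["x_donor_only"]
        if x_dyn < 0:
            penalty = -x_dyn * 1e4
        pmfs = self.expected_pmf(params)
        for hist, pmf in zip(self.histograms, pmfs):
            expected = hist.n_windows * pmf
            r = (hist.counts - expected) / np.sqrt(np.maximum(expected, 1.0))
            res.append(r)
        out = np.concatenate(res)
        if penalty:
            out = np.concatenate([out, [penalty]])
        return out

    # -- fitting ------------------------------------------------------------

    def _dynamic_grid_refine(self, params: lmfit.Parameters) -> lmfit.Parameters:
        """Coarse global scan of the exchanging-pair parameters.

        In the fully averaged regime (window >> relaxation time) the
        chi-square surface has long, narrow valleys in (distance, rates):
        gradient descent from a distant start can settle on a secondary
        basin.  With all other parameters frozen at their current values the
        dynamic component is re-evaluated on a coarse (r_open-state, k_open,
        k_close) grid and the parameters are moved to the best node before
        the final polish.
        """
        v = params.valuesdict()
        x_dyn = 1.0 - sum(v[f"x_{sp.name}"] for sp in self.static_species) \
            - v["x_donor_only"]
        if x_dyn <= 1e-6:
            return params
        # static part of the pmf is unchanged along the scan
        static_parts = []
        for hist, kern in zip(self.histograms, self._kernels):
            pmf = v["x_donor_only"] * donor_only_pmf(
                hist, self.corrections, self.pair, _kernel=kern)
            for sp in self.static_species:
                sp_now = FretSpecies(sp.name, v[f"r_{sp.name}"], sp.sigma, 1.0)
                pmf = pmf + v[f"x_{sp.name}"] * static_species_pmf(
                    sp_now, hist, self.corrections, self.pair, _kernel=kern)
            static_parts.append(pmf)
        r_a = v[f"r_{self.static_species[0].name}"] if self.share_mf_distance \
            else v["r_dyn_a"]
        r_b_grid = np.arange(38.0, 58.1, 2.5) if params["r_dyn_b"].vary \
            else [v["r_dyn_b"]]
        ko_grid = np.linspace(3.8, 5.2, 6) if params["log10_k_open"].vary \
            else [v["log10_k_open"]]
        kc_grid = np.linspace(3.6, 5.2, 6) if params["log10_k_close"].vary \
            else [v["log10_k_close"]]
        best = (np.inf, None)
        for r_b in r_b_grid:
            for lko in ko_grid:
                for lkc in kc_grid:
                    dyn = ExchangingPair(
                        FretSpecies("a", r_a, self.dynamic.state_a.sigma),
                        FretSpecies("b", r_b, self.dynamic.state_b.sigma),
                        10.0 ** lko, 10.0 ** lkc)
                    chi2 = 0.0
                    for hist, kern, stat in zip(self.histograms, self._kernels,
                                                static_parts):
                        pmf = stat + x_dyn * dynamic_pmf(
                            dyn, hist, self.corrections, self.pair,
                            n_occ=120, n_quad_sigma=3, _kernel=kern)
                        exp = hist.n_windows * pmf
                        chi2 += float(np.sum(
                            (hist.counts - exp) ** 2 / np.maximum(exp, 1.0)))
                    if chi2 < best[0]:
                        best = (chi2, (r_b, lko, lkc))
        if best[1] is not None:
            r_b, lko, lkc = best[1]
            params = params.copy()
            params["r_dyn_b"].value = r_b
            params["log10_k_open"].value = lko
            params["log10_k_close"].value = lkc
        return params

    def fit(self, vary=(), params: lmfit.Parameters | None = None,
            method: str = "leastsq", grid_refine: bool | None = None,
            **kws) -> DynamicPDAResults:
        """Joint Poisson-weighted least-squares fit over all time windows.

        When the exchange rates are free (and ``grid_refine`` is not
        disabled) an initial local fit is followed by a coarse global scan
        of the dynamic parameters and a final polish; the best of the two
        local solutions is returned.
        """
        if params is None:
            params = self.make_params(vary)
        else:
            self._check_identifiable(params)
        result = lmfit.minimize(self._residuals, params, method=method, **kws)
        if grid_refine is None:
            grid_refine = (
                self.dynamic is not None
                and (params["log10_k_open"].vary or params["log10_k_close"].vary)
            )
        if grid_refine:
            seeded = self._dynamic_grid_refine(result.params)
            result2 = lmfit.minimize(self._residuals, seeded, method=method, **kws)
            if np.sum(np.asarray(result2.residual) ** 2) < np.sum(
                np.asarray(result.residual) ** 2
            ):
                result = result2
        pmfs = self.expected_pmf(result.params)
        residuals, expected = [], []
        chi2 = 0.0
        nbins = 0
        for hist, pmf in zip(self.histograms, pmfs):
            exp = hist.n_windows * pmf
            r = (hist.counts - exp) / np.sqrt(np.maximum(exp, 1.0))
            residuals.append(r)
            expected.append(exp)
            chi2 += float(np.sum(r**2))
            nbins += r.size
        chi2_red = chi2 / max(nbins - result.nvarys, 1)
        return DynamicPDAResults(
            model=self,
            params=result.params,
            chi2_red=chi2_red,
            residuals=residuals,
            expected=expected,
            lmfit_result=result,
        )
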