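"""Staged inference for slow, tight-binding inhibition assays.

The analysis mirrors the classical Morrison-Walsh treatment of slow-binding
inhibitors:

1.  Each progress curve (product vs time at fixed [I], [S]) is fitted with the
    integrated form of ``v_I = v_s + (v_0 - v_s) e^{-k_obs t}``,

        P(t) = v_s t + (v_0 - v_s)(1 - e^{-k_obs t}) / k_obs,

    yielding the initial velocity v_0, the steady-state velocity v_s and the
    observed onset rate k_obs.
2.  The (inhibitor concentration, k_obs) series is fitted with the induced-fit
    hyperbola ``k_obs = k6 + k5 [I]/(K_I + [I])`` (and, for display, with the
    double-reciprocal line ``1/k_obs = (1/k5)(K_I/[I] + 1)``).
3.  The sign of the k_obs trend discriminates induced fit (rising, saturating)
    from conformational selection (falling); both hyperbolas are fitted and
    compared.
4.  The tight-binding dissociation constant K_I* is obtained independently
    from preincubated fractional velocities via the Henderson linearization
    ``[I]/(1 - v_i/v_0) = K_I*app (v_0/v_i) + E_t`` with the competitive
    correction ``K_I* = K_I*app / (1 + [S]/K_m)``.

All fits are deterministic given the data.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np
import pandas as pd
from scipy import stats

from .kinetics import KineticScheme, MichaelisParams, ThermoContext, ddg_from_ratio

__all__ = [
    "ProgressCurve",
    "ProgressFit",
    "KobsSeries",
    "MechanismVerdict",
    "HendersonTable",
    "HendersonFit",
    "SaturationFit",
    "DoubleReciprocalFit",
    "fit_progress_curve",
    "fit_kobs_saturation",
    "fit_double_reciprocal",
    "classify_mechanism",
    "henderson_fit",
    "fit_michaelis",
    "read_progress_csv",
    "write_progress_csv",
    "estimate_scheme",
]

PROGRESS_CSV_COLUMNS = [
    "time_s", "signal", "inhibitor_M", "substrate_M", "replicate", "preincubated",
]


@dataclass
class ProgressCurve:
    """One deformylation time course at fixed inhibitor/substrate concentration.

    ``signal`` is accumulated product (M).  At least 8 points; times strictly
    increasing.
    """

    times: np.ndarray
    signal: np.ndarray
    inhibitor_conc: float
    substrate_conc: float
    preincubated: bool = False
    replicate: int = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.times.shape != self.signal.shape:
            raise ValueError("times and signal must have the same length")
        if len(self.times) < 8:
            raise ValueError(f"need >= 8 points, got {len(self.times)}")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class ProgressFit:
    """Fitted (v0, vs, kobs) of one progress curve, with standard errors."""

    v0: float
    vs: float
    kobs: float | None
    v0_se: float | None = None
    vs_se: float | None = None
    kobs_se: float | None = None
    converged: bool = True
    degenerate: bool = False
    preincubated: bool = False

    @property
    def tightening(self) -> bool:
        """True when vs <= v0, the slow-onset signature (non-preincubated)."""
        return self.vs <= self.v0


@dataclass
class KobsSeries:
    """(inhibitor concentration, k_obs, se) triples from progress-curve fits."""

    conc: np.ndarray
    kobs: np.ndarray
    se: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.conc = np.asarray(self.conc, dtype=float)
        self.kobs = np.asarray(self.kobs, dtype=float)
        if self.se is not None:
            self.se = np.asarray(self.se, dtype=float)

    def span_ok(self) -> bool:
        """>= 5 distinct concentrations spanning >= 10-fold, as required for
        a mechanism call."""
        pos = self.conc[self.conc > 0]
        distinct = np.unique(pos)
        return len(distinct) >= 5 and distinct.max() / distinct.min() >= 10.0

    def aggregate_replicates(self) -> "KobsSeries":
        """Collapse replicate measurements at each concentration to their mean
        with a standard error (sample SD / sqrt(n)); levels with a single
        measurement keep their individual se (or none)."""
        levels = np.unique(self.conc)
        kobs, se = [], []
        for c in levels:
            m = self.conc == c
            vals = self.kobs[m]
            kobs.append(vals.mean())
            if m.sum() >= 2:
                se.append(vals.std(ddof=1) / np.sqrt(m.sum()))
            elif self.se is not None:
                se.append(float(self.se[m][0]))
            else:
                se.append(np.nan)
        se = np.asarray(se)
        return KobsSeries(conc=levels, kobs=np.asarray(kobs),
                          se=None if np.any(~np.isfinite(se)) else se)

    def weights(self) -> np.ndarray | None:
        if self.se is None or np.any(~np.isfinite(self.se)) or np.any(self.se <= 0):
            return None
        return 1.0 / self.se**2


@dataclass
class SaturationFit:
    """Induced-fit hyperbola fit: asymptote k5+k6, intercept k6, midpoint K_I."""

    k5: float
    k6: float
    KI: float
    k5_se: float | None
    k6_se: float | None
    KI_se: float | None
    rss: float
    aic: float
    decreasing_flag: bool = False  # series trend inconsistent with the model


@dataclass
class DoubleReciprocalFit:
    """OLS of 1/kobs on 1/[I]: slope = K_I/k5, intercept = 1/k5."""

    slope: float
    intercept: float
    r_squared: float
    n_used: int

    @property
    def k5(self) -> float:
        return 1.0 / self.intercept

    @property
    def KI(self) -> float:
        return self.slope / self.intercept


@dataclass
class MechanismVerdict:
    """Induced fit vs conformational selection decision for a k_obs series."""

    label: str  # "induced_fit" | "conformational_selection" | "ambiguous"
    trend_tau: float
    trend_p: float
    increasing_fit: SaturationFit | None
    decreasing_fit: "DecreasingFit | None"
    reason: str = ""


@dataclass
class DecreasingFit:
    """Conformational-selection hyperbola k6 + k5/(1+[I]/K_I) fit summary."""

    k5: float
    k6: float
    KI: float
    rss: float
    aic: float


@dataclass
class HendersonTable:
    """Rows of (inhibitor_conc, substrate_conc, vi/v0 fractional velocity)."""

    inhibitor_conc: np.ndarray
    substrate_conc: np.ndarray
    fractional_velocity: np.ndarray

    def __post_init__(self) -> None:
        self.inhibitor_conc = np.asarray(self.inhibitor_conc, dtype=float)
        self.substrate_conc = np.asarray(self.substrate_conc, dtype=float)
        self.fractional_velocity = np.asarray(self.fractional_velocity, dtype=float)
        if np.any(self.fractional_velocity <= 0):
            raise ValueError("fractional velocities must be > 0")


@dataclass
class HendersonFit:
    """Henderson regression results, per substrate level and pooled."""

    KIstar_app: dict[float, float]  # substrate level -> apparent K_I* (M)
    Et: dict[float, float]          # substrate level -> intercept (M)
    KIstar: float                   # pooled, competition-corrected (M)
    Et_pooled: float                # pooled intercept (M)


def _integrated_progress(t, v0, vs, kobs):
    return vs * t + (v0 - vs) * (1.0 - np.exp(-kobs * t)) / kobs


def _segment_slope(t, p, frac=0.1, min_pts=3):
    n = max(min_pts, int(round(frac * len(t))))
    return np.polyfit(t[:n], p[:n], 1)[0], np.polyfit(t[-n:], p[-n:], 1)[0]


def fit_progress_curve(
    curve: ProgressCurve,
    degeneracy_tol: float = 0.05,
) -> ProgressFit:
    """Fit the integrated slow-binding form to one progress curve.

    Initial guesses: v0 from the slope over the first 10% of points, vs from
    the last 10%, k_obs from the amplitude of the burst term.  When the two
    segment slopes agree within ``degeneracy_tol`` (relative), the curve has
    no measurable curvature: a straight line is fitted instead and the result
    is flagged degenerate with ``kobs=None``.
    """
    t, p = curve.times, curve.signal
    v0g, vsg = _segment_slope(t, p)
    scale = max(abs(v0g), abs(vsg), 1e-30)
    if abs(v0g - vsg) < degeneracy_tol * scale:
        slope, icpt = np.polyfit(t, p, 1)
        return ProgressFit(v0=float(slope), vs=float(slope), kobs=None,
                           degenerate=True, preincubated=curve.preincubated)

    # burst amplitude (v0-vs)/k estimated from the late-time offset of P - vs*t
    tail = p[-max(3, len(t) // 10):] - vsg * t[-max(3, len(t) // 10):]
    amp = np.median(tail)
    kg = (v0g - vsg) / amp if amp * (v0g - vsg) > 0 else 1.0 / (t[-1] - t[0])
    kg = float(np.clip(abs(kg), 1e-8, 1e3))

    # fit on a normalized signal so parameter magnitudes are O(1) regardless
    # of whether the product scale is nM or mM
    scale = float(np.max(np.abs(p))) or 1.0
    pn = p / scale
    model = lmfit.Model(_integrated_progress, independent_vars=["t"])
    params = model.make_params(
        v0=dict(value=max(v0g / scale, 1e-12), min=0),
        vs=dict(value=max(vsg / scale, 0.0), min=0),
        kobs=dict(value=kg, min=1e-10, max=1e4),
    )
    res = model.fit(pn, params, t=t, max_nfev=5000)
    def _se(name):
        err = res.params[name].stderr
        if err is None:
            return None
        return err * scale if name != "kobs" else err
    return ProgressFit(
        v0=res.params["v0"].value * scale,
        vs=res.params["vs"].value * scale,
        kobs=res.params["kobs"].value,
        v0_se=_se("v0"), vs_se=_se("vs"), kobs_se=_se("kobs"),
        converged=bool(res.success),
        preincubated=curve.preincubated,
    )


def _hyperbola_up(I, k5, k6, KI):
    return k6 + k5 * I / (KI + I)


def _hyperbola_down(I, k5, k6, KI):
    return k6 + k5 / (1.0 + I / KI)


def _aic(rss: float, n: int, k: int) -> float:
    return n * np.log(max(rss, 1e-300) / n) + 2 * k


def fit_kobs_saturation(series: KobsSeries) -> SaturationFit:
    """Weighted fit of the induced-fit hyperbola to a k_obs series.

    Weights are inverse-variance when replicate standard errors are present,
    else unit.  A decreasing series is still fitted but flagged
    inconsistent-with-model.
    """
    I, y = series.conc, series.kobs
    w = series.weights()
    model = lmfit.Model(_hyperbola_up, independent_vars=["I"])
    params = model.make_params(
        k5=dict(value=max(y.max() - y.min(), 1e-8), min=0),
        k6=dict(value=max(y.min() * 0.5, 1e-10), min=0),
        KI=dict(value=np.median(I[I > 0]) if np.any(I > 0) else 1e-7, min=1e-12),
    )
    res = model.fit(y, params, I=I, weights=None if w is None else np.sqrt(w))
    resid = y - _hyperbola_up(I, *[res.params[k].value for k in ("k5", "k6", "KI")])
    rss = float((resid ** 2).sum())
    tau, _ = stats.kendalltau(I, y)
    return SaturationFit(
        k5=res.params["k5"].value, k6=res.params["k6"].value,
        KI=res.params["KI"].value,
        k5_se=res.params["k5"].stderr, k6_se=res.params["k6"].stderr,
        KI_se=res.params["KI"].stderr,
        rss=rss, aic=_aic(rss, len(y), 3),
        decreasing_flag=bool(np.isfinite(tau) and tau < 0),
    )


def fit_double_reciprocal(
    series: KobsSeries,
    k6: float,
    cutoff: float = 10.0,
) -> DoubleReciprocalFit:
    """OLS of 1/k_obs on 1/[I], restricted to points with k_obs > cutoff*k6.

    On induced-fit data the plot is the straight line
    ``1/k_obs = (K_I/k5)(1/[I]) + 1/k5`` (valid where k_obs >> k6), so the
    intercept estimates 1/k5 and slope/intercept estimates K_I.
    """
    mask = (series.kobs > cutoff * k6) & (series.conc > 0)
    if mask.sum() < 3:
        raise ValueError(
            f"only {int(mask.sum())} points with kobs > {cutoff}*k6; need >= 3"
        )
    x = 1.0 / series.conc[mask]
    y = 1.0 / series.kobs[mask]
    reg = stats.linregress(x, y)
    return DoubleReciprocalFit(
        slope=float(reg.slope), intercept=float(reg.intercept),
        r_squared=float(reg.rvalue ** 2), n_used=int(mask.sum()),
    )


def classify_mechanism(series: KobsSeries, alpha: float = 0.05) -> MechanismVerdict:
    """Decide induced fit vs conformational selection from the k_obs trend.

    Fits both candidate hyperbolas, compares their AIC, and tests the
    monotone trend of k_obs vs [I] (Kendall tau).  The verdict is
    ``induced_fit`` for a significant rising trend backed by the rising
    model, ``conformational_selection`` for the mirror case, and
    ``ambiguous`` whenever the trend is not significant at ``alpha`` or the
    two criteria disagree.
    """
    if not series.span_ok():
        return MechanismVerdict(
            label="ambiguous", trend_tau=np.nan, trend_p=np.nan,
            increasing_fit=None, decreasing_fit=None,
            reason="concentration span too narrow (< 5 levels or < 10-fold)",
        )
    inc = fit_kobs_saturation(series)

    I, y = series.conc, series.kobs
    model = lmfit.Model(_hyperbola_down, independent_vars=["I"])
    params = model.make_params(
        k5=dict(value=max(y.max() - y.min(), 1e-8), min=0),
        k6=dict(value=max(y.min() * 0.5, 1e-10), min=0),
        KI=dict(value=np.median(I[I > 0]), min=1e-12),
    )
    w = series.weights()
    res = model.fit(y, params, I=I, weights=None if w is None else np.sqrt(w))
    resid = y - _hyperbola_down(I, *[res.params[k].value for k in ("k5", "k6", "KI")])
    rss = float((resid ** 2).sum())
    dec = DecreasingFit(
        k5=res.params["k5"].value, k6=res.params["k6"].value,
        KI=res.params["KI"].value, rss=rss, aic=_aic(rss, len(y), 3),
    )

    tau, p = stats.kendalltau(I, y)
    rising = np.isfinite(tau) and tau > 0 and p < alpha
    falling = np.isfinite(tau) and tau < 0 and p < alpha
    if rising and inc.aic <= dec.aic:
        label, reason = "induced_fit", "rising saturable k_obs"
    elif falling and dec.aic <= inc.aic:
        label, reason = "conformational_selection", "k_obs decreases with [I]"
    else:
        label = "ambiguous"
        reason = ("no significant monotone trend" if not (rising or falling)
                  else "trend and model comparison disagree")
    return MechanismVerdict(
        label=label, trend_tau=float(tau) if np.isfinite(tau) else np.nan,
        trend_p=float(p) if np.isfinite(p) else np.nan,
        increasing_fit=inc, decreasing_fit=dec, reason=reason,
    )


def henderson_fit(table: HendersonTable, Km: float) -> HendersonFit:
    """Henderson regression for a tight-binding competitive inhibitor.

    For each substrate level, regress ``[I]/(1 - vi/v0)`` on ``v0/vi``: the
    slope is the apparent dissociation constant K_I*app and the intercept is
    the total active-enzyme concentration E_t.  The competitive correction
    ``K_I* = K_I*app/(1 + [S]/Km)`` is applied per level and the corrected
    values pooled (unweighted mean).  Rows with vi >= v0 carry no information
    and are excluded with a warning.
    """
    f = table.fractional_velocity
    usable = (f < 1.0) & (table.inhibitor_conc > 0)
    n_dropped = int((~usable).sum())
    if n_dropped:
        warnings.warn(f"excluding {n_dropped} rows with vi >= v0 or [I] = 0")
    if usable.sum() == 0:
        raise ValueError("no usable rows (all have vi >= v0 or [I] = 0)")

    KIstar_app: dict[float, float] = {}
    Et: dict[float, float] = {}
    corrected = []
    for S in np.unique(table.substrate_conc[usable]):
        m = usable & (table.substrate_conc == S)
        if m.sum() < 2:
            warnings.warn(f"substrate level {S}: fewer than 2 usable rows, skipped")
            continue
        x = 1.0 / f[m]                                  # v0/vi
        y = table.inhibitor_conc[m] / (1.0 - f[m])      # [I]/(1 - vi/v0)
        reg = stats.linregress(x, y)
        KIstar_app[float(S)] = float(reg.slope)
        Et[float(S)] = float(reg.intercept)
        corrected.append(reg.slope / (1.0 + S / Km))
    if not corrected:
        raise ValueError("no substrate level had enough usable rows")
    return HendersonFit(
        KIstar_app=KIstar_app, Et=Et,
        KIstar=float(np.mean(corrected)),
        Et_pooled=float(np.mean(list(Et.values()))),
    )


def fit_michaelis(vel_vs_S, E: float) -> tuple[MichaelisParams, dict]:
    """Nonlinear Michaelis-Menten fit of (S, v) pairs; kcat = Vmax/E.

    Returns the fitted parameters and a details dict with standard errors.
    Warns when the substrate range does not reach saturation (max S < 2*Km).
    """
    arr = np.asarray(vel_vs_S, dtype=float)
    S, v = arr[:, 0], arr[:, 1]
    if len(np.unique(S)) < 5:
        raise ValueError("need >= 5 substrate levels")

    def mm(S, Vmax, Km):
        return Vmax * S / (Km + S)

    model = lmfit.Model(mm, independent_vars=["S"])
    params = model.make_params(
        Vmax=dict(value=v.max() * 1.2, min=0),
        Km=dict(value=np.median(S), min=1e-15),
    )
    res = model.fit(v, params, S=S)
    Vmax, Km = res.params["Vmax"].value, res.params["Km"].value
    if S.max() < 2 * Km:
        warnings.warn(
            f"substrate range (max {S.max():.3g} M) does not bracket saturation "
            f"(fitted Km {Km:.3g} M): wide confidence intervals expected"
        )
    details = {
        "Vmax": Vmax, "Vmax_se": res.params["Vmax"].stderr,
        "Km_se": res.params["Km"].stderr,
        "kcat_se": (res.params["Vmax"].stderr / E
                    if res.params["Vmax"].stderr is not None else None),
    }
    return MichaelisParams(kcat=Vmax / E, Km=Km), details


def write_progress_csv(curves: list[ProgressCurve], path_or_buf) -> None:
    """Write progress curves in the package's long CSV dialect."""
    frames = []
    for c in curves:
        frames.append(pd.DataFrame({
            "time_s": c.times, "signal": c.signal,
            "inhibitor_M": c.inhibitor_conc, "substrate_M": c.substrate_conc,
            "replicate": c.replicate, "preincubated": c.preincubated,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path_or_buf, index=False)


def read_progress_csv(path_or_buf) -> list[ProgressCurve]:
    """Read progress curves from CSV (columns: time_s, signal, inhibitor_M,
    substrate_M, replicate, preincubated); one curve per
    (inhibitor, substrate, replicate, preincubated) group."""
    if isinstance(path_or_buf, str) and "\n" in path_or_buf:
        path_or_buf = io.StringIO(path_or_buf)
    df = pd.read_csv(path_or_buf)
    missing = [c for c in PROGRESS_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing CSV columns: {missing}")
    if df.empty:
        raise ValueError("empty progress-curve CSV")
    curves = []
    keys = ["inhibitor_M", "substrate_M", "replicate", "preincubated"]
    for (I, S, rep, pre), g in df.groupby(keys, sort=True):
        g = g.sort_values("time_s")
        curves.append(ProgressCurve(
            times=g["time_s"].to_numpy(), signal=g["signal"].to_numpy(),
            inhibitor_conc=float(I), substrate_conc=float(S),
            preincubated=bool(pre), replicate=int(rep),
        ))
    return curves


@dataclass
class SchemeEstimate:
    """End-to-end estimate: per-curve fits, k_obs series, scheme and report."""

    progress_fits: list[ProgressFit]
    series: KobsSeries
    saturation: SaturationFit
    verdict: MechanismVerdict
    scheme: KineticScheme
    report: dict = field(default_factory=dict)


def estimate_scheme(
    curves: list[ProgressCurve],
    k3: float = 1e9,
    alpha: float = 0.05,
    ctx: ThermoContext | None = None,
) -> SchemeEstimate:
    """Full staged pipeline: curves -> k_obs series -> scheme -> derived report.

    Curves at [I] = 0 or flagged degenerate contribute no k_obs point.  k4 is
    reconstructed from the fitted K_I assuming diffusion-limited association
    (k4 = k3*K_I), the convention for sub-uM encounter complexes.
    """
    fits, conc, kobs, se = [], [], [], []
    for c in curves:
        f = fit_progress_curve(c)
        fits.append(f)
        usable = (f.kobs is not None and not f.degenerate and f.converged
                  and c.inhibitor_conc > 0
                  # an uninformative fit (no stderr, or stderr exceeding the
                  # estimate) contributes noise, not signal
                  and f.kobs_se is not None and np.isfinite(f.kobs_se)
                  and f.kobs_se < f.kobs)
        if usable:
            conc.append(c.inhibitor_conc)
            kobs.append(f.kobs)
            se.append(f.kobs_se)
    if len(conc) < 3:
        raise ValueError("too few inhibited curves with a defined k_obs")
    se = np.asarray(se)
    series = KobsSeries(
        conc=np.asarray(conc), kobs=np.asarray(kobs),
        se=None if np.any(~np.isfinite(se)) else se,
    )
    sat = fit_kobs_saturation(series)
    verdict = classify_mechanism(series, alpha=alpha)
    KI = sat.KI
    scheme = KineticScheme(k3=k3, k4=k3 * KI, k5=sat.k5, k6=sat.k6)
    from .kinetics import complex_half_life, ki_star  # local to avoid cycle noise
    KIs = ki_star(scheme)
    report = {
        "KI_nM": KI * 1e9,
        "KI_star_nM": KIs * 1e9,
        "KI_ratio": KI / KIs,
        "k5_per_s": sat.k5,
        "k6_per_s": sat.k6,
        "k4_per_s": scheme.k4,
        "t_half_min": complex_half_life(scheme) / 60.0,
        "ddG_tightening_kcal_per_mol": ddg_from_ratio(KI / KIs, ctx),
        "mechanism": verdict.label,
    }
    return SchemeEstimate(
        progress_fits=fits, series=series, saturation=sat,
        verdict=verdict, scheme=scheme, report=report,
    )
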