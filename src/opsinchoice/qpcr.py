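"""Construct-calibrated qPCR quantification of cone-opsin expression.

Raw amplification curves are reduced to per-reaction estimates of PCR
efficiency (E), initial concentration (N0) and the critical threshold
cycle (Ct) by regressing log10 fluorescence on cycle number inside a
"window of linearity" — the log-linear stretch of the curve between the
baseline noise floor and the plateau.  Duplicate reactions are subjected
to the study's QC rule (efficiency 75–125%, Ct sd <= 0.5), a per-plate
construct dilution series gives each gene a standard curve
(Ct ~ m * log10 concentration + b), and relative expression of the four
cone opsins (SWS2b, SWS2a, RH2A, LWS) is the back-calculated N0 of each
gene divided by the summed N0 of all four.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

GENES = ("SWS2b", "SWS2a", "RH2A", "LWS")

NO_AMPLIFICATION = "no_amplification"


@dataclass(frozen=True)
class WindowConfig:
    """Settings for the window-of-linearity search.

    baseline_cycles : inclusive cycle range averaged to estimate the
        baseline fluorescence (subtracted before log-transforming), or
        None for curves recorded baseline-free.
    min_window, max_window : allowed window sizes (number of cycles).
    plateau_fraction : windows must end before the first cycle whose
        corrected fluorescence reaches this fraction of the curve maximum.
    noise_floor_fraction : cycles whose corrected fluorescence falls
        below this fraction of the curve maximum are excluded from
        window candidacy, keeping spuriously linear baseline noise out
        of the search.
    threshold : fixed Ct threshold in corrected fluorescence units; when
        None the per-plate, per-gene geometric mean of windowed
        fluorescence is used (computed at the plate level).
    log_base : base B of the standard-curve back-calculation
        N0_i = B**((Ct_i - b_i) / m_i).  Any common base works because it
        cancels between the curve and the back-calculation; 10 is the
        qPCR convention.
    """

    baseline_cycles: tuple[int, int] | None = (3, 8)
    min_window: int = 4
    max_window: int = 6
    plateau_fraction: float = 0.8
    noise_floor_fraction: float = 1e-3
    threshold: float | None = None
    log_base: float = 10.0


@dataclass(frozen=True)
class AmplificationCurve:
    plate_id: str
    well_id: str
    sample_id: str
    gene: str
    replicate_index: int
    cycles: np.ndarray
    fluorescence: np.ndarray
    is_dilution_standard: bool = False
    log10_concentration: float | None = None

    def __post_init__(self):
        c = np.asarray(self.cycles, dtype=float)
        f = np.asarray(self.fluorescence, dtype=float)
        if c.shape != f.shape or c.ndim != 1:
            raise ValueError("cycles and fluorescence must be matching 1-d arrays")
        if len(c) < 15:
            raise ValueError("amplification curve needs >= 15 cycles")
        if np.any(np.diff(c) <= 0):
            raise ValueError("cycles must be strictly increasing")
        if not np.all(np.isfinite(f)):
            raise ValueError("fluorescence values must be finite")
        object.__setattr__(self, "cycles", c)
        object.__setattr__(self, "fluorescence", f)
        if self.is_dilution_standard and self.log10_concentration is None:
            raise ValueError("dilution standards need log10_concentration")


@dataclass
class AmplificationFit:
    """Window-of-linearity regression result for one reaction."""

    curve: AmplificationCurve | None
    window: tuple[int, int] | None  # (first_cycle, last_cycle), inclusive
    slope_log10F_per_cycle: float
    intercept_log10F: float
    efficiency_E: float
    N0: float
    Ct: float
    r_squared: float
    baseline: float
    qc_flags: set = field(default_factory=set)
    window_fluorescence: np.ndarray | None = None

    @property
    def efficiency_percent(self) -> float:
        return (self.efficiency_E - 1.0) * 100.0

    @property
    def ok(self) -> bool:
        return NO_AMPLIFICATION not in self.qc_flags

    def ct_at(self, threshold: float) -> float:
        """Fractional cycle at which the fitted line crosses ``threshold``."""
        if not self.ok:
            return float("nan")
        return (math.log10(threshold) - self.intercept_log10F) / self.slope_log10F_per_cycle

    def with_threshold(self, threshold: float) -> "AmplificationFit":
        ct = self.ct_at(threshold)
        out = replace(self, Ct=ct)
        out.qc_flags = set(self.qc_flags)
        if self.ok and self.curve is not None:
            lo, hi = self.curve.cycles[0], self.curve.cycles[-1]
            if not (lo <= ct <= hi):
                out.qc_flags.add("ct_out_of_range")
        return out


def _failed_fit(curve: AmplificationCurve, baseline: float) -> AmplificationFit:
    nan = float("nan")
    return AmplificationFit(curve, None, nan, nan, nan, nan, nan, nan,
                            baseline, {NO_AMPLIFICATION})


def fit_amplification(curve: AmplificationCurve,
                      cfg: WindowConfig = WindowConfig()) -> AmplificationFit:
    """Fit the log-linear window of one amplification curve.

    The mean fluorescence over ``cfg.baseline_cycles`` is subtracted, then
    among all contiguous windows of ``min_window``..``max_window`` cycles
    whose corrected fluorescence is positive and strictly below
    ``plateau_fraction`` of the corrected maximum, the window with the
    highest r-squared of log10(F) ~ cycle wins (ties: longer window, then
    earlier window).  E = 10**slope, N0 = 10**intercept, and Ct is the
    fractional cycle where the fitted line crosses the threshold.
    """
    c, f = curve.cycles, curve.fluorescence
    if cfg.baseline_cycles is not None:
        lo, hi = cfg.baseline_cycles
        sel = (c >= lo) & (c <= hi)
        baseline = float(f[sel].mean()) if sel.any() else 0.0
    else:
        baseline = 0.0
    fc = f - baseline
    if not np.any(fc > 0):
        return _failed_fit(curve, baseline)
    cutoff = cfg.plateau_fraction * fc.max()
    floor = cfg.noise_floor_fraction * fc.max()
    above = np.nonzero(fc >= cutoff)[0]
    upper = above[0] if len(above) else len(fc)  # windows end before `upper`
    eligible = (fc > 0) & (fc > floor) & (np.arange(len(fc)) < upper)

    best = None  # ((r2, length, -start_idx), slope, intercept, window_vals, (c0, c1))
    logf = np.where(eligible, np.log10(np.where(fc > 0, fc, 1.0)), 0.0)
    # sliding-window OLS via prefix sums, one pass per window size
    z = np.concatenate([[0.0], np.cumsum(c * eligible)])
    zy = np.concatenate([[0.0], np.cumsum(logf)])
    zxx = np.concatenate([[0.0], np.cumsum(c * c * eligible)])
    zyy = np.concatenate([[0.0], np.cumsum(logf * logf)])
    zxy = np.concatenate([[0.0], np.cumsum(c * logf)])
    elig_run = np.concatenate([[0], np.cumsum(eligible)])
    for w in range(cfg.min_window, cfg.max_window + 1):
        if w > len(fc):
            break
        starts = np.arange(0, len(fc) - w + 1)
        ok = (elig_run[starts + w] - elig_run[starts]) == w
        if not ok.any():
            continue
        s = starts[ok]
        sx = z[s + w] - z[s]
        sy = zy[s + w] - zy[s]
        sxx = zxx[s + w] - zxx[s]
        syy = zyy[s + w] - zyy[s]
        sxy = zxy[s + w] - zxy[s]
        vx = sxx - sx * sx / w
        vy = syy - sy * sy / w
        cxy = sxy - sx * sy / w
        slope = cxy / vx
        intercept = (sy - slope * sx) / w
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = np.where(vy > 0, cxy * cxy / (vx * vy), 1.0)
        r2 = np.clip(r2, 0.0, 1.0)
        for i, start in enumerate(s):
            key = (r2[i], w, -int(start))
            if best is None or key > best[0]:
                best = (key, slope[i], intercept[i],
                        fc[start:start + w].copy(),
                        (int(c[start]), int(c[start + w - 1])))
    if best is None:
        return _failed_fit(curve, baseline)
    (r2, _, _), slope, intercept, wvals, window = best
    if slope <= 0:
        return _failed_fit(curve, baseline)
    fit = AmplificationFit(
        curve=curve, window=window,
        slope_log10F_per_cycle=float(slope), intercept_log10F=float(intercept),
        efficiency_E=float(10.0 ** slope), N0=float(10.0 ** intercept),
        Ct=float("nan"), r_squared=float(r2), baseline=baseline,
        window_fluorescence=wvals,
    )
    if cfg.threshold is not None:
        fit = fit.with_threshold(cfg.threshold)
    return fit


# ---------------------------------------------------------------------------
# duplicate QC

EFFICIENCY_RANGE = (75.0, 125.0)   # percent, inclusive
MAX_CT_SD = 0.5                    # sample sd (ddof=1) of duplicate Cts


@dataclass
class DuplicateQC:
    sample_id: str
    gene: str
    mean_Ct: float
    mean_N0: float
    passed: bool
    reasons: list


def qc_duplicates(fit_a: AmplificationFit, fit_b: AmplificationFit) -> DuplicateQC:
    """Apply the duplicate QC rule: both efficiencies in 75–125 % and the
    sample sd of the two Cts <= 0.5.  Means are returned regardless."""
    sample = fit_a.curve.sample_id if fit_a.curve is not None else ""
    gene = fit_a.curve.gene if fit_a.curve is not None else ""
    reasons = []
    if not (fit_a.ok and fit_b.ok):
        return DuplicateQC(sample, gene, float("nan"), float("nan"), False,
                           ["fit_failure"])
    for fit in (fit_a, fit_b):
        lo, hi = EFFICIENCY_RANGE
        if not (lo <= fit.efficiency_percent <= hi):
            reasons.append("efficiency_range")
            break
    cts = np.array([fit_a.Ct, fit_b.Ct], dtype=float)
    sd = float(np.std(cts, ddof=1))
    if np.isnan(sd) or sd > MAX_CT_SD:
        reasons.append("ct_sd")
    return DuplicateQC(sample, gene,
                       float(cts.mean()), float((fit_a.N0 + fit_b.N0) / 2.0),
                       not reasons, reasons)


# ---------------------------------------------------------------------------
# construct standard curve

@dataclass
class StandardCurve:
    gene: str
    slope_m: float           # Ct per log-unit concentration; negative
    intercept_b: float       # Ct at log-concentration 0
    r_squared: float
    n_points: int
    log_base: float = 10.0
    flags: set = field(default_factory=set)


def fit_standard_curve(points, gene: str = "",
                       log_base: float = 10.0) -> StandardCurve:
    """OLS of Ct on log concentration for one gene's dilution series.

    ``points`` is an iterable of (log10_concentration, Ct) pairs or of
    AmplificationFits carrying curve.log10_concentration.  At least three
    points spanning >= 2 log units are required; a perfect series with
    per-cycle efficiency E has slope m = -1/log10(E).
    """
    pts = []
    for p in points:
        if isinstance(p, AmplificationFit):
            if not p.ok:
                continue
            pts.append((p.curve.log10_concentration, p.Ct))
            gene = gene or p.curve.gene
        else:
            pts.append((float(p[0]), float(p[1])))
    if len(pts) < 3:
        raise ValueError("standard curve needs >= 3 dilution points")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    flags = set()
    if x.max() - x.min() < 2.0:
        flags.add("narrow_range")
    slope, intercept, r, _, _ = stats.linregress(x, y)
    if slope >= 0:
        flags.add("inverted_series")
    return StandardCurve(gene, float(slope), float(intercept), float(r * r),
                         len(pts), log_base, flags)


# ---------------------------------------------------------------------------
# relative expression

@dataclass
class ExpressionProfile:
    sample_id: str
    proportions: dict          # gene -> fraction of total opsin expression
    mean_Ct: dict
    metadata: dict = field(default_factory=dict)
    complete: bool = True
    missing: tuple = ()

    def as_row(self) -> dict:
        row = {"sample": self.sample_id, "complete": self.complete}
        for g in GENES:
            row[f"prop_{g}"] = self.proportions.get(g, float("nan"))
            row[f"ct_{g}"] = self.mean_Ct.get(g, float("nan"))
        row.update(self.metadata)
        return row


def relative_expression(mean_cts: dict, curves: dict, sample_id: str = "",
                        metadata: dict | None = None,
                        log_base: float | None = None) -> ExpressionProfile:
    """Back-calculate each gene's N0 from its construct standard curve and
    normalise: N0_i = B**((Ct_i - b_i)/m_i), proportion_i = N0_i / sum_j N0_j.
    """
    missing = tuple(g for g in GENES
                    if g not in mean_cts or g not in curves
                    or not np.isfinite(mean_cts.get(g, float("nan"))))
    if missing:
        return ExpressionProfile(sample_id, {}, dict(mean_cts),
                                 metadata or {}, complete=False, missing=missing)
    n0 = {}
    for g in GENES:
        curve = curves[g]
        base = log_base if log_base is not None else curve.log_base
        n0[g] = base ** ((mean_cts[g] - curve.intercept_b) / curve.slope_m)
    total = sum(n0.values())
    props = {g: n0[g] / total for g in GENES}
    return ExpressionProfile(sample_id, props, dict(mean_cts), metadata or {})


# ---------------------------------------------------------------------------
# plate-level pipeline

def _geometric_mean(values: np.ndarray) -> float:
    v = np.asarray(values, dtype=float)
    v = v[v > 0]
    if len(v) == 0:
        return float("nan")
    return float(np.exp(np.mean(np.log(v))))


def quantify(curves_df: pd.DataFrame, meta_df: pd.DataFrame | None = None,
             cfg: WindowConfig = WindowConfig()):
    """Run the full quantification stage on a long-format curve table.

    Expected columns: plate, well, sample, gene, replicate, cycle,
    fluorescence, is_standard (0/1), log10_concentration (standards only).

    Returns (profiles_df, qc_df, fits_df).  Samples failing duplicate QC
    for any gene, or missing a gene, yield incomplete profiles that are
    flagged (complete=False) and meant to be excluded downstream.
    """
    fits = {}
    keycols = ["plate", "well", "sample", "gene", "replicate"]
    for key, grp in curves_df.groupby(keycols, sort=True):
        plate, well, sample, gene, rep = key
        grp = grp.sort_values("cycle")
        is_std = bool(grp["is_standard"].iloc[0]) if "is_standard" in grp else False
        logc = grp["log10_concentration"].iloc[0] if is_std else None
        curve = AmplificationCurve(str(plate), str(well), str(sample), str(gene),
                                   int(rep), grp["cycle"].to_numpy(),
                                   grp["fluorescence"].to_numpy(),
                                   is_dilution_standard=is_std,
                                   log10_concentration=logc)
        fits[key] = fit_amplification(curve, cfg)

    # per plate x gene threshold: geometric mean of windowed fluorescence
    thresholds = {}
    for (plate, well, sample, gene, rep), fit in fits.items():
        if fit.ok:
            thresholds.setdefault((plate, gene), []).extend(fit.window_fluorescence)
    thresholds = {k: (cfg.threshold if cfg.threshold is not None
                      else _geometric_mean(np.array(v)))
                  for k, v in thresholds.items()}
    fits = {k: (f.with_threshold(thresholds[(k[0], k[3])])
                if f.ok and (k[0], k[3]) in thresholds else f)
            for k, f in fits.items()}

    # standard curves per plate x gene
    std_curves = {}
    for (plate, well, sample, gene, rep), fit in fits.items():
        if fit.curve is not None and fit.curve.is_dilution_standard:
            std_curves.setdefault((plate, gene), []).append(fit)
    std_curves = {k: fit_standard_curve(v, gene=k[1], log_base=cfg.log_base)
                  for k, v in std_curves.items() if len(v) >= 3}

    # duplicate QC per sample x gene
    qc_rows, qc_results = [], {}
    sample_fits = {}
    for key, fit in fits.items():
        plate, well, sample, gene, rep = key
        if fit.curve is not None and fit.curve.is_dilution_standard:
            continue
        sample_fits.setdefault((plate, sample, gene), []).append(fit)
    for (plate, sample, gene), ff in sorted(sample_fits.items()):
        if len(ff) != 2:
            qc = DuplicateQC(sample, gene, float("nan"), float("nan"), False,
                             ["replicate_count"])
        else:
            qc = qc_duplicates(ff[0], ff[1])
        qc_results[(plate, sample, gene)] = qc
        qc_rows.append({"plate": plate, "sample": sample, "gene": gene,
                        "mean_ct": qc.mean_Ct, "mean_n0": qc.mean_N0,
                        "pass": qc.passed, "reasons": ";".join(qc.reasons)})

    meta_lookup = {}
    if meta_df is not None:
        meta_lookup = {str(r["sample"]): {k: r[k] for k in meta_df.columns
                                          if k != "sample"}
                       for _, r in meta_df.iterrows()}

    profiles = []
    by_sample = {}
    for (plate, sample, gene), qc in qc_results.items():
        by_sample.setdefault((plate, sample), {})[gene] = qc
    for (plate, sample), per_gene in sorted(by_sample.items()):
        cts = {g: qc.mean_Ct for g, qc in per_gene.items() if qc.passed}
        curves = {g: std_curves[(plate, g)] for g in cts
                  if (plate, g) in std_curves}
        prof = relative_expression({g: cts[g] for g in curves}, curves,
                                   sample_id=sample,
                                   metadata=meta_lookup.get(sample, {}),
                                   log_base=cfg.log_base)
        profiles.append(prof)

    profiles_df = pd.DataFrame([p.as_row() for p in profiles])
    qc_df = pd.DataFrame(qc_rows)
    fit_rows = []
    for (plate, well, sample, gene, rep), fit in sorted(fits.items()):
        fit_rows.append({
            "plate": plate, "well": well, "sample": sample, "gene": gene,
            "replicate": rep,
            "is_standard": bool(fit.curve.is_dilution_standard) if fit.curve else False,
            "window_first": fit.window[0] if fit.window else np.nan,
            "window_last": fit.window[1] if fit.window else np.nan,
            "efficiency_E": fit.efficiency_E,
            "efficiency_percent": fit.efficiency_percent,
            "N0": fit.N0, "Ct": fit.Ct, "r_squared": fit.r_squared,
            "flags": ";".join(sorted(fit.qc_flags)),
        })
    fits_df = pd.DataFrame(fit_rows)
    return profiles_df, qc_df, fits_df
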