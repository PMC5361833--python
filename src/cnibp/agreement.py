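"""Method-comparison statistics for paired blood-pressure series.

Implements the full agreement battery used to validate a continuous
non-invasive monitor against an arterial line:

* Pearson correlation with Shapiro-Wilk normality screening,
* Bland-Altman bias, SD and 95% limits of agreement with normal-theory
  confidence intervals,
* the Pitman-Morgan test of equal variances for paired samples,
* 4-quadrant trending concordance with a central exclusion zone,
* polar trend analysis (angle from the line of identity) with empirical
  90%/95% angular boundaries,
* the AAMI/ISO 81060-2 "zero-zone" procedure (reference window mean +/- 1
  SD; readings inside score zero), and
* the AAMI verdict: |bias| <= 5 mmHg and SD <= 8 mmHg, limits inclusive.

The user-facing surface follows the model/results idiom: build a
:class:`MethodComparison` from paired series (or a DataFrame), call
``fit()``, and read the :class:`AgreementResults` (``summary()``, plots,
JSON export).  Differences are oriented test - reference throughout.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats as _st

__all__ = [
    "BlandAltmanResult", "TrendResult", "ZeroZoneResult", "AamiVerdict",
    "bland_altman", "pearson_and_normality", "pitman_test",
    "four_quadrant", "polar_trend", "zero_zone_aami", "aami_verdict",
    "consecutive_changes", "MethodComparison", "AgreementResults",
]

AAMI_BIAS_LIMIT_MMHG = 5.0
AAMI_SD_LIMIT_MMHG = 8.0
ZERO_ZONE_RANGE_LIMITS_MMHG = {"sbp": 20.0, "dbp": 12.0}


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass
class BlandAltmanResult:
    bias_mmhg: float
    sd_mmhg: float
    loa_lower_mmhg: float
    loa_upper_mmhg: float
    bias_ci_mmhg: tuple
    loa_lower_ci_mmhg: tuple
    loa_upper_ci_mmhg: tuple
    n: int


@dataclass
class TrendResult:
    concordance: float
    mean_polar_bias_deg: float
    boundary_90_deg: float
    boundary_95_deg: float
    n_retained: int
    n_excluded: int
    angles_deg: np.ndarray = field(repr=False, default=None)
    changes: pd.DataFrame = field(repr=False, default=None)


@dataclass
class ZeroZoneResult:
    mean_diff_mmhg: float
    sd_diff_mmhg: float
    n_readings: int
    n_excluded_reference: int
    n_in_zone: int
    passed: bool
    diffs_mmhg: np.ndarray = field(repr=False, default=None)


@dataclass
class AamiVerdict:
    passed: bool
    bias_mmhg: float
    sd_mmhg: float
    bias_margin_mmhg: float   # limit - |bias|; negative when exceeded
    sd_margin_mmhg: float


# ---------------------------------------------------------------------------
# core statistics
# ---------------------------------------------------------------------------

def bland_altman(ref, test, ci: float = 0.95) -> BlandAltmanResult:
    """Bland-Altman bias, SD and limits of agreement (test - ref).

    Limits are bias +/- 1.96 SD; confidence intervals use the standard
    normal-theory forms (bias: t * SD / sqrt(n); limits: t * SD *
    sqrt(3/n)).  Requires at least 2 pairs.
    """
    ref = np.asarray(ref, dtype=float)
    test = np.asarray(test, dtype=float)
    if len(ref) != len(test):
        raise ValueError("paired series must have equal length")
    n = len(ref)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = test - ref
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    lo, hi = bias - 1.96 * sd, bias + 1.96 * sd
    t = _st.t.ppf(0.5 + ci / 2, n - 1)
    se_bias = sd / math.sqrt(n)
    se_loa = sd * math.sqrt(3.0 / n)
    return BlandAltmanResult(
        bias_mmhg=bias, sd_mmhg=sd, loa_lower_mmhg=lo, loa_upper_mmhg=hi,
        bias_ci_mmhg=(bias - t * se_bias, bias + t * se_bias),
        loa_lower_ci_mmhg=(lo - t * se_loa, lo + t * se_loa),
        loa_upper_ci_mmhg=(hi - t * se_loa, hi + t * se_loa),
        n=n)


def pearson_and_normality(ref, test) -> dict:
    """Product-moment correlation plus per-device Shapiro-Wilk p-values.

    A zero-variance series makes r undefined; it is reported as NaN with
    ``degenerate=True``.
    """
    ref = np.asarray(ref, dtype=float)
    test = np.asarray(test, dtype=float)
    out = {"n": len(ref)}
    if ref.std() == 0 or test.std() == 0:
        out.update(r=np.nan, r_p=np.nan, degenerate=True)
    else:
        r, p = _st.pearsonr(ref, test)
        out.update(r=float(r), r_p=float(p), degenerate=False)
    for name, x in (("ref", ref), ("test", test)):
        if len(x) >= 3 and x.std() > 0:
            out[f"shapiro_p_{name}"] = float(_st.shapiro(x).pvalue)
        else:
            out[f"shapiro_p_{name}"] = np.nan
    return out


def pitman_test(ref, test) -> dict:
    """Pitman-Morgan test of equal marginal variances in paired samples.

    The statistic is the correlation between the pair sums and the pair
    differences; under equal variances it is zero, and its t-transform
    gives the p-value.  Degenerate (zero-variance) inputs are flagged.
    """
    ref = np.asarray(ref, dtype=float)
    test = np.asarray(test, dtype=float)
    n = len(ref)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    s, d = test + ref, test - ref
    if s.std() == 0 or d.std() == 0:
        return {"statistic": 0.0, "p": 1.0, "n": n, "degenerate": True}
    r = float(np.corrcoef(s, d)[0, 1])
    tval = r * math.sqrt(n - 2) / math.sqrt(max(1.0 - r * r, 1e-300))
    p = float(2 * _st.t.sf(abs(tval), n - 2))
    return {"statistic": r, "t": tval, "p": p, "n": n, "degenerate": False}


def consecutive_changes(values_ref, values_test, times=None,
                        interval_s: float | None = None) -> pd.DataFrame:
    """Paired consecutive changes (delta_ref, delta_test).

    When interval start times are given, changes are formed only between
    adjacent retained intervals (spacing == ``interval_s``); gaps from
    excluded intervals are never bridged.
    """
    r = np.asarray(values_ref, dtype=float)
    t = np.asarray(values_test, dtype=float)
    dr, dt = np.diff(r), np.diff(t)
    if times is not None and interval_s is not None:
        tt = np.asarray(times, dtype=float)
        adjacent = np.isclose(np.diff(tt), interval_s)
        dr, dt = dr[adjacent], dt[adjacent]
    return pd.DataFrame({"d_ref": dr, "d_test": dt})


def _exclusion_radius(changes: pd.DataFrame, zone: float,
                      mode: str) -> np.ndarray:
    """Boolean retain-mask after the central exclusion zone."""
    dr = changes["d_ref"].to_numpy()
    dt = changes["d_test"].to_numpy()
    if mode == "radius":
        # mean absolute change below the zone radius -> excluded
        return (np.abs(dr) + np.abs(dt)) / 2.0 >= zone
    if mode == "cap":
        # alternative reading: both changes smaller than the cap -> excluded
        return np.maximum(np.abs(dr), np.abs(dt)) >= zone
    raise ValueError("mode must be 'radius' or 'cap'")


def four_quadrant(changes: pd.DataFrame, zone_mmhg: float = 10.0,
                  mode: str = "radius") -> dict:
    """4-quadrant concordance of consecutive changes.

    After excluding pairs inside the central zone, concordance is the
    fraction whose changes agree in sign.  All-excluded input is flagged
    undefined.
    """
    keep = _exclusion_radius(changes, zone_mmhg, mode)
    dr = changes["d_ref"].to_numpy()[keep]
    dt = changes["d_test"].to_numpy()[keep]
    if len(dr) == 0:
        return {"concordance": np.nan, "n_retained": 0,
                "n_excluded": int(len(changes)), "undefined": True}
    agree = np.sign(dr) == np.sign(dt)
    return {"concordance": float(np.mean(agree)),
            "n_retained": int(len(dr)),
            "n_excluded": int(len(changes) - len(dr)),
            "undefined": False}


def polar_trend(changes: pd.DataFrame, zone_mmhg: float = 10.0,
                mode: str = "radius") -> TrendResult:
    """Polar trend analysis of consecutive changes.

    Each retained change pair becomes a point with angle theta =
    atan2(delta_test, delta_ref) - 45 deg (zero on the line of identity,
    wrapped to (-180, 180]) and radius = mean change magnitude.  The mean
    angle is the polar bias; the 90%/95% boundaries are the empirical
    symmetric half-widths about the identity line containing that share
    of the retained angles.
    """
    keep = _exclusion_radius(changes, zone_mmhg, mode)
    dr = changes["d_ref"].to_numpy()[keep]
    dt = changes["d_test"].to_numpy()[keep]
    n_ex = int(len(changes) - keep.sum())
    if len(dr) == 0:
        return TrendResult(concordance=np.nan, mean_polar_bias_deg=np.nan,
                           boundary_90_deg=np.nan, boundary_95_deg=np.nan,
                           n_retained=0, n_excluded=n_ex,
                           angles_deg=np.array([]), changes=changes.iloc[:0])
    theta = np.degrees(np.arctan2(dt, dr)) - 45.0
    theta = (theta + 180.0) % 360.0 - 180.0
    theta[theta == -180.0] = 180.0
    b90 = float(np.quantile(np.abs(theta), 0.90))
    b95 = float(np.quantile(np.abs(theta), 0.95))
    agree = np.sign(dr) == np.sign(dt)
    return TrendResult(concordance=float(np.mean(agree)),
                       mean_polar_bias_deg=float(theta.mean()),
                       boundary_90_deg=b90, boundary_95_deg=b95,
                       n_retained=int(len(theta)), n_excluded=n_ex,
                       angles_deg=theta,
                       changes=changes[keep].reset_index(drop=True))


def zero_zone_aami(reading_times_s, readings_mmhg, ref_times_s, ref_mmhg,
                   quantity: str = "sbp", window_s: float = 30.0) -> ZeroZoneResult:
    """AAMI/ISO 81060-2 zero-zone scoring of test readings.

    For each test reading, the reference values within +/- ``window_s``
    define a window.  If the window's max-minus-min range exceeds 20 mmHg
    (systolic) or 12 mmHg (diastolic), that reference is excluded.
    Otherwise the zone is the window mean +/- 1 SD: readings inside score
    a difference of 0, readings outside score the signed distance to the
    nearest zone edge.  The verdict passes iff |mean difference| <= 5 mmHg
    and SD <= 8 mmHg.
    """
    if quantity not in ZERO_ZONE_RANGE_LIMITS_MMHG:
        raise ValueError("zero-zone is defined for 'sbp' and 'dbp'")
    range_limit = ZERO_ZONE_RANGE_LIMITS_MMHG[quantity]
    rt = np.asarray(reading_times_s, dtype=float)
    rv = np.asarray(readings_mmhg, dtype=float)
    ft = np.asarray(ref_times_s, dtype=float)
    fv = np.asarray(ref_mmhg, dtype=float)

    diffs = []
    n_excluded = n_in_zone = 0
    for t, x in zip(rt, rv):
        sel = (ft >= t - window_s) & (ft <= t + window_s)
        w = fv[sel]
        w = w[np.isfinite(w)]
        if len(w) == 0:
            continue  # no reference data: reading skipped
        if w.max() - w.min() > range_limit:
            n_excluded += 1
            continue
        m, s = w.mean(), w.std(ddof=1) if len(w) > 1 else 0.0
        lo, hi = m - s, m + s
        if lo <= x <= hi:
            diffs.append(0.0)
            n_in_zone += 1
        elif x > hi:
            diffs.append(x - hi)
        else:
            diffs.append(x - lo)
    diffs = np.asarray(diffs)
    if len(diffs) == 0:
        return ZeroZoneResult(mean_diff_mmhg=np.nan, sd_diff_mmhg=np.nan,
                              n_readings=0, n_excluded_reference=n_excluded,
                              n_in_zone=0, passed=False, diffs_mmhg=diffs)
    mean = float(diffs.mean())
    sd = float(diffs.std(ddof=1)) if len(diffs) > 1 else 0.0
    return ZeroZoneResult(
        mean_diff_mmhg=mean, sd_diff_mmhg=sd, n_readings=int(len(diffs)),
        n_excluded_reference=n_excluded, n_in_zone=n_in_zone,
        passed=(abs(mean) <= AAMI_BIAS_LIMIT_MMHG and sd <= AAMI_SD_LIMIT_MMHG),
        diffs_mmhg=diffs)


def aami_verdict(bias_mmhg: float, sd_mmhg: float) -> AamiVerdict:
    """AAMI 81060-2 accuracy verdict: |bias| <= 5 and SD <= 8 mmHg.

    Limits are inclusive ("not greater than").  Margins report the
    headroom to each limit (negative when exceeded).
    """
    bm = AAMI_BIAS_LIMIT_MMHG - abs(bias_mmhg)
    sm = AAMI_SD_LIMIT_MMHG - sd_mmhg
    return AamiVerdict(passed=(bm >= 0 and sm >= 0),
                       bias_mmhg=float(bias_mmhg), sd_mmhg=float(sd_mmhg),
                       bias_margin_mmhg=float(bm), sd_margin_mmhg=float(sm))


# ---------------------------------------------------------------------------
# model / results surface
# ---------------------------------------------------------------------------

QUANTITIES = ("sbp", "dbp", "map")


class MethodComparison:
    """Paired-series comparison of a test device against a reference.

    Parameters
    ----------
    data : DataFrame with ``interval_start_s`` and ``ref_``/``test_``
        prefixed columns for each quantity (sbp, dbp, map).
    interval_s : spacing of the interval grid (s); consecutive-change
        statistics only pair adjacent intervals.
    zone_mmhg : central exclusion-zone radius for trending statistics.
    zone_mode : 'radius' (mean absolute change below the radius is
        excluded, the default) or 'cap'.
    """

    def __init__(self, data: pd.DataFrame, interval_s: float = 10.0,
                 zone_mmhg: float = 10.0, zone_mode: str = "radius"):
        required = {"interval_start_s"} | {
            f"{side}_{q}" for side in ("ref", "test") for q in QUANTITIES}
        missing = required - set(data.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        self.data = data.sort_values("interval_start_s").reset_index(drop=True)
        self.interval_s = interval_s
        self.zone_mmhg = zone_mmhg
        self.zone_mode = zone_mode

    @classmethod
    def from_paired_series(cls, paired, **kw) -> "MethodComparison":
        """Build from a :class:`cnibp.series.PairedSeries`."""
        return cls(paired.data, interval_s=paired.interval_s, **kw)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, ref_prefix="ref_",
                       test_prefix="test_", **kw) -> "MethodComparison":
        ren = {}
        for q in QUANTITIES:
            ren[f"{ref_prefix}{q}"] = f"ref_{q}"
            ren[f"{test_prefix}{q}"] = f"test_{q}"
        return cls(df.rename(columns=ren), **kw)

    def fit(self, zero_zone: bool = True,
            zero_zone_window_s: float = 30.0) -> "AgreementResults":
        """Compute every agreement statistic and return the results."""
        per_q = {}
        for q in QUANTITIES:
            ref = self.data[f"ref_{q}"].to_numpy()
            test = self.data[f"test_{q}"].to_numpy()
            times = self.data["interval_start_s"].to_numpy()
            ch = consecutive_changes(ref, test, times, self.interval_s)
            entry = {
                "bland_altman": bland_altman(ref, test),
                "pearson": pearson_and_normality(ref, test),
                "pitman": pitman_test(ref, test) if len(ref) >= 3 else None,
                "four_quadrant": four_quadrant(ch, self.zone_mmhg, self.zone_mode),
                "polar": polar_trend(ch, self.zone_mmhg, self.zone_mode),
            }
            ba = entry["bland_altman"]
            entry["aami"] = aami_verdict(ba.bias_mmhg, ba.sd_mmhg)
            if zero_zone and q in ZERO_ZONE_RANGE_LIMITS_MMHG:
                entry["zero_zone"] = zero_zone_aami(
                    times, test, times, ref, quantity=q,
                    window_s=zero_zone_window_s)
            per_q[q] = entry
        return AgreementResults(self, per_q)


class AgreementResults:
    """Fitted agreement statistics for each quantity (SBP, DBP, MAP)."""

    def __init__(self, model: MethodComparison, per_quantity: dict):
        self.model = model
        self.per_quantity = per_quantity

    def __getitem__(self, q: str) -> dict:
        return self.per_quantity[q]

    @property
    def n_pairs(self) -> int:
        return len(self.model.data)

    def summary(self) -> str:
        """Plain-text table in the style of a validation report."""
        lines = [
            "Method comparison (test - reference), "
            f"n = {self.n_pairs} paired 10-s intervals",
            "=" * 78,
            f"{'quantity':<9}{'bias':>8}{'SD':>8}{'LoA':>18}{'r':>7}"
            f"{'concord.':>10}{'polar bias':>12}{'AAMI':>6}",
            "-" * 78,
        ]
        for q, e in self.per_quantity.items():
            ba, fq, po = e["bland_altman"], e["four_quadrant"], e["polar"]
            loa = f"[{ba.loa_lower_mmhg:6.2f},{ba.loa_upper_mmhg:6.2f}]"
            r = e["pearson"]["r"]
            lines.append(
                f"{q.upper():<9}{ba.bias_mmhg:8.2f}{ba.sd_mmhg:8.2f}{loa:>18}"
                f"{r:7.3f}{fq['concordance']:10.3f}"
                f"{po.mean_polar_bias_deg:12.2f}"
                f"{'pass' if e['aami'].passed else 'FAIL':>6}")
        lines.append("-" * 78)
        lines.append("AAMI 81060-2 limits: |bias| <= 5 mmHg, SD <= 8 mmHg "
                     "(inclusive); polar bias in degrees.")
        for q, e in self.per_quantity.items():
            zz = e.get("zero_zone")
            if zz is not None and zz.n_readings:
                lines.append(
                    f"zero-zone {q.upper()}: mean {zz.mean_diff_mmhg:.2f} "
                    f"SD {zz.sd_diff_mmhg:.2f} mmHg over {zz.n_readings} "
                    f"readings ({zz.n_excluded_reference} reference windows "
                    f"excluded) -> {'pass' if zz.passed else 'FAIL'}")
        return "\n".join(lines)

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        def clean(obj):
            if isinstance(obj, (BlandAltmanResult, AamiVerdict)):
                return {k: clean(v) for k, v in vars(obj).items()}
            if isinstance(obj, (TrendResult, ZeroZoneResult)):
                return {k: clean(v) for k, v in vars(obj).items()
                        if k not in ("angles_deg", "changes", "diffs_mmhg")}
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, (tuple, list)):
                return [clean(v) for v in obj]
            if isinstance(obj, (np.floating, float)):
                v = float(obj)
                return None if math.isnan(v) else v
            if isinstance(obj, (np.integer,)):
                return int(obj)
            if isinstance(obj, (np.bool_, bool)):
                return bool(obj)
            return obj
        return {"n_pairs": self.n_pairs,
                "quantities": clean(self.per_quantity)}

    def to_json(self, path=None, **kw) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True, **kw)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for q, e in self.per_quantity.items():
            ba = e["bland_altman"]
            rows.append({
                "quantity": q, "n": ba.n, "bias_mmhg": ba.bias_mmhg,
                "sd_mmhg": ba.sd_mmhg, "loa_lower_mmhg": ba.loa_lower_mmhg,
                "loa_upper_mmhg": ba.loa_upper_mmhg,
                "pearson_r": e["pearson"]["r"],
                "pitman_p": e["pitman"]["p"] if e["pitman"] else np.nan,
                "concordance": e["four_quadrant"]["concordance"],
                "polar_bias_deg": e["polar"].mean_polar_bias_deg,
                "aami_pass": e["aami"].passed,
            })
        return pd.DataFrame(rows)

    # -- plotting (thin wrappers; see cnibp.plots) --------------------------

    def plot_bland_altman(self, quantity="sbp", ax=None):
        from . import plots
        return plots.bland_altman_plot(self, quantity, ax=ax)

    def plot_four_quadrant(self, quantity="sbp", ax=None):
        from . import plots
        return plots.four_quadrant_plot(self, quantity, ax=ax)

    def plot_polar(self, quantity="sbp", ax=None):
        from . import plots
        return plots.polar_plot(self, quantity, ax=ax)
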