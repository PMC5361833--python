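"""Figures for the agreement report: Bland-Altman, correlation,
4-quadrant, polar trend, and SD-over-time."""

from __future__ import annotations

import numpy as np

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

_LABEL = {"sbp": "systolic", "dbp": "diastolic", "map": "MAP"}


def _ax(ax, polar=False):
    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"} if polar else None)
    return ax


def bland_altman_plot(results, quantity="sbp", ax=None):
    ax = _ax(ax)
    d = results.model.data
    ref = d[f"ref_{quantity}"].to_numpy()
    test = d[f"test_{quantity}"].to_numpy()
    ba = results[quantity]["bland_altman"]
    mean = (ref + test) / 2.0
    ax.scatter(mean, test - ref, s=6, alpha=0.5)
    for y, style in ((ba.bias_mmhg, "-"), (ba.loa_lower_mmhg, "--"),
                     (ba.loa_upper_mmhg, "--")):
        ax.axhline(y, color="k", linestyle=style, linewidth=1)
    ax.set_xlabel(f"mean of methods, {_LABEL[quantity]} (mmHg)")
    ax.set_ylabel("test - reference (mmHg)")
    ax.set_title(f"Bland-Altman, {_LABEL[quantity]}: bias "
                 f"{ba.bias_mmhg:.2f}, SD {ba.sd_mmhg:.2f} mmHg")
    return ax


def correlation_plot(results, quantity="sbp", ax=None):
    ax = _ax(ax)
    d = results.model.data
    ref = d[f"ref_{quantity}"].to_numpy()
    test = d[f"test_{quantity}"].to_numpy()
    ax.scatter(ref, test, s=6, alpha=0.5)
    lims = [min(ref.min(), test.min()), max(ref.max(), test.max())]
    ax.plot(lims, lims, "k--", linewidth=1)
    r = results[quantity]["pearson"]["r"]
    ax.set_xlabel(f"reference {_LABEL[quantity]} (mmHg)")
    ax.set_ylabel(f"test {_LABEL[quantity]} (mmHg)")
    ax.set_title(f"correlation, {_LABEL[quantity]}: r = {r:.3f}")
    return ax


def four_quadrant_plot(results, quantity="sbp", ax=None):
    ax = _ax(ax)
    po = results[quantity]["polar"]
    zone = results.model.zone_mmhg
    ch = po.changes
    ax.scatter(ch["d_ref"], ch["d_test"], s=8, alpha=0.6)
    lim = max(15.0, zone * 2.0)
    if len(ch):
        lim = max(lim, 1.1 * max(ch["d_ref"].abs().max(), ch["d_test"].abs().max()))
    ax.add_patch(plt.Rectangle((-zone, -zone), 2 * zone, 2 * zone,
                               fill=False, edgecolor="gray", linestyle=":"))
    ax.plot([-lim, lim], [-lim, lim], "k--", linewidth=1)
    ax.axhline(0, color="k", linewidth=0.5)
    ax.axvline(0, color="k", linewidth=0.5)
    ax.set_xlim(-lim, lim)
    ax.set_ylim(-lim, lim)
    ax.set_xlabel("consecutive change, reference (mmHg)")
    ax.set_ylabel("consecutive change, test (mmHg)")
    fq = results[quantity]["four_quadrant"]
    ax.set_title(f"4-quadrant, {_LABEL[quantity]}: "
                 f"concordance {fq['concordance']:.3f}")
    return ax


def polar_plot(results, quantity="sbp", ax=None):
    ax = _ax(ax, polar=True)
    po = results[quantity]["polar"]
    ch = po.changes
    if len(ch):
        radius = (ch["d_ref"].abs() + ch["d_test"].abs()) / 2.0
        ax.scatter(np.radians(po.angles_deg), radius, s=8, alpha=0.6)
        rmax = float(radius.max()) * 1.1
    else:
        rmax = 1.0
    for b in (po.boundary_90_deg, po.boundary_95_deg):
        if np.isfinite(b):
            for sgn in (1, -1):
                ax.plot([sgn * np.radians(b)] * 2, [0, rmax], "k--",
                        linewidth=0.8)
    ax.set_thetamin(-90)
    ax.set_thetamax(90)
    ax.set_title(f"polar trend, {_LABEL[quantity]}: bias "
                 f"{po.mean_polar_bias_deg:.1f} deg, "
                 f"90/95% at {po.boundary_90_deg:.1f}/"
                 f"{po.boundary_95_deg:.1f} deg")
    return ax


def sd_over_time_plot(results, window_n: int = 18, ax=None):
    """Rolling SD of the differences over the record (drift check)."""
    ax = _ax(ax)
    d = results.model.data
    t = d["interval_start_s"].to_numpy() / 60.0
    for q in ("sbp", "dbp"):
        diff = (d[f"test_{q}"] - d[f"ref_{q}"])
        sd = diff.rolling(window_n, min_periods=3, center=True).std()
        ax.plot(t, sd, label=_LABEL[q])
    ax.set_xlabel("time (min)")
    ax.set_ylabel("rolling SD of differences (mmHg)")
    ax.legend()
    ax.set_title("difference SD over time")
    return ax
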