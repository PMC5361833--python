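"""10-second averaging and pairing of the two devices' beat-level outputs.

Both the arterial line and the cuff device report beat-level SBP/DBP;
for comparison each is averaged over contiguous half-open 10-s intervals,
intervals with too few beats are invalidated, and only intervals valid on
both devices (and not excluded by the quality mask) are retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import mean_arterial_pressure

__all__ = ["BPSeries", "PairedSeries", "beats_to_series", "pair_series",
           "intra_patient_range"]

INTERVAL_S = 10.0
MIN_BEATS_PER_INTERVAL = 3


@dataclass
class BPSeries:
    """10-s-averaged SBP/DBP/MAP for one device.

    ``data`` columns: interval_start_s, sbp, dbp, map, n_beats, valid.
    Intervals are contiguous and half-open, [t, t+width).
    """

    data: pd.DataFrame
    device: str
    interval_s: float = INTERVAL_S

    def __len__(self):
        return len(self.data)

    @property
    def valid(self) -> pd.DataFrame:
        return self.data[self.data["valid"]]

    def to_frame(self) -> pd.DataFrame:
        out = self.data.rename(columns={"sbp": "sbp_mmhg", "dbp": "dbp_mmhg",
                                        "map": "map_mmhg"})
        out.insert(1, "device", self.device)
        return out

    def to_csv(self, path):
        self.to_frame().to_csv(path, index=False)


@dataclass
class PairedSeries:
    """Mutually valid 10-s intervals of reference and test devices.

    ``data`` columns: interval_start_s, then ref_/test_ prefixed
    sbp/dbp/map.  ``n_dropped`` counts grid intervals lost to invalidity
    or mask exclusion.
    """

    data: pd.DataFrame
    interval_s: float
    n_dropped: int = 0

    def __len__(self):
        return len(self.data)

    @property
    def excluded_fraction(self) -> float:
        total = len(self.data) + self.n_dropped
        return self.n_dropped / total if total else 0.0

    def quantity(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        """(reference, test) arrays for 'sbp' | 'dbp' | 'map'."""
        return (self.data[f"ref_{name}"].to_numpy(),
                self.data[f"test_{name}"].to_numpy())


def beats_to_series(beat_times_s, sbp, dbp, window: tuple[float, float],
                    device: str = "device", interval_s: float = INTERVAL_S,
                    min_beats: int = MIN_BEATS_PER_INTERVAL) -> BPSeries:
    """Average beat-level SBP/DBP into contiguous 10-s bins.

    Beats are assigned to half-open bins [t, t+interval) anchored at the
    window start; bins with fewer than ``min_beats`` beats are flagged
    invalid.  MAP follows DBP + PP/3.  Empty input yields an all-invalid
    series over the window.
    """
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("window end must follow start")
    starts = np.arange(t0, t1 - 1e-9, interval_s)
    bt = np.asarray(beat_times_s, dtype=float)
    sbp = np.asarray(sbp, dtype=float)
    dbp = np.asarray(dbp, dtype=float)

    rows = []
    for s in starts:
        in_bin = (bt >= s) & (bt < s + interval_s)
        n = int(in_bin.sum())
        if n >= min_beats:
            sb, db = float(sbp[in_bin].mean()), float(dbp[in_bin].mean())
            rows.append({"interval_start_s": s, "sbp": sb, "dbp": db,
                         "map": float(mean_arterial_pressure(sb, db)),
                         "n_beats": n, "valid": db < sb})
        else:
            rows.append({"interval_start_s": s, "sbp": np.nan, "dbp": np.nan,
                         "map": np.nan, "n_beats": n, "valid": False})
    return BPSeries(data=pd.DataFrame(rows), device=device,
                    interval_s=interval_s)


def pair_series(ref: BPSeries, test: BPSeries, mask=None) -> PairedSeries:
    """Join two series on their common interval grid.

    Keeps intervals valid on both devices and free of any mask-excluded
    second; a pair is dropped, never imputed.  Raises on disjoint grids.
    """
    if ref.interval_s != test.interval_s:
        raise ValueError("series use different interval widths")
    a, b = ref.data, test.data
    common = np.intersect1d(a["interval_start_s"].to_numpy(),
                            b["interval_start_s"].to_numpy())
    if len(common) == 0:
        raise ValueError("series grids are disjoint")

    ra = a.set_index("interval_start_s").loc[common]
    rb = b.set_index("interval_start_s").loc[common]
    keep = ra["valid"].to_numpy() & rb["valid"].to_numpy()

    if mask is not None:
        w = int(ref.interval_s)
        for k, s in enumerate(common):
            lo = int(s)
            hi = min(lo + w, len(mask))
            if lo >= len(mask) or not np.all(mask.both_valid[lo:hi]):
                keep[k] = False

    data = pd.DataFrame({
        "interval_start_s": common[keep],
        "ref_sbp": ra["sbp"].to_numpy()[keep],
        "ref_dbp": ra["dbp"].to_numpy()[keep],
        "ref_map": ra["map"].to_numpy()[keep],
        "test_sbp": rb["sbp"].to_numpy()[keep],
        "test_dbp": rb["dbp"].to_numpy()[keep],
        "test_map": rb["map"].to_numpy()[keep],
    })
    return PairedSeries(data=data, interval_s=ref.interval_s,
                        n_dropped=int(len(common) - keep.sum()))


def intra_patient_range(series: BPSeries) -> dict:
    """Max-minus-min SBP/DBP/MAP over the valid intervals (mmHg)."""
    v = series.valid
    if len(v) == 0:
        raise ValueError("no valid intervals")
    return {q: float(v[q].max() - v[q].min()) for q in ("sbp", "dbp", "map")}
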