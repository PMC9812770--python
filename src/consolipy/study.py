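"""Across-day study assembly: event trains -> day series -> transition fits.

Bridges the per-session event level (detected tables or generator ground
truth) and the transition-dynamics level: per-event coupling indicators
are split into tertiles per session, smoothed/normalized, and fitted with
the rise (PFC-M1 SO coupling) and drop (delta SO-SWR coupling) sigmoids
whose midpoints order the two consolidation stages.
"""

from __future__ import annotations

import numpy as np

from . import coupling as cpl
from . import dynamics as dyn


def coupling_indicators(target_times, reference_times, window) -> np.ndarray:
    """Per-target 0/100 indicator of nearest-reference coupling (time order)."""
    targets = np.sort(np.asarray(target_times, dtype=float))
    if len(targets) == 0 or len(reference_times) == 0:
        return np.empty(0)
    lags = cpl.nearest_lags(targets, reference_times).lags
    return 100.0 * ((lags >= window[0]) & (lags <= window[1]))


def pfc_m1_series(day_events: dict, window=(-0.2, 0.2)) -> dyn.DaySeries:
    """PFC-M1 SO coupling day series from post-sleep events.

    ``day_events`` maps day -> {'post': {'pfc_up', 'm1_up', ...}, 'pre': ...}
    with event-time arrays. Items are per-M1-SO coupling indicators so the
    tertile split follows event order within the session.
    """
    sessions = {}
    for day, blocks in day_events.items():
        b = blocks["post"]
        sessions[day] = coupling_indicators(b["m1_up"], b["pfc_up"], window)
    return dyn.tertile_series(sessions, "pfc_m1_so_coupling")


def delta_so_swr_series(day_events: dict, window=(-0.75, 0.75)) -> dyn.DaySeries:
    """Delta SO-SWR coupling (post minus pre) day series.

    Post-sleep per-SWR indicators are tertiled; the session's pre-sleep
    mean coupling is subtracted so each tertile value is a post-minus-pre
    difference in percentage points.
    """
    sessions = {}
    for day, blocks in day_events.items():
        post = coupling_indicators(blocks["post"]["swr_peak"],
                                   blocks["post"]["m1_up"], window)
        pre = coupling_indicators(blocks["pre"]["swr_peak"],
                                  blocks["pre"]["m1_up"], window)
        if len(pre) == 0 or len(post) == 0:
            sessions[day] = np.empty(0)
        else:
            sessions[day] = post - float(np.mean(pre))
    return dyn.tertile_series(sessions, "delta_so_swr_coupling")


def events_from_ground_truth(days) -> dict:
    """day_events mapping from a list of generator DayData objects."""
    out = {}
    for d in days:
        out[d.day] = {}
        for blk, gt in (("pre", d.pre), ("post", d.post)):
            out[d.day][blk] = {
                "pfc_up": gt.so_up["PFC"],
                "m1_up": gt.so_up["M1"],
                "swr_peak": gt.swr_peak,
            }
    return out


def recover_transitions(day_events: dict, fit_range=(3, 13)):
    """Smoothed/normalized series and sigmoid fits for rise and drop.

    Returns dict with the two DaySeries, their SigmoidFit objects and the
    grand-midpoint (median of rise and drop midpoints).
    """
    rise = dyn.smooth_normalize(pfc_m1_series(day_events))
    drop = dyn.smooth_normalize(delta_so_swr_series(day_events))
    fit_rise = dyn.fit_sigmoid(rise.x_days, rise.normalized, fit_range)
    fit_drop = dyn.fit_sigmoid(drop.x_days, drop.normalized, fit_range)
    return {
        "rise_series": rise, "drop_series": drop,
        "rise_fit": fit_rise, "drop_fit": fit_drop,
        "grand_midpoint": dyn.grand_midpoint(fit_rise.x_mid, fit_drop.x_mid),
    }
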