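"""End-to-end per-session pipeline driver.

Runs the per-session analysis sequence on a session container: NREMS
staging on the M1 LFP of each sleep block, oscillation detection per area,
coupling summaries (PFC-M1 SO, SO-SWR with delta, SO-spindle, triple
coupling), GPFA on the training trials, SWR-condition labelling,
fixed-window reactivation and cross-area CCA, writing CSV results and a
provenance record. The run is a pure function of (inputs, config, seed).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import coupling as cpl
from . import detect, gpfa, io, reactivation, staging
from .types import IntervalSet


class StageError(RuntimeError):
    def __init__(self, stage, err):
        super().__init__(f"pipeline stage '{stage}' failed: {err}")
        self.stage = stage


def _stage(name):
    def deco(fn):
        def wrapped(*a, **k):
            try:
                return fn(*a, **k)
            except StageError:
                raise
            except Exception as e:
                raise StageError(name, e) from e
        return wrapped
    return deco


def _summary_row(s: cpl.CouplingSummary, block):
    return dict(block=block, metric=s.metric, value=s.value, n=s.n_events,
                window_lo=s.window[0], window_hi=s.window[1],
                flagged=s.flagged, note=s.note)


@_stage("staging")
def _stage_block(recordings, manifest, block, cfg, seed):
    st = cfg["staging"]
    area = st.get("trace_area", "M1")
    rec = recordings[area]
    lo, hi = manifest.block_interval(block)
    if hi - lo < st["epoch_s"]:
        raise ValueError(f"no NREMS available: {block} block shorter than one epoch")
    tr = detect.make_trace(rec, "plain_mean",
                           artifact_sd=cfg["detection"]["artifact_sd"])
    i0 = int(round((lo - rec.t0) * rec.rate))
    i1 = int(round((hi - rec.t0) * rec.rate))
    nrems = staging.stage_block(tr[i0:i1], rec.rate, seed=seed, cfg=st,
                                t_offset=lo)
    if nrems.total_duration() <= 0:
        raise ValueError(f"no NREMS available in {block} block")
    return nrems


def run_session(container_path, out_dir, config=None, seed=0):
    """Run the full per-session pipeline; returns the results dict."""
    cfg = config or io.load_config()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = io.load_manifest(container_path)
    recordings = {a: io.load_recording(container_path, a)
                  for a in ("PFC", "M1", "HPC")}
    spikes = io.load_spikes(container_path)
    trials = io.load_trials(container_path)
    results = {"coupling": [], "reactivation": [], "provenance": {
        "config_hash": io.config_hash(cfg), "seed": int(seed),
        "animal": manifest.animal_id, "day": manifest.day}}

    events = {}
    nrems_by_block = {}
    for block in ("pre_sleep", "post_sleep"):
        nrems = _stage_block(recordings, manifest, block, cfg, seed)
        nrems_by_block[block] = nrems
        io.write_intervals(nrems, out / f"nrems_{block}.csv")
        try:
            tables = detect.detect_block(recordings, nrems, cfg)
        except Exception as e:
            raise StageError("detection", e) from e
        for (kind, area), tab in tables.items():
            events[(block, kind, area)] = tab
            io.write_events(tab, out / f"events_{block}_{area}_{kind}.csv")

    ccfg = cfg["coupling"]
    so_swr = {}
    for block in ("pre_sleep", "post_sleep"):
        try:
            pfc_up = events[(block, "SO", "PFC")]["t_peak"].to_numpy()
            m1_up = events[(block, "SO", "M1")]["t_peak"].to_numpy()
            swr_pk = events[(block, "SWR", "HPC")]["t_peak"].to_numpy()
            sp_pk = events[(block, "SPINDLE", "M1")]["t_peak"].to_numpy()
            s = cpl.pfc_m1_so_coupling(pfc_up, m1_up,
                                       tuple(ccfg["pfc_m1_window"]))
            results["coupling"].append(_summary_row(s, block))
            s = cpl.so_swr_coupling(swr_pk, m1_up, tuple(ccfg["so_swr_window"]))
            so_swr[block] = s
            results["coupling"].append(_summary_row(s, block))
            s = cpl.so_spindle_coupling(m1_up, sp_pk,
                                        tuple(ccfg["so_spindle_window"]))
            results["coupling"].append(_summary_row(s, block))
            if len(swr_pk):
                s = cpl.multi_coupling(swr_pk, m1_up, sp_pk, "triple",
                                       window=tuple(ccfg["multi_window"]))
                results["coupling"].append(_summary_row(s, block))
        except StageError:
            raise
        except Exception as e:
            raise StageError("coupling", e) from e
    if so_swr.get("pre_sleep") and so_swr.get("post_sleep"):
        pre, post = so_swr["pre_sleep"], so_swr["post_sleep"]
        if pre.value is not None and post.value is not None:
            results["delta_so_swr"] = cpl.delta_coupling(post, pre)

    # ---- training-block GPFA + sleep reactivation
    gcfg = cfg["gpfa"]
    m1 = spikes.by_area("M1")
    if len(m1) and len(trials):
        try:
            tensor = gpfa.bin_zscore([t for _, _, t in m1.units], m1.unit_ids,
                                     trials["reach_onset"].to_numpy(),
                                     tuple(gcfg["window"]), gcfg["bin_s"],
                                     min_rate_hz=gcfg["min_rate_hz"])
            q = min(gcfg["top_factors"], tensor.n_units - 1)
            model = gpfa.fit_gpfa(tensor, q, tol=gcfg["em_tol"],
                                  max_iter=min(gcfg["em_max_iter"], 100),
                                  seed=seed,
                                  gp_noise_frac=gcfg["gp_noise_frac"])
            trajs, shared_frac, sot = gpfa.extract_trajectories(model, tensor)
            template = reactivation.reach_template(trajs)
            results["shared_over_total"] = sot
            rs = [gpfa.gpfa_correlation(t, template) for t in trajs]
            results["gpfa_correlation_mean"] = float(np.mean(rs))
            fid = gpfa.fidelity(rs)
            results["fidelity"] = fid.fidelity
        except StageError:
            raise
        except Exception as e:
            raise StageError("gpfa", e) from e

        try:
            rcfg = cfg["reactivation"]
            nrems = nrems_by_block["post_sleep"]
            swr_tab = events[("post_sleep", "SWR", "HPC")]
            m1_up = events[("post_sleep", "SO", "M1")]["t_peak"].to_numpy()
            if len(swr_tab):
                labels = cpl.label_swr_conditions(
                    swr_tab["t_onset"].to_numpy(), m1_up, nrems, seed=seed,
                    follow_s=ccfg["swr_so_plus_window"])
                unit_times = [t for (uid, _, t) in m1.units
                              if uid in tensor.unit_ids]
                r_plus = reactivation.reactivation_fixed(
                    unit_times, labels.swr_onsets, model, tensor, template,
                    rcfg["fixed_window_s"], rcfg["bin_s"])
                r_minus = reactivation.reactivation_fixed(
                    unit_times, labels.swr_minus_onsets, model, tensor,
                    template, rcfg["fixed_window_s"], rcfg["bin_s"])
                for cond, rv, onsets in (
                        ("SWR+", r_plus, labels.swr_onsets),
                        ("SWR-", r_minus, labels.swr_minus_onsets),
                        ("SWR+SO+", r_plus[labels.so_plus], None),
                        ("SWR+SO-", r_plus[~labels.so_plus], None)):
                    ok = np.isfinite(rv)
                    results["reactivation"].append(dict(
                        condition=cond, n_events=int(ok.sum()),
                        mean_R=float(np.mean(rv[ok])) if ok.any() else None,
                        median_R=float(np.median(rv[ok])) if ok.any() else None,
                        window_ms=rcfg["fixed_window_s"] * 1000.0, lag_ms=0.0))
        except StageError:
            raise
        except Exception as e:
            raise StageError("reactivation", e) from e

    # ---- cross-area communication subspace (CCA) during post-sleep SWRs
    pfc = spikes.by_area("PFC")
    if len(pfc) >= 2 and len(m1) >= 2 and ("post_sleep", "SWR", "HPC") in events:
        swr_on = events[("post_sleep", "SWR", "HPC")]["t_onset"].to_numpy()
        if len(swr_on) >= 5:
            try:
                rcfg = cfg["reactivation"]
                m1_up = events[("post_sleep", "SO", "M1")]["t_peak"].to_numpy()
                labels = cpl.label_swr_conditions(
                    swr_on, m1_up, nrems_by_block["post_sleep"], seed=seed,
                    follow_s=ccfg["swr_so_plus_window"])
                pfc_t = [t for _, _, t in pfc.units]
                m1_t = [t for _, _, t in m1.units]
                X = reactivation.cca_event_matrix(pfc_t, swr_on,
                                                  rcfg["cca_window_s"],
                                                  rcfg["bin_s"])
                Y = reactivation.cca_event_matrix(m1_t, swr_on,
                                                  rcfg["cca_window_s"],
                                                  rcfg["bin_s"])
                cca = reactivation.fit_cca(X, Y)
                results["cca_top_correlation"] = cca.corr
                nb = int(np.floor(rcfg["cca_window_s"] / rcfg["bin_s"] + 1e-9))
                mask = np.repeat(labels.so_plus, nb)
                r_pp = reactivation.cross_area_r(cca, X[mask], Y[mask])
                r_pm = reactivation.cross_area_r(cca, X[~mask], Y[~mask])
                results["cross_area_r_so_plus"] = r_pp
                results["cross_area_r_so_minus"] = r_pm
                results["delta_cross_area_r"] = r_pp - r_pm
            except StageError:
                raise
            except ValueError:
                pass  # too few events in a condition: CCA results omitted
            except Exception as e:
                raise StageError("cca", e) from e

    pd.DataFrame(results["coupling"]).to_csv(out / "coupling.csv", index=False)
    if results["reactivation"]:
        pd.DataFrame(results["reactivation"]).to_csv(
            out / "reactivation.csv", index=False)
    with open(out / "provenance.json", "w") as fh:
        json.dump(results["provenance"], fh, indent=2, sort_keys=True)
    scalars = {k: v for k, v in results.items()
               if isinstance(v, (int, float))}
    with open(out / "summary.json", "w") as fh:
        json.dump(scalars, fh, indent=2, sort_keys=True)
    return results
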