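import numpy as np
import pytest

from consolipy import detect, gpfa, io, synth


@pytest.fixture(scope="session")
def sim_cfg():
    """Short-block generator config shared by the slower fixtures."""
    return synth.SimConfig(sleep_block_s=300.0, n_trials=30)


@pytest.fixture(scope="session")
def sleep_block(sim_cfg):
    """One synthesized sleep block (recordings + ground truth)."""
    return synth.simulate_sleep_block(sim_cfg, seed=42)


@pytest.fixture(scope="session")
def trained_session(sim_cfg):
    """Training block with fitted GPFA model, trajectories and template."""
    from consolipy import reactivation as rx

    spikes, trials, gt = synth.simulate_training_block(sim_cfg, seed=7)
    tensor = gpfa.bin_zscore([t for _, _, t in spikes.units],
                             spikes.unit_ids,
                             trials["reach_onset"].to_numpy(),
                             sim_cfg.trial_window_s)
    model = gpfa.fit_gpfa(tensor, 3, max_iter=60, tol=1e-5)
    trajs, _, _ = gpfa.extract_trajectories(model, tensor)
    template = rx.reach_template(trajs)
    return dict(spikes=spikes, trials=trials, gt=gt, tensor=tensor,
                model=model, trajs=trajs, template=template, cfg=sim_cfg)


@pytest.fixture()
def session_container(tmp_path, sim_cfg):
    """A one-day session container on disk (pre-sleep/training/post-sleep)."""
    days = synth.simulate_study(sim_cfg, seed=5, n_days=1, lfp=True)
    d = days[0]
    recs = synth.assemble_session_recordings(d, sim_cfg, seed=5)
    path = tmp_path / "session.h5"
    for rec in recs.values():
        io.write_recording(path, rec)
    io.write_spikes(path, d.spikes)
    io.write_trials(path, d.trials)
    io.write_manifest(path, d.manifest)
    return path, d


def match_f1(detected, truth, tol=0.1):
    """Greedy one-to-one peak matching -> (f1, precision, recall)."""
    det = np.sort(np.asarray(detected, dtype=float))
    true = np.sort(np.asarray(truth, dtype=float))
    used = np.zeros(len(det), bool)
    tp = 0
    for t in true:
        if not len(det):
            break
        d = np.abs(det - t)
        i = int(np.argmin(np.where(used, np.inf, d)))
        if not used[i] and d[i] < tol:
            used[i] = True
            tp += 1
    prec = tp / len(det) if len(det) else 0.0
    rec = tp / len(true) if len(true) else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    return f1, prec, rec
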