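import dataclasses

import numpy as np
import pandas as pd
import pytest

from nremscope import behavior, psg_io, synthsleep
from nremscope.synthsleep import (DEFAULT_TRANSITION, GroupEffects, SimConfig,
                                  gen_behavior, gen_hypnogram, gen_psg,
                                  gen_subject, stationary_distribution,
                                  write_subject)


def _rng(seed=0):
    return np.random.default_rng(np.random.SeedSequence(seed))


def _replace(cfg, **kw):
    return dataclasses.replace(cfg, **kw)


def test_determinism():
    cfg = SimConfig(seed=3, n_epochs=60)
    a = gen_subject(cfg, _rng(3))
    b = gen_subject(cfg, _rng(3))
    np.testing.assert_array_equal(a.recording.data, b.recording.data)
    pd.testing.assert_frame_equal(a.ground_truth, b.ground_truth)
    np.testing.assert_array_equal(a.hypnogram.stages, b.hypnogram.stages)
    assert a.tapping == b.tapping and a.clinical == b.clinical


def test_absorbing_chain():
    P = np.zeros((5, 5))
    P[0, 2] = 1.0              # Wake -> N2
    for i in (1, 2, 3, 4):
        P[i, i] = 1.0
    cfg = _replace(SimConfig(n_epochs=10), transition=P)
    hyp = gen_hypnogram(cfg, _rng(0))
    assert list(hyp.stages) == ["Wake"] + ["N2"] * 9


def test_invalid_transition_rejected():
    bad = np.full((5, 5), 0.3)
    with pytest.raises(ValueError):
        gen_hypnogram(_replace(SimConfig(), transition=bad), _rng(0))


def test_stationary_distribution_oracle():
    pi = stationary_distribution(DEFAULT_TRANSITION)
    assert pi.sum() == pytest.approx(1.0)
    np.testing.assert_allclose(pi @ DEFAULT_TRANSITION, pi, atol=1e-12)
    # long-run stage proportions approach the stationary distribution
    cfg = SimConfig(n_epochs=5000)
    hyp = gen_hypnogram(cfg, _rng(0))
    counts = np.array([(hyp.stages == s).sum()
                       for s in synthsleep.STAGE_ORDER]) / len(hyp)
    # Markov samples are autocorrelated, so allow a loose absolute band
    np.testing.assert_allclose(counts, pi, atol=0.05)


def test_zero_densities_give_pure_noise():
    cfg = SimConfig(seed=1, n_epochs=40)
    cfg = _replace(
        cfg,
        spindles=dataclasses.replace(cfg.spindles, density_per_epoch=0.0),
        slow_waves=dataclasses.replace(cfg.slow_waves, density_per_epoch=0.0,
                                       bg_density_per_epoch=0.0),
        coupling=dataclasses.replace(cfg.coupling, coupled_fraction=0.0))
    hyp = gen_hypnogram(cfg, _rng(1))
    rec, gt = gen_psg(hyp, cfg, _rng(2))
    assert len(gt) == 0
    assert rec.data.shape == (4, 40 * 3000)


def test_event_counts_are_exact_bookkeeping():
    cfg = SimConfig(seed=2, n_epochs=60)
    cfg = _replace(cfg, spindles=dataclasses.replace(cfg.spindles,
                                                     density_per_epoch=2.0))
    hyp = gen_hypnogram(cfg, _rng(4))
    n_nonrem = len(hyp.epochs_in(psg_io.NONREM_STAGES))
    rec, gt = gen_psg(hyp, cfg, _rng(5))
    for ch in ("C3", "C4"):
        sub = gt[gt.channel == ch]
        assert (sub.kind == "spindle").sum() == round(2.0 * n_nonrem)
        assert (sub.kind == "sw").sum() == round(
            cfg.slow_waves.density_per_epoch * n_nonrem)
        assert (sub.kind == "bg_sw").sum() == round(
            cfg.slow_waves.bg_density_per_epoch * n_nonrem)


def test_zero_sigma_delays_equal_mu():
    cfg = SimConfig(seed=3, n_epochs=60)
    cfg = _replace(cfg, coupling=dataclasses.replace(
        cfg.coupling, coupled_fraction=1.0, delay_sd_s=0.0))
    hyp = gen_hypnogram(cfg, _rng(6))
    rec, gt = gen_psg(hyp, cfg, _rng(7))
    delays = gt[gt.kind == "spindle"].delay_s.dropna()
    assert len(delays) > 0
    np.testing.assert_allclose(delays, cfg.coupling.delay_mean_s, atol=1e-9)


def test_coupled_spindles_reference_existing_sws():
    cfg = SimConfig(seed=4, n_epochs=80)
    hyp = gen_hypnogram(cfg, _rng(8))
    rec, gt = gen_psg(hyp, cfg, _rng(9))
    coupled = gt[gt.kind == "spindle"].dropna(subset=["coupled_sw_id"])
    assert len(coupled) > 0
    sw_ids = set(gt.loc[gt.kind == "sw", "event_id"])
    assert set(coupled.coupled_sw_id.astype(int)) <= sw_ids
    # coupled pairs live on the same channel
    by_id = gt.set_index("event_id")
    for _, row in coupled.iterrows():
        assert by_id.loc[int(row.coupled_sw_id), "channel"] == row.channel


def test_events_confined_to_nonrem_epochs():
    cfg = SimConfig(seed=5, n_epochs=80)
    hyp = gen_hypnogram(cfg, _rng(10))
    rec, gt = gen_psg(hyp, cfg, _rng(11))
    nonrem = set(hyp.epochs_in(psg_io.NONREM_STAGES).tolist())
    start_ep = (gt.onset_s // 30.0).astype(int)
    end_ep = ((gt.onset_s + gt.duration_s) // 30.0).astype(int)
    assert set(start_ep) <= nonrem and set(end_ep) <= nonrem


def test_density_too_high_raises():
    cfg = SimConfig(seed=6, n_epochs=40)
    cfg = _replace(cfg, spindles=dataclasses.replace(cfg.spindles,
                                                     density_per_epoch=40.0))
    hyp = gen_hypnogram(cfg, _rng(12))
    with pytest.raises(ValueError, match="density too high"):
        gen_psg(hyp, cfg, _rng(13))


def test_rereferencing_recovers_constructed_channels():
    cfg = SimConfig(seed=7, n_epochs=40)
    hyp = gen_hypnogram(cfg, _rng(14))
    rec, gt = gen_psg(hyp, cfg, _rng(15))
    # C3 - A2 removes the mastoid noise added to the raw C3 channel exactly
    out = psg_io.rereference_contralateral_mastoid(rec)
    np.testing.assert_array_equal(
        out.channel("C3"), rec.channel("C3") - rec.channel("A2"))


def test_behavior_noise_free_gains():
    cfg = SimConfig()
    cfg = _replace(cfg, tapping=dataclasses.replace(
        cfg.tapping, noise_sd=0.0, overnight_gain=0.0, round_counts=False))
    session, _ = gen_behavior(cfg, _rng(16))
    scores = behavior.score_tapping(session)
    assert scores.consolidation_abs == pytest.approx(0.0, abs=1e-12)

    cfg2 = _replace(cfg, tapping=dataclasses.replace(
        cfg.tapping, noise_sd=0.0, overnight_gain=0.10, round_counts=False))
    session2, _ = gen_behavior(cfg2, _rng(17))
    scores2 = behavior.score_tapping(session2)
    assert scores2.consolidation_rel == pytest.approx(0.10, abs=1e-12)


def test_behavior_cohort_mean_gain():
    cfg = SimConfig()
    cfg = _replace(cfg, tapping=dataclasses.replace(
        cfg.tapping, overnight_gain=0.08, round_counts=False))
    rng = _rng(18)
    rels = [behavior.score_tapping(gen_behavior(cfg, rng)[0]).consolidation_rel
            for _ in range(200)]
    se = np.std(rels, ddof=1) / np.sqrt(len(rels))
    assert abs(np.mean(rels) - 0.08) < 3 * se


def test_group_effects_applied():
    cfg = SimConfig(seed=8, n_epochs=60)
    hyp = gen_hypnogram(cfg, _rng(19))
    base_rec, base = gen_psg(hyp, cfg, _rng(20))
    _, scaled = gen_psg(hyp, cfg, _rng(20),
                        effects=GroupEffects(sw_amplitude_mult=0.8))
    a = base[base.kind == "sw"].amplitude_uv.to_numpy()
    b = scaled[scaled.kind == "sw"].amplitude_uv.to_numpy()
    np.testing.assert_allclose(b, 0.8 * a, rtol=1e-12)


def test_write_subject_round_trip(tmp_path, small_subject):
    sub, cfg = small_subject
    paths = write_subject(sub, tmp_path / sub.subject_id)
    rec = psg_io.read_recording(paths["edf"])
    assert rec.fs == cfg.fs
    # 16-bit EDF quantization error bound per channel
    step = 2 * np.abs(sub.recording.data).max(axis=1) * 1.01 / 65535.0
    err = np.abs(rec.data - sub.recording.data).max(axis=1)
    assert np.all(err <= step)
    hyp = psg_io.read_hypnogram(paths["hypnogram"])
    np.testing.assert_array_equal(hyp.stages, sub.hypnogram.stages)
    mask = psg_io.read_artifact_mask(paths["artifacts"], n_epochs=len(hyp),
                                     channels=["C3", "C4"])
    np.testing.assert_array_equal(mask.flags, sub.artifact_mask.flags)
    sess = behavior.read_tapping_sessions(paths["tapping"])[sub.subject_id]
    assert sess == sub.tapping
    course = behavior.read_hamd_courses(paths["hamd"])[sub.subject_id]
    assert course == sub.clinical
    gt = pd.read_csv(paths["ground_truth"], sep="\t")
    assert len(gt) == len(sub.ground_truth)
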