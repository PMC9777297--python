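import numpy as np
import pytest
from scipy import signal as ss
from scipy.stats import ttest_ind

from emodecode import (SimConfig, build_block_schedule, generate_cohort,
                       generate_recording)
from emodecode.synthetic import block_duration, load_recording, save_recording


def welch_alpha_faa_contrast(recording, pair=("F3", "F4")) -> float:
    """Oracle: Welch-PSD alpha power per emotion segment, FAA = lnR - lnL,
    averaged per condition; returns pleasure minus grief."""
    m, fs = recording.montage, recording.sampling_rate
    li, ri = m.index(pair[0]), m.index(pair[1])
    per_cond = {"pleasure": [], "grief": []}
    for a in recording.annotations:
        if a.condition not in per_cond:
            continue
        i0, i1 = round(a.onset * fs), round((a.onset + a.duration) * fs)
        f, pl = ss.welch(recording.data[li, i0:i1], fs=fs, nperseg=512)
        _, pr = ss.welch(recording.data[ri, i0:i1], fs=fs, nperseg=512)
        sel = (f >= 8) & (f <= 15)
        per_cond[a.condition].append(np.log(pr[sel].mean()) - np.log(pl[sel].mean()))
    return float(np.mean(per_cond["pleasure"]) - np.mean(per_cond["grief"]))


class TestSchedule:
    def test_default_block_is_84_s(self):
        cfg = SimConfig(seed=0)
        assert block_duration(cfg) == 84.0
        sched = build_block_schedule(cfg)
        first_block = sched[:7]
        assert sum(a.duration for a in first_block) == 84.0
        assert [a.condition for a in first_block] == \
            ["pleasure", "neutral"] * 3 + ["pleasure"]

    def test_one_second_segments_give_7_s_block(self):
        cfg = SimConfig(segment_duration=1.0, seed=0)
        assert block_duration(cfg) == 7.0

    def test_eight_blocks_cover_8x84_s(self):
        cfg = SimConfig(blocks_per_condition=4, seed=0)
        sched = build_block_schedule(cfg)
        assert sum(a.duration for a in sched) == 8 * 84.0
        conditions = {a.condition for a in sched}
        assert conditions == {"pleasure", "grief", "neutral"}
        emo = [a for a in sched if a.condition != "neutral"]
        assert len(emo) == 8 * 4  # four emotion trials per block
        assert len({a.trial_id for a in sched}) == len(sched)

    def test_schedule_conserves_recording_length(self):
        cfg = SimConfig(blocks_per_condition=1, segment_duration=2.0, seed=0)
        rec = generate_recording(cfg, 0)
        total = sum(a.duration for a in rec.annotations)
        assert rec.n_samples == round(total * cfg.sampling_rate)


class TestGenerator:
    def test_same_seed_bit_identical(self):
        cfg = SimConfig(blocks_per_condition=1, segment_duration=2.0, seed=42)
        a = generate_recording(cfg, 3)
        b = generate_recording(cfg, 3)
        assert np.array_equal(a.data, b.data)
        assert a.annotations == b.annotations

    def test_cohort_seeds_distinct_and_derived(self):
        cfg = SimConfig(n_participants=3, blocks_per_condition=1,
                        segment_duration=2.0, seed=7)
        cohort = generate_cohort(cfg)
        assert len(cohort) == 3
        assert not np.array_equal(cohort[0].data, cohort[1].data)
        # n=1 cohort equals a direct generate_recording call
        solo = generate_cohort(SimConfig(n_participants=1, blocks_per_condition=1,
                                         segment_duration=2.0, seed=7))[0]
        assert np.array_equal(solo.data, cohort[0].data)
        # master seed change propagates to every participant
        other = generate_cohort(SimConfig(n_participants=3, blocks_per_condition=1,
                                          segment_duration=2.0, seed=8))
        for x, y in zip(cohort, other):
            assert not np.array_equal(x.data, y.data)

    def test_zero_effect_conditions_exchangeable(self):
        # any single seed can produce a false alarm at the 1% level, so the
        # two-sample test runs on three independent recordings and the
        # majority must be non-significant
        pvals = []
        for seed in (10, 12, 14):
            # 5 blocks/condition x 4 trials x 5 1-s windows = 100 windows/class
            cfg = SimConfig(blocks_per_condition=5, segment_duration=5.0,
                            faa_effect=0.0, artifact_rate=0.0, seed=seed)
            rec = generate_recording(cfg, 0)
            m, fs = rec.montage, rec.sampling_rate
            li = m.index("F3")
            sos = ss.butter(4, [8, 15], btype="bandpass", fs=fs, output="sos")
            alpha = ss.sosfiltfilt(sos, rec.data[li])
            powers = {"pleasure": [], "grief": []}
            for a in rec.annotations:
                if a.condition not in powers:
                    continue
                i0 = round(a.onset * fs)
                for w in range(int(a.duration)):
                    seg = alpha[i0 + w * round(fs):i0 + (w + 1) * round(fs)]
                    powers[a.condition].append(np.mean(seg**2))
            assert len(powers["pleasure"]) + len(powers["grief"]) >= 200
            pvals.append(ttest_ind(powers["pleasure"], powers["grief"])[1])
        assert sum(p > 0.01 for p in pvals) >= 2

    def test_faa_contrast_recovered_and_monotone(self):
        measured = []
        for delta in (0.0, 0.5, 1.0):
            cfg = SimConfig(n_participants=14, blocks_per_condition=2,
                            segment_duration=6.0, artifact_rate=0.0,
                            faa_effect=delta, seed=11)
            vals = [welch_alpha_faa_contrast(r) for r in generate_cohort(cfg)]
            measured.append(np.mean(vals))
        assert measured[0] < measured[1] < measured[2]
        assert abs(measured[2] - 1.0) <= 0.2

    def test_background_follows_one_over_f(self):
        cfg = SimConfig(blocks_per_condition=2, segment_duration=6.0,
                        oscillations=(), artifact_rate=0.0, faa_effect=0.0,
                        noise_exponent=1.0, seed=3)
        rec = generate_recording(cfg, 0)
        f, p = ss.welch(rec.data, fs=cfg.sampling_rate, nperseg=2048, axis=1)
        sel = (f >= 2) & (f <= 40)
        slope = np.polyfit(np.log(f[sel]), np.log(p[:, sel].mean(axis=0)), 1)[0]
        assert abs(slope - (-1.0)) <= 0.2


class TestConfigValidation:
    def test_sampling_rate_must_clear_band_edges(self):
        with pytest.raises(ValueError):
            SimConfig(sampling_rate=50.0, seed=0)

    def test_segment_times_rate_must_be_integral(self):
        with pytest.raises(ValueError):
            SimConfig(segment_duration=1.0003, seed=0)

    def test_negative_effect_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(faa_effect=-0.5, seed=0)


def test_save_load_round_trip(tmp_path):
    cfg = SimConfig(blocks_per_condition=1, segment_duration=2.0, seed=9)
    rec = generate_recording(cfg, 4)
    sidecar = save_recording(rec, tmp_path)
    loaded = load_recording(sidecar)
    assert loaded.participant_id == 4
    assert loaded.annotations == rec.annotations
    assert loaded.montage == rec.montage
    np.testing.assert_allclose(loaded.data, rec.data, rtol=1e-6, atol=1e-4)
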