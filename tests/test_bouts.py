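"""Bout segmentation and objective OSPA accumulation."""

from itertools import groupby, product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from deskbreak import (
    AlgorithmConfig,
    Bout,
    EpochSeries,
    ValidityMask,
    classify_epoch_validity,
    cohort_ospa,
    day_ospa,
    segment_day,
)
from deskbreak.bouts import AMBULATORY, INVALID, STATIONARY, DayOSPA


def series(counts):
    return EpochSeries(participant="P01", day=0, counts=np.asarray(counts))


def segment(counts, cfg):
    s = series(counts)
    return segment_day(s, classify_epoch_validity(s, cfg), cfg)


def brute_segment(counts, cfg):
    """Independent oracle: per-epoch labels via groupby run enumeration."""
    valid = []
    for is_zero, grp in groupby(counts, key=lambda c: c == 0):
        n = len(list(grp))
        valid.extend([not (is_zero and n >= cfg.invalid_run_epochs)] * n)
    labels = []
    i = 0
    for v, grp in groupby(valid):
        seg = counts[i:i + len(list(grp))]
        if not v:
            labels.extend([INVALID] * len(seg))
        else:
            for moving, g2 in groupby(seg, key=lambda c: c >= cfg.active_count_threshold):
                n2 = len(list(g2))
                lab = AMBULATORY if moving and n2 >= cfg.min_ambulatory_epochs else STATIONARY
                labels.extend([lab] * n2)
        i += len(seg)
    out = []
    j = 0
    for lab, grp in groupby(labels):
        n = len(list(grp))
        out.append((j, j + n, lab))
        j += n
    return out


class TestSegmentDay:
    def test_stationary_ambulatory_stationary(self, config):
        # isolated fidget epochs keep the zeros below the 40-run rule
        still = ([0] * 20 + [1] + [0] * 11) * 6  # 192 epochs, no 40-zero-run
        counts = still + [9] * 20 + still
        bouts = segment(counts, config)
        assert [b.label for b in bouts] == [STATIONARY, AMBULATORY, STATIONARY]
        assert bouts[1].duration_minutes == 5.0

    def test_short_movement_run_absorbed(self, config):
        counts = [0] * 10 + [5] * 3 + [0] * 10  # 3 < min_ambulatory_epochs
        bouts = segment(counts, config)
        assert [b.label for b in bouts] == [STATIONARY]
        assert bouts[0].n_epochs == 23

    def test_invalid_bout_terminates_stationary_run(self, config):
        counts = [0] * 100 + [0] * 40 + [0] * 100
        # one long zero run: entirely invalid
        bouts = segment(counts, config)
        assert [b.label for b in bouts] == [INVALID]
        counts = [0, 1] * 50 + [0] * 40 + [0, 1] * 50
        bouts = segment(counts, config)
        assert [b.label for b in bouts] == [STATIONARY, INVALID, STATIONARY]

    def test_movement_run_split_by_invalid_is_absorbed(self, config):
        # 2 movement epochs on each side of a 40-zero run: both runs < 4 epochs
        counts = [0, 1] * 30 + [9, 9] + [0] * 40 + [9, 9] + [0, 1] * 30
        bouts = segment(counts, config)
        assert [b.label for b in bouts] == [STATIONARY, INVALID, STATIONARY]

    def test_length_mismatch_rejected(self, config):
        s = series([1, 2, 3])
        mask = ValidityMask(np.array([True, True]), 15)
        with pytest.raises(ValueError):
            segment_day(s, mask, config)

    def test_tiling_conservation(self, config, rng):
        counts = (rng.random(2000) < 0.5).astype(int) * 9
        s = series(counts)
        mask = classify_epoch_validity(s, config)
        bouts = segment_day(s, mask, config)
        assert bouts[0].start_epoch == 0 and bouts[-1].end_epoch == 2000
        assert all(a.end_epoch == b.start_epoch for a, b in zip(bouts, bouts[1:]))
        assert all(a.label != b.label for a, b in zip(bouts, bouts[1:]))
        valid_min = sum(
            b.duration_minutes for b in bouts if b.label in (STATIONARY, AMBULATORY)
        )
        assert valid_min == pytest.approx(mask.valid_minutes)

    def test_idempotence(self, config, rng):
        """Re-segmenting the reconstructed label stream reproduces the bouts."""
        counts = (rng.random(2000) < 0.45).astype(int) * 7
        s = series(counts)
        mask = classify_epoch_validity(s, config)
        bouts = segment_day(s, mask, config)
        # rebuild a count/validity stream realising exactly those labels
        re_counts = np.zeros(2000, dtype=int)
        re_valid = np.ones(2000, dtype=bool)
        for b in bouts:
            if b.label == AMBULATORY:
                re_counts[b.start_epoch:b.end_epoch] = 9
            elif b.label == INVALID:
                re_valid[b.start_epoch:b.end_epoch] = False
        re_bouts = segment_day(series(re_counts), ValidityMask(re_valid, 15), config)
        assert [(b.start_epoch, b.end_epoch, b.label) for b in re_bouts] == [
            (b.start_epoch, b.end_epoch, b.label) for b in bouts
        ]

    @given(st.lists(st.integers(0, 9), min_size=1, max_size=300),
           st.integers(1, 5))
    @settings(deadline=None, max_examples=150)
    def test_raising_threshold_never_adds_ambulatory_time(self, counts, thr):
        cfg_lo = AlgorithmConfig(active_count_threshold=thr)
        cfg_hi = AlgorithmConfig(active_count_threshold=thr + 1)
        amb = lambda cfg: sum(
            b.duration_minutes for b in segment(counts, cfg) if b.label == AMBULATORY
        )
        assert amb(cfg_hi) <= amb(cfg_lo)

    def test_exhaustive_oracle_small_strings(self, small_config):
        for n in range(1, 13):
            for counts in product((0, 1), repeat=n):
                got = [
                    (b.start_epoch, b.end_epoch, b.label)
                    for b in segment(list(counts), small_config)
                ]
                assert got == brute_segment(list(counts), small_config), counts

    def test_oracle_random_long_strings(self, config, rng):
        for _ in range(100):
            counts = (rng.random(2000) < 0.6).astype(int)
            got = [
                (b.start_epoch, b.end_epoch, b.label)
                for b in segment(counts.tolist(), config)
            ]
            assert got == brute_segment(counts.tolist(), config)


def make_bouts(plan_minutes):
    """plan_minutes: list of (label, minutes) tiling a synthetic day."""
    bouts, pos = [], 0
    for label, minutes in plan_minutes:
        n = int(minutes * 4)
        bouts.append(Bout("P01", 0, pos, pos + n, label))
        pos += n
    return bouts


class TestDayOSPA:
    def test_sixty_minute_bout_is_prolonged(self, config):
        ospa = day_ospa(make_bouts([(STATIONARY, 60.0)]), config)
        assert ospa.n_prolonged_bouts == 1
        assert ospa.prolonged_minutes == 60.0

    def test_just_under_sixty_is_not(self, config):
        ospa = day_ospa(make_bouts([(STATIONARY, 59.75)]), config)
        assert ospa.n_prolonged_bouts == 0

    def test_hand_summed_day(self, config):
        bouts = make_bouts(
            [(STATIONARY, 70), (AMBULATORY, 10), (STATIONARY, 30),
             (AMBULATORY, 5), (STATIONARY, 65)]
        )
        ospa = day_ospa(bouts, config)
        assert ospa.stationary_minutes == 165
        assert ospa.ambulatory_minutes == 15
        assert ospa.n_prolonged_bouts == 2
        assert ospa.prolonged_minutes == 135

    def test_invalid_split_prevents_prolonged(self, config):
        bouts = make_bouts([(STATIONARY, 40), (INVALID, 10), (STATIONARY, 40)])
        ospa = day_ospa(bouts, config)
        assert ospa.n_prolonged_bouts == 0
        assert ospa.stationary_minutes == 80


class TestCohortOSPA:
    def test_identical_days_mean_equals_day(self):
        days = [DayOSPA("P01", d, 300.0, 60.0, 2, 130.0) for d in range(4)]
        table = cohort_ospa(days)
        assert table.loc["P01", "stationary_minutes"] == 300.0
        assert table.loc["P01", "n_prolonged_bouts"] == 2.0

    def test_two_day_mean(self):
        days = [DayOSPA("P01", 0, 300.0, 50.0, 1, 60.0),
                DayOSPA("P01", 1, 400.0, 70.0, 3, 200.0)]
        assert cohort_ospa(days).loc["P01", "stationary_minutes"] == 350.0

    def test_empty_input_gives_empty_table(self):
        assert cohort_ospa([]).empty
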