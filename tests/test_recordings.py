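"""Parsing, full-day extraction, exclusions, and subgroup labeling."""

import datetime as dt

import numpy as np
import pytest

from elf_expochar import recordings as rec
from elf_expochar import synthetic


def make_recording(start, hours, interval=30, value=0.05, **meta):
    n = int(hours * 3600 / interval)
    return rec.Recording(
        subject_id=meta.pop("subject_id", "S1"),
        start_time=start,
        sample_interval_s=interval,
        values=np.full(n, value),
        metadata=meta,
    )


class TestReadRecording:
    def test_roundtrip_through_csv(self, tmp_path, rng):
        plan = synthetic.sample_day_plan(
            synthetic.CohortSpec(n_subjects=1),
            {"subject_id": "S7"}, rng)
        day = synthetic.render_day(plan, rng, subject_meta={"subject_id": "S7"})
        path = tmp_path / "day.csv"
        rec.write_recording(day, path)
        loaded = rec.read_recording(path, metadata={"subject_id": "S7"})
        assert loaded.sample_interval_s == 30
        np.testing.assert_allclose(loaded.values, day.values, rtol=1e-9)

    def test_gap_reported_with_first_bad_timestamp(self, tmp_path):
        lines = ["timestamp_iso,field_uT"]
        t = dt.datetime(2020, 1, 1)
        for i in range(10):
            if i == 6:  # skip one sample -> 60 s step
                continue
            lines.append(f"{(t + dt.timedelta(seconds=30 * i)).isoformat()},0.05")
        path = tmp_path / "gap.csv"
        path.write_text("\n".join(lines))
        with pytest.raises(ValueError, match="non-uniform"):
            rec.read_recording(path)

    def test_full_day_file_spans_24h(self, tmp_path):
        day = make_recording(dt.datetime(2020, 1, 1), hours=24)
        path = tmp_path / "full.csv"
        rec.write_recording(day, path)
        loaded = rec.read_recording(path)
        assert loaded.n_samples == 2880
        assert loaded.time_of(loaded.n_samples - 1) - loaded.start_time == dt.timedelta(
            seconds=86400 - 30)

    def test_negative_values_rejected(self, tmp_path):
        path = tmp_path / "neg.csv"
        path.write_text("timestamp_iso,field_uT\n2020-01-01T00:00:00,-0.05\n")
        with pytest.raises(ValueError, match="non-negative"):
            rec.read_recording(path)


class TestExtractFullDays:
    def test_exact_day_yields_2880_samples(self):
        r = make_recording(dt.datetime(2020, 1, 1), hours=24)
        days = rec.extract_full_days(r)
        assert len(days) == 1 and days[0].n_samples == 2880

    def test_short_recording_eliminated(self):
        r = make_recording(dt.datetime(2020, 1, 1), hours=23)
        assert rec.extract_full_days(r) == []

    def test_multi_day_span_cut_at_midnights(self):
        """13:30 day 1 through 02:00 day 3 encloses exactly one full day."""
        start = dt.datetime(2020, 1, 1, 13, 30)
        hours = (dt.datetime(2020, 1, 3, 2) - start).total_seconds() / 3600
        r = make_recording(start, hours=hours, interval=3)
        days = rec.extract_full_days(r)
        assert len(days) == 1
        assert days[0].date == dt.date(2020, 1, 2)
        assert days[0].n_samples == 28_800

    def test_retained_days_are_contiguous_slices_of_input(self):
        start = dt.datetime(2020, 1, 1, 22, 0)
        r = make_recording(start, hours=50)
        r.values[:] = np.arange(r.n_samples)
        days = rec.extract_full_days(r)
        assert len(days) == 2
        concat = np.concatenate([d.values for d in days])
        offset = int((dt.datetime(2020, 1, 2) - start).total_seconds() / 30)
        np.testing.assert_array_equal(concat, r.values[offset:offset + 2 * 2880])


class TestExclusions:
    def _cohort(self, n, flag_rate, seed=0):
        rng = np.random.default_rng(seed)
        return [
            make_recording(dt.datetime(2020, 1, 1), 1,
                           subject_id=f"S{i}", alarm_clock_near=bool(rng.random() < flag_rate))
            for i in range(n)
        ]

    def test_flagged_recordings_removed(self):
        recs = self._cohort(3, 0.0)
        recs[1].metadata["alarm_clock_near"] = True
        assert len(rec.apply_exclusions(recs)) == 2

    def test_rule_disabled_is_identity(self):
        recs = self._cohort(3, 1.0)
        rules = rec.ExclusionRules(exclude_alarm_clock_near=False)
        assert rec.apply_exclusions(recs, rules) == recs

    def test_retained_fraction_matches_flag_rate(self):
        recs = self._cohort(1000, 0.1, seed=4)
        kept = rec.apply_exclusions(recs)
        assert abs(len(kept) / 1000 - 0.9) < 3 * np.sqrt(0.1 * 0.9 / 1000)


class TestSubgroups:
    @pytest.mark.parametrize("age,expected", [(0, "0-4"), (4, "0-4"), (7, "5-9"),
                                              (10, "10-14"), (14, "10-14")])
    def test_age_groups(self, age, expected):
        assert rec.age_group(age) == expected

    @pytest.mark.parametrize("inhab,expected", [
        (800, "rural (<2000 inhab.)"),
        (3500, "2000-4999 inhab."),
        (150_000, "100000-199999 inhab."),
        (1_347_000, "200000-1999999 inhab."),
    ])
    def test_inhabitants_classes(self, inhab, expected):
        assert rec.inhabitants_group(inhab) == expected

    def test_substation_level_passthrough_and_validation(self):
        keys = rec.assign_subgroups({"substation_class": "same building or adjacent"})
        assert rec.SubgroupKey("substation", "same building or adjacent") in keys
        with pytest.raises(ValueError, match="substation"):
            rec.assign_subgroups({"substation_class": "next door"})

    def test_age_outside_study_range_rejected(self):
        with pytest.raises(ValueError, match="age"):
            rec.age_group(15)

    def test_labeling_partitions_any_cohort(self):
        """Each subject maps to exactly one level per present dimension."""
        rng = np.random.default_rng(1)
        cohort = synthetic.CohortSpec(n_subjects=40)
        for i in range(40):
            meta = synthetic.sample_subject_metadata(cohort, i, rng)
            keys = rec.assign_subgroups(meta)
            dims = [k.dimension for k in keys]
            assert sorted(dims) == sorted(set(dims))
            assert set(dims) == {"age", "inhabitants", "substation"}
            for k in keys:
                assert k.level in rec.SUBGROUP_DIMENSIONS[k.dimension]

    def test_vocabulary_table_matches_code(self):
        vocab = rec.subgroup_vocabulary()
        for dim, levels in rec.SUBGROUP_DIMENSIONS.items():
            assert list(vocab[vocab.dimension == dim].level) == list(levels)


class TestDayNight:
    def test_midday_event_is_day(self):
        assert rec.assign_daynight(dt.datetime(2020, 1, 1, 12), dt.datetime(2020, 1, 1, 12, 30)) == "day"

    def test_midnight_spanning_event_is_night(self):
        assert rec.assign_daynight(dt.datetime(2020, 1, 1, 23), dt.datetime(2020, 1, 2, 2)) == "night"

    def test_majority_overlap_decides_boundary_events(self):
        # 20:00-23:00 holds 1 h of day window and 2 h of night
        assert rec.assign_daynight(dt.datetime(2020, 1, 1, 20), dt.datetime(2020, 1, 1, 23)) == "night"

    def test_exact_tie_goes_to_day(self):
        # 19:00-23:00: 2 h day, 2 h night
        assert rec.assign_daynight(dt.datetime(2020, 1, 1, 19), dt.datetime(2020, 1, 1, 23)) == "day"

    def test_zero_length_window_rejected(self):
        t = dt.datetime(2020, 1, 1, 12)
        with pytest.raises(ValueError):
            rec.assign_daynight(t, t)
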