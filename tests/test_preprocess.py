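"""Valid windows, eligibility, deduplication, rare-code filter, month panel."""

import numpy as np
import pandas as pd
import pytest

from recurmine.cohort import ClaimEvent, CodeGroupMap, ConfigurationError, claims_frame
from recurmine.preprocess import (
    DAYS_PER_MONTH,
    assign_valid_window,
    assign_valid_windows,
    build_month_panel,
    deduplicate_daily,
    filter_eligible,
    filter_rare_codes,
    month_of_day,
)

from conftest import make_record


def day_of_month(m: int, offset: int = 10) -> int:
    return int(m * DAYS_PER_MONTH) + offset


def dx(pid, day, code="D01A"):
    return ClaimEvent(pid, day, "ICD9CM", code, "diagnosis")


def px(pid, day, code="P01A"):
    return ClaimEvent(pid, day, "CPT", code, "procedure")


class TestValidWindow:
    def test_simple_window_relative(self):
        rec = make_record("A", followup_end_day=1000)
        w = assign_valid_window(rec, bin_mode="relative")
        assert w.start_month == 6
        assert w.end_month == month_of_day(rec, 1000, "relative") == 32

    def test_calendar_start_is_first_full_month_after_six(self):
        first = make_record("A", jitter_month=3, jitter_day=1)
        mid = make_record("B", jitter_month=3, jitter_day=15)
        assert assign_valid_window(first).start_month == 6
        assert assign_valid_window(mid).start_month == 7

    def test_nonbreast_primary_censors_three_months_before(self):
        rec = make_record(
            "A",
            followup_end_day=day_of_month(60),
            nonbreast_primary_day=day_of_month(40),
        )
        w = assign_valid_window(rec, bin_mode="relative")
        assert w.end_month == 37

    def test_second_event_censors_one_month_before(self):
        rec = make_record(
            "A",
            sbce_day=day_of_month(20),
            second_sbce_day=day_of_month(30),
            followup_end_day=day_of_month(60),
        )
        w = assign_valid_window(rec, bin_mode="relative")
        assert w.end_month == 29
        assert w.sbce_month == 20

    def test_empty_window_flags_ineligible(self):
        rec = make_record("A", followup_end_day=100)
        w = assign_valid_window(rec, bin_mode="relative")
        assert w.is_empty


class TestFilterEligible:
    def run(self, records, claims):
        windows = assign_valid_windows(records, "relative")
        return filter_eligible(records, windows, claims_frame(claims), "relative")

    def test_event_patient_without_post_event_claims_excluded(self):
        rec = make_record("A", sbce_day=day_of_month(20), followup_end_day=day_of_month(40))
        kept, excluded = self.run([rec], [dx("A", day_of_month(10))])
        assert not kept
        assert excluded[0].reason == "no_post_event_claims"

    def test_claims_only_before_window_excluded(self):
        rec = make_record("A", followup_end_day=day_of_month(40))
        kept, excluded = self.run([rec], [dx("A", d) for d in (5, 40, 120)])
        assert not kept
        assert excluded[0].reason == "no_claims_in_window"

    def test_single_claim_at_window_start_retained(self):
        rec = make_record("A", followup_end_day=day_of_month(40))
        start_day = int(np.ceil(6 * DAYS_PER_MONTH))
        kept, excluded = self.run([rec], [dx("A", start_day)])
        assert [r.patient_id for r in kept] == ["A"] and not excluded


class TestDeduplicateDaily:
    def test_same_code_same_day_collapses(self):
        claims = [dx("A", 100), dx("A", 100)]
        assert len(deduplicate_daily(claims)) == 1

    def test_same_code_distinct_days_survive(self):
        claims = [dx("A", 100), dx("A", 101)]
        assert len(deduplicate_daily(claims)) == 2

    def test_distinct_codes_one_day_survive(self):
        claims = [dx("A", 100, "D01A"), dx("A", 100, "D01B"), px("A", 100)]
        assert len(deduplicate_daily(claims)) == 3

    def test_idempotent_and_order_invariant(self):
        rng = np.random.default_rng(0)
        claims = [
            dx(f"P{rng.integers(3)}", int(rng.integers(50)), f"D0{rng.integers(1, 3)}A")
            for _ in range(60)
        ]
        once = deduplicate_daily(claims)
        twice = deduplicate_daily(once)
        shuffled = deduplicate_daily(list(reversed(claims)))
        pd.testing.assert_frame_equal(once, twice)
        pd.testing.assert_frame_equal(once, shuffled)


class TestFilterRareCodes:
    def test_code_spread_thin_across_patients_dropped(self):
        claims = [dx(f"P{i}", 100 + i) for i in range(5)]  # one day each
        kept, dropped = filter_rare_codes(claims)
        assert dropped == ["D01A"] and kept.empty

    def test_two_days_for_one_patient_retains_everywhere(self):
        claims = [dx("A", 100), dx("A", 200)] + [dx(f"P{i}", 50) for i in range(3)]
        kept, dropped = filter_rare_codes(claims)
        assert not dropped and len(kept) == 5

    def test_procedure_codes_exempt_by_default(self):
        claims = [px("A", 100)]
        kept, dropped = filter_rare_codes(claims)
        assert not dropped and len(kept) == 1

    def test_switch_extends_rule_to_procedures(self):
        claims = [px("A", 100)]
        kept, dropped = filter_rare_codes(claims, include_procedures=True)
        assert dropped == ["P01A"] and kept.empty


class TestMonthPanel:
    def build(self, records, claims, groupmap):
        windows = assign_valid_windows(records, "relative")
        return build_month_panel(
            claims_frame(claims), records, windows, groupmap, "relative"
        )

    def test_group_sums_match_brute_force(self, tiny_groupmap):
        rec = make_record("A", followup_end_day=day_of_month(40))
        claims = [
            dx("A", day_of_month(10), "D01A"),
            dx("A", day_of_month(10, offset=12), "D01B"),  # same group, same month
            dx("A", day_of_month(10, offset=14), "D02A"),
            dx("A", day_of_month(11), "D01A"),
            px("A", day_of_month(10), "P01A"),
            px("A", day_of_month(12), "P02A"),
            px("A", day_of_month(12, offset=11), "P02A"),
            dx("A", day_of_month(20), "D01A"),
            px("A", day_of_month(20), "P01A"),
            dx("A", day_of_month(39), "D02A"),
        ]
        panel = self.build([rec], claims, tiny_groupmap)
        # independent brute-force oracle over the claim list
        expected = {}
        for ev in claims:
            gid = tiny_groupmap.entries[ev.code][0]
            month = int(ev.day // DAYS_PER_MONTH)
            expected[(month, gid)] = expected.get((month, gid), 0) + 1
        got = {
            (r.month_index, r.group_id): r.count
            for r in panel.counts.itertuples(index=False)
        }
        assert got == expected
        assert got[(10, "DG01")] == 2  # two codes, one group, one month

    def test_claim_before_window_start_not_counted(self, tiny_groupmap):
        rec = make_record("A", followup_end_day=day_of_month(40))
        claims = [dx("A", day_of_month(5)), dx("A", day_of_month(7))]
        panel = self.build([rec], claims, tiny_groupmap)
        assert panel.total_count() == 1
        assert set(panel.counts["month_index"]) == {7}

    def test_conservation_of_in_window_mapped_claims(self, tiny_groupmap):
        rng = np.random.default_rng(5)
        records = [make_record(f"P{i}", followup_end_day=day_of_month(30)) for i in range(4)]
        codes = list(tiny_groupmap.entries) + ["ZZZ"]  # one unmapped code
        claims = []
        for _ in range(300):
            code = codes[rng.integers(len(codes))]
            cls = "diagnosis" if code.startswith(("D", "Z")) else "procedure"
            system = "ICD9CM" if cls == "diagnosis" else "CPT"
            claims.append(
                ClaimEvent(f"P{rng.integers(4)}", int(rng.integers(0, 1000)), system, code, cls)
            )
        frame = claims_frame(claims)
        windows = assign_valid_windows(records, "relative")
        panel = build_month_panel(frame, records, windows, tiny_groupmap, "relative")
        months = (frame["day"] // DAYS_PER_MONTH).astype(int)
        in_window = frame[(months >= 6) & (months <= 30) & (frame["code"] != "ZZZ")]
        assert panel.total_count() == len(in_window)
        assert panel.n_unmapped_claims == int((frame["code"] == "ZZZ").sum())

    def test_input_order_invariance(self, tiny_groupmap):
        rec = make_record("A", followup_end_day=day_of_month(30))
        claims = [dx("A", day_of_month(m), "D01A") for m in range(6, 20)]
        a = self.build([rec], claims, tiny_groupmap)
        b = self.build([rec], list(reversed(claims)), tiny_groupmap)
        pd.testing.assert_frame_equal(a.counts, b.counts)

    def test_empty_groupmap_is_configuration_error(self):
        rec = make_record("A", followup_end_day=day_of_month(30))
        with pytest.raises(ConfigurationError):
            self.build([rec], [dx("A", day_of_month(10))], CodeGroupMap({}))
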