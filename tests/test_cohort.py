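"""Eligibility exclusions, participant-flow arithmetic, nearest-age matching
with replacement, and timeline alignment."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import otcscan as o
from otcscan import months
from otcscan.cohort import align_timeline, availability_from_roster


# -- flow percentage --------------------------------------------------------

@pytest.mark.parametrize("num, den, expected", [
    (86, 182, 47.3), (142, 427, 33.3),   # card ownership shares
    (22, 160, 13.8), (5, 178, 2.8),      # card-detail mismatch shares
    (173, 178, 97.2), (138, 160, 86.3),  # purchase histories transferred
    (160, 427, 37.5),                    # ID-verified controls
    (0, 10, 0.0), (1, 8, 12.5),
])
def test_flow_percentage_matches_printed_tables(num, den, expected):
    assert o.flow_percentage(num, den) == expected


def test_flow_percentage_rounds_half_away_from_zero():
    assert o.flow_percentage(1375, 10000) == 13.8
    assert o.flow_percentage(125, 1000) == 12.5


@pytest.mark.parametrize("num, den", [(1, 0), (5, 3), (-1, 10)])
def test_flow_percentage_rejects_bad_inputs(num, den):
    with pytest.raises(ValueError):
        o.flow_percentage(num, den)


# -- exclusions -------------------------------------------------------------

def _mini_roster(prev):
    return pd.DataFrame({
        "participant_id": [f"p{i}" for i in range(len(prev))],
        "arm": ["case"] * len(prev),
        "age_years": 60.0,
        "cards": "HSR1",
        "previous_cancer": prev,
        "withdrawn": False,
        "sufficient_consent": True,
        "card_details_matched": True,
    })


def test_exclusions_keep_nonmelanoma_drop_other():
    eligible, report = o.apply_exclusions(
        _mini_roster(["none", "nonmelanoma_skin", "other"]))
    assert len(eligible) == 2
    assert set(eligible["previous_cancer"]) == {"none", "nonmelanoma_skin"}
    assert report["steps"][-1]["removed_cases"] == 1


def test_exclusions_unknown_code_rejected():
    with pytest.raises(ValueError, match="sarcoma"):
        o.apply_exclusions(_mini_roster(["none", "sarcoma"]))


def test_exclusions_equal_brute_force_predicate():
    rng = np.random.default_rng(0)
    n = 200
    roster = pd.DataFrame({
        "participant_id": [f"p{i}" for i in range(n)],
        "arm": rng.choice(["case", "control"], n),
        "age_years": 50.0,
        "cards": "HSR2",
        "previous_cancer": rng.choice(
            ["none", "nonmelanoma_skin", "other"], n),
        "withdrawn": rng.random(n) < 0.05,
        "sufficient_consent": rng.random(n) > 0.05,
        "card_details_matched": rng.random(n) > 0.1,
    })
    eligible, _ = o.apply_exclusions(roster)
    keep = (~roster["withdrawn"] & roster["sufficient_consent"]
            & roster["card_details_matched"]
            & (roster["previous_cancer"] != "other"))
    assert list(eligible["participant_id"]) == \
        list(roster.loc[keep, "participant_id"])


def build_study_flow_roster(rng=None):
    """Roster mirroring the published participant flow: 178 cases with
    purchase histories requested (5 card-detail mismatches, 20 previous
    cancers among the rest) and 160 controls (22 mismatches, 18 previous
    cancers), leaving 153 cases and 120 controls eligible."""
    rng = rng or np.random.default_rng(42)
    rows = []
    for arm, n, n_mismatch, n_prev in (("case", 178, 5, 20),
                                       ("control", 160, 22, 18)):
        for i in range(n):
            rows.append({
                "participant_id": f"{arm}_{i:04d}",
                "arm": arm,
                "age_years": float(np.round(rng.normal(
                    64.7 if arm == "case" else 51.6, 5), 1)),
                "cards": rng.choice(["HSR1", "HSR2", "both"]),
                "previous_cancer": "none",
                "withdrawn": False,
                "sufficient_consent": True,
                "card_details_matched": i >= n_mismatch,
                "diagnosis_month": "2021-06" if arm == "case" else None,
                "data_start_month": "2018-01",
                "data_end_month": "2021-12",
            })
        # previous cancers among those whose card details matched
        for j in range(n_mismatch, n_mismatch + n_prev):
            rows[-n + j]["previous_cancer"] = "other"
    return pd.DataFrame(rows)


def test_study_flow_reproduces_analysis_set_counts():
    """178 requested cases → 173 transferred → 153 after previous-cancer
    exclusion; matching at 2:1 yields 306 control slots."""
    roster = build_study_flow_roster()
    eligible, report = o.apply_exclusions(roster)
    assert report["eligible"]["cases"] == 153
    assert report["eligible"]["controls"] == 120
    sets, match_report = o.match(eligible, ratio=2)
    assert match_report["n_sets"] == 153
    assert match_report["n_control_slots"] == 306
    assert match_report["n_unique_controls"] <= 120
    assert o.flow_percentage(5, 178) == 2.8
    assert o.flow_percentage(22, 160) == 13.8


# -- matching ---------------------------------------------------------------

def _roster_rows(specs):
    rows = []
    for pid, arm, age, cards in specs:
        rows.append({"participant_id": pid, "arm": arm, "age_years": age,
                     "cards": cards, "previous_cancer": "none"})
    return pd.DataFrame(rows)


def test_single_control_reused_within_set():
    df = _roster_rows([("c1", "case", 60.0, "HSR1"),
                       ("k1", "control", 60.0, "HSR1")])
    sets, report = o.match(df, ratio=2)
    assert sets[0].control_ids == ["k1", "k1"]
    assert report["n_unique_controls"] == 1


def test_match_is_exact_on_card_stratum():
    df = _roster_rows([("c1", "case", 60.0, "both"),
                       ("k1", "control", 60.0, "HSR1"),
                       ("k2", "control", 60.0, "both")])
    sets, _ = o.match(df, ratio=2)
    assert sets[0].control_ids == ["k2", "k2"]


def test_empty_stratum_error_names_stratum():
    df = _roster_rows([("c1", "case", 60.0, "HSR2"),
                       ("k1", "control", 60.0, "HSR1")])
    with pytest.raises(ValueError, match="HSR2"):
        o.match(df)


def test_match_equals_exhaustive_nearest_age_search():
    rng = np.random.default_rng(5)
    rows = [(f"case_{i:03d}", "case", float(rng.uniform(40, 80)),
             rng.choice(["HSR1", "HSR2", "both"])) for i in range(40)]
    rows += [(f"ctrl_{i:03d}", "control", float(rng.uniform(30, 85)),
              rng.choice(["HSR1", "HSR2", "both"])) for i in range(60)]
    df = _roster_rows(rows)
    sets, _ = o.match(df, ratio=2)
    controls = df[df["arm"] == "control"]
    by_set = {s.case_id: s.control_ids for s in sets}
    for _, case in df[df["arm"] == "case"].iterrows():
        pool = controls[controls["cards"] == case["cards"]]
        ranked = sorted(pool.itertuples(),
                        key=lambda r: (abs(r.age_years - case["age_years"]),
                                       r.participant_id))
        expect = [ranked[j % len(ranked)].participant_id for j in range(2)]
        assert by_set[case["participant_id"]] == expect


def test_match_invariant_to_input_order():
    rng = np.random.default_rng(6)
    rows = [(f"case_{i:02d}", "case", float(rng.uniform(40, 80)), "HSR1")
            for i in range(10)]
    rows += [(f"ctrl_{i:02d}", "control", float(rng.uniform(30, 85)), "HSR1")
             for i in range(30)]
    df = _roster_rows(rows)
    shuffled = df.sample(frac=1, random_state=1).reset_index(drop=True)
    sets_a, _ = o.match(df)
    sets_b, _ = o.match(shuffled)
    assert [(s.case_id, s.control_ids) for s in sets_a] == \
        [(s.case_id, s.control_ids) for s in sets_b]


@given(st.integers(5, 30), st.integers(0, 1000))
def test_median_age_gap_shrinks_with_nested_control_pools(extra, seed):
    rng = np.random.default_rng(seed)
    rows = [(f"case_{i:02d}", "case", float(rng.uniform(40, 80)), "HSR1")
            for i in range(8)]
    base = [(f"ctrl_a{i:02d}", "control", float(rng.uniform(30, 85)), "HSR1")
            for i in range(10)]
    more = [(f"ctrl_b{i:02d}", "control", float(rng.uniform(30, 85)), "HSR1")
            for i in range(extra)]
    small = _roster_rows(rows + base)
    big = _roster_rows(rows + base + more)

    def med_abs_gap(sets):
        gaps = [abs(a - s.case_age) for s in sets for a in s.control_ages]
        return float(np.median(gaps))

    sets_small, _ = o.match(small)
    sets_big, _ = o.match(big)
    assert med_abs_gap(sets_big) <= med_abs_gap(sets_small) + 1e-12


def test_caliper_restricts_and_errors_when_unmatched():
    df = _roster_rows([("c1", "case", 60.0, "HSR1"),
                       ("k1", "control", 70.0, "HSR1")])
    with pytest.raises(ValueError, match="caliper"):
        o.match(df, caliper=5.0)


# -- alignment --------------------------------------------------------------

def _one_set():
    return o.MatchedSet(set_id="s1", case_id="c1", control_ids=["k1", "k2"],
                        cards="HSR1", case_age=60.0, control_ages=[60.0, 61.0])


def test_alignment_uses_case_window_when_covered():
    s = _one_set()
    diag = "2021-06"
    do = months.to_ordinal(diag)
    avail = {"k1": (do - 40, do + 2), "k2": (do - 30, do)}
    align_timeline(s, diag, avail)
    assert s.alignment["case"]["window_start"] == do - 24
    for c in s.alignment["controls"]:
        assert c["rule"] == "case_window"
        assert c["window_start"] == do - 24


def test_alignment_falls_back_to_own_latest_months():
    s = _one_set()
    diag = "2021-06"
    do = months.to_ordinal(diag)
    avail = {"k1": (do - 60, do - 30), "k2": (do - 24, do - 1)}
    align_timeline(s, diag, avail)
    assert s.alignment["controls"][0]["rule"] == "own_latest"
    assert s.alignment["controls"][0]["window_start"] == (do - 30) - 23
    assert s.alignment["controls"][1]["rule"] == "case_window"


def test_alignment_rule_matches_interval_containment_oracle():
    rng = np.random.default_rng(9)
    diag = months.to_ordinal("2021-06")
    for _ in range(50):
        lo = diag - int(rng.integers(24, 80))
        hi = lo + int(rng.integers(24, 60))
        s = o.MatchedSet(set_id="s", case_id="c", control_ids=["k", "k"],
                         cards="HSR1", case_age=60.0,
                         control_ages=[60.0, 60.0])
        align_timeline(s, diag, {"k": (lo, hi)})
        covered = lo <= diag - 24 and hi >= diag - 1
        expect = "case_window" if covered else "own_latest"
        assert s.alignment["controls"][0]["rule"] == expect


def test_alignment_short_availability_errors_unless_truncated():
    s = _one_set()
    diag = months.to_ordinal("2021-06")
    avail = {"k1": (diag - 10, diag - 1), "k2": (diag - 40, diag)}
    with pytest.raises(ValueError, match="k1"):
        align_timeline(s, diag, avail)
    align_timeline(s, diag, avail, truncate=True)  # no raise
    assert s.alignment["controls"][0]["rule"] == "own_latest"


def test_relative_month_mapping_covers_24_slots():
    s = _one_set()
    diag = months.to_ordinal("2021-06")
    avail = {"k1": (diag - 40, diag), "k2": (diag - 40, diag)}
    align_timeline(s, diag, avail)
    rels = [s.relative_month("case", m) for m in range(diag - 24, diag)]
    assert rels == list(range(-24, 0))
    with pytest.raises(ValueError):
        s.relative_month("case", diag)  # diagnosis month itself excluded


def test_alignment_does_not_mutate_shared_control_data(small_panel):
    """A control reused across sets keeps distinct per-set alignment."""
    _, eligible, sets = small_panel
    seen: dict[str, set] = {}
    for s in sets:
        for k, cid in enumerate(s.control_ids):
            seen.setdefault(cid, set()).add(
                (s.alignment["controls"][k]["window_start"],
                 s.alignment["controls"][k]["rule"]))
    # at least one control serves several sets (with-replacement design)
    assert any(len(v) >= 1 for v in seen.values())
    reused = [c for s in sets for c in s.control_ids]
    assert len(reused) > len(set(reused))
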