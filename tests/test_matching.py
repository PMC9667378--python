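"""Threshold validation, direct matching, selection and full strategies."""

from __future__ import annotations

import pytest

from fnmdlink.blocking import block_pairs
from fnmdlink.cleaning import make_clean_record
from fnmdlink.distance import DistanceProfile, field_distances
from fnmdlink.matching import (
    MatchResult,
    Thresholds,
    deceased_ids,
    direct_match,
    run_strategy,
    select_best,
    validate_pair,
)
from fnmdlink.records import ConfigurationError, MortalityRecord, PersonRecord

T = Thresholds()


@pytest.mark.parametrize("profile, ok", [
    (DistanceProfile(0, 0, 0, 0), True),
    (DistanceProfile(0, 1, 0, 1), True),       # total 2, all bounds met
    (DistanceProfile(3, 0, 0, 0), False),      # first-name bound
    (DistanceProfile(2, 1, 0, 0), False),      # only the total bound binds
    (DistanceProfile(2, 0, 0, 0), True),
    (DistanceProfile(0, 2, 0, 0), False),      # surname bound
    (DistanceProfile(0, 0, 2, 0), False),      # date bound
])
def test_validate_pair(profile, ok):
    assert validate_pair(profile, T) is ok


def test_threshold_invariants():
    with pytest.raises(ConfigurationError):
        Thresholds(max_total=6)  # exceeds the per-field sum 2+1+1+1
    with pytest.raises(ConfigurationError):
        Thresholds(max_first=-1, max_total=0)


def _local(**kw):
    base = dict(record_id="L1", first_name="Jean", birth_surname="Dupont",
                birth_date_raw="1950-03-21", sex="m")
    base.update(kw)
    return PersonRecord(**base)


def _fnmd(**kw):
    base = dict(fnmd_id="F1", first_name="Jean", surname="Dupont",
                birth_date_raw="1950-03-21", sex="m",
                death_date="2010-06-01")
    base.update(kw)
    return MortalityRecord(**base)


def test_direct_match_exact_and_accent_insensitive():
    assert direct_match(_local(), _fnmd())
    assert not direct_match(_local(birth_surname="Dupond"), _fnmd())
    assert direct_match(_local(first_name="Hélène", sex="f"),
                        _fnmd(first_name="Helene", sex="f"))
    # direct matching performs no date repair
    assert not direct_match(_local(birth_date_raw="1950-00-00"), _fnmd())
    # current surname used only when the birth surname is absent
    assert direct_match(_local(birth_surname=None, current_surname="Dupont"),
                        _fnmd())


def _result(fnmd_id, total, city=None, death="2010-01-01"):
    return MatchResult(local_id="L1", fnmd_id=fnmd_id,
                       profile=DistanceProfile(total, 0, 0, 0, city),
                       death_date=death)


def test_select_single_pair():
    out = select_best([_result("F1", 0)])
    assert out[0].selected and not out[0].ambiguous


def test_select_minimal_total_wins():
    out = select_best([_result("F1", 0), _result("F2", 2)])
    winners = [m.fnmd_id for m in out if m.selected]
    assert winners == ["F1"]
    assert not any(m.ambiguous for m in out)


def test_select_city_breaks_total_ties():
    out = select_best([_result("F1", 1, city=3), _result("F2", 1, city=0)])
    assert [m.fnmd_id for m in out if m.selected] == ["F2"]


def test_select_undefined_city_sorts_last():
    out = select_best([_result("F1", 1, city=None), _result("F2", 1, city=5)])
    assert [m.fnmd_id for m in out if m.selected] == ["F2"]


def test_select_flags_unresolvable_ties_deterministically():
    out = select_best([_result("F2", 1, city=0, death="2012-01-01"),
                       _result("F1", 1, city=0, death="2011-01-01")])
    tied = [m for m in out if m.ambiguous]
    assert len(tied) == 2
    assert [m.fnmd_id for m in out if m.selected] == ["F1"]  # earliest death


def test_run_strategy_empty_mortality_file():
    assert run_strategy([_local()], [], "dld") == []
    assert run_strategy([_local()], [], "direct") == []


def test_both_strategies_find_exact_subset(clean_cohort):
    locals_, fnmds, gold = clean_cohort
    truly_dead = {rid for rid, fid in gold.true_match.items() if fid}
    for strategy in ("dld", "direct"):
        found = deceased_ids(run_strategy(locals_, fnmds, strategy))
        assert found == truly_dead, strategy


def test_single_substitution_noise_separates_strategies():
    locals_ = [_local(record_id=f"L{i}", birth_surname=f"Dupon{c}")
               for i, c in enumerate("tdxzq")]
    fnmds = [_fnmd(fnmd_id=f"F{i}", surname=f"Dupon{c}".replace("n", "m", 1))
             for i, c in enumerate("tdxzq")]
    assert len(deceased_ids(run_strategy(locals_, fnmds, "dld"))) == 5
    assert len(deceased_ids(run_strategy(locals_, fnmds, "direct"))) == 0


def test_blocked_validation_equals_brute_force(noisy_cohort):
    locals_, fnmds, _ = noisy_cohort
    cl = [make_clean_record(r) for r in locals_]
    cf = [make_clean_record(r) for r in fnmds]
    via_pipeline = {(m.local_id, m.fnmd_id)
                    for m in run_strategy(locals_, fnmds, "dld")}
    brute = set()
    for l in cl:
        for f in cf:
            if (l.block_key_date == f.block_key_date
                    or l.block_key_name == f.block_key_name):
                if validate_pair(field_distances(l, f), T):
                    brute.add((l.source_id, f.source_id))
    assert via_pipeline == brute


def test_raising_thresholds_never_removes_pairs(noisy_cohort):
    locals_, fnmds, _ = noisy_cohort
    previous: set = set()
    for mt in range(0, 6):
        t = Thresholds(max_total=mt)
        pairs = {(m.local_id, m.fnmd_id)
                 for m in run_strategy(locals_, fnmds, "dld", t)}
        assert previous <= pairs
        previous = pairs


def test_direct_matches_are_dld_matches_at_defaults(noisy_cohort):
    locals_, fnmds, _ = noisy_cohort
    direct = {(m.local_id, m.fnmd_id)
              for m in run_strategy(locals_, fnmds, "direct")}
    dld_pairs = {(m.local_id, m.fnmd_id)
                 for m in run_strategy(locals_, fnmds, "dld")}
    assert direct <= dld_pairs


def test_unknown_strategy_rejected():
    with pytest.raises(ConfigurationError):
        run_strategy([], [], "fuzzy")
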