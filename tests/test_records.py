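"""Record model, I/O, taxon grouping, and scheme filters."""

from __future__ import annotations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from batsurvey.records import (
    DetectionRecord,
    FormatError,
    Guild,
    Microhabitat,
    TaxonLevel,
    TemporalPattern,
    collapse_taxa,
    filter_design,
    filter_temporal,
    identification_summary_from_counts,
    parse_clock_time,
    read_records,
    round_half_up,
    summarize_identification,
    write_records,
)

from conftest import make_record


class TestClockConversion:
    @pytest.mark.parametrize(
        "clock, minutes",
        [
            ("21:30", 0.0),       # window start
            ("05:29", 479.0),     # last minute of the window
            ("22:00", 30.0),
            ("00:00", 150.0),     # past midnight, same night
            ("03:30", 360.0),
            ("125.5", 125.5),     # already minutes-from-start
        ],
    )
    def test_clock_to_window_minutes(self, clock, minutes):
        assert parse_clock_time(clock) == pytest.approx(minutes)

    def test_malformed_clock_rejected(self):
        with pytest.raises(ValueError):
            parse_clock_time("21:30:00:00")


class TestRecordInvariants:
    @pytest.mark.parametrize("bad_t", [-1.0, 480.0, 700.0])
    def test_timestamp_outside_window_rejected(self, bad_t):
        with pytest.raises(ValueError, match="window"):
            make_record(timestamp=bad_t)

    def test_unknown_guild_only_at_order_level(self):
        with pytest.raises(ValueError, match="UNKNOWN"):
            make_record(guild=Guild.UNKNOWN)  # species-level record
        rec = make_record(taxon="Chiroptera", taxon_level=TaxonLevel.ORDER, guild=Guild.UNKNOWN)
        assert rec.guild is Guild.UNKNOWN


class TestReadRecords:
    def test_roundtrip(self, records_csv, tmp_path):
        records = read_records(records_csv)
        assert len(records) == 5
        assert records[0].timestamp == 0.0
        assert records[1].timestamp == 479.0
        out = tmp_path / "copy.csv"
        write_records(records, out)
        again = read_records(out)
        assert [r.taxon for r in again] == [r.taxon for r in records]
        assert [r.timestamp for r in again] == [r.timestamp for r in records]

    def test_guild_assigned_from_default_table(self, records_csv):
        records = read_records(records_csv)
        by_taxon = {r.taxon: r.guild for r in records}
        assert by_taxon["Myotis myotis"] is Guild.SRE
        assert by_taxon["Nyctalus sp."] is Guild.LRE
        assert by_taxon["Chiroptera"] is Guild.UNKNOWN

    def test_missing_column_is_format_error(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("night_id,time,cell,plot,site,taxon,level\n")
        with pytest.raises(FormatError, match="microhabitat"):
            read_records(p)

    def test_row_missing_value_names_line(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text(
            "night_id,time,cell,plot,site,microhabitat,taxon,level\n"
            "n01,21:30,C01,P1,S1,GA,Myotis myotis,species\n"
            "n01,22:00,C01,P1,S1,,Myotis myotis,species\n"
        )
        with pytest.raises(FormatError, match="bad.csv:3"):
            read_records(p)

    def test_out_of_window_row_warns_or_raises(self, tmp_path):
        p = tmp_path / "late.csv"
        p.write_text(
            "night_id,time,cell,plot,site,microhabitat,taxon,level\n"
            "n01,12:00,C01,P1,S1,GA,Myotis myotis,species\n"
            "n01,22:00,C01,P1,S1,GA,Myotis myotis,species\n"
        )
        with pytest.warns(UserWarning, match="late.csv:2"):
            records = read_records(p)
        assert len(records) == 1
        with pytest.raises(FormatError):
            read_records(p, strict=True)


class TestCollapseTaxa:
    @pytest.mark.parametrize(
        "taxa, expected_distinct",
        [
            (["Plecotus auritus", "Plecotus austriacus"], {"Plecotus sp."}),
            (["Myotis myotis"], {"Myotis myotis"}),
            (
                ["Nyctalus noctula", "Nyctalus leisleri", "Myotis daubentonii"],
                {"Nyctalus sp.", "Myotis daubentonii"},
            ),
            (["Eptesicus serotinus", "Eptesicus nilssoni"], {"Eptesicus sp."}),
        ],
    )
    def test_grouping(self, taxa, expected_distinct):
        records = [make_record(taxon=t, guild=Guild.SRE) for t in taxa]
        out = collapse_taxa(records)
        assert {r.taxon for r in out} == expected_distinct

    def test_collapsed_level_is_species_group(self):
        (rec,) = collapse_taxa([make_record(taxon="Plecotus auritus", guild=Guild.SRE)])
        assert rec.taxon_level is TaxonLevel.SPECIES_GROUP

    def test_idempotent(self):
        records = [
            make_record(taxon=t, guild=Guild.SRE)
            for t in ["Plecotus auritus", "Nyctalus noctula", "Myotis myotis"]
        ]
        once = collapse_taxa(records)
        twice = collapse_taxa(once)
        assert [r.taxon for r in once] == [r.taxon for r in twice]

    def test_custom_mapping(self):
        (rec,) = collapse_taxa(
            [make_record(taxon="Myotis brandtii", guild=Guild.SRE)],
            mapping={"Myotis brandtii": "Myotis brandtii/mystacinus"},
        )
        assert rec.taxon == "Myotis brandtii/mystacinus"


class TestTemporalFilter:
    @pytest.mark.parametrize(
        "t, kept_by",
        [
            (30.0, {TemporalPattern.FULL_NIGHT, TemporalPattern.FIRST_4H, TemporalPattern.SPLIT_2H_2H}),
            (270.0, {TemporalPattern.FULL_NIGHT}),                              # 02:00
            (390.0, {TemporalPattern.FULL_NIGHT, TemporalPattern.SPLIT_2H_2H}),  # 04:00
            (120.0, {TemporalPattern.FULL_NIGHT, TemporalPattern.FIRST_4H}),     # 23:30 boundary
            (360.0, {TemporalPattern.FULL_NIGHT, TemporalPattern.SPLIT_2H_2H}),  # 03:30 boundary
            (240.0, {TemporalPattern.FULL_NIGHT}),                              # 01:30 boundary
        ],
    )
    def test_window_membership(self, t, kept_by):
        rec = make_record(timestamp=t)
        for pattern in TemporalPattern:
            kept = filter_temporal([rec], pattern)
            assert bool(kept) == (pattern in kept_by)

    @given(st.lists(st.floats(min_value=0, max_value=479.999), max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_full_night_is_identity_and_subwindows_nest(self, times):
        records = [make_record(timestamp=t) for t in times]
        assert filter_temporal(records, TemporalPattern.FULL_NIGHT) == records
        n_split = len(filter_temporal(records, TemporalPattern.SPLIT_2H_2H))
        n_first = len(filter_temporal(records, TemporalPattern.FIRST_4H))
        union = {
            id(r)
            for p in (TemporalPattern.SPLIT_2H_2H, TemporalPattern.FIRST_4H)
            for r in filter_temporal(records, p)
        }
        assert n_split + n_first >= len(union)
        assert len(union) <= len(records)


class TestDesignFilter:
    def test_single_and_pair_designs(self):
        records = [
            make_record(microhabitat=m, site_id=f"s-{m.value}")
            for m in (Microhabitat.GAP, Microhabitat.GROUND, Microhabitat.CANOPY)
        ]
        only_gap = filter_design(records, {Microhabitat.GAP})
        assert {r.microhabitat for r in only_gap} == {Microhabitat.GAP}
        pair = filter_design(records, {Microhabitat.GAP, Microhabitat.GROUND})
        assert {r.microhabitat for r in pair} == {Microhabitat.GAP, Microhabitat.GROUND}
        assert filter_design(records, set(Microhabitat)) == records

    def test_empty_design_rejected(self):
        with pytest.raises(ValueError):
            filter_design([make_record()], set())


class TestIdentificationSummary:
    def test_survey_scale_percentages(self):
        # identification ladder of a large campaign: species-level share of
        # the grand total prints at one decimal
        levels = {
            TaxonLevel.SPECIES: 129_671,
            TaxonLevel.SPECIES_GROUP: 10_948,
            TaxonLevel.GENUS: 4_128,
            TaxonLevel.GENUS_GROUP: 168,
            TaxonLevel.ORDER: 518,
        }
        taxa = {"Pipistrellus pipistrellus": 113_340, "others": 16_687}
        s = identification_summary_from_counts(levels, taxa)
        assert s.total == 145_433
        by_level = dict(zip(s.by_level["level"], s.by_level["pct_of_total"]))
        assert by_level["species"] == 89.2
        assert by_level["species_group"] == 7.5
        dominant = s.by_taxon.set_index("taxon").loc["Pipistrellus pipistrellus"]
        assert dominant["pct_of_guild_assignable"] == 87.17

    def test_single_record(self):
        s = summarize_identification([make_record()])
        assert s.by_level["pct_of_total"].tolist() == [100.0]
        assert s.by_taxon["pct_of_guild_assignable"].tolist() == [100.0]

    def test_order_level_excluded_from_taxon_table(self, records_csv):
        s = summarize_identification(read_records(records_csv))
        assert "Chiroptera" not in set(s.by_taxon["taxon"])
        assert s.total == 5
        assert s.total_guild_assignable == 4

    @given(
        st.dictionaries(
            st.sampled_from(list(TaxonLevel)),
            st.integers(min_value=1, max_value=10_000),
            min_size=1,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_level_percentages_sum_to_100(self, levels):
        s = identification_summary_from_counts(levels, {"x": 1})
        tol = 0.05 * len(s.by_level)
        assert abs(s.by_level["pct_of_total"].sum() - 100.0) <= tol

    def test_empty_input(self):
        s = summarize_identification([])
        assert s.by_level.empty and s.by_taxon.empty


@pytest.mark.parametrize(
    "x, nd, expected",
    [(252.877, 1, 252.9), (183.911, 1, 183.9), (0.25, 1, 0.3), (87.165, 2, 87.17)],
)
def test_round_half_up(x, nd, expected):
    assert round_half_up(x, nd) == expected
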