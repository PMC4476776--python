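import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import aisfish as af
from aisfish.ingest import FormatError, length_class
from aisfish._text import jaro, levenshtein_similarity


def _ais_csv(rows):
    df = pd.DataFrame(rows, columns=["ais_vessel_id", "timestamp", "lat",
                                     "lon", "speed"])
    return io.StringIO(df.to_csv(index=False))


def _row(i, vessel="V1", lat=57.0, lon=11.0, speed=5.0):
    return (vessel, f"2024-03-01T{i // 60:02d}:{i % 60:02d}:00Z", lat, lon, speed)


class TestReadAis:
    def test_well_formed_rows_all_kept(self):
        df, rej = af.read_ais(_ais_csv([_row(i) for i in range(100)]))
        assert len(df) == 100
        assert rej.n_kept == 100
        assert rej.n_unparsable == rej.n_out_of_range == rej.n_duplicate == 0

    def test_out_of_range_latitude_rejected(self):
        rows = [_row(i) for i in range(99)] + [_row(99, lat=95.0)]
        df, rej = af.read_ais(_ais_csv(rows))
        assert len(df) == 99
        assert rej.n_out_of_range == 1

    def test_unparsable_timestamp_rejected(self):
        rows = [_row(i) for i in range(5)] + [("V1", "not-a-time", 57, 11, 5)]
        df, rej = af.read_ais(_ais_csv(rows))
        assert len(df) == 5
        assert rej.n_unparsable == 1

    def test_duplicates_collapsed_and_logged(self):
        rows = [_row(0), _row(0), _row(1)]
        df, rej = af.read_ais(_ais_csv(rows))
        assert len(df) == 2
        assert rej.n_duplicate == 1

    def test_timestamps_increasing_per_vessel(self):
        rows = [_row(3), _row(1, "V2"), _row(2), _row(0, "V2")]
        df, _ = af.read_ais(_ais_csv(rows))
        for _, grp in df.groupby("ais_vessel_id"):
            assert grp["timestamp"].is_monotonic_increasing

    def test_missing_column_is_format_error(self):
        buf = io.StringIO("ais_vessel_id,timestamp,lat,lon\nV1,2024-01-01,57,11\n")
        with pytest.raises(FormatError):
            af.read_ais(buf)


def _vessels(pairs):
    """Build matched (register, ais) tables from (callsign, name) pairs."""
    reg = pd.DataFrame([dict(register_id=f"R{i}", callsign=c, name=n)
                        for i, (c, n) in enumerate(pairs)])
    ais = pd.DataFrame([dict(ais_vessel_id=f"A{i}", callsign=c, name=n)
                        for i, (c, n) in enumerate(pairs)])
    return reg, ais


class TestLinkRegister:
    def test_identical_callsigns_join_exactly(self):
        reg, ais = _vessels([("SFB1234", "NORDKAP"), ("SAA9", "VESTRA")])
        m = af.link_register(reg, ais)
        assert (m.method == "exact").all()
        assert (m.similarity == 1.0).all()

    def test_single_edit_callsign_recovered_fuzzily(self):
        """Levenshtein similarity 6/7 ~ 0.857 clears the 0.85 threshold."""
        reg, ais = _vessels([("SFB1234", "NORDKAP")])
        ais.loc[0, "callsign"] = "SFB123A"
        ais.loc[0, "name"] = "KATSUND"  # name must not rescue the match
        m = af.link_register(reg, ais, threshold=0.85)
        assert m.loc[0, "method"] == "fuzzy-callsign"
        assert levenshtein_similarity("SFB1234", "SFB123A") == pytest.approx(6 / 7)
        assert m.loc[0, "similarity"] >= 6 / 7  # Jaro may score the pair higher

    def test_equidistant_candidates_both_unmatched(self):
        reg = pd.DataFrame([
            dict(register_id="R0", callsign="AAAB", name="ALPHA"),
            dict(register_id="R1", callsign="AAAC", name="BRAVO"),
        ])
        ais = pd.DataFrame([dict(ais_vessel_id="A0", callsign="AAAD",
                                 name="CHARLIE")])
        m = af.link_register(reg, ais, threshold=0.5)
        assert (m.method == "unmatched").all()

    def test_empty_callsigns_skipped_not_matched(self):
        reg = pd.DataFrame([dict(register_id="R0", callsign="", name="XQJVK")])
        ais = pd.DataFrame([dict(ais_vessel_id="A0", callsign="", name="ZWPMY")])
        m = af.link_register(reg, ais)
        assert (m.method == "unmatched").all()

    def test_typo_free_register_fully_recovered_exactly(self, small_fleet):
        ais = (small_fleet.messages[["ais_vessel_id", "callsign", "name"]]
               .drop_duplicates("ais_vessel_id"))
        m = af.link_register(small_fleet.register, ais)
        assert (m.method == "exact").all()

    def test_single_edit_corruptions_recovered(self, small_fleet):
        """Simulated callsigns are unique at distance >= 2, so one edit
        still has a unique nearest neighbour and full fuzzy recall."""
        reg, typo_map = af.inject_typos(small_fleet.register, 0.3, seed=21)
        ais = (small_fleet.messages[["ais_vessel_id", "callsign", "name"]]
               .drop_duplicates("ais_vessel_id"))
        m = af.link_register(reg, ais, threshold=0.85)
        assert (m.method != "unmatched").all()
        # every corrupted vessel is still paired with its own AIS identity
        truth = small_fleet.truth.vessels.set_index("register_id")["ais_vessel_id"]
        for rid in typo_map.register_id:
            assert m.set_index("register_id").loc[rid, "ais_vessel_id"] == truth[rid]

    def test_one_to_one_never_violated(self, small_fleet):
        reg, _ = af.inject_typos(small_fleet.register, 0.5, seed=8)
        ais = (small_fleet.messages[["ais_vessel_id", "callsign", "name"]]
               .drop_duplicates("ais_vessel_id"))
        for thr in (0.5, 0.7, 0.85, 0.95):
            m = af.link_register(reg, ais, threshold=thr)
            matched = m[m.method != "unmatched"]
            assert matched.register_id.is_unique
            assert matched.ais_vessel_id.is_unique


@given(st.text(alphabet="AB1", max_size=6), st.text(alphabet="AB1", max_size=6))
def test_similarity_scores_bounded_and_symmetric(a, b):
    for f in (levenshtein_similarity, jaro):
        s = f(a, b)
        assert 0.0 <= s <= 1.0
        assert s == f(b, a)
        assert f(a, a) == 1.0


def _uptake_register(counts):
    rows = []
    for stratum, (n_reg, _) in counts.items():
        for k in range(n_reg):
            rows.append(dict(register_id=f"{stratum}-{k}", stratum=stratum))
    return pd.DataFrame(rows)


def _uptake_inputs(counts):
    """Register with n_registered rows per stratum, of which n_with_ais transmit."""
    register = _uptake_register(counts)
    match_rows, msg_rows = [], []
    for stratum, (_, n_ais) in counts.items():
        for k in range(n_ais):
            rid, aid = f"{stratum}-{k}", f"AIS-{stratum}-{k}"
            match_rows.append(dict(register_id=rid, ais_vessel_id=aid,
                                   method="exact", similarity=1.0))
            msg_rows.append(dict(ais_vessel_id=aid,
                                 timestamp=pd.Timestamp("2024-03-01T00:00Z"),
                                 lat=57.0, lon=11.0, speed=5.0))
    return register, pd.DataFrame(match_rows), pd.DataFrame(msg_rows)


class TestUptake:
    def test_per_length_class_rates(self):
        """Fleet-register head counts by length class give the published
        uptake percentages (1195/2082, 2550/3206, 2361/2842)."""
        counts = {"15-18m": (2082, 1195), "18-24m": (3206, 2550),
                  ">24m": (2842, 2361)}
        register, matches, messages = _uptake_inputs(counts)
        rep = af.uptake(register, matches, messages, strata="stratum")
        rates = rep.set_index("stratum")["rate"]
        assert round(rates["15-18m"], 1) == 57.4
        assert round(rates["18-24m"], 1) == 79.5
        assert rates[">24m"] == pytest.approx(100 * 2361 / 2842)

    def test_zero_with_ais_is_zero_percent(self):
        register, matches, messages = _uptake_inputs({"s": (10, 0)})
        matches = pd.DataFrame(columns=["register_id", "ais_vessel_id",
                                        "method", "similarity"])
        rep = af.uptake(register, matches,
                        pd.DataFrame(columns=["ais_vessel_id"]), strata="stratum")
        assert rep.rate.iloc[0] == 0.0

    def test_all_transmitting_is_100_percent(self, small_fleet):
        ais = (small_fleet.messages[["ais_vessel_id", "callsign", "name"]]
               .drop_duplicates("ais_vessel_id"))
        matches = af.link_register(small_fleet.register, ais)
        rep = af.uptake(small_fleet.register, matches, small_fleet.messages)
        assert (rep.rate == 100.0).all()

    def test_monthly_rates_cumulative_nondecreasing(self, small_fleet):
        ais = (small_fleet.messages[["ais_vessel_id", "callsign", "name"]]
               .drop_duplicates("ais_vessel_id"))
        matches = af.link_register(small_fleet.register, ais)
        rep = af.uptake_by_month(small_fleet.register, matches,
                                 small_fleet.messages)
        assert rep.rate.is_monotonic_increasing
        assert (rep.rate <= 100.0).all()


def test_length_classes_partition_lengths():
    assert length_class(15.0) == "15-18m"
    assert length_class(17.99) == "15-18m"
    assert length_class(18.0) == "18-24m"
    assert length_class(24.0) == ">24m"
    assert length_class(14.9) == "<15m"
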