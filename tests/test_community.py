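"""Community transformations, Bray-Curtis, and the time-lag curve."""

import numpy as np
import pandas as pd
import pytest

import planktonts as pts
from planktonts import (
    CommunityTable,
    aggregate_groups,
    bray_curtis_dissimilarity,
    bray_curtis_similarity,
    copy_number_normalize,
    exclude_taxa,
    time_lag_similarity,
    to_relative,
)
from planktonts.community import read_community_csv, write_community_csv
from tests.conftest import brute_force_bray_curtis


def make_table(values, taxa, groups=None, copies=None, value_kind="counts",
               dates=None, trophic_level="bacterioplankton"):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if dates is None:
        dates = pd.date_range("2015-01-01", periods=values.shape[0], freq="7D")
    tax = pd.DataFrame(
        {
            "group": groups or {t: t for t in taxa},
            "trophic_level": trophic_level,
            "genome_copy_number": copies or {t: np.nan for t in taxa},
            "carbon_factor": np.nan,
        },
        index=pd.Index(taxa, name="taxon"),
    )
    return CommunityTable(
        data=pd.DataFrame(values, index=dates, columns=taxa),
        taxonomy=tax,
        value_kind=value_kind,
        trophic_level=trophic_level,
    )


# ---------------------------------------------------------------- normalization

def test_copy_number_normalize_hand_example():
    t = make_table([[10, 10]], ["a", "b"], copies={"a": 1, "b": 2})
    out = copy_number_normalize(t)
    np.testing.assert_allclose(out.data.iloc[0], [2 / 3, 1 / 3])
    assert out.value_kind == "relative"


def test_copy_number_equal_copies_is_plain_relative():
    t = make_table([[3, 9, 6]], ["a", "b", "c"], copies={"a": 3, "b": 3, "c": 3})
    out = copy_number_normalize(t)
    np.testing.assert_allclose(out.data.iloc[0], [3 / 18, 9 / 18, 6 / 18])


def test_copy_number_scale_invariance_and_closure(rng):
    counts = rng.integers(1, 500, size=(6, 8)).astype(float)
    taxa = [f"t{i}" for i in range(8)]
    copies = {t: float(c) for t, c in zip(taxa, rng.integers(1, 8, size=8))}
    t1 = make_table(counts, taxa, copies=copies)
    t2 = make_table(2 * counts, taxa, copies=copies)
    a = copy_number_normalize(t1).data
    b = copy_number_normalize(t2).data
    pd.testing.assert_frame_equal(a, b)
    np.testing.assert_allclose(a.sum(axis=1), 1.0)


def test_copy_number_single_taxon_and_zero_sample():
    t = make_table([[42]], ["only"], copies={"only": 5})
    assert copy_number_normalize(t).data.iloc[0, 0] == pytest.approx(1.0)
    t0 = make_table([[0, 0]], ["a", "b"], copies={"a": 1, "b": 1})
    with pytest.raises(ValueError, match="all-zero"):
        copy_number_normalize(t0)


def test_copy_number_missing_copies_fall_back_to_median(caplog):
    t = make_table([[10, 10, 10]], ["a", "b", "c"],
                   copies={"a": 2.0, "b": 4.0, "c": np.nan})
    out = copy_number_normalize(t)  # c falls back to median(2, 4) = 3
    expect = np.array([10 / 2, 10 / 4, 10 / 3])
    np.testing.assert_allclose(out.data.iloc[0], expect / expect.sum())


# ---------------------------------------------------------------- exclusion

def test_exclude_recloses_compositional_table():
    t = make_table([[0.5, 0.3, 0.2]], ["Synechococcus", "x", "y"],
                   groups={"Synechococcus": "Cyanobacteria", "x": "A", "y": "B"},
                   value_kind="relative")
    out = exclude_taxa(t, lambda taxon, row: row["group"] == "Cyanobacteria")
    np.testing.assert_allclose(out.data.iloc[0], [0.6, 0.4])
    assert list(out.taxa) == ["x", "y"]


def test_exclude_nothing_is_identity_and_counts_untouched():
    t = make_table([[5, 7]], ["a", "b"])
    out = exclude_taxa(t, lambda taxon, row: False)
    pd.testing.assert_frame_equal(out.data, t.data)
    t2 = make_table([[5, 7, 2]], ["a", "b", "c"])
    out2 = exclude_taxa(t2, lambda taxon, row: taxon == "c")
    np.testing.assert_allclose(out2.data.iloc[0], [5.0, 7.0])


def test_exclude_everything_is_an_error():
    t = make_table([[1, 2]], ["a", "b"])
    with pytest.raises(ValueError):
        exclude_taxa(t, lambda taxon, row: True)


# ---------------------------------------------------------------- aggregation

def test_aggregate_sums_group_members():
    t = make_table([[3, 4, 2]], ["Acartia", "Temora", "Bosmina"],
                   groups={"Acartia": "Copepoda", "Temora": "Copepoda",
                           "Bosmina": "Cladocera"})
    out, audit = aggregate_groups(t)
    assert out.data.iloc[0]["Copepoda"] == pytest.approx(7.0)
    assert out.data.iloc[0]["Cladocera"] == pytest.approx(2.0)
    assert audit == []


def test_aggregate_all_one_group_equals_row_sums(rng):
    vals = rng.random((4, 5))
    t = make_table(vals, [f"t{i}" for i in range(5)],
                   groups={f"t{i}": "G" for i in range(5)})
    out, _ = aggregate_groups(t)
    np.testing.assert_allclose(out.data["G"].to_numpy(), vals.sum(axis=1))


def test_aggregate_audits_large_other_members():
    # a 5% member hiding in the 'Other' catch-all violates the <2% rule
    t = make_table([[0.9, 0.05, 0.05]], ["a", "big", "small"],
                   groups={"a": "Copepoda", "big": "Other zooplankton",
                           "small": "Copepoda"},
                   value_kind="relative")
    _, audit = aggregate_groups(t, minor_threshold=0.02)
    assert audit == ["big"]


# ---------------------------------------------------------------- Bray-Curtis

def test_bray_curtis_hand_example():
    assert bray_curtis_dissimilarity([1, 2], [3, 2]) == pytest.approx(0.25)
    assert bray_curtis_similarity([1, 2], [3, 2]) == pytest.approx(0.75)


def test_bray_curtis_identity_and_disjoint():
    assert bray_curtis_dissimilarity([4, 1, 3], [4, 1, 3]) == 0.0
    assert bray_curtis_dissimilarity([1, 0, 2], [0, 5, 0]) == pytest.approx(1.0)


def test_bray_curtis_zero_vector_rejected():
    with pytest.raises(ValueError):
        bray_curtis_dissimilarity([0, 0], [1, 2])


def test_bray_curtis_matches_brute_force_oracle(rng):
    for _ in range(1000):
        n = rng.integers(2, 20)
        x = rng.random(n) * rng.integers(1, 100)
        y = rng.random(n) * rng.integers(1, 100)
        got = bray_curtis_dissimilarity(x, y)
        want = brute_force_bray_curtis(x, y)
        assert abs(got - want) < 1e-12
        assert 0.0 <= got <= 1.0
        assert got == pytest.approx(bray_curtis_dissimilarity(y, x), abs=1e-15)
        perm = rng.permutation(n)
        assert bray_curtis_dissimilarity(x[perm], y[perm]) == pytest.approx(got, abs=1e-12)


# ---------------------------------------------------------------- lag curve

def test_lag_curve_identical_community_always_one():
    t = make_table(np.tile([0.2, 0.8], (10, 1)), ["a", "b"], value_kind="relative",
                   dates=pd.date_range("2015-01-01", periods=10, freq="30D"))
    curve = time_lag_similarity(t)
    assert np.allclose(curve["mean_similarity"], 1.0)


def test_lag_curve_pair_count_combinatorics():
    t = make_table([[1, 2], [2, 1], [1, 1]], ["a", "b"],
                   dates=pd.date_range("2015-01-01", periods=3, freq="20D"))
    curve = time_lag_similarity(t)
    assert curve["n_pairs"].sum() == 3


def test_lag_curve_total_pairs_is_n_choose_2(rng):
    n = 40
    vals = rng.random((n, 5)) + 0.01
    t = make_table(vals, [f"t{i}" for i in range(5)],
                   dates=pd.date_range("2012-01-01", periods=n, freq="17D"))
    curve = time_lag_similarity(t)
    assert curve["n_pairs"].sum() == n * (n - 1) // 2


def test_lag_curve_first_bin_is_within_one_month():
    dates = pd.to_datetime(["2015-01-01", "2015-01-20", "2015-03-15"])
    t = make_table([[1, 1], [1, 2], [2, 1]], ["a", "b"], dates=dates)
    curve = time_lag_similarity(t).set_index("lag_months")
    assert curve.loc[1, "n_pairs"] == 1  # the 19-day pair
    # the other two pairs lie 54 and 73 days apart -> months 2 and 3
    assert curve.loc[2, "n_pairs"] == 1
    assert curve.loc[3, "n_pairs"] == 1


def test_periodic_community_peaks_at_annual_lags():
    """A strictly annual composition shows local similarity maxima at lags
    12/24/36 months.  Sampling five times per year (73-day cadence) puts
    annual pairs at exactly 365*k days, inside bins 12/24/36 with zero
    phase drift against the 30.44-day bin grid."""
    dates = pd.date_range("2011-01-15", periods=40, freq="73D")
    days = np.array([pts.julian_day(d) for d in dates], dtype=float)
    share = 0.5 + 0.4 * np.cos(2 * np.pi * (days - 105) / 365)
    vals = np.column_stack([share, 1 - share])
    t = make_table(vals, ["a", "b"], value_kind="relative", dates=dates)
    curve = time_lag_similarity(t).set_index("lag_months")["mean_similarity"]
    bins = curve.index.to_numpy()
    for peak in (12, 24, 36):
        prev = bins[bins < peak].max()
        nxt = bins[bins > peak].min()
        assert curve[peak] > curve[prev]
        assert curve[peak] > curve[nxt]
        assert curve[peak] > 0.95  # annual pairs nearly identical


def test_monotone_drift_similarity_non_increasing():
    n = 36
    dates = pd.date_range("2011-01-01", periods=n, freq="30D")
    p = np.linspace(0.1, 0.9, n)
    vals = np.column_stack([p, 1 - p])
    t = make_table(vals, ["a", "b"], value_kind="relative", dates=dates)
    curve = time_lag_similarity(t)
    sims = curve.sort_values("lag_months")["mean_similarity"].to_numpy()
    assert np.all(np.diff(sims) <= 1e-12)


def test_lag_curve_needs_two_samples():
    t = make_table([[1, 2]], ["a", "b"])
    with pytest.raises(ValueError):
        time_lag_similarity(t)


# ---------------------------------------------------------------- io

def test_community_csv_round_trip(tmp_path):
    t = make_table([[1.5, 2.5], [3.0, 0.5]], ["a", "b"],
                   groups={"a": "G1", "b": "G2"}, value_kind="biomass",
                   trophic_level="phytoplankton")
    write_community_csv(t, tmp_path / "c.csv", taxonomy_path=tmp_path / "tax.csv")
    back = read_community_csv(tmp_path / "c.csv", tmp_path / "tax.csv")
    pd.testing.assert_frame_equal(back.data, t.data, check_freq=False)
    assert back.value_kind == "biomass"
    assert back.trophic_level == "phytoplankton"
    assert list(back.taxonomy["group"]) == ["G1", "G2"]


def test_to_relative_closes_rows(rng):
    vals = rng.random((5, 4)) + 0.1
    t = make_table(vals, list("abcd"), value_kind="biomass")
    rel = to_relative(t)
    np.testing.assert_allclose(rel.data.sum(axis=1), 1.0)
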