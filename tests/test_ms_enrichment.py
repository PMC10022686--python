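"""Spectral-count filtering against hand evaluations and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from filotip import synthetic_data as syn
from filotip.ms_enrichment import (
    BIOID_FILTER,
    FERM_FILTER,
    DatasetFilter,
    apply_filter,
    dataset_overlap,
    fold_change,
    normalize_protein_id,
    read_count_table,
    volcano_table,
    write_count_table,
)


def make_table(rows: dict[str, dict[tuple[str, int], int]]) -> pd.DataFrame:
    """Build a count table from {protein: {(sample, replicate): count}}."""
    df = pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int)
    df.index.name = "protein_id"
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=["sample", "replicate"])
    return df


def oracle_passes(table, f: DatasetFilter) -> set[str]:
    """Independent per-protein re-evaluation of the filter rule."""
    out = set()
    for pid in table.index:
        bait = sum(table.loc[pid, (f.bait, r)] for r in table[f.bait].columns)
        ok = bait > f.count_threshold
        for c in f.controls:
            ctrl = sum(table.loc[pid, (c, r)] for r in table[c].columns)
            fc = (bait + 1) / (ctrl + 1) if ctrl == 0 else bait / ctrl
            ok = ok and fc >= f.min_fold_change
        if ok:
            out.add(pid)
    return out


class TestFoldChange:
    def test_plain_ratio(self):
        assert fold_change(20, 5) == pytest.approx(4.0)

    def test_zero_zero_is_one(self):
        assert fold_change(0, 0) == pytest.approx(1.0)

    def test_zero_control_pseudocount(self):
        assert fold_change(9, 0) == pytest.approx(10.0)

    def test_matches_resummation_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            b, c = rng.integers(0, 40, 2)
            expected = (b + 1) / (c + 1) if c == 0 else b / c
            assert fold_change(float(b), float(c)) == pytest.approx(expected)


class TestApplyFilter:
    def ferm_table(self, bait=(12, 9), gfp=(2, 1), tln=(3, 2)):
        return make_table(
            {
                "MYO10": {
                    ("MYO10_FERM", 1): bait[0], ("MYO10_FERM", 2): bait[1],
                    ("GFP", 1): gfp[0], ("GFP", 2): gfp[1],
                    ("TLN1_FERM", 1): tln[0], ("TLN1_FERM", 2): tln[1],
                }
            }
        )

    def test_ferm_hand_example_passes(self):
        # bait total 21, GFP 3, TLN 5: FC 7.0 and 4.2, 21 > 10 -> passes
        rec, = apply_filter(self.ferm_table(), FERM_FILTER)
        assert rec.total_bait_count == 21
        assert rec.fold_change_vs_control["GFP"] == pytest.approx(7.0)
        assert rec.fold_change_vs_control["TLN1_FERM"] == pytest.approx(4.2)
        assert rec.passes_filter

    def test_count_threshold_is_strict(self):
        # "more than ten": bait total 8 fails however enriched;
        # exactly 10 also fails, 11 passes
        rec, = apply_filter(self.ferm_table(bait=(5, 3), gfp=(0, 0), tln=(0, 0)), FERM_FILTER)
        assert not rec.passes_filter
        rec10, = apply_filter(self.ferm_table(bait=(5, 5), gfp=(0, 0), tln=(0, 0)), FERM_FILTER)
        assert not rec10.passes_filter
        rec11, = apply_filter(self.ferm_table(bait=(6, 5), gfp=(0, 0), tln=(0, 0)), FERM_FILTER)
        assert rec11.passes_filter

    def test_must_beat_every_control(self):
        # twofold over GFP but not over TLN1-FERM -> fails
        rec, = apply_filter(self.ferm_table(bait=(10, 10), gfp=(2, 2), tln=(8, 8)), FERM_FILTER)
        assert not rec.passes_filter

    def test_missing_sample_named(self):
        table = self.ferm_table().drop(columns=["TLN1_FERM"], level="sample")
        with pytest.raises(KeyError, match="TLN1_FERM"):
            apply_filter(table, FERM_FILTER)

    def test_planted_hits_recovered_exactly(self):
        ids = [f"P{i:04d}" for i in range(50)]
        gt = syn.CountTableGroundTruth(
            50, frozenset(ids[:10]), baseline_mean=3.0, enrichment_factor=20.0, seed=12
        )
        table = syn.generate_count_table(gt)
        filt = DatasetFilter("demo", "bait", ("control",), 2.0, 10)
        passing = {r.protein_id for r in apply_filter(table, filt)
                   if r.passes_filter}
        assert passing == set(gt.enriched_ids)

    def test_agrees_with_bruteforce_on_random_tables(self):
        rng = np.random.default_rng(7)
        filt = DatasetFilter("rand", "bait", ("ctrlA", "ctrlB"), 2.0, 10)
        for _ in range(50):
            n = rng.integers(1, 15)
            table = make_table(
                {
                    f"P{i}": {
                        ("bait", 1): int(rng.integers(0, 30)),
                        ("bait", 2): int(rng.integers(0, 30)),
                        ("ctrlA", 1): int(rng.integers(0, 10)),
                        ("ctrlA", 2): int(rng.integers(0, 10)),
                        ("ctrlB", 1): int(rng.integers(0, 10)),
                        ("ctrlB", 2): int(rng.integers(0, 10)),
                    }
                    for i in range(n)
                }
            )
            got = {r.protein_id for r in apply_filter(table, filt) if r.passes_filter}
            assert got == oracle_passes(table, filt)

    @settings(max_examples=30, deadline=None)
    @given(
        base=st.integers(0, 20),
        bump=st.integers(1, 40),
        seed=st.integers(0, 2**16),
    )
    def test_filter_monotone_in_bait_counts(self, base, bump, seed):
        """Raising a bait replicate count never flips a pass to a fail."""
        rng = np.random.default_rng(seed)
        row = {
            ("bait", 1): base, ("bait", 2): int(rng.integers(0, 20)),
            ("ctrlA", 1): int(rng.integers(0, 10)), ("ctrlA", 2): int(rng.integers(0, 10)),
        }
        filt = DatasetFilter("m", "bait", ("ctrlA",), 2.0, 10)
        before, = apply_filter(make_table({"P": row}), filt)
        bumped = dict(row)
        bumped[("bait", 1)] = base + bump
        after, = apply_filter(make_table({"P": bumped}), filt)
        if before.passes_filter:
            assert after.passes_filter


class TestVolcano:
    def test_equal_totals_zero_log2fc(self):
        table = make_table(
            {"P": {("bait", 1): 5, ("bait", 2): 5, ("control", 1): 4, ("control", 2): 6}}
        )
        rec, = apply_filter(table, DatasetFilter("d", "bait", ("control",)))
        assert rec.log2_fc == pytest.approx(0.0)

    def test_planted_twentyfold_near_log2_20(self):
        ids = [f"P{i:04d}" for i in range(200)]
        gt = syn.CountTableGroundTruth(
            200, frozenset(ids[:50]), baseline_mean=5.0, enrichment_factor=20.0,
            n_replicates_bait=5, n_replicates_control=5, seed=21,
        )
        table = syn.generate_count_table(gt)
        recs = apply_filter(table, DatasetFilter("d", "bait", ("control",), 2.0, 5))
        planted = [r.log2_fc for r in recs if r.protein_id in gt.enriched_ids]
        # small positive bias from E[log2(control total)] < log2(E[total])
        assert np.mean(planted) == pytest.approx(np.log2(20), abs=0.5)

    def test_constant_replicates_p_missing(self):
        table = make_table(
            {"P": {("bait", 1): 5, ("bait", 2): 5, ("control", 1): 5, ("control", 2): 5}}
        )
        rec, = apply_filter(table, DatasetFilter("d", "bait", ("control",)))
        assert np.isnan(rec.neg_log10_p)
        df = volcano_table([rec])
        assert df["neg_log10_p"].isna().all()

    def test_bioid_threshold_is_five(self):
        assert BIOID_FILTER.count_threshold == 5
        table = make_table(
            {
                "P": {**{("MYO10_BioID", r): 1 for r in range(1, 6)},
                      **{("GFP_MYO10", r): 0 for r in range(1, 6)}}
            }
        )
        rec, = apply_filter(table, BIOID_FILTER)
        assert not rec.passes_filter  # total 5 is not "over five"


class TestOverlap:
    def test_basic_intersection(self):
        inter, excl = dataset_overlap({"d1": {"A", "B", "C"}, "d2": {"B", "C", "D"}})
        assert inter == {"B", "C"}
        assert excl == {"d1": {"A"}, "d2": {"D"}}

    def test_disjoint(self):
        inter, _ = dataset_overlap({"d1": {"A"}, "d2": {"B"}})
        assert inter == set()

    def test_symmetry_and_normalization(self):
        a = {"d1": {"myo10", "Raph1"}, "d2": {"MYO10", "RAPH1", "VASP"}}
        b = {"d2": a["d2"], "d1": a["d1"]}
        assert dataset_overlap(a)[0] == dataset_overlap(b)[0] == {"MYO10", "RAPH1"}

    def test_normalization_idempotent(self):
        for pid in ["  myo10 ", "RAPH1", "vAsP"]:
            once = normalize_protein_id(pid)
            assert normalize_protein_id(once) == once

    def test_needs_two_sets(self):
        with pytest.raises(ValueError):
            dataset_overlap({"only": {"A"}})


def test_count_table_round_trip(tmp_path):
    ids = [f"P{i:04d}" for i in range(10)]
    gt = syn.CountTableGroundTruth(10, frozenset(ids[:2]), 3.0, 20.0, seed=5)
    table = syn.generate_count_table(gt)
    path = tmp_path / "t.csv"
    write_count_table(path, table)
    back = read_count_table(path)
    np.testing.assert_array_equal(table.to_numpy(), back.to_numpy())
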