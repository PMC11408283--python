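"""Curation rules: labeling, weight window, dedup, capping, overlap, split."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cpipred.curation import (
    AssayType,
    BioactivityRecord,
    Compound,
    CurationConfig,
    cap_negatives_per_protein,
    curate,
    dataset_overlap_stats,
    deduplicate_ligand_bias,
    filter_by_weight,
    normalize_potency_uM,
    overlap_percentage,
    resolve_activity,
    split_dataset,
    tanimoto,
)

CFG = CurationConfig()


def _rec(value=None, label=None, assay=None, src="A", cid="C1", pid="P1"):
    if assay is None:
        assay = AssayType.BINARY if label is not None else AssayType.IC50
    return BioactivityRecord(compound_id=cid, protein_id=pid, assay_type=assay,
                             value_uM=value, binary_label=label, source=src)


class TestResolveActivity:
    @pytest.mark.parametrize("values,labels,expect_label,expect_rep", [
        ([5.0], [], 1, 5.0),                # below threshold
        ([10.0], [], 1, 10.0),              # boundary inclusive
        ([15.0, 20.0], [], 0, 15.0),        # all inactive, min representative
        ([20.0], ["active"], 1, 20.0),      # any-active overrides potency
        ([8.0, 3.0, 20.0], [], 1, 3.0),     # min over multiple sources
    ])
    def test_labeling_rules(self, values, labels, expect_label, expect_rep):
        records = [_rec(value=v, src=f"s{i}") for i, v in enumerate(values)]
        records += [_rec(label=l, src=f"b{i}") for i, l in enumerate(labels)]
        pair = resolve_activity(records, CFG)
        assert pair.label == expect_label
        assert pair.representative_value_uM == expect_rep

    def test_any_active_dominance(self):
        """Adding a positive record can never flip a pair to negative."""
        base = [_rec(value=50.0), _rec(value=30.0, src="B")]
        assert resolve_activity(base, CFG).label == 0
        for extra in (_rec(value=1.0, src="C"), _rec(label="active", src="C")):
            assert resolve_activity(base + [extra], CFG).label == 1

    def test_binary_only_pair_has_no_representative(self):
        pair = resolve_activity([_rec(label="active")], CFG)
        assert pair.label == 1 and pair.representative_value_uM is None

    def test_mixed_pairs_rejected(self):
        with pytest.raises(ValueError):
            resolve_activity([_rec(value=1.0, cid="C1"), _rec(value=1.0, cid="C2")], CFG)

    def test_provenance_collects_sources(self):
        pair = resolve_activity([_rec(value=1.0, src="dbA"), _rec(value=2.0, src="dbB")], CFG)
        assert pair.provenance == frozenset({"dbA", "dbB"})


class TestUnitsAndWeight:
    @pytest.mark.parametrize("value,unit,expected", [
        (500.0, "nM", 0.5), (2.0, "uM", 2.0), (0.01, "mM", 10.0),
    ])
    def test_unit_normalization(self, value, unit, expected):
        assert normalize_potency_uM(value, unit) == pytest.approx(expected)

    def test_unknown_unit_rejected(self):
        with pytest.raises(ValueError):
            normalize_potency_uM(1.0, "parsec")

    @pytest.mark.parametrize("mw,kept", [
        (99.9, False), (100.0, True), (1000.0, True), (1500.0, False),
    ])
    def test_weight_window_inclusive(self, mw, kept):
        comps = {"C": Compound("C", mol_weight_Da=mw)}
        assert ("C" in filter_by_weight(comps, CFG)) is kept

    def test_missing_weight_warns_and_drops(self):
        comps = {"C": Compound("C", mol_weight_Da=None)}
        with pytest.warns(UserWarning):
            assert filter_by_weight(comps, CFG) == {}


class TestTanimoto:
    def test_known_values(self):
        a = np.zeros(8); a[[1, 2, 3]] = 1
        b = np.zeros(8); b[[2, 3, 4]] = 1
        assert tanimoto(a, b) == 0.5
        assert tanimoto(a, a) == 1.0
        assert tanimoto(a, 1 - a.astype(bool)) == 0.0

    def test_both_empty_defined_zero(self):
        assert tanimoto(np.zeros(8), np.zeros(8)) == 0.0

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            tanimoto(np.zeros(8), np.zeros(16))

    @given(st.integers(0, 10**6))
    @settings(max_examples=30, deadline=None)
    def test_symmetric_and_bounded(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.integers(0, 2, (2, 64))
        t = tanimoto(a, b)
        assert t == tanimoto(b, a) and 0.0 <= t <= 1.0


def _clustered_fixture(rng, n=8):
    """Random compounds with known pairwise similarities for dedup oracles."""
    fps = {}
    comps = []
    for i in range(n):
        fp = (rng.random(128) < 0.3).astype(np.uint8)
        cid = f"C{i}"
        fps[cid] = fp
        comps.append((Compound(cid), int(rng.integers(1, 20))))
    return comps, fps


def brute_force_leaders(compounds_with_counts, fps, cutoff):
    """Greedy grouping by descending count, re-derived independently."""
    order = sorted(compounds_with_counts, key=lambda t: (-t[1], t[0].compound_id))
    leaders = []
    for comp, _ in order:
        a = fps[comp.compound_id]
        if not any(
            (np.logical_and(a, fps[l.compound_id]).sum()
             / np.logical_or(a, fps[l.compound_id]).sum()) > cutoff
            for l in leaders
        ):
            leaders.append(comp)
    return [l.compound_id for l in leaders]


class TestDedupAndCap:
    def test_similar_group_keeps_most_connected(self):
        fp = (np.arange(64) < 20).astype(np.uint8)
        fps = {"A": fp.copy(), "B": fp.copy(), "C": fp.copy()}
        cwc = [(Compound("A"), 5), (Compound("B"), 3), (Compound("C"), 1)]
        kept = deduplicate_ligand_bias("P", cwc, fps, CFG)
        assert [c.compound_id for c in kept] == ["A"]

    def test_dissimilar_pair_untouched(self):
        fps = {"A": np.r_[np.ones(16), np.zeros(48)].astype(np.uint8),
               "B": np.r_[np.zeros(48), np.ones(16)].astype(np.uint8)}
        kept = deduplicate_ligand_bias(
            "P", [(Compound("A"), 1), (Compound("B"), 1)], fps, CFG)
        assert len(kept) == 2

    def test_tie_broken_lexicographically(self):
        fp = np.ones(32, dtype=np.uint8)
        fps = {"B": fp, "A": fp.copy()}
        kept = deduplicate_ligand_bias(
            "P", [(Compound("B"), 2), (Compound("A"), 2)], fps, CFG)
        assert [c.compound_id for c in kept] == ["A"]

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        cwc, fps = _clustered_fixture(rng)
        kept = deduplicate_ligand_bias("P", cwc, fps, CFG)
        assert [c.compound_id for c in kept] == brute_force_leaders(
            cwc, fps, CFG.tanimoto_cutoff)

    def test_dedup_idempotent(self):
        rng = np.random.default_rng(9)
        cwc, fps = _clustered_fixture(rng, n=10)
        once = deduplicate_ligand_bias("P", cwc, fps, CFG)
        counts = dict((c.compound_id, n) for c, n in cwc)
        twice = deduplicate_ligand_bias(
            "P", [(c, counts[c.compound_id]) for c in once], fps, CFG)
        assert [c.compound_id for c in twice] == [c.compound_id for c in once]

    def test_cap_limits_count_and_dissimilarity(self):
        rng = np.random.default_rng(4)
        cfg = CurationConfig(negatives_cap_per_protein=3)
        cwc, fps = _clustered_fixture(rng, n=12)
        kept = cap_negatives_per_protein("P", cwc, fps, cfg)
        assert len(kept) <= 3
        for a, b in itertools.combinations(kept, 2):
            assert tanimoto(fps[a.compound_id], fps[b.compound_id]) < cfg.tanimoto_cutoff

    def test_cap_skips_similar_candidate(self):
        fp1 = np.r_[np.ones(30), np.zeros(34)].astype(np.uint8)
        fp2 = fp1.copy(); fp2[0] = 0  # Tanimoto 29/30 > 0.8
        fp3 = np.r_[np.zeros(34), np.ones(30)].astype(np.uint8)
        fps = {"A": fp1, "B": fp2, "C": fp3}
        kept = cap_negatives_per_protein(
            "P", [(Compound("A"), 9), (Compound("B"), 5), (Compound("C"), 1)],
            fps, CFG)
        assert sorted(c.compound_id for c in kept) == ["A", "C"]

    def test_small_input_all_retained(self):
        rng = np.random.default_rng(10)
        cwc, fps = _clustered_fixture(rng, n=3)
        kept = cap_negatives_per_protein(
            "P", cwc, fps, CurationConfig(negatives_cap_per_protein=1000))
        assert len(kept) == len(brute_force_leaders(cwc, fps, CFG.tanimoto_cutoff)) \
            or len(kept) <= 3


class TestOverlapStats:
    def test_published_style_arithmetic(self):
        assert overlap_percentage(825_533, 905_350, 558_453) == 67.65
        assert overlap_percentage(12_941, 825_533, 3_158) == 24.40

    def test_identical_sets_100(self):
        s = {("a", "p"), ("b", "q")}
        m = dataset_overlap_stats({"x": s, "y": set(s)})
        assert m.loc["y", "x"] == 100.0
        assert m.loc["x", "y"] == 2

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(0)
        a = {(f"c{i}", "p") for i in rng.integers(0, 50, 30)}
        b = {(f"c{i}", "p") for i in rng.integers(0, 50, 20)}
        assert overlap_percentage(len(a), len(b), len(a & b)) == \
            overlap_percentage(len(b), len(a), len(a & b))
        assert 0 <= overlap_percentage(len(a), len(b), len(a & b)) <= 100

    def test_empty_dataset_absent(self):
        m = dataset_overlap_stats({"x": {("a", "p")}, "y": set()})
        assert np.isnan(m.loc["y", "x"])


class TestSplit:
    def _pairs(self, n):
        from cpipred.curation import CPIPair

        return [CPIPair(f"C{i}", "P", label=i % 2) for i in range(n)]

    def test_sizes_and_partition(self):
        train, test = split_dataset(self._pairs(10), CurationConfig(seed=3))
        assert len(train) == 8 and len(test) == 2
        keys = {p.key for p in train} | {p.key for p in test}
        assert len(keys) == 10

    def test_round_half_up(self):
        # the documented large-n rounding: round(0.8 * 1,014,627) = 811,702
        assert int(np.floor(0.8 * 1_014_627 + 0.5)) == 811_702
        train, test = split_dataset(self._pairs(7), CurationConfig(seed=0))
        assert len(train) == 6  # 5.6 rounds up

    def test_deterministic_under_seed(self):
        p = self._pairs(20)
        t1, _ = split_dataset(p, CurationConfig(seed=5))
        t2, _ = split_dataset(p, CurationConfig(seed=5))
        assert [x.key for x in t1] == [x.key for x in t2]

    def test_too_small_errors(self):
        with pytest.raises(ValueError):
            split_dataset(self._pairs(4), CFG)


class TestFullCuration:
    def test_golden_fixture_survivors(self, golden):
        records, compounds, fps, expected = golden
        pairs, report = curate(records, compounds, fps, CFG)
        got = {p.key: (p.label, p.representative_value_uM) for p in pairs}
        assert got == expected
        assert report["n_records"] == 12
        assert report["n_final"] == 7
        assert report["n_positive"] == 5 and report["n_negative"] == 2

    def test_no_duplicate_keys_and_counts_consistent(self, small_curated):
        pairs, report = small_curated
        keys = [p.key for p in pairs]
        assert len(keys) == len(set(keys))
        assert report["n_positive"] + report["n_negative"] == report["n_final"]

    def test_twin_compounds_removed_from_shared_proteins(self, small_benchmark):
        b = small_benchmark
        pairs, _ = curate(b.records, b.compounds, b.fingerprints,
                          CurationConfig(seed=11))
        by_protein_label = {}
        for p in pairs:
            by_protein_label.setdefault((p.protein_id, p.label), set()).add(p.compound_id)
        for base, twin in b.twin_pairs:
            for (pid, _lab), cids in by_protein_label.items():
                assert not ({base, twin} <= cids), (
                    f"near-duplicates {base},{twin} both kept for {pid}")
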