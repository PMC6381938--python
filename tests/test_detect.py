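"""Window placement, per-position fits, and candidate calling."""

import numpy as np
import pytest

import novallele as nv
from novallele.detect import DetectionConfig, MutationWindow, find_windows, legacy_window
from novallele.profiles import PositionFrequencyTable


def _table(bins, occupancy, freq_map):
    """Frequency table with freq_map[position 1-based] per-bin arrays."""
    bins = np.asarray(bins)
    freqs = np.zeros((len(bins), 312))
    for pos, values in freq_map.items():
        freqs[:, pos - 1] = values
    return PositionFrequencyTable(
        bins=bins,
        occupancy=np.asarray(occupancy),
        freqs=freqs,
        germline_sites=np.ones(312, bool),
    )


class TestFindWindows:
    def test_primary_window_at_most_frequent_positive_count(self):
        ws = find_windows({0: 40, 1: 50, 2: 30})
        assert ws[0] == MutationWindow(start=1, end=10, evaluation_x=0)

    def test_secondary_windows_above_and_below(self):
        # counts with at least 1/8 of the most frequent (100/8 = 12.5)
        # start their own windows, above or below the primary
        ws = find_windows({7: 100, 8: 40, 1: 20})
        assert [(w.start, w.end) for w in ws] == [(1, 10), (7, 16), (8, 17)]
        assert [w.evaluation_x for w in ws] == [0, 6, 7]

    def test_below_ratio_counts_ignored(self):
        ws = find_windows({3: 8, 4: 0})
        assert [(w.start, w.end) for w in ws] == [(3, 12)]

    def test_no_positive_counts(self):
        assert find_windows({0: 100}) == []

    def test_window_invariants(self):
        for w in find_windows({1: 10, 5: 80, 9: 30}):
            assert w.end - w.start == 9
            assert w.evaluation_x == w.start - 1
            assert w.start >= 1


class TestLegacyWindow:
    def test_lower_bound_capped_at_five(self):
        w = legacy_window({7: 100, 8: 40})
        assert (w.start, w.end, w.evaluation_x) == (5, 10, 0)

    def test_behaves_as_updated_when_m_is_one(self):
        hist = {0: 40, 1: 50, 2: 30}
        w = legacy_window(hist)
        assert (w.start, w.end, w.evaluation_x) == (1, 10, 0)
        assert find_windows(hist)[0] == MutationWindow(1, 10, 0)


class TestFitPosition:
    def test_constant_full_frequency_is_polymorphic(self):
        table = _table(range(1, 11), [50] * 10, {17: np.ones(10)})
        ev = nv.fit_position(table, 17, MutationWindow.updated(1))
        assert ev.verdict == "polymorphic"
        assert ev.predicted_frequency == pytest.approx(1.0)

    def test_zero_frequency_not_polymorphic(self):
        table = _table(range(1, 11), [50] * 10, {})
        ev = nv.fit_position(table, 20, MutationWindow.updated(1))
        assert ev.verdict == "not_polymorphic"
        assert ev.predicted_frequency == pytest.approx(0.0)

    def test_pure_shm_pattern_extrapolates_to_zero(self):
        # frequency x/312 rising with the sequence-wide count is the
        # somatic-hypermutation signature; the least-squares line through
        # the exactly-linear points predicts x/312 at x=0, i.e. 0
        bins = np.arange(1, 11)
        table = _table(bins, [50] * 10, {100: bins / 312})
        ev = nv.fit_position(table, 100, MutationWindow.updated(1))
        assert ev.verdict == "not_polymorphic"
        assert ev.predicted_frequency == pytest.approx(0.0, abs=1e-12)
        assert ev.fitted_slope == pytest.approx(1 / 312)

    def test_insufficient_bins(self):
        table = _table([1, 2], [50, 50], {10: np.ones(2)})
        ev = nv.fit_position(table, 10, MutationWindow.updated(1))
        assert ev.verdict == "insufficient_data"

    def test_sparse_bins_excluded(self):
        # bins under min_seqs_per_bin do not enter the fit
        table = _table([1, 2, 3, 4], [50, 3, 50, 50], {10: [0, 1, 0, 0]})
        ev = nv.fit_position(table, 10, MutationWindow.updated(1))
        assert ev.occupied_bins_used == 3
        assert ev.predicted_frequency == pytest.approx(0.0, abs=1e-12)

    def test_gap_position_rejected(self):
        table = _table(range(1, 11), [50] * 10, {})
        object.__setattr__(table, "germline_sites", np.zeros(312, bool))
        with pytest.raises(ValueError):
            nv.fit_position(table, 5, MutationWindow.updated(1))


def _one_allele_group(db, allele, n=600, seed=0, poisson_mean=4.0):
    cfg = nv.SimConfig(
        db=db,
        genotype={allele.name.gene: {allele.full_name: 1.0}},
        sequences_per_gene=n,
        poisson_mean=poisson_mean,
        seed=seed,
    )
    rep, _ = nv.simulate_repertoire(cfg)
    return rep


class TestDetectForAllele:
    def test_specificity_on_database_allele(self, small_db):
        base = small_db["SIMV1-1*01"]
        rep = _one_allele_group(small_db, base, seed=5)
        assert nv.detect_for_allele(rep, base, db=small_db) == []

    def test_recovers_single_snp_allele(self, small_db):
        base = small_db["SIMV2-1*01"]
        novel = nv.inject_snps(base, 1, 11)
        simdb = small_db.copy()
        simdb.add(novel)
        rep = _one_allele_group(simdb, novel, seed=6)
        cands = nv.detect_for_allele(rep, base, db=small_db)
        assert {c.v_region for c in cands} == {novel.v_region}
        assert all(c.supporting_unmutated_count > 0 for c in cands)

    def test_seven_snp_allele_needs_dynamic_window(self, small_db):
        # the original fixed window [min(L,5), 10] cannot see an allele
        # seven polymorphisms away; the dynamic window can
        base = small_db["SIMV2-1*01"]
        novel = nv.inject_snps(base, 7, 13)
        simdb = small_db.copy()
        simdb.add(novel)
        rep = _one_allele_group(simdb, novel, seed=8)
        updated = nv.detect_for_allele(rep, base, db=small_db)
        assert {c.v_region for c in updated} == {novel.v_region}
        legacy = nv.detect_for_allele(
            rep, base, DetectionConfig(legacy_mode=True), db=small_db
        )
        assert legacy == []

    def test_small_group_skipped(self, small_db):
        base = small_db["SIMV1-1*01"]
        rep = _one_allele_group(small_db, base, n=20, seed=5)
        assert nv.detect_for_allele(rep, base, db=small_db) == []

    def test_order_determinism(self, small_db):
        base = small_db["SIMV2-1*01"]
        novel = nv.inject_snps(base, 2, 17)
        simdb = small_db.copy()
        simdb.add(novel)
        rep = _one_allele_group(simdb, novel, seed=9)
        shuffled = nv.Repertoire(
            rep.data.sample(frac=1.0, random_state=1).reset_index(drop=True)
        )
        a = nv.detect_for_allele(rep, base, db=small_db)
        b = nv.detect_for_allele(shuffled, base, db=small_db)
        assert [(c.candidate_name, c.v_region) for c in a] == [
            (c.candidate_name, c.v_region) for c in b
        ]

    def test_clonality_guard_suppresses_single_clone(self, small_db):
        # all "novel" support from one (J, junction length) combination
        # looks like a clonal expansion and is suppressed
        base = small_db["SIMV2-1*01"]
        novel = nv.inject_snps(base, 1, 19)
        simdb = small_db.copy()
        simdb.add(novel)
        cfg = nv.SimConfig(
            db=simdb,
            genotype={base.name.gene: {novel.full_name: 1.0}},
            sequences_per_gene=600,
            n_junction_classes=1,
            seed=10,
        )
        rep, _ = nv.simulate_repertoire(cfg)
        guarded = nv.detect_for_allele(rep, base, db=small_db)
        assert guarded == []
        unguarded = nv.detect_for_allele(
            rep, base, DetectionConfig(clonality_guard=False), db=small_db
        )
        assert {c.v_region for c in unguarded} == {novel.v_region}


class TestDetectNovelAlleles:
    def test_empty_repertoire(self, small_db):
        import pandas as pd

        rep = nv.Repertoire(
            pd.DataFrame(columns=["sequence_id", "sequence_alignment", "v_call"])
        )
        assert nv.detect_novel_alleles(rep, small_db) == []

    def test_full_subject_recovers_exactly_hidden_alleles(self, het_subject):
        db, novel, rep, _ = het_subject
        cands = nv.detect_novel_alleles(rep, db)
        assert {c.v_region for c in cands} == {novel.v_region}
        assert cands[0].candidate_name == novel.full_name

    def test_duplicate_candidates_merged(self, small_db):
        # two base alleles implying the same candidate sequence report it once
        base = small_db["SIMV1-1*01"]
        novel = nv.inject_snps(base, 2, 23)
        simdb = small_db.copy()
        simdb.add(novel)
        rep = _one_allele_group(simdb, novel, n=1200, seed=12)
        # assign half the group to each of two (identical-gene) bases
        half = len(rep.data) // 2
        calls = [base.full_name] * half + ["SIMV1-1*02"] * (len(rep.data) - half)
        rep.data["v_call_genotyped"] = calls
        cands = nv.detect_novel_alleles(rep, simdb.copy() if False else small_db)
        regions = [c.v_region for c in cands]
        assert len(regions) == len(set(regions))
        assert novel.v_region in regions


def test_specificity_across_many_simulated_groups(small_db):
    # repertoires simulated purely from database alleles yield no
    # candidates, across >= 100 groups at varied somatic mutation loads
    n_groups = 0
    for seed in range(25):
        for allele_name in ("SIMV1-1*01", "SIMV1-2*01", "SIMV2-1*01", "SIMV2-2*01"):
            base = small_db[allele_name]
            rep = _one_allele_group(
                small_db, base, n=200, seed=seed, poisson_mean=2 + (seed % 4)
            )
            assert nv.detect_for_allele(rep, base, db=small_db) == []
            n_groups += 1
    assert n_groups >= 100
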