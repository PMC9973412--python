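"""Tests for frequencies, fold changes, exact tests, BH, and hit calling."""

import itertools
import warnings
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import spearmanr
from statsmodels.stats.multitest import multipletests

from snvscreen import (
    FoldChangePolicy,
    HitCallParams,
    ValidationError,
    adjust_bh,
    call_hits,
    compare_screens,
    enrichment_test,
    fold_change,
    fold_change_from_counts,
    score_screen,
    screen_report,
    variant_frequency,
)
from snvscreen.enrichment import EnrichmentRecord
from snvscreen.simulate import ground_truth


def fisher_oracle(a, n1, b, n2):
    """Brute-force two-sided conditional p via exact rational hypergeometric
    summation (independent of the implementation's log-space path)."""
    k_total, n_all = a + b, n1 + n2
    lo, hi = max(0, k_total - n1), min(k_total, n2)
    den = comb(n_all, n2)
    pmf = {
        x: Fraction(comb(k_total, x) * comb(n_all - k_total, n2 - x), den)
        for x in range(lo, hi + 1)
    }
    obs = pmf[b]
    cutoff = obs * (1 + Fraction(1, 10**7))
    return float(sum(p for p in pmf.values() if p <= cutoff))


# ---------------------------------------------------------------------------
# variant_frequency / fold_change


def test_variant_frequency_definition():
    assert variant_frequency(0, 100) == 0.0
    assert variant_frequency(250, 1000) == 0.25
    with pytest.raises(ValidationError, match="undefined"):
        variant_frequency(5, 0)
    with pytest.raises(ValidationError):
        variant_frequency(11, 10)


def test_fold_change_definition():
    assert fold_change(0.02, 0.0001) == pytest.approx(200.0)
    assert fold_change(0.37, 0.37) == 1.0
    with pytest.raises(ValidationError):
        fold_change(0.5, 0.0)
    with pytest.raises(ValidationError):
        fold_change(1.5, 0.1)


def test_fold_change_pseudocount_hand_computation():
    # zero-library variant, 200 timepoint reads, depth 1e5, pseudocount 0.5:
    # ((200 + .5)/1e5) / ((0 + .5)/1e5) = 401
    fc = fold_change_from_counts(200, 100_000, 0, 100_000,
                                 FoldChangePolicy(pseudocount=0.5))
    assert fc == pytest.approx(401.0)


def test_fold_change_strict_policy_excludes_zero_library():
    policy = FoldChangePolicy(strict=True)
    assert fold_change_from_counts(10, 100, 0, 100, policy) is None
    assert fold_change_from_counts(10, 100, 5, 100, policy) == pytest.approx(2.0)


# ---------------------------------------------------------------------------
# enrichment_test


def test_identical_proportions_give_p_one():
    assert enrichment_test((10, 10_000), (10, 10_000)) == 1.0


def test_exact_test_matches_hypergeometric_oracle_example():
    p = enrichment_test((10, 10_000), (500, 10_000))
    assert p == pytest.approx(fisher_oracle(10, 10_000, 500, 10_000), rel=1e-10)


def test_exact_test_exhaustive_small_tables():
    for n1, n2 in itertools.product(range(1, 9), range(1, 9)):
        for a in range(n1 + 1):
            for b in range(n2 + 1):
                got = enrichment_test((a, n1), (b, n2))
                want = fisher_oracle(a, n1, b, n2)
                assert got == pytest.approx(want, rel=1e-10, abs=1e-300)


def test_exact_test_random_tables_up_to_200():
    rng = np.random.default_rng(0)
    for _ in range(500):
        n1, n2 = (int(v) for v in rng.integers(1, 201, 2))
        a, b = int(rng.integers(0, n1 + 1)), int(rng.integers(0, n2 + 1))
        got = enrichment_test((a, n1), (b, n2))
        want = fisher_oracle(a, n1, b, n2)
        assert got == pytest.approx(want, rel=1e-10, abs=1e-300)


def test_normal_approximation_close_to_exact_for_large_cells():
    """z approximation within 10% of the exact p at moderate significance
    (all cells >= 50, proportions near-null where the CLT is accurate)."""
    rng = np.random.default_rng(1)
    checked = 0
    while checked < 50:
        n1, n2 = (int(v) for v in rng.integers(500, 2000, 2))
        p0 = rng.uniform(0.15, 0.5)
        a = int(rng.binomial(n1, p0))
        b = int(rng.binomial(n2, p0))
        if min(a, n1 - a, b, n2 - b) < 50:
            continue
        exact = enrichment_test((a, n1), (b, n2))
        if exact < 0.01:  # deep tails are the exact test's job
            continue
        approx = enrichment_test((a, n1), (b, n2), method="normal")
        assert approx == pytest.approx(exact, rel=0.10)
        checked += 1


def test_enrichment_test_validation():
    with pytest.raises(ValidationError):
        enrichment_test((0, 0), (1, 10))
    with pytest.raises(ValidationError):
        enrichment_test((11, 10), (1, 10))
    with pytest.raises(ValidationError):
        enrichment_test((1, 10), (1, 10), method="bayes")


# ---------------------------------------------------------------------------
# adjust_bh


def test_bh_single_p_is_identity():
    assert adjust_bh([0.042]) == pytest.approx([0.042])


def test_bh_hand_computation():
    np.testing.assert_allclose(adjust_bh([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
    np.testing.assert_allclose(adjust_bh([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])


def test_bh_matches_statsmodels_oracle():
    rng = np.random.default_rng(2)
    for _ in range(20):
        p = rng.uniform(0, 1, size=rng.integers(1, 200))
        _, q_ref, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(adjust_bh(p), q_ref, rtol=1e-12)


@given(st.lists(st.floats(0, 1), min_size=1, max_size=50), st.randoms())
@settings(max_examples=50, deadline=None)
def test_bh_permutation_invariance(p, rand):
    idx = list(range(len(p)))
    rand.shuffle(idx)
    q = adjust_bh(p)
    q_perm = adjust_bh([p[i] for i in idx])
    for j, i in enumerate(idx):
        assert q_perm[j] == pytest.approx(q[i])


def test_bh_rejects_out_of_range():
    with pytest.raises(ValidationError):
        adjust_bh([0.5, 1.5])
    with pytest.raises(ValidationError):
        adjust_bh([-0.1])


# ---------------------------------------------------------------------------
# hit calling


def _record(i, fc, q, lib_reads=100):
    return EnrichmentRecord(
        position=i, ref="A", alt="G", codon_index=(i - 1) // 3 + 1,
        ref_aa="K", alt_aa="R", effect="missense",
        freq_library=1e-4, freq_timepoint=fc * 1e-4, fold_change=fc,
        p_value=q, q_value=q, hit=False, lib_reads=lib_reads, tp_reads=100,
    )


def test_call_hits_partition():
    records = [_record(i, 100.0, 1e-9) for i in range(1, 11)]
    records += [_record(i, 2.0, 0.5) for i in range(11, 101)]
    _, n_hits, n_passengers = call_hits(records, HitCallParams())
    assert n_hits == 10 and n_passengers == 90


def test_call_hits_thresholds_are_strict():
    params = HitCallParams(min_fold_change=50.0, max_q=1e-5)
    at_fold = _record(1, 50.0, 1e-9)     # fold exactly at threshold: hit
    at_q = _record(2, 100.0, 1e-5)       # q exactly at threshold: not a hit
    low_lib = _record(3, 100.0, 1e-9, lib_reads=0)
    _, n_hits, _ = call_hits([at_fold, at_q, low_lib], params)
    assert at_fold.hit and not at_q.hit and not low_lib.hit
    assert n_hits == 1


def test_hit_call_params_validation():
    with pytest.raises(ValidationError):
        HitCallParams(min_fold_change=0)
    with pytest.raises(ValidationError):
        HitCallParams(max_q=0.0)


# ---------------------------------------------------------------------------
# score_screen on simulated screens


@pytest.fixture(scope="module")
def scored_default(default_screen):
    sim = default_screen
    return sim, score_screen(
        sim.library_counts, sim.timepoint_counts[8], sim.space
    )


def test_score_screen_recovers_planted_hits(scored_default):
    sim, result = scored_default
    planted = {
        (int(r.codon_index), r.alt_aa) for r in ground_truth(sim).itertuples()
    }
    hits = {(r.codon_index, r.alt_aa) for r in result.records if r.hit}
    recall = len(planted & hits) / len(planted)
    assert recall >= 0.9
    # every planted record outranks every passenger by fold change
    planted_folds = [
        r.fold_change
        for r in result.records
        if (r.codon_index, r.alt_aa) in planted
    ]
    passenger_folds = [
        r.fold_change
        for r in result.records
        if (r.codon_index, r.alt_aa) not in planted
    ]
    assert min(planted_folds) > max(passenger_folds)


def test_fold_change_rank_tracks_planted_delta(scored_default):
    sim, result = scored_default
    gt = {(int(r.codon_index), r.alt_aa): r.delta_rate
          for r in ground_truth(sim).itertuples()}
    pairs = [
        (gt[(r.codon_index, r.alt_aa)], r.fold_change)
        for r in result.records
        if (r.codon_index, r.alt_aa) in gt
    ]
    rho = spearmanr([d for d, _ in pairs], [f for _, f in pairs]).statistic
    assert rho >= 0.9


def test_score_screen_row_order_invariance(default_screen):
    sim = default_screen
    lib, tp = sim.library_counts, sim.timepoint_counts[8]
    from snvscreen.counts_io import VariantCountTable

    rng = np.random.default_rng(3)
    shuffled = VariantCountTable(
        tp.sample_id, tp.frame.sample(frac=1.0, random_state=rng.integers(1 << 31))
    )
    a = score_screen(lib, tp, sim.space)
    b = score_screen(lib, shuffled, sim.space)
    assert [(r.position, r.alt, r.fold_change, r.q_value, r.hit) for r in a.records] \
        == [(r.position, r.alt, r.fold_change, r.q_value, r.hit) for r in b.records]


def test_score_screen_fold_one_for_identical_tables(small_space, small_cds):
    from snvscreen.counts_io import VariantCountTable

    rows = []
    for v in small_space.nt_variants[:6]:
        rows.append((v.position, v.ref_base, v.alt_base, 50, 10_000))
    frame = pd.DataFrame(
        rows, columns=["pos", "ref", "alt", "variant_reads", "locus_total_reads"]
    )
    lib = VariantCountTable("lib", frame)
    tp = VariantCountTable("tp", frame.copy())
    result = score_screen(lib, tp, small_space)
    assert all(r.fold_change == pytest.approx(1.0) for r in result.records)
    assert all(r.p_value == 1.0 for r in result.records)
    assert result.n_hits == 0


def test_score_screen_disjoint_tables_warns_empty(small_space):
    from snvscreen.counts_io import VariantCountTable

    cols = ["pos", "ref", "alt", "variant_reads", "locus_total_reads"]
    v1, v2 = small_space.nt_variants[0], small_space.nt_variants[5]
    lib = VariantCountTable(
        "lib", pd.DataFrame([(v1.position, v1.ref_base, v1.alt_base, 5, 100)], columns=cols)
    )
    tp = VariantCountTable(
        "tp", pd.DataFrame([(v2.position, v2.ref_base, v2.alt_base, 5, 100)], columns=cols)
    )
    with pytest.warns(UserWarning, match="no assessable"):
        result = score_screen(lib, tp, small_space)
    assert result.status == "empty" and result.records == []


def test_score_screen_rejects_out_of_space_variants(scored_default):
    sim, result = scored_default
    # stop-codon variants are sequenced but outside the default space
    import re

    stop_positions = set(range(sim.cds.length - 2, sim.cds.length + 1))
    for msg in result.rejects:
        assert "not in variant space" in msg
    observed_positions = {
        int(re.match(r"variant (\d+)", m).group(1)) for m in result.rejects
    }
    assert observed_positions <= stop_positions


# ---------------------------------------------------------------------------
# compare_screens / screen_report


def test_compare_screens_identical(scored_default):
    _, result = scored_default
    report = compare_screens(result, result, top_n=10)
    assert report.n_shared == 10
    assert all(ra == rb for _, ra, rb in report.shared)


def test_compare_screens_disjoint():
    a_records = [_record(i, 100.0, 1e-9) for i in range(1, 6)]
    b_records = [_record(i, 100.0, 1e-9) for i in range(601, 606)]
    from snvscreen.enrichment import ScreenResult

    ra = ScreenResult(a_records, 5, 5, 0, 0.0, HitCallParams())
    rb = ScreenResult(b_records, 5, 5, 0, 0.0, HitCallParams())
    with pytest.warns(UserWarning, match="capped"):
        report = compare_screens(ra, rb, top_n=10)
    assert report.n_shared == 0 and report.top_n == 5


def test_screen_report_tables(scored_default):
    sim, result = scored_default
    report = screen_report(result.records, sim.space)
    assert list(report.plot_table.columns) == [
        "residue", "fold_change", "freq_timepoint", "hit"
    ]
    assert len(report.plot_table) == len(result.records)
    hit_rows = report.plot_table[report.plot_table["hit"]]
    assert (hit_rows["fold_change"] >= result.params.min_fold_change).all()
    assert report.spectrum["count"].sum() == len(result.records)


def test_screen_report_empty(small_space):
    report = screen_report([], small_space)
    assert len(report.plot_table) == 0
    assert report.coverage_aa_percent == 0.0
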