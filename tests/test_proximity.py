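import numpy as np
import pytest

from retroprev.benchmarks import (
    brute_force_closest,
    brute_force_genic_count,
    random_interval_instance,
)
from retroprev.proximity import (
    GeneRecord,
    closest_distances,
    genic_insertion_count,
    load_cgo_flags,
    load_gene_bed,
    proximity_stats,
)
from retroprev.repeats import RepeatRecord


def _q(start, end, chrom="c1"):
    return RepeatRecord(chrom, start, end, "+", "L1", 1.0)


def _g(start, end, chrom="c1", gid="g"):
    return GeneRecord(chrom, start, end, gid)


def test_closest_distance_conventions():
    d, _ = closest_distances([_q(10, 20)], [_g(15, 30)])
    assert d[0] == 0  # overlap
    d, _ = closest_distances([_q(10, 20)], [_g(25, 40)])
    assert d[0] == 5  # edge gap
    d, _ = closest_distances([_q(10, 20)], [_g(20, 30), _g(100, 200)])
    assert d[0] == 0  # bookended: shares no base, gap 20 - 20 = 0
    d, _ = closest_distances([_q(50, 60)], [_g(10, 20)])
    assert d[0] == 30  # target to the left


def test_gap1_dialect_shifts_nonoverlap_distances():
    d, _ = closest_distances([_q(10, 20), _q(10, 20)], [_g(25, 40)], dialect="gap1")
    assert list(d) == [6, 6]
    d, _ = closest_distances([_q(10, 20)], [_g(15, 30)], dialect="gap1")
    assert d[0] == 0  # overlap stays 0


def test_queries_without_chromosome_targets_are_flagged():
    d, n_skipped = closest_distances([_q(10, 20, "cX"), _q(10, 20)], [_g(25, 40)])
    assert list(d) == [5]
    assert n_skipped == 1


def test_genic_insertion_count_conventions():
    assert genic_insertion_count([_q(10, 20)], [_g(15, 30)]) == 1
    # one repeat overlapping two genes counts once
    assert genic_insertion_count([_q(10, 100)], [_g(15, 30), _g(50, 80)]) == 1
    assert genic_insertion_count([_q(10, 20)], [_g(30, 40)]) == 0
    assert genic_insertion_count([], [_g(30, 40)]) == 0


@pytest.mark.parametrize("seed", range(5))
def test_interval_ops_match_brute_force(seed):
    rng = np.random.default_rng(seed)
    for _ in range(60):
        queries, targets = random_interval_instance(rng, max_n=60, max_m=60)
        fast, n_skipped = closest_distances(queries, targets)
        exp = [brute_force_closest(q, targets) for q in queries]
        assert list(fast) == [d for d in exp if d is not None]
        assert n_skipped == sum(d is None for d in exp)
        assert genic_insertion_count(queries, targets) == brute_force_genic_count(
            queries, targets
        )
        assert genic_insertion_count(queries, targets) <= len(queries)


def test_distances_are_translation_invariant():
    rng = np.random.default_rng(3)
    queries, targets = random_interval_instance(rng, max_n=40, max_m=40)
    shift = 10_000
    q2 = [RepeatRecord(q.chrom, q.start + shift, q.end + shift, q.strand,
                       q.superfamily, q.divergence) for q in queries]
    t2 = [GeneRecord(t.chrom, t.start + shift, t.end + shift, t.gene_id)
          for t in targets]
    d1, s1 = closest_distances(queries, targets)
    d2, s2 = closest_distances(q2, t2)
    assert list(d1) == list(d2) and s1 == s2
    assert genic_insertion_count(queries, targets) == genic_insertion_count(q2, t2)


def test_proximity_stats_symmetric_case():
    st = proximity_stats(list(range(1, 10)))
    assert st.median == 5 and st.iqr_mean == 5 and st.n_excluded_outliers == 0


def test_proximity_stats_hand_computed_outlier_case():
    st = proximity_stats([0, 10, 20, 30, 40, 50, 60, 70, 1000])
    assert (st.q1, st.q3) == (20, 60)
    assert (st.lower_bound, st.upper_bound) == (-40, 120)
    assert st.median == 40
    assert st.iqr_mean == 35
    assert st.n_excluded_outliers == 1
    assert st.iqr == st.q3 - st.q1


def test_proximity_stats_degenerate_and_empty():
    st = proximity_stats([7])
    assert st.median == 7 and st.iqr == 0 and st.iqr_mean == 7
    with pytest.raises(ValueError, match="no distances"):
        proximity_stats([])


def test_iqr_mean_equals_plain_mean_without_outliers():
    rng = np.random.default_rng(1)
    for _ in range(20):
        d = rng.uniform(0, 100, size=rng.integers(3, 50))
        st = proximity_stats(d)
        kept_min = d[(d >= st.lower_bound) & (d <= st.upper_bound)]
        assert kept_min.min() <= st.iqr_mean <= kept_min.max()
        if st.n_excluded_outliers == 0:
            assert st.iqr_mean == pytest.approx(d.mean(), abs=1e-9)


def test_gene_bed_and_cgo_sidecar_loading(tmp_path):
    bed = tmp_path / "genes.bed"
    bed.write_text("chr1\t100\t5000\tgeneA\t0\t+\nchr1\t9000\t12000\tgeneB\t0\t-\n")
    sidecar = tmp_path / "cgo.tsv"
    sidecar.write_text("gene_id\tcategories\ngeneB\tsomatic,oncogene\n")
    genes = load_gene_bed(bed, load_cgo_flags(sidecar))
    assert genes[0].is_cgo is False
    assert genes[1].is_cgo is True
    assert genes[1].cgo_categories == frozenset({"somatic", "oncogene"})
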