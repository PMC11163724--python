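import numpy as np
import pytest

from skiptics.errors import DataError
from skiptics.junction_io import ExonRecord, SpliceJunction
from skiptics.psi import (
    JunctionIndex,
    compute_psi,
    delta_psi,
    index_junctions,
    psi_matrix,
)


def brute_force_psi(exon, junctions, min_reads=10):
    """Reference classifier: enumerate junctions and classify each by
    interval arithmetic against the exon (independent of JunctionIndex)."""
    i3 = i5 = excl = 0
    for j in junctions:
        if j.chrom != exon.chrom or j.strand != exon.strand:
            continue
        if exon.strand == "+":
            if j.end == exon.start:
                i3 += j.reads
            if j.start == exon.end:
                i5 += j.reads
        else:
            if j.start == exon.end:
                i3 += j.reads
            if j.end == exon.start:
                i5 += j.reads
        if j.start < exon.start and j.end > exon.end:
            excl += j.reads
    psi3 = i3 / (i3 + excl) if i3 + excl else None
    psi5 = i5 / (i5 + excl) if i5 + excl else None
    covered = (i3 + excl) >= min_reads and (i5 + excl) >= min_reads
    return i3, i5, excl, psi3, psi5, covered


def random_instance(rng, max_junctions=20, max_exons=5):
    junctions = []
    for _ in range(int(rng.integers(0, max_junctions + 1))):
        start = int(rng.integers(0, 300))
        end = start + int(rng.integers(1, 200))
        strand = str(rng.choice(["+", "-", "."]))
        junctions.append(
            SpliceJunction("chr1", start, end, strand, int(rng.integers(0, 50)), "s1")
        )
    exons = []
    for k in range(int(rng.integers(1, max_exons + 1))):
        start = int(rng.integers(0, 400))
        end = start + int(rng.integers(1, 150))
        strand = str(rng.choice(["+", "-"]))
        exons.append(ExonRecord("chr1", start, end, strand, "g", f"e{k}", "t"))
    return junctions, exons


class TestJunctionIndex:
    def test_acceptor_lookup_is_additive(self, make_junction):
        index = index_junctions(
            [make_junction(100, 1000, reads=30), make_junction(400, 1000, reads=20)]
        )
        assert index.reads_ending_at("chr1", 1000, "+") == 50

    def test_empty_collection_lookups_return_zero(self):
        index = index_junctions([])
        assert index.reads_ending_at("chr1", 1000, "+") == 0
        assert index.reads_starting_at("chr1", 1000, "+") == 0
        assert index.reads_spanning("chr1", 10, 20, "+") == 0

    def test_duplicate_intervals_merged_with_warning(self, make_junction):
        with pytest.warns(UserWarning, match="duplicate"):
            index = index_junctions(
                [make_junction(100, 200, reads=5), make_junction(100, 200, reads=7)]
            )
        assert index.reads_ending_at("chr1", 200, "+") == 12
        assert index.n_junctions == 1

    def test_mixed_samples_rejected(self, make_junction):
        with pytest.raises(DataError):
            index_junctions(
                [
                    make_junction(1, 5, sample_id="a"),
                    make_junction(7, 9, sample_id="b"),
                ]
            )


class TestComputePsi:
    def test_ratio_formula(self, make_exon, make_junction):
        exon = make_exon(1000, 1100)
        index = index_junctions(
            [
                make_junction(500, 1000, reads=90),  # inclusion, acceptor
                make_junction(1100, 1500, reads=90),  # inclusion, donor
                make_junction(500, 1500, reads=10),  # exclusion
            ]
        )
        est = compute_psi(exon, index)
        assert est.psi3 == pytest.approx(0.9)
        assert est.psi5 == pytest.approx(0.9)
        assert est.psi == pytest.approx(0.9)
        assert est.covered

    def test_fully_skipped_exon_has_psi_zero(self, make_exon, make_junction):
        exon = make_exon(1000, 1100)
        index = index_junctions([make_junction(500, 1500, reads=25)])
        est = compute_psi(exon, index, min_reads=10)
        assert est.psi == 0.0 and est.covered

    def test_coverage_gate_below_min_reads(self, make_exon, make_junction):
        exon = make_exon(1000, 1100)
        index = index_junctions(
            [
                make_junction(500, 1000, reads=3),
                make_junction(1100, 1500, reads=2),
                make_junction(500, 1500, reads=1),
            ]
        )
        est = compute_psi(exon, index, min_reads=10)
        assert est.psi3 == pytest.approx(0.75)
        assert est.psi5 == pytest.approx(2 / 3)
        assert not est.covered

    def test_boundary_touching_junction_is_inclusion_not_exclusion(
        self, make_exon, make_junction
    ):
        # junction ends exactly at exon start: acceptor inclusion on '+'
        exon = make_exon(1000, 1100)
        index = index_junctions([make_junction(500, 1000, reads=10)])
        est = compute_psi(exon, index)
        assert est.inclusion_reads_3ss == 10 and est.exclusion_reads == 0

    def test_minus_strand_acceptor_is_high_coordinate_boundary(
        self, make_exon, make_junction
    ):
        exon = make_exon(1000, 1100, strand="-")
        index = index_junctions([make_junction(1100, 1600, strand="-", reads=40)])
        est = compute_psi(exon, index)
        assert est.inclusion_reads_3ss == 40

    def test_unstranded_junctions_excluded_by_default(self, make_exon, make_junction):
        exon = make_exon(1000, 1100)
        index = index_junctions([make_junction(500, 1000, strand=".", reads=10)])
        assert compute_psi(exon, index).inclusion_reads_3ss == 0
        assert (
            compute_psi(exon, index, include_unstranded=True).inclusion_reads_3ss == 10
        )

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(300):
            junctions, exons = random_instance(rng)
            index = index_junctions(junctions)
            # merge duplicates exactly as the index does before comparing
            for exon in exons:
                i3, i5, excl, psi3, psi5, covered = brute_force_psi(exon, junctions)
                est = compute_psi(exon, index)
                assert (est.inclusion_reads_3ss, est.inclusion_reads_5ss) == (i3, i5)
                assert est.exclusion_reads == excl
                assert est.psi3 == psi3 and est.psi5 == psi5
                assert est.covered == covered

    def test_strand_mirror_symmetry(self, rng):
        """Reflecting all coordinates and flipping strands preserves PSI."""
        L = 10_000
        for _ in range(50):
            junctions, exons = random_instance(rng)
            flip = {"+": "-", "-": "+", ".": "."}
            mirrored_j = [
                SpliceJunction("chr1", L - j.end, L - j.start, flip[j.strand], j.reads, "s1")
                for j in junctions
            ]
            index = index_junctions(junctions)
            mirrored_index = index_junctions(mirrored_j)
            for exon in exons:
                mirrored_e = ExonRecord(
                    "chr1", L - exon.end, L - exon.start, flip[exon.strand],
                    exon.gene_id, exon.exon_id, exon.transcript_id,
                )
                assert (
                    compute_psi(exon, index).psi
                    == compute_psi(mirrored_e, mirrored_index).psi
                )


class TestPsiMatrix:
    def test_cardinality_and_row_order(self, make_exon, make_junction):
        exons = [make_exon(100, 200, exon_id="b"), make_exon(50, 90, exon_id="a")]
        samples = {
            "s2": index_junctions([make_junction(10, 50, sample_id="s2")]),
            "s1": index_junctions([make_junction(10, 50, sample_id="s1")]),
        }
        estimates = psi_matrix(exons, samples)
        assert len(estimates) == 4
        assert [(e.exon_id, e.sample_id) for e in estimates] == [
            ("a", "s1"), ("a", "s2"), ("b", "s1"), ("b", "s2"),
        ]

    def test_sample_without_junctions_gives_undefined_psi(self, make_exon):
        estimates = psi_matrix([make_exon(100, 200)], {"s1": index_junctions([])})
        assert estimates[0].psi is None and not estimates[0].covered
        assert estimates[0].sample_id == "s1"

    def test_duplicate_samples_give_identical_columns(self, make_exon, make_junction):
        exon = make_exon(1000, 1100)
        js = [
            make_junction(500, 1000, reads=30),
            make_junction(1100, 1500, reads=28),
            make_junction(500, 1500, reads=4),
        ]
        samples = {"a": index_junctions(js), "b": index_junctions(js)}
        ests = psi_matrix([exon], samples)
        assert ests[0].psi == ests[1].psi


def _estimate(exon_id, i3, i5, excl, sample_id="s1", min_reads=10):
    from skiptics.psi import PsiEstimate

    psi3 = i3 / (i3 + excl) if i3 + excl else None
    psi5 = i5 / (i5 + excl) if i5 + excl else None
    defined = [v for v in (psi3, psi5) if v is not None]
    return PsiEstimate(
        exon_id, sample_id, i3, i5, excl, psi3, psi5,
        sum(defined) / len(defined) if defined else None,
        (i3 + excl) >= min_reads and (i5 + excl) >= min_reads,
    )


class TestDeltaPsi:
    def test_large_repression(self):
        control = [_estimate("e1", 95, 95, 5)]
        treated = [_estimate("e1", 5, 5, 95)]
        (rec,) = delta_psi(control, treated)
        assert rec.delta_psi == pytest.approx(-0.90)
        assert rec.covered_both

    def test_identical_groups_give_zero(self):
        group = [_estimate("e1", 40, 42, 8), _estimate("e2", 30, 30, 3)]
        for rec in delta_psi(group, group):
            assert rec.delta_psi == 0.0

    def test_uncovered_condition_yields_undefined_delta(self):
        control = [_estimate("e1", 95, 95, 5)]
        treated = [_estimate("e1", 2, 1, 1)]
        (rec,) = delta_psi(control, treated)
        assert not rec.covered_both and rec.delta_psi is None

    def test_disjoint_exon_sets_error_lists_ids(self):
        with pytest.raises(DataError, match="e2"):
            delta_psi([_estimate("e1", 9, 9, 1)], [_estimate("e2", 9, 9, 1)])

    def test_pooled_aggregation_sums_reads_before_ratio(self):
        control = [
            _estimate("e1", 1, 1, 0, sample_id="c1"),
            _estimate("e1", 99, 99, 0, sample_id="c2"),
        ]
        treated = [_estimate("e1", 50, 50, 50, sample_id="t1")]
        (rec,) = delta_psi(control, treated, aggregator="pooled")
        assert rec.psi_control == pytest.approx(1.0)
        assert rec.psi_treated == pytest.approx(0.5)

    def test_mean_aggregation_averages_per_sample_psi(self):
        control = [
            _estimate("e1", 10, 10, 0, sample_id="c1"),  # psi 1.0
            _estimate("e1", 5, 5, 5, sample_id="c2"),  # psi 0.5
        ]
        treated = [_estimate("e1", 10, 10, 0, sample_id="t1")]
        (rec,) = delta_psi(control, treated, aggregator="mean")
        assert rec.psi_control == pytest.approx(0.75)


def test_pooled_psi_consistent_with_binomial_truth(rng):
    """Pooled PSI concentrates around the generating inclusion fraction."""
    from skiptics.simulate import SimConfig, simulate_junctions
    from skiptics.psi import compute_psi

    cfg = SimConfig(
        seed=11, n_genes=40, n_skiptic=0, read_depth=500,
        n_replicates=1, psi_control_range=(0.2, 0.95),
    )
    sim = simulate_junctions(cfg)
    index = index_junctions(sim.samples["control_1"])
    for gene in sim.genes:
        est = compute_psi(gene.target, index)
        assert abs(est.psi - gene.psi_control) < 0.08
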