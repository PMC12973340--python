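"""Network alteration metrics: NAD, GD, OI, stratification, associations.

The NAD/GD/OI arithmetic is checked exhaustively against brute-force oracles
over every impairment pattern of a 6-parcel, 3-network scheme.
"""

import itertools

import numpy as np
import pytest

from connvae.io import SubjectRecord
from connvae.metrics import (
    altered_networks,
    associate_with_volume,
    association_table,
    cohort_summary,
    gd,
    nad,
    overlap_index,
    stratify_by_tissue,
    subject_metrics,
)
from connvae.parcellation import ParcellationScheme

# 6 parcels in 3 networks: left A (2 parcels), left B (1), right C (3)
SMALL = ParcellationScheme(
    parcel_ids=("p0", "p1", "p2", "p3", "p4", "p5"),
    hemisphere=("left", "left", "left", "right", "right", "right"),
    raw_network=("A", "A", "B", "C", "C", "C"),
)


def oracle_nad(impaired, scheme):
    out = []
    for idx in range(scheme.n_networks):
        members = [i for i in range(scheme.n_parcels)
                   if scheme.network_index[i] == idx]
        out.append(100.0 * sum(impaired[i] for i in members) / len(members))
    return np.array(out)


class TestNAD:
    def test_worked_example(self):
        scheme = ParcellationScheme(
            tuple(f"p{i}" for i in range(10)), ("left",) * 10, ("A",) * 10)
        impaired = np.zeros(10, dtype=bool)
        impaired[:3] = True
        assert nad(impaired, scheme)[0] == pytest.approx(30.0)

    def test_boundary_patterns(self):
        assert np.all(nad(np.zeros(6, dtype=bool), SMALL) == 0)
        assert np.all(nad(np.ones(6, dtype=bool), SMALL) == 100.0)

    def test_exhaustive_against_oracle(self):
        for bits in itertools.product([0, 1], repeat=6):
            impaired = np.array(bits, dtype=bool)
            assert np.allclose(nad(impaired, SMALL), oracle_nad(impaired, SMALL))


class TestGD:
    def test_worked_example(self):
        assert gd(np.array([0.0, 0.0, 30.0, 100.0])) == 2
        assert gd(np.zeros(4)) == 0
        assert gd(np.full(36, 1.0)) == 36

    def test_two_path_equivalence_exhaustive(self):
        """GD from NAD equals GD from network-level any-impairment flags."""
        for bits in itertools.product([0, 1], repeat=6):
            impaired = np.array(bits, dtype=bool)
            via_nad = gd(nad(impaired, SMALL))
            via_sets = len(altered_networks(impaired, SMALL))
            assert via_nad == via_sets

    def test_network_sizes_partition_parcels(self):
        assert SMALL.network_sizes().sum() == SMALL.n_parcels


class TestOverlapIndex:
    def test_worked_example(self):
        assert overlap_index({0, 1, 2, 3}, {0, 1, 9}) == pytest.approx(50.0)
        assert overlap_index({0, 1}, {5}) == 0.0
        assert np.isnan(overlap_index(set(), {1}))

    def test_subset_gives_100(self):
        assert overlap_index({1, 2}, {0, 1, 2, 3}) == 100.0

    def test_exhaustive_against_counting_oracle(self):
        nets = range(SMALL.n_networks)
        subsets = [set(s) for r in range(4) for s in itertools.combinations(nets, r)]
        for single in subsets:
            for integrated in subsets:
                got = overlap_index(single, integrated)
                if not single:
                    assert np.isnan(got)
                else:
                    want = 100.0 * sum(1 for n in single if n in integrated) / len(single)
                    assert got == pytest.approx(want)


class TestStratification:
    def _record(self, tumor, edema):
        rec = SubjectRecord("g", "glioma", "test",
                            tumor_fraction=np.asarray(tumor, dtype=float),
                            edema_fraction=np.asarray(edema, dtype=float),
                            lesion_hemisphere="left")
        rec.validate(6)
        return rec

    def test_tumor_takes_precedence_over_edema(self):
        rec = self._record([0.2, 0, 0, 0, 0, 0], [0, 0.5, 0, 0, 0, 0])
        classes = stratify_by_tissue(SMALL, rec)
        assert classes[0] == "tumor"  # network A has tumor + edema parcels

    def test_edema_only_and_healthy(self):
        rec = self._record([0] * 6, [0, 0, 0.4, 0, 0, 0])
        assert stratify_by_tissue(SMALL, rec) == ["healthy", "edema", "healthy"]
        rec0 = self._record([0] * 6, [0] * 6)
        assert stratify_by_tissue(SMALL, rec0) == ["healthy"] * 3

    def test_overlap_threshold_filters_small_fractions(self):
        rec = self._record([0.05, 0, 0, 0, 0, 0], [0] * 6)
        assert stratify_by_tissue(SMALL, rec, overlap_threshold=0.1)[0] == "healthy"


class TestCohortSummary:
    def _metrics(self, fc, sc, fcsc, tumor=None):
        rec = SubjectRecord(
            "g", "glioma", "test",
            tumor_fraction=np.asarray(tumor if tumor is not None else [0] * 6,
                                      dtype=float),
            edema_fraction=np.zeros(6), lesion_hemisphere="left")
        rec.validate(6)
        return subject_metrics(
            {"FC": np.asarray(fc, bool), "SC": np.asarray(sc, bool),
             "FCSC": np.asarray(fcsc, bool)}, SMALL, rec)

    def test_single_subject_single_combination(self):
        m = self._metrics([1, 0, 0, 0, 0, 0], [0] * 6, [0] * 6)
        summary = cohort_summary([m], SMALL)
        assert len(summary) == 1
        row = summary.iloc[0]
        assert row.combination == "FC_only"
        assert row.percent_subjects == 100.0
        assert row.network == "A"

    def test_partition_conservation(self):
        """Combination cells for one network/tissue sum to the fraction of
        subjects with any alteration there."""
        ms = [
            self._metrics([1, 0, 0, 0, 0, 0], [1, 0, 0, 0, 0, 0], [0] * 6),
            self._metrics([1, 0, 0, 0, 0, 0], [0] * 6, [1, 0, 0, 0, 0, 0]),
            self._metrics([0] * 6, [0] * 6, [0] * 6),
        ]
        summary = cohort_summary(ms, SMALL)
        cell = summary[(summary.network == "A")]
        # 2 of 3 subjects altered network A, in two distinct exclusive combos
        assert set(cell.combination) == {"FC_and_SC", "FC_and_FCSC"}
        assert cell.percent_subjects.sum() == pytest.approx(200.0 / 3)

    def test_gd_and_oi_wiring(self):
        m = self._metrics([1, 0, 1, 0, 0, 0], [0] * 6, [1, 0, 0, 0, 0, 0])
        assert m.gd["FC"] == 2 and m.gd["FCSC"] == 1
        assert m.oi_fc == pytest.approx(50.0)
        assert np.isnan(m.oi_sc)


def bh_oracle(pvals):
    """Textbook Benjamini-Hochberg step-up adjustment."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p)
    adjusted = np.empty(n)
    prev = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = n - rank_from_end
        prev = min(prev, p[idx] * n / rank)
        adjusted[idx] = prev
    return adjusted


class TestAssociations:
    def test_linear_relation_pearson_one(self):
        vol = np.array([1.0, 2, 3, 4, 5])
        coef, p = associate_with_volume(2 * vol + 1, vol, "pearson")
        assert coef == pytest.approx(1.0)

    def test_monotone_nonlinear_spearman_one(self):
        vol = np.array([1.0, 2, 3, 4, 5])
        values = np.exp(vol)
        assert associate_with_volume(values, vol, "spearman")[0] == pytest.approx(1.0)
        assert associate_with_volume(values, vol, "pearson")[0] < 1.0

    def test_constant_values_sentinel(self):
        coef, p = associate_with_volume(np.ones(5), np.arange(5.0), "pearson")
        assert np.isnan(coef) and np.isnan(p)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            associate_with_volume(np.array([1.0, 2]), np.array([1.0, 2]), "pearson")

    def test_bh_adjustment_matches_step_up_oracle(self):
        rng = np.random.default_rng(5)
        vol = rng.uniform(1, 10, 30)
        tests = []
        for i in range(6):
            noise = rng.normal(0, 1 + i, 30)
            tests.append((f"t{i}", vol * (i % 3) + noise, vol, "pearson"))
        table = association_table(tests)
        oracle = bh_oracle(table.p_raw.to_numpy())
        assert np.allclose(table.p_adjusted.to_numpy(), oracle)
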