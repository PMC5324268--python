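"""Δ statistics, cutoff classification, rank tests and ROC calibration."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from rinvar.centrality import CentralityProfile
from rinvar.delta_classifier import (
    BENIGN_LIKE,
    PATHOGENIC_LIKE,
    DataIntegrityError,
    DeltaRecord,
    classify,
    compute_delta,
    confusion_counts,
    group_test,
    load_reported_deltas,
    roc,
)


def _profile(b_ct, deg=None, cc=None, c=None, e=None, eb=None):
    nodes = list(b_ct)
    return CentralityProfile(
        b_ct=b_ct,
        b_ct_raw=dict(b_ct),
        degree=deg or {n: 0 for n in nodes},
        cc_ct=cc or {n: 0.0 for n in nodes},
        c_ct=c or {n: 0.0 for n in nodes},
        e_ct=e or {n: 0 for n in nodes},
        eb_ct=eb or {},
    )


class TestComputeDelta:
    def test_identical_profiles_give_zero_deltas(self):
        p = _profile({"s": 0.02}, deg={"s": 4}, cc={"s": 0.5}, c={"s": 0.3}, e={"s": 3})
        rec = compute_delta(p, p, "s", label="X1X", group="CONTROL")
        assert (rec.delta_b_ct, rec.delta_d, rec.delta_cc_ct,
                rec.delta_c_ct, rec.delta_e_ct) == (0.0, 0, 0.0, 0.0, 0)
        assert rec.call == BENIGN_LIKE

    def test_betweenness_drop_on_reported_scale(self):
        # site B_ct 2.2 -> 0.39 on the ×100 scale gives ΔB_ct = -1.81
        wt = _profile({"s": 0.022})
        mut = _profile({"s": 0.0039})
        rec = compute_delta(wt, mut, "s", label="L858H")
        assert rec.delta_b_ct == pytest.approx(-1.81)
        assert rec.call == PATHOGENIC_LIKE

    def test_degree_loss_counted(self):
        wt = _profile({"s": 0.0}, deg={"s": 4})
        mut = _profile({"s": 0.0}, deg={"s": 3})
        assert compute_delta(wt, mut, "s").delta_d == -1

    def test_missing_site_raises(self):
        p = _profile({"s": 0.0})
        with pytest.raises(KeyError):
            compute_delta(p, _profile({"t": 0.0}), "s")


class TestClassify:
    @pytest.mark.parametrize(
        "delta,expected",
        [(0.27, PATHOGENIC_LIKE), (-0.27, PATHOGENIC_LIKE),
         (0.0, BENIGN_LIKE), (0.26, BENIGN_LIKE), (-0.26, BENIGN_LIKE)],
    )
    def test_strict_cutoff_rule(self, delta, expected):
        rec = DeltaRecord(label="x", group="GF", delta_b_ct=delta)
        assert classify(rec, 0.26) == expected

    def test_monotone_in_cutoff(self):
        recs = [DeltaRecord(label=str(v), group="GF", delta_b_ct=v)
                for v in (-2.0, -0.1, 0.0, 0.1, 2.0)]
        assert all(classify(r, 1e12) == BENIGN_LIKE for r in recs)
        tiny = [classify(r, 1e-9) for r in recs]
        assert tiny == [PATHOGENIC_LIKE, PATHOGENIC_LIKE, BENIGN_LIKE,
                        PATHOGENIC_LIKE, PATHOGENIC_LIKE]

    def test_nonpositive_cutoff_rejected(self):
        with pytest.raises(ValueError):
            classify(DeltaRecord(label="x", group="GF", delta_b_ct=1.0), 0.0)


class TestGroupTest:
    def test_identical_samples_not_significant(self):
        stat, p = group_test([1, 2, 3, 4], [1, 2, 3, 4])
        assert p == pytest.approx(1.0, abs=0.05)

    def test_exact_rank_sum_enumeration(self):
        # complete separation of 3 vs 3: 2 of the 20 rank assignments are as
        # extreme, so the exact two-sided p is 0.1
        _, p = group_test([10, 11, 12], [0, 0.1, 0.2])
        assert p == pytest.approx(2 / 20)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(1, 1, 20), rng.normal(0, 1, 25)
        _, p1 = group_test(np.abs(a), np.abs(b))
        _, p2 = group_test(np.exp(np.abs(a)), np.exp(np.abs(b)))
        assert p1 == pytest.approx(p2)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            group_test([1.0], [1, 2, 3])

    def test_signed_rank_variant_requires_pairing(self):
        with pytest.raises(ValueError):
            group_test([1, 2, 3], [1, 2], variant="signed-rank")
        stat, p = group_test([1, 5, 3, 9], [0, 1, 2, 3], variant="signed-rank")
        assert 0 <= p <= 1


def _records(pos_scores, neg_scores):
    recs = [DeltaRecord(label=f"p{i}", group="GF", delta_b_ct=v)
            for i, v in enumerate(pos_scores)]
    recs += [DeltaRecord(label=f"n{i}", group="CONTROL", delta_b_ct=v)
             for i, v in enumerate(neg_scores)]
    return recs


class TestRoc:
    def test_perfect_separation(self):
        res = roc(_records([2, 3, 4], [0.1, 0.2, 0.3]))
        assert res.auc == pytest.approx(1.0)
        assert res.sens_at_cutoff == 1.0 and res.spec_at_cutoff == 1.0
        assert 0.3 < res.best_cutoff < 2.0

    def test_indistinguishable_classes(self):
        res = roc(_records([1, 2, 3], [1, 2, 3]))
        assert res.auc == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc([DeltaRecord(label="x", group="GF", delta_b_ct=1.0)])

    def test_rank_auc_equals_trapezoid_auc(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            pos = np.round(np.abs(rng.normal(1.0, 1.0, 15)), 1)
            neg = np.round(np.abs(rng.normal(0.3, 0.4, 25)), 1)
            res = roc(_records(list(pos), list(neg)))
            y = np.r_[np.ones(15), np.zeros(25)]
            scores = np.r_[pos, neg]
            assert res.auc == pytest.approx(roc_auc_score(y, scores), abs=1e-12)

    def test_ci_brackets_auc(self):
        res = roc(_records([0.5, 2, 3, 0.1], [0.1, 0.2, 0.6, 0.05]))
        lo, hi = res.auc_ci_95
        assert 0.0 <= lo <= res.auc <= hi <= 1.0

    def test_counts_sum_to_sample_size(self):
        recs = _records([0.5, 2, 3], [0.1, 0.2, 0.6, 0.05])
        res = roc(recs)
        assert sum(res.counts.values()) == len(recs)


class TestReportedData:
    def test_reference_set_composition(self):
        records = load_reported_deltas()
        assert len(records) == 83
        groups = [r.group for r in records]
        assert groups.count("GF") == 30 and groups.count("CONTROL") == 53
        subs = [r.subgroup for r in records]
        assert subs.count("IEM") == 20 and subs.count("SFN") == 5
        assert subs.count("PEPD") == 5
        assert subs.count("nABN") == 4 and subs.count("hSNP") == 49

    def test_named_records(self):
        by_label = {r.label: r for r in load_reported_deltas()}
        i848t = by_label["I848T"]
        assert i848t.delta_b_ct == pytest.approx(-5.83)
        assert (i848t.group, i848t.subgroup) == ("GF", "IEM")
        i1399d = by_label["I1399D"]
        assert i1399d.delta_b_ct == pytest.approx(-1.63)
        assert (i1399d.group, i1399d.subgroup) == ("CONTROL", "hSNP")

    def test_checksum_guard(self, monkeypatch):
        import rinvar.delta_classifier as mod

        monkeypatch.setattr(mod, "_REPORTED_SHA256", "0" * 64)
        with pytest.raises(DataIntegrityError):
            load_reported_deltas()

    def test_confusion_counts_at_published_cutoff(self):
        counts = confusion_counts(load_reported_deltas(), 0.26)
        assert counts == {"tp": 23, "fp": 9, "tn": 44, "fn": 7}
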