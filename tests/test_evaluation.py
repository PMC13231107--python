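"""Multilabel counting, micro/macro averaging, cluster bootstrap, and
Krippendorff's alpha."""

import random
from collections import Counter

import numpy as np
import pytest

from sdohkit.evaluation import (
    LabelCounts,
    cluster_bootstrap_ci,
    count_errors,
    evaluate_predictions,
    krippendorff_alpha,
    macro_prf,
    micro_f1_metric,
    micro_prf,
    report,
)
from sdohkit.schema import GoldAnnotation, LabelSet


def _gold(sid, doms=(), subs=()):
    return GoldAnnotation(sid, LabelSet.of(doms or ("none of the above",),
                                           subs or ("N/A",)))


class TestCountErrors:
    def test_exact_match_counts_tp(self, tax):
        gold = [_gold("s1", subs=["homelessness"])]
        pred = [("s1", LabelSet.of((), {"homelessness"}))]
        counts = count_errors(gold, pred, tax, "subcategory")
        assert counts.counts["homelessness"] == (1, 0, 0)

    def test_gold_sentinel_yields_fp_only(self, tax):
        """A gold 'N/A' contributes no TP or FN for any positive label."""
        gold = [_gold("s1")]  # sentinel-only gold
        pred = [("s1", LabelSet.of((), {"homelessness"}))]
        counts = count_errors(gold, pred, tax, "subcategory")
        assert counts.counts["homelessness"] == (0, 1, 0)
        assert counts.totals() == (0, 1, 0)

    def test_unmatched_segment_id_rejected(self, tax):
        with pytest.raises(ValueError, match="unknown segment"):
            count_errors([_gold("s1")], [("sX", LabelSet.of((), ("N/A",)))],
                         tax, "subcategory")

    def test_matches_brute_force_per_label_oracle(self, tax):
        """50 random multilabel segments vs exhaustive set comparison."""
        rng = random.Random(3)
        subs = list(tax.subcategories)
        gold, pred = [], []
        for i in range(50):
            g = set(rng.sample(subs, rng.randint(0, 3)))
            p = set(rng.sample(subs, rng.randint(0, 3)))
            gold.append(_gold(f"s{i}", subs=g or None))
            pred.append((f"s{i}", LabelSet.of((), p or {"N/A"})))
        counts = count_errors(gold, pred, tax, "subcategory")
        oracle = Counter()
        for g_ann, (_, p_ls) in zip(gold, pred):
            g = g_ann.label_set.positive_subcategories(tax)
            p = p_ls.positive_subcategories(tax)
            for lbl in subs:
                if lbl in g and lbl in p:
                    oracle[lbl, "tp"] += 1
                elif lbl in p:
                    oracle[lbl, "fp"] += 1
                elif lbl in g:
                    oracle[lbl, "fn"] += 1
        for lbl, (tp, fp, fn) in counts.counts.items():
            assert (tp, fp, fn) == (
                oracle[lbl, "tp"], oracle[lbl, "fp"], oracle[lbl, "fn"]
            )

    def test_tp_plus_fn_equals_gold_positive_count(self, tax):
        """Count conservation: per label TP+FN equals the number of gold
        positives regardless of the predictions."""
        rng = random.Random(9)
        subs = list(tax.subcategories)
        gold = [
            _gold(f"s{i}", subs=set(rng.sample(subs, rng.randint(0, 3))) or None)
            for i in range(40)
        ]
        gold_pos = Counter(
            lbl for g in gold for lbl in g.label_set.positive_subcategories(tax)
        )
        for trial in range(5):
            pred = [
                (f"s{i}",
                 LabelSet.of((), set(rng.sample(subs, rng.randint(0, 3))) or {"N/A"}))
                for i in range(40)
            ]
            counts = count_errors(gold, pred, tax, "subcategory")
            for lbl, n in gold_pos.items():
                tp, _, fn = counts.counts.get(lbl, (0, 0, 0))
                assert tp + fn == n


class TestAverages:
    def test_micro_zero_convention(self):
        assert micro_prf(LabelCounts("subcategory", {})) == (0.0, 0.0, 0.0)

    def test_micro_f1_is_harmonic_mean(self):
        counts = LabelCounts("subcategory", {"a": (10, 3, 7), "b": (5, 2, 1)})
        p, r, f = micro_prf(counts)
        assert f == pytest.approx(2 * p * r / (p + r))

    def test_single_label_macro_equals_micro(self):
        counts = LabelCounts("subcategory", {"a": (8, 2, 4)})
        assert macro_prf(counts) == pytest.approx(micro_prf(counts))

    def test_macro_is_unweighted_mean(self):
        counts = LabelCounts("subcategory", {"a": (5, 0, 0), "b": (0, 3, 3)})
        assert macro_prf(counts) == pytest.approx((0.5, 0.5, 0.5))

    def test_macro_matches_per_label_hand_computation(self):
        rng = random.Random(21)
        counts = {
            f"l{i}": (rng.randint(0, 9), rng.randint(0, 9), rng.randint(0, 9))
            for i in range(5)
        }
        got = macro_prf(LabelCounts("subcategory", counts))
        ps, rs, fs = [], [], []
        for tp, fp, fn in counts.values():
            if tp + fp + fn == 0:
                continue
            p = tp / (tp + fp) if tp + fp else 0.0
            r = tp / (tp + fn) if tp + fn else 0.0
            ps.append(p)
            rs.append(r)
            fs.append(2 * p * r / (p + r) if p + r else 0.0)
        assert got == pytest.approx(
            (np.mean(ps), np.mean(rs), np.mean(fs))
        )

    def test_macro_with_no_eligible_labels_errors(self):
        with pytest.raises(ValueError):
            macro_prf(LabelCounts("subcategory", {}))


def _clustered_fixture(tax, n_patients, frac_correct, segs_per_patient=1):
    """Each patient's segments are all correct or all wrong, so the
    bootstrap metric distribution has a known binomial form."""
    gold, pred, patient_of = [], [], {}
    n_correct = round(n_patients * frac_correct)
    for i in range(n_patients):
        for j in range(segs_per_patient):
            sid = f"p{i}:s{j}"
            gold.append(_gold(sid, subs=["homelessness"]))
            if i < n_correct:
                pred.append((sid, LabelSet.of((), {"homelessness"})))
            else:
                pred.append((sid, LabelSet.of((), {"N/A"})))
            patient_of[sid] = f"p{i}"
    return gold, pred, patient_of


def _recall_metric(tax):
    def fn(gold, pred):
        tp = fn_ = 0
        for g, p in zip(gold, pred, strict=True):
            g_subs = g.label_set.positive_subcategories(tax)
            p_subs = p.positive_subcategories(tax)
            tp += len(g_subs & p_subs)
            fn_ += len(g_subs - p_subs)
        return tp / (tp + fn_) if tp + fn_ else 0.0

    return fn


class TestClusterBootstrap:
    def test_constant_metric_gives_degenerate_ci(self, tax):
        gold, pred, patient_of = _clustered_fixture(tax, 10, 1.0)
        lo, hi = cluster_bootstrap_ci(
            micro_f1_metric(tax, "subcategory"), gold, pred, patient_of,
            n_boot=200, seed=0,
        )
        assert lo == hi == 1.0

    def test_fixed_seed_reproducible(self, tax):
        gold, pred, patient_of = _clustered_fixture(tax, 20, 0.6)
        fn = micro_f1_metric(tax, "subcategory")
        a = cluster_bootstrap_ci(fn, gold, pred, patient_of, n_boot=300, seed=42)
        b = cluster_bootstrap_ci(fn, gold, pred, patient_of, n_boot=300, seed=42)
        assert a == b

    def test_matches_analytic_binomial_percentiles(self, tax):
        """With one segment per patient and all-or-nothing correctness,
        the replicate recall is X/N with X ~ Binomial(N, m/N); the
        bootstrap percentiles must sit on the analytic quantiles within
        Monte-Carlo tolerance."""
        from scipy import stats

        n, frac = 40, 0.7
        gold, pred, patient_of = _clustered_fixture(tax, n, frac)
        lo, hi = cluster_bootstrap_ci(
            _recall_metric(tax), gold, pred, patient_of, n_boot=2000, seed=7
        )
        a_lo = stats.binom.ppf(0.025, n, frac) / n
        a_hi = stats.binom.ppf(0.975, n, frac) / n
        assert lo == pytest.approx(a_lo, abs=1.5 / n)
        assert hi == pytest.approx(a_hi, abs=1.5 / n)

    def test_ci_width_shrinks_with_more_patients(self, tax):
        fn = _recall_metric(tax)
        widths = []
        for n in (20, 200):
            gold, pred, patient_of = _clustered_fixture(tax, n, 0.7)
            lo, hi = cluster_bootstrap_ci(fn, gold, pred, patient_of,
                                          n_boot=500, seed=1)
            widths.append(hi - lo)
        assert widths[1] < widths[0]


class TestKrippendorffAlpha:
    SPACE = ("A", "B", "C")

    def test_perfect_agreement_is_one(self):
        units = []
        for u in range(5):
            labels = {"A"} if u % 2 else {"B", "C"}
            units.append((f"u{u}", "coder1", labels))
            units.append((f"u{u}", "coder2", labels))
        assert krippendorff_alpha(units, self.SPACE) == pytest.approx(1.0)

    def test_hand_computed_coincidence_example(self):
        """Two coders, 4 units, one binary decision each, one disagreement:
        the pooled coincidence matrix gives alpha = 8/15 (worked by hand)."""
        units = [
            ("u1", "c1", {"A"}), ("u1", "c2", {"A"}),
            ("u2", "c1", {"A"}), ("u2", "c2", {"A"}),
            ("u3", "c1", set()), ("u3", "c2", set()),
            ("u4", "c1", set()), ("u4", "c2", {"A"}),
        ]
        assert krippendorff_alpha(units, ("A",)) == pytest.approx(8 / 15)

    def test_complementary_coding_goes_negative(self):
        units = []
        for u in range(6):
            units.append((f"u{u}", "c1", {"A"}))
            units.append((f"u{u}", "c2", {"B"}))
        assert krippendorff_alpha(units, ("A", "B")) < 0

    def test_matches_from_scratch_oracle_on_randomized_sets(self):
        """>= 20 randomized annotation sets vs an independent pairwise
        disagreement computation."""
        rng = random.Random(17)
        for trial in range(25):
            n_units = rng.randint(3, 8)
            n_coders = rng.randint(2, 4)
            units = []
            for u in range(n_units):
                for c in range(n_coders):
                    if rng.random() < 0.15:
                        continue  # some units not coded by everyone
                    labels = set(rng.sample(self.SPACE, rng.randint(0, 2)))
                    units.append((f"u{u}", f"c{c}", labels))
            try:
                got = krippendorff_alpha(units, self.SPACE)
            except ValueError:
                continue  # no co-coded unit this trial
            expect = self._oracle(units, self.SPACE)
            if expect is None:
                continue
            assert got == pytest.approx(expect, abs=1e-12)

    @staticmethod
    def _oracle(units, space):
        by_unit = {}
        for uid, coder, labels in units:
            by_unit.setdefault(uid, {})[coder] = set(labels)
        pseudo = []
        for coder_sets in by_unit.values():
            if len(coder_sets) < 2:
                continue
            decisions = list(coder_sets.values())
            for lbl in space:
                pseudo.append([int(lbl in d) for d in decisions])
        n = sum(len(p) for p in pseudo)
        d_o = sum(
            sum(vi != vj for i, vi in enumerate(p) for j, vj in enumerate(p) if i != j)
            / (len(p) - 1)
            for p in pseudo
        ) / n
        cnt = Counter(v for p in pseudo for v in p)
        d_e = sum(cnt[a] * cnt[b] for a in cnt for b in cnt if a != b) / (n * (n - 1))
        if d_e == 0:
            return None
        return 1 - d_o / d_e

    def test_invariant_to_coder_relabeling_and_unit_order(self):
        rng = random.Random(2)
        units = [
            (f"u{u}", f"c{c}", set(rng.sample(self.SPACE, rng.randint(0, 2))))
            for u in range(6) for c in range(3)
        ]
        base = krippendorff_alpha(units, self.SPACE)
        renamed = [(u, {"c0": "x", "c1": "y", "c2": "z"}[c], l) for u, c, l in units]
        rng.shuffle(renamed)
        assert krippendorff_alpha(renamed, self.SPACE) == pytest.approx(base)

    def test_single_coder_rejected(self):
        with pytest.raises(ValueError):
            krippendorff_alpha([("u1", "c1", {"A"})], self.SPACE)


class TestReport:
    def _reports(self, tax):
        gold = [_gold("s1", subs=["homelessness"]), _gold("s2", subs=["job loss"])]
        good = [("s1", LabelSet.of((), {"homelessness"})),
                ("s2", LabelSet.of((), {"job loss"}))]
        bad = [("s1", LabelSet.of((), {"N/A"})),
               ("s2", LabelSet.of((), {"job loss"}))]
        return {
            "good": evaluate_predictions(gold, good, tax, "subcategory"),
            "bad": evaluate_predictions(gold, bad, tax, "subcategory"),
        }

    def test_rows_sorted_by_f1_descending(self, tax, tmp_path):
        df = report(self._reports(tax), tmp_path / "r.csv")
        assert list(df["system"]) == ["good", "bad"]
        assert df["micro_f1"].is_monotonic_decreasing

    def test_csv_round_trip(self, tax, tmp_path):
        import pandas as pd

        path = tmp_path / "r.csv"
        df = report(self._reports(tax), path)
        back = pd.read_csv(path)
        pd.testing.assert_frame_equal(back, df)
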