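import numpy as np
import pytest

from trophicsw.metrics import TopologySummary, summarize
from trophicsw.null_ensemble import EnsembleSummary, ensemble_metrics, generate_er
from trophicsw.sw_test import (
    classify_conf,
    compare_methods,
    evaluate,
    small_world_ness,
)


def _summary(S=10, L=40, CPL=2.0, CC=0.3, degrees=None, name="web"):
    if degrees is None:
        # any sequence with the right handshake sum; E = L here (projection edges)
        degrees = tuple([2 * L // S] * S)
    return TopologySummary(
        name=name, S=S, L=L, C=L / S**2, CPL=CPL, CC=CC,
        degrees=degrees, n_unreachable_pairs=0,
    )


def _ens(metric, values, S=10, L=40, level=0.99):
    values = np.asarray(values, dtype=float)
    lo, hi = np.quantile(values, [(1 - level) / 2, 1 - (1 - level) / 2])
    return EnsembleSummary(
        metric_name=metric, replicates=values, mean=float(values.mean()),
        ci_low=float(lo), ci_high=float(hi), n_rep=len(values), seed=0,
        S=S, L=L, level=level,
    )


class TestClassifyConf:
    def test_low_cpl_high_cc_is_small_world(self):
        cpl_ens = _ens("CPL", np.linspace(2.4, 2.6, 100))
        cc_ens = _ens("CC", np.linspace(0.05, 0.15, 100))
        v = classify_conf(_summary(CPL=2.0, CC=0.3), cpl_ens, cc_ens)
        assert v.cpl_ok and v.cc_ok and v.is_small_world_conf

    def test_cc_inside_interval_fails(self):
        cpl_ens = _ens("CPL", np.linspace(2.4, 2.6, 100))
        cc_ens = _ens("CC", np.linspace(0.05, 0.40, 100))
        v = classify_conf(_summary(CPL=2.0, CC=0.3), cpl_ens, cc_ens)
        assert not v.cc_ok and not v.is_small_world_conf

    def test_cpl_within_interval_counts_as_ok(self):
        # "within or to the left" of the interval: non-strict at the upper bound
        cpl_ens = _ens("CPL", np.linspace(1.9, 2.1, 100))
        cc_ens = _ens("CC", np.linspace(0.05, 0.15, 100))
        v = classify_conf(_summary(CPL=2.0, CC=0.3), cpl_ens, cc_ens)
        assert v.cpl_ok

    def test_mismatched_sizes_rejected(self):
        cpl_ens = _ens("CPL", np.linspace(2, 3, 50), S=99)
        cc_ens = _ens("CC", np.linspace(0.1, 0.2, 50), S=99)
        with pytest.raises(ValueError, match="does not match"):
            classify_conf(_summary(S=10), cpl_ens, cc_ens)

    def test_monotone_in_empirical_values(self):
        cpl_ens = _ens("CPL", np.linspace(2.4, 2.6, 200))
        cc_ens = _ens("CC", np.linspace(0.05, 0.15, 200))
        prev_cc_ok = True
        for cc in np.linspace(0.5, 0.01, 20):
            ok = classify_conf(_summary(CC=float(cc)), cpl_ens, cc_ens).cc_ok
            assert prev_cc_ok or not ok  # once false, stays false as CC decreases
            prev_cc_ok = ok
        prev_cpl_ok = True
        for cpl in np.linspace(1.5, 4.0, 20):
            ok = classify_conf(_summary(CPL=float(cpl)), cpl_ens, cc_ens).cpl_ok
            assert prev_cpl_ok or not ok
            prev_cpl_ok = ok


class TestSmallWorldNess:
    def test_equal_ratios_give_unity(self):
        cpl_ens = _ens("CPL", np.full(100, 2.0) + np.linspace(-0.01, 0.01, 100))
        cc_ens = _ens("CC", np.full(100, 0.1) + np.linspace(-0.001, 0.001, 100))
        v = small_world_ness(_summary(CPL=4.0, CC=0.2), cpl_ens, cc_ens)
        assert v.sws == pytest.approx(1.0, abs=1e-12)

    def test_printed_ratio_pair_reproduces_sws(self):
        # gamma/lambda for ratios 1.35 and 0.98 (the Gulf of Lions coordinates)
        cpl_ens = _ens("CPL", np.linspace(1.9, 2.1, 100))
        cc_ens = _ens("CC", np.linspace(0.09, 0.11, 100))
        summary = _summary(CPL=0.98 * cpl_ens.mean, CC=1.35 * cc_ens.mean)
        v = small_world_ness(summary, cpl_ens, cc_ens)
        assert v.sws == pytest.approx(1.35 / 0.98, rel=1e-9)
        assert v.sws == pytest.approx(1.3776, abs=5e-4)

    def test_er_graph_scored_against_own_ensemble_is_near_unity(self):
        """Self-consistency: an ER graph's S^ws against its own matched ensemble
        averages ~1 over repeated trials."""
        from trophicsw.metrics import characteristic_path_length, clustering_coefficient

        S, L = 60, 240
        values = []
        for trial in range(30):
            g = generate_er(S, L, seed=1000 + trial)
            cpl, _ = characteristic_path_length(g)
            cc = clustering_coefficient(g)
            cpl_ens, cc_ens = ensemble_metrics(S, L, n_rep=100, seed=trial)
            summary = _summary(S=S, L=L, CPL=cpl, CC=cc)
            values.append(small_world_ness(summary, cpl_ens, cc_ens).sws)
        assert np.mean(values) == pytest.approx(1.0, abs=0.05)

    def test_zero_mean_cc_rejected(self):
        cpl_ens = _ens("CPL", np.linspace(2, 3, 50))
        cc_ens = _ens("CC", np.zeros(50))
        with pytest.raises(ValueError, match="positive"):
            small_world_ness(_summary(), cpl_ens, cc_ens)


class TestCompareMethods:
    def _verdict(self, name, conf, sws_flag):
        from trophicsw.sw_test import SWVerdict

        return SWVerdict(
            name=name, cpl_ratio=1.0, cc_ratio=1.0,
            cpl_ok=conf, cc_ok=conf, is_small_world_conf=conf,
            sws=2.0 if sws_flag else 0.5, sws_ci_high=1.0,
            is_small_world_sws=sws_flag,
        )

    def test_all_negative(self):
        out = compare_methods([self._verdict("a", False, False)] * 3)
        assert out["n_sw_conf"] == 0 and out["n_sw_sws"] == 0
        assert out["disagreements"] == []

    def test_single_disagreement_listed(self):
        out = compare_methods(
            [self._verdict("a", False, True), self._verdict("b", True, True)]
        )
        assert out["disagreements"] == ["a"]
        assert out["n_sw_conf"] == 1 and out["n_sw_sws"] == 2

    def test_counts_match_table(self):
        verdicts = [
            self._verdict(f"w{i}", i % 2 == 0, i % 3 == 0) for i in range(9)
        ]
        out = compare_methods(verdicts)
        assert out["n_sw_conf"] == out["table"]["SW_conf"].sum()
        assert out["n_sw_sws"] == out["table"]["SW_sws"].sum()


def test_evaluate_merges_both_criteria(k5_directed):
    summary = summarize(k5_directed)
    cpl_ens, cc_ens = ensemble_metrics(5, 10, n_rep=20, seed=0)
    v = evaluate(summary, cpl_ens, cc_ens)
    # complete graph against forced-complete ensemble: identical, so not SW
    assert v.cpl_ok and not v.cc_ok and not v.is_small_world_conf
    assert v.sws == 1.0 and not v.is_small_world_sws
    assert v.is_small_world_conf == (v.cpl_ok and v.cc_ok)
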