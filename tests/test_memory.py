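"""Echo/intensity retrieval, model-variant trial loops, criterion, scoring."""

import numpy as np
import pytest

from hemagl import engine
from hemagl.encoding import SequenceItem, Trace, encode_trace
from hemagl.hrr import cosine, dirconv, make_lexicon
from hemagl.memory import (
    MemoryStore,
    ModelConfig,
    echo_intensity,
    run_participant,
    score,
    set_criterion,
)


def oracle_echo_intensity(probe, traces, exponent=3):
    """Explicit-loop recomputation of activation, echo and intensity."""
    echo = np.zeros_like(probe, dtype=float)
    for tr in traces:
        a = cosine(probe, tr) ** exponent
        echo = echo + a * tr
    return cosine(echo, probe)


def store_of(vectors):
    ms = MemoryStore()
    for i, v in enumerate(vectors):
        ms.add(Trace(values=np.asarray(v, float), source=str(i),
                     L_applied=1.0, components_used=()))
    return ms


class TestEchoIntensity:
    def test_probe_identical_to_single_trace(self, rng):
        v = rng.normal(size=40)
        assert echo_intensity(v, store_of([v])) == pytest.approx(1.0)

    def test_matches_loop_oracle(self, rng):
        traces = [rng.normal(size=60) for _ in range(15)]
        probe = rng.normal(size=60)
        got = echo_intensity(probe, store_of(traces))
        want = oracle_echo_intensity(probe, traces)
        assert got == pytest.approx(want, abs=1e-10)

    def test_batch_matches_loop_oracle(self, rng):
        P, M, n = 7, 12, 50
        mem = rng.normal(size=(P, M, n))
        probe = rng.normal(size=(P, n))
        got = engine._batch_echo_intensity(
            probe, mem, np.linalg.norm(mem, axis=2), exponent=3
        )
        for p in range(P):
            want = oracle_echo_intensity(probe[p], list(mem[p]))
            assert got[p] == pytest.approx(want, abs=1e-10)

    def test_stored_probes_outscore_unrelated_probes(self):
        # The echo is tilted toward any probe by construction (activation
        # carries the sign of similarity), so even an unrelated probe has a
        # positive expected intensity; what matters for classification is
        # that probes resembling memory score reliably higher.
        rng = np.random.default_rng(11)
        stored, unrelated = [], []
        for _ in range(200):
            traces = [rng.normal(size=100) for _ in range(20)]
            ms = store_of(traces)
            noisy = traces[0] + 0.5 * rng.normal(size=100)
            stored.append(echo_intensity(noisy, ms))
            unrelated.append(echo_intensity(rng.normal(size=100), ms))
        stored, unrelated = np.array(stored), np.array(unrelated)
        se = np.hypot(stored.std(ddof=1), unrelated.std(ddof=1)) / np.sqrt(200)
        assert stored.mean() - unrelated.mean() > 3 * se

    def test_empty_memory_rejected(self, rng):
        with pytest.raises(ValueError):
            echo_intensity(rng.normal(size=10), MemoryStore())

    def test_zero_probe_intensity_zero(self, rng):
        assert echo_intensity(np.zeros(20), store_of([rng.normal(size=20)])) == 0.0


class TestEngineComponentMatrix:
    def test_matches_dirconv_of_lexicon_vectors(self, rng):
        """The batched bigram matrix equals dirconv on a matching lexicon."""
        from hemagl.hrr import Lexicon

        P, S, n = 3, 4, 32
        base = rng.normal(size=(P, S, n))
        pl = np.argsort(rng.random((P, n)), axis=1)
        pr = np.argsort(rng.random((P, n)), axis=1)
        defs = np.array([[0, 1], [2, 3], [1, 1]])
        got = engine._component_matrix(base, pl, pr, defs)
        for p in range(P):
            lex = Lexicon(symbols=("a", "b", "c", "d"), vectors=base[p],
                          left_perm=pl[p], right_perm=pr[p], n=n, sd=1 / n)
            for ci, (i, j) in enumerate(defs):
                want = dirconv(base[p, i], base[p, j], lex)
                np.testing.assert_allclose(got[p, ci], want, atol=1e-12)


class TestSetCriterion:
    def test_saturation_and_floor(self, rng):
        x = list(rng.normal(size=10))
        _, all_in = set_criterion(x, 1.0)
        assert all(all_in)
        _, none_in = set_criterion(x, 0.0)
        assert not any(none_in)

    def test_half_rate_on_distinct_intensities(self, rng):
        x = list(rng.permutation(32) / 32)
        k, endorsed = set_criterion(x, 0.5)
        assert sum(endorsed) == 16
        assert all(x[i] >= k for i, e in enumerate(endorsed) if e)
        assert all(x[i] < k for i, e in enumerate(endorsed) if not e)

    def test_ties_broken_by_presentation_order(self):
        k, endorsed = set_criterion([0.5, 0.5, 0.5, 0.1], 0.5)
        assert endorsed == [True, True, False, False]
        assert k == 0.5

    def test_endorsed_proportion_within_half_item(self):
        rng = np.random.default_rng(21)
        for _ in range(200):
            n = int(rng.integers(2, 60))
            rate = float(rng.random())
            x = list(rng.normal(size=n))
            _, endorsed = set_criterion(x, rate)
            assert abs(sum(endorsed) / n - rate) <= 1 / (2 * n) + 1e-12

    def test_bad_rate_rejected(self):
        with pytest.raises(ValueError):
            set_criterion([0.1, 0.2], 1.5)
        with pytest.raises(ValueError):
            set_criterion([], 0.5)


class TestScore:
    def test_saturation_gives_zero_discrimination(self):
        h, fa, d = score([True] * 4, ["grammatical", "ungrammatical"] * 2)
        assert (h, fa, d) == (1.0, 1.0, 0.0)

    def test_perfect_separation(self):
        h, fa, d = score(
            [True, True, False, False],
            ["grammatical", "grammatical", "ungrammatical", "ungrammatical"],
        )
        assert (h, fa, d) == (1.0, 0.0, 1.0)

    def test_hand_enumeration(self):
        # intensities [.9,.8,.3,.1], labels G,U,G,U, rate .5 -> endorse top 2
        labels = ["grammatical", "ungrammatical"] * 2
        _, endorsed = set_criterion([0.9, 0.8, 0.3, 0.1], 0.5)
        h, fa, d = score(endorsed, labels)
        assert (h, fa, d) == (0.5, 0.5, 0.0)

    def test_missing_class_rejected(self):
        with pytest.raises(ValueError):
            score([True, False], ["grammatical", "grammatical"])


def _config(variant, **kw):
    defaults = dict(L_train=0.8, L_test=0.8, g=3, q=2, seed=0)
    defaults.update(kw)
    return ModelConfig(variant=variant, **defaults)


class TestRunParticipant:
    def test_memory_growth_by_variant(self, item_sets):
        items = item_sets["standard"]
        train, test = list(items.train), list(items.test)
        for variant, extra in [("HEM-C", 0), ("HEM-TC", len(test)),
                               ("HEM-T", len(test))]:
            res = run_participant(variant, train, test, _config(variant),
                                  endorsement_rate=0.5,
                                  rng=np.random.default_rng(0))
            assert res.n_stored == len(train) + extra

    def test_variants_collapse_at_full_test_rate(self, item_sets):
        """With L_test=1 HEM-TC and HEM-T are identical draw for draw."""
        items = item_sets["standard"]
        train, test = list(items.train), list(items.test)
        for seed in range(5):
            cfg = _config("HEM-TC", L_test=1.0, seed=seed)
            a = run_participant("HEM-TC", train, test, cfg, 0.5,
                                rng=np.random.default_rng(seed))
            b = run_participant("HEM-T", train, test, cfg, 0.5,
                                rng=np.random.default_rng(seed))
            assert a.intensities == b.intensities

    def test_unknown_variant_rejected(self, item_sets):
        items = item_sets["standard"]
        with pytest.raises(ValueError):
            run_participant("HEM-X", list(items.train), list(items.test),
                            _config("HEM-TC"), 0.5)

    def test_diff_consistent_with_scoring(self, item_sets):
        items = item_sets["standard"]
        res = run_participant("HEM-TC", list(items.train), list(items.test),
                              _config("HEM-TC"), 0.5,
                              rng=np.random.default_rng(3))
        labels = [it.label for it in items.test]
        h, fa, d = score(list(res.endorsements), labels)
        assert (res.hit_rate, res.fa_rate, res.diff) == (h, fa, d)


class TestVariantSemantics:
    def test_hem_c_memory_is_static_during_test(self, item_sets):
        """HEM-C intensities are fully determined by the training memory."""
        items = item_sets["standard"]
        compiled = engine.compile_materials(
            list(items.train), list(items.test), "bigram"
        )
        out = engine.simulate_participants(
            compiled, "HEM-C", L_train=0.8, L_test=0.8, g=3, rate=0.5,
            n_participants=2, keep_arrays=True, rng=np.random.default_rng(8),
        )
        assert out["n_stored"] == compiled.n_train
        mem = out["memory"]
        for p in range(2):
            for t in range(compiled.n_test):
                want = oracle_echo_intensity(out["probes"][p, t], list(mem[p]))
                assert out["intensities"][p, t] == pytest.approx(want, abs=1e-10)

    def test_hem_tc_intensities_depend_on_stored_test_items(self, item_sets):
        """Recomputing HEM-TC intensities against the training memory alone
        must disagree for late test items: memory grows during test."""
        items = item_sets["standard"]
        compiled = engine.compile_materials(
            list(items.train), list(items.test), "bigram"
        )
        out = engine.simulate_participants(
            compiled, "HEM-TC", L_train=0.8, L_test=0.8, g=3, rate=0.5,
            n_participants=1, keep_arrays=True, rng=np.random.default_rng(8),
        )
        train_mem = list(out["memory"][0, : compiled.n_train])
        last = compiled.n_test - 1
        static = oracle_echo_intensity(out["probes"][0, last], train_mem)
        assert out["intensities"][0, last] != pytest.approx(static, abs=1e-10)

    def test_learning_rate_increases_discrimination_without_test_learning(
        self, item_sets
    ):
        """Mean H-Fa under HEM-C rises with the training learning rate."""
        from scipy import stats

        items = item_sets["standard"]
        compiled = engine.compile_materials(
            list(items.train), list(items.test), "bigram"
        )
        diffs = {}
        for L in (0.1, 0.9):
            out = engine.simulate_participants(
                compiled, "HEM-C", L_train=L, L_test=1.0, g=3, rate=0.5,
                n_participants=200, rng=np.random.default_rng(int(L * 10)),
            )
            diffs[L] = out["diff"]
        t = stats.ttest_ind(diffs[0.9], diffs[0.1], alternative="greater")
        assert t.pvalue < 0.01


def test_results_export_as_rows(item_sets):
    from hemagl.memory import results_to_frame

    items = item_sets["standard"]
    cfg = _config("HEM-C")
    results = [
        run_participant("HEM-C", list(items.train), list(items.test), cfg,
                        0.5, rng=np.random.default_rng(i))
        for i in range(3)
    ]
    df = results_to_frame(results, "dual_train")
    assert list(df.columns) == ["participant", "condition", "hit_rate",
                                "fa_rate", "diff"]
    assert len(df) == 3
    assert (df["diff"] == df["hit_rate"] - df["fa_rate"]).all()


def test_model_config_validation():
    with pytest.raises(ValueError):
        ModelConfig(variant="HEM-Z", L_train=0.5, L_test=0.5, g=2)
    with pytest.raises(ValueError):
        ModelConfig(variant="HEM-TC", L_train=1.5, L_test=0.5, g=2)
    with pytest.raises(ValueError):
        ModelConfig(variant="HEM-TC", L_train=0.5, L_test=0.5, g=2,
                    activation_exponent=2)
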