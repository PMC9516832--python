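"""The funnel: per-stage filters, intDiv, desirability reporting and
benchmark assembly."""
import numpy as np
import pandas as pd
import pytest
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator

from molbias import SamplingConfig
from molbias.corpus import Corpus
from molbias.metrics import (
    desirability,
    internal_diversity,
    novelty_filter,
    run_benchmark,
    run_funnel,
    temperature_sweep,
    uniqueness_filter,
    validity_filter,
)
from molbias.objectives import Objective, compute_descriptors

ALWAYS = Objective("always", lambda d: True)
NEVER = Objective("never", lambda d: False)


class TestValidity:
    def test_one_malformed_string(self):
        frac, valid = validity_filter(["CCO", "C(", "c1ccccc1"])
        assert frac == pytest.approx(2 / 3)
        assert len(valid) == 2

    def test_all_valid_fixture(self, tiny_corpus):
        frac, _ = validity_filter(tiny_corpus.raw_strings)
        assert frac == 1.0

    def test_empty_input_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            frac, valid = validity_filter([])
        assert frac == 0.0 and valid == []

    def test_matches_per_string_parse_recount(self):
        rng = np.random.default_rng(0)
        alphabet = list("CCONc1()=#")
        strings = [
            "".join(rng.choice(alphabet, size=rng.integers(1, 15)))
            for _ in range(300)
        ]
        frac, _ = validity_filter(strings)
        recount = sum(Chem.MolFromSmiles(s) is not None for s in strings)
        assert frac == pytest.approx(recount / 300)


class TestNovelty:
    def test_subset_of_training_is_not_novel(self, tiny_corpus):
        frac, novel = novelty_filter(
            [r.canonical for r in tiny_corpus.records[:10]], tiny_corpus
        )
        assert frac == 0.0 and novel == []

    def test_disjoint_sets_fully_novel(self, tiny_corpus):
        frac, _ = novelty_filter(["C#CCCCCCCC#C"], tiny_corpus)
        assert frac == 1.0

    def test_canonical_equivalence_detected(self):
        training = Corpus.from_smiles(["CCO"])
        _, valid = validity_filter(["OCC"])
        frac, _ = novelty_filter(valid, training)
        assert frac == 0.0


class TestUniqueness:
    def test_duplicate_elimination(self):
        frac, unique = uniqueness_filter(["CCO", "CCO", "CCN"])
        assert frac == pytest.approx(2 / 3)
        assert unique == ["CCO", "CCN"]

    def test_all_distinct(self):
        frac, _ = uniqueness_filter(["CCO", "CCN", "CCC"])
        assert frac == 1.0

    def test_resulting_set_order_invariant(self):
        a = set(uniqueness_filter(["CCO", "CCN", "CCO"])[1])
        b = set(uniqueness_filter(["CCN", "CCO", "CCO"])[1])
        assert a == b


class TestInternalDiversity:
    def test_identical_molecules_give_zero(self):
        assert internal_diversity(["CCO"] * 5) == pytest.approx(0.0, abs=1e-12)

    def test_singleton_gives_zero(self):
        assert internal_diversity(["CCO"]) == pytest.approx(0.0, abs=1e-12)

    def test_matches_double_loop_oracle(self, tiny_corpus):
        mols = [r.canonical for r in tiny_corpus.records[:20]]
        value = internal_diversity(mols)
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=1024)
        fps = [gen.GetFingerprint(Chem.MolFromSmiles(s)) for s in mols]
        total = 0.0
        for fa in fps:
            for fb in fps:
                total += DataStructs.TanimotoSimilarity(fa, fb)
        assert value == pytest.approx(1.0 - total / 400, abs=1e-12)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            internal_diversity([])


class TestDesirability:
    def test_always_false(self):
        frac, count, passing = desirability(["CCO", "CCN"], NEVER)
        assert (frac, count, passing) == (0.0, 0, [])

    def test_percentage_and_count_both_reported(self):
        """150 unique with 15 passing -> 10 % but 15 molecules."""
        unique = ["C" * i + "O" for i in range(1, 151)]
        threshold = compute_descriptors(unique[14]).mol_weight
        light = Objective("light", lambda d: d.mol_weight <= threshold)
        frac, count, _ = desirability(unique, light)
        assert count == 15
        assert frac == pytest.approx(0.10)

    def test_count_matches_recount(self, tiny_corpus):
        mols = [r.canonical for r in tiny_corpus.records]
        no_ring = Objective("acyclic", lambda d: d.aromatic_rings + d.non_aromatic_rings == 0)
        _, count, _ = desirability(mols, no_ring)
        recount = sum(
            Chem.MolFromSmiles(s).GetRingInfo().NumRings() == 0 for s in mols
        )
        assert count == recount

    def test_percentage_can_mislead_without_count(self):
        """A 5-molecule model at 100 % desirability still loses on count to
        a 150-molecule model at 10 %."""
        small_unique = ["C" * i + "O" for i in range(1, 6)]
        frac_a, count_a, _ = desirability(small_unique, ALWAYS)
        big_unique = ["C" * i + "O" for i in range(1, 151)]
        threshold = compute_descriptors(big_unique[14]).mol_weight
        light = Objective("light", lambda d: d.mol_weight <= threshold)
        frac_b, count_b, _ = desirability(big_unique, light)
        assert frac_a > frac_b and count_a < count_b


class TestFunnel:
    def test_monotone_counts_on_adversarial_mix(self, tiny_corpus):
        generated = (
            tiny_corpus.raw_strings[:20] * 2          # training members, duplicated
            + ["C(", "xx", "c1ccc"] * 10              # malformed
            + ["C#CCCCC#C", "C#CCCCC#C", "OCC"]       # novel + duplicate
        )
        funnel = run_funnel(generated, tiny_corpus, ALWAYS)
        n, v, nov, u, d = funnel.counts()
        assert n >= v >= nov >= u >= d

    def test_fractions_relative_to_previous_stage(self, tiny_corpus):
        generated = tiny_corpus.raw_strings[:10] + ["C(", "C#CCCCC#C", "C#CCCCC#C"]
        f = run_funnel(generated, tiny_corpus, ALWAYS)
        assert f.validity == pytest.approx(len(f.valid_set) / f.n_generated)
        assert f.novelty == pytest.approx(len(f.novel_set) / len(f.valid_set))
        assert f.uniqueness == pytest.approx(len(f.unique_set) / len(f.novel_set))
        assert f.desirability_fraction == pytest.approx(
            f.desirability_count / len(f.unique_set)
        )


class TestBenchmark:
    def test_zero_samples_rejected(self, tiny_g, tiny_corpus):
        with pytest.raises(ValueError):
            run_benchmark(tiny_g, tiny_corpus, n=0)

    def test_deterministic_given_seed_list(self, tiny_g, tiny_corpus):
        a = run_benchmark(tiny_g, tiny_corpus, ALWAYS, n=100, seeds=(1, 2))
        b = run_benchmark(tiny_g, tiny_corpus, ALWAYS, n=100, seeds=(1, 2))
        pd.testing.assert_frame_equal(a.per_seed, b.per_seed)

    def test_funnel_counts_non_increasing_each_run(self, tiny_g, tiny_corpus):
        report = run_benchmark(tiny_g, tiny_corpus, ALWAYS, n=150, seeds=(3,))
        for funnel in report.funnels:
            n, v, nov, u, d = funnel.counts()
            assert n >= v >= nov >= u >= d

    def test_report_files(self, tmp_path, tiny_g, tiny_corpus):
        report = run_benchmark(tiny_g, tiny_corpus, ALWAYS, n=50, seeds=(1,))
        report.to_json(tmp_path / "report.json")
        report.to_csv(tmp_path / "report.csv")
        table = pd.read_csv(tmp_path / "report.csv")
        assert {"validity", "novelty", "uniqueness", "int_div",
                "desirability_pct", "desirability_count"} <= set(table.columns)


class TestTemperatureSweep:
    def test_single_temperature_matches_run_benchmark(self, tiny_g, tiny_corpus):
        sweep = temperature_sweep(tiny_g, tiny_corpus, temps=[1.0], n=100, seeds=(4,))
        report = run_benchmark(
            tiny_g, tiny_corpus, n=100,
            sampling=SamplingConfig(temperature=1.0), seeds=(4,),
        )
        assert sweep.validity.iloc[0] == pytest.approx(report.per_seed.validity.iloc[0])
        assert sweep.uniqueness.iloc[0] == pytest.approx(report.per_seed.uniqueness.iloc[0])

    def test_rejects_nonpositive_temperature(self, tiny_g, tiny_corpus):
        with pytest.raises(ValueError):
            temperature_sweep(tiny_g, tiny_corpus, temps=[0.5, 0.0], n=10)
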