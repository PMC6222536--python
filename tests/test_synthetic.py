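import filecmp

import numpy as np
import pytest
from scipy import stats

from cytofeat import GeneratorConfig, extract_features, gen_sequences, kfold_cv
from cytofeat._alphabet import ALPHA_ORDER
from cytofeat.errors import ValidationError
from cytofeat.synthetic import gen_dataset, gen_objects, gen_profile, gen_structure


def _dir_identical(a, b):
    cmp = filecmp.dircmp(a, b)
    if cmp.left_only or cmp.right_only or cmp.diff_files:
        return False
    (_, mismatch, errors) = filecmp.cmpfiles(a, b, cmp.common_files, shallow=False)
    if mismatch or errors:
        return False
    return all(_dir_identical(a / d, b / d) for d in cmp.common_dirs)


class TestConfig:
    def test_min_length_guard(self):
        with pytest.raises(ValidationError, match="20"):
            GeneratorConfig(min_length=10)

    def test_negative_effect_guard(self):
        with pytest.raises(ValidationError):
            GeneratorConfig(effect_size=-1)


class TestGenSequences:
    def test_counts_and_labels(self):
        pairs = gen_sequences(GeneratorConfig(n_pos=3, n_neg=27, seed=0))
        assert len(pairs) == 30
        assert sum(1 for _, lab in pairs if lab == 1) == 3

    def test_lengths_in_range(self):
        cfg = GeneratorConfig(n_pos=10, n_neg=10, min_length=25, max_length=40, seed=1)
        for seq, _ in gen_sequences(cfg):
            assert 25 <= len(seq) <= 40

    def test_null_compositions_indistinguishable(self):
        """At effect_size = 0 the pooled class compositions pass a chi-square
        two-sample test at alpha = 0.01 in nearly every seeded run."""
        rejections = 0
        runs = 40
        for seed in range(runs):
            cfg = GeneratorConfig(n_pos=30, n_neg=30, effect_size=0.0, seed=seed)
            pairs = gen_sequences(cfg)
            pos = "".join(s.residues for s, lab in pairs if lab == 1)
            neg = "".join(s.residues for s, lab in pairs if lab == -1)
            table = np.array(
                [[pos.count(a) for a in ALPHA_ORDER], [neg.count(a) for a in ALPHA_ORDER]]
            )
            _, p, _, _ = stats.chi2_contingency(table)
            rejections += p < 0.01
        assert rejections / runs <= 0.05

    def test_strong_effect_separable_on_ngram(self):
        cfg = GeneratorConfig(n_pos=50, n_neg=50, effect_size=1.0, seed=5)
        data = gen_objects(cfg)
        fm = extract_features("ngram420", sequences=data.sequences, labels=data.labels)
        result = kfold_cv(fm, k=10, kernel="linear", seed=0)
        assert result.mean["acc"] > 0.9


class TestGenProfile:
    def test_noiseless_profile_is_deterministic_pattern(self):
        pairs = gen_sequences(GeneratorConfig(n_pos=1, n_neg=0, seed=2))
        seq = pairs[0][0]
        prof = gen_profile(seq, pssm_noise=0.0, conservation=5.0, seed=0)
        from cytofeat._alphabet import PSSM_ORDER

        for i, ch in enumerate(seq.residues):
            expected = -np.ones(20)
            expected[PSSM_ORDER.index(ch)] = 5.0
            np.testing.assert_array_equal(prof.scores[i], expected)

    def test_shape(self):
        pairs = gen_sequences(GeneratorConfig(n_pos=1, n_neg=0, seed=3))
        prof = gen_profile(pairs[0][0], seed=1)
        assert prof.scores.shape == (len(pairs[0][0]), 20)

    def test_conserved_column_means_match_hand_formula(self):
        """With zero noise, each sigmoid column mean is a closed-form mix of
        sigmoid(conservation) on own-residue hits and sigmoid(-1) elsewhere."""
        from cytofeat import sigmoid_normalize, pssm20
        from cytofeat._alphabet import PSSM_ORDER

        pairs = gen_sequences(GeneratorConfig(n_pos=1, n_neg=0, seed=4))
        seq = pairs[0][0]
        s = 5.0
        prof = gen_profile(seq, pssm_noise=0.0, conservation=s, seed=0)
        got = pssm20(sigmoid_normalize(prof))
        L = len(seq)
        hi, lo = 1 / (1 + np.exp(-s)), 1 / (1 + np.e)
        for j, a in enumerate(PSSM_ORDER):
            count = seq.residues.count(a)
            assert got[j] == pytest.approx((count * hi + (L - count) * lo) / L, abs=1e-12)


class TestGenStructure:
    def test_row_sums_exactly_one(self):
        pairs = gen_sequences(GeneratorConfig(n_pos=2, n_neg=2, seed=6))
        for seq, lab in pairs:
            sp = gen_structure(seq, structure_bias=0.5, label=lab, seed=1)
            np.testing.assert_array_equal(sp.probabilities.sum(axis=1), np.ones(len(seq)))

    def test_probability_peaks_on_realized_state(self):
        pairs = gen_sequences(GeneratorConfig(n_pos=1, n_neg=0, seed=7))
        sp = gen_structure(pairs[0][0], seed=2)
        for i, state in enumerate(sp.states):
            assert sp.probabilities[i, "CHE".index(state)] == 0.8

    def test_null_bias_state_frequencies_match(self):
        """At zero structure bias the per-sequence state frequencies of the
        two classes are statistically indistinguishable (the chains are
        autocorrelated, so the unit of replication is the sequence)."""
        cfg = GeneratorConfig(n_pos=120, n_neg=120, structure_bias=0.0, seed=8)
        data = gen_objects(cfg)
        for j, state in enumerate("HEC"):
            freqs = {
                lab: [sp.states.count(state) / len(sp)
                      for sp, l in zip(data.structures, data.labels) if l == lab]
                for lab in (1, -1)
            }
            _, p = stats.ttest_ind(freqs[1], freqs[-1])
            assert p > 0.005


class TestGenDataset:
    def test_directory_contents(self, tmp_path):
        cfg = GeneratorConfig(n_pos=3, n_neg=27, seed=9)
        gen_dataset(cfg, tmp_path / "d")
        fasta = (tmp_path / "d" / "sequences.fasta").read_text()
        assert fasta.count(">") == 30
        assert len(list((tmp_path / "d" / "pssm").glob("*.pssm"))) == 30
        assert len(list((tmp_path / "d" / "ss2").glob("*.ss2"))) == 30
        labels = (tmp_path / "d" / "labels.tsv").read_text().splitlines()[1:]
        assert sum(1 for l in labels if l.endswith("\t1")) == 3
        assert (tmp_path / "d" / "manifest.json").exists()

    def test_same_seed_byte_identical(self, tmp_path):
        cfg = GeneratorConfig(n_pos=4, n_neg=4, seed=10)
        gen_dataset(cfg, tmp_path / "a")
        gen_dataset(cfg, tmp_path / "b")
        assert _dir_identical(tmp_path / "a", tmp_path / "b")

    def test_accuracy_monotone_in_effect_size(self):
        """Full-pipeline CV accuracy is non-decreasing over effect sizes
        {0, 0.5, 2} at fixed seeds (structure bias scales along)."""
        accs = []
        for effect in (0.0, 0.5, 2.0):
            cfg = GeneratorConfig(
                n_pos=30, n_neg=30, effect_size=effect,
                structure_bias=effect / 2, seed=12,
            )
            data = gen_objects(cfg)
            fm = extract_features(
                "sp48",
                sequences=data.sequences,
                structures=data.structures,
                labels=data.labels,
            )
            accs.append(kfold_cv(fm, k=5, kernel="linear", seed=0).mean["acc"])
        assert accs[0] <= accs[1] + 0.05 and accs[1] <= accs[2] + 0.05
        assert accs[2] > accs[0]
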