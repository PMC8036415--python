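import itertools
import math

import numpy as np
import pytest

from enhancerkit.seq_io import DnaSequence
from enhancerkit.seqgan import (
    DINUCLEOTIDES,
    Discriminator,
    GanTrainConfig,
    GeneratorPolicy,
    RolloutConfig,
    action_value,
    adversarial_train,
    detokenize,
    discriminator_loss,
    generate_sequences,
    generator_gradient,
    pairwise_identity,
    pretrain_generator,
    redundancy_filter,
    sequences_to_token_ids,
)
from enhancerkit.tokenize import non_overlapped_2gram
from tests.conftest import random_dna


class ConstantDiscriminator:
    def __init__(self, c):
        self.c = c

    def score(self, token_ids):
        token_ids = np.atleast_2d(token_ids)
        return np.full(len(token_ids), self.c)


class FirstTokenDiscriminator:
    """Deterministic score keyed on the first token (oracle-friendly)."""

    def __init__(self, table):
        self.table = np.asarray(table, dtype=float)

    def score(self, token_ids):
        token_ids = np.atleast_2d(token_ids)
        return self.table[token_ids[:, 0]]


class SumDiscriminator:
    """Score = normalized token sum; depends on the whole sequence."""

    def __init__(self, V, T):
        self.denom = (V - 1) * T

    def score(self, token_ids):
        token_ids = np.atleast_2d(token_ids)
        return 0.05 + 0.9 * token_ids.sum(axis=1) / self.denom


def tiny_generator(V=2, T=3, seed=0):
    return GeneratorPolicy(
        tokens=[chr(65 + i) for i in range(V)],
        horizon=T,
        hidden_size=1,
        embed_dim=1,
        seed=seed,
    )


def enumerate_sequence_probs(gen):
    """Exact P(Y) for every token sequence of length `horizon` (oracle)."""
    out = {}
    for seq in itertools.product(range(gen.V), repeat=gen.horizon):
        p = 1.0
        for t in range(gen.horizon):
            probs = gen.conditional_probs(list(seq[:t]))
            p *= probs[seq[t]]
        out[seq] = p
    return out


def exact_objective(gen, disc):
    """J(theta) = sum_Y P(Y) D(Y) by full enumeration (oracle)."""
    total = 0.0
    for seq, p in enumerate_sequence_probs(gen).items():
        total += p * float(disc.score(np.array(seq)[None, :])[0])
    return total


class TestGeneratorPolicy:
    def test_step_distribution_normalized(self, rng):
        gen = GeneratorPolicy(horizon=10, hidden_size=8, embed_dim=4, seed=1)
        for prefix in ([], [3], [3, 7, 1]):
            probs = gen.conditional_probs(prefix)
            assert probs.sum() == pytest.approx(1.0, abs=1e-9)
            assert (probs > 0).all()

    def test_sample_shape_and_range(self, rng):
        gen = GeneratorPolicy(horizon=12, hidden_size=8, embed_dim=4, seed=2)
        ids = gen.sample(7, rng)
        assert ids.shape == (7, 12)
        assert ids.min() >= 0 and ids.max() < gen.V

    def test_sample_deterministic_given_rng_seed(self):
        gen = GeneratorPolicy(horizon=8, hidden_size=4, embed_dim=3, seed=3)
        a = gen.sample(5, np.random.default_rng(42))
        b = gen.sample(5, np.random.default_rng(42))
        assert np.array_equal(a, b)

    def test_save_load_round_trip(self, tmp_path):
        gen = GeneratorPolicy(horizon=6, hidden_size=4, embed_dim=3, seed=4)
        path = tmp_path / "gen.model"
        gen.save(path)
        back = GeneratorPolicy.load(path)
        for k in gen.params:
            assert np.array_equal(back.params[k], gen.params[k])
        assert back.tokens == gen.tokens

    def test_prefix_continuation_consistent_with_replay(self, rng):
        """Continuing from stored hidden states equals replaying the prefix."""
        gen = GeneratorPolicy(horizon=10, hidden_size=6, embed_dim=3, seed=5)
        samples, hiddens = gen.sample(4, np.random.default_rng(0), keep_hidden=True)
        t = 4
        c1 = gen.sample(
            4, np.random.default_rng(9), prefix=samples[:, :t], h0=hiddens[t - 1]
        )
        c2 = gen.sample(4, np.random.default_rng(9), prefix=samples[:, :t])
        assert np.array_equal(c1, c2)


class TestPretrainGenerator:
    def test_memorizes_degenerate_corpus(self):
        gen = GeneratorPolicy(
            tokens=["A", "B", "C", "D"], horizon=6, hidden_size=8, embed_dim=4, seed=0
        )
        target = np.tile(np.array([[0, 1, 2, 3, 0, 1]]), (32, 1))
        cfg = GanTrainConfig(pretrain_epochs=60, batch_size=8, seed=0)
        pretrain_generator(target, gen, cfg)
        # greedy decode
        h = gen.initial_hidden(1)
        inp = np.array([gen.start_id])
        decoded = []
        for _ in range(6):
            h, probs = gen.step_probs(inp, h)
            inp = probs.argmax(axis=1)
            decoded.append(int(inp[0]))
        assert decoded == [0, 1, 2, 3, 0, 1]

    def test_nll_decreases(self):
        gen = tiny_generator(V=4, T=5, seed=1)
        rng = np.random.default_rng(0)
        corpus = rng.integers(0, 4, size=(40, 5))
        corpus[:, 0] = 2  # learnable structure
        cfg = GanTrainConfig(pretrain_epochs=10, batch_size=10, seed=1)
        before = gen.nll(corpus)
        log = pretrain_generator(corpus, gen, cfg)
        assert log[-1] < before
        assert len(log) == 10

    def test_empty_corpus_errors(self):
        gen = tiny_generator()
        with pytest.raises(ValueError):
            pretrain_generator(np.empty((0, 3), dtype=int), gen, GanTrainConfig())


class TestActionValue:
    def test_terminal_branch_exact_no_sampling(self):
        gen = tiny_generator(V=3, T=4)
        disc = FirstTokenDiscriminator([0.2, 0.5, 0.9])
        rng = np.random.default_rng(0)
        state_before = rng.bit_generator.state
        q = action_value([1, 2, 0], 2, gen, disc, RolloutConfig(n_rollouts=8), rng)
        assert q == 0.5  # D of the completed sequence, exactly
        assert rng.bit_generator.state == state_before  # no rollouts drawn

    def test_constant_discriminator(self, rng):
        gen = tiny_generator(V=2, T=5)
        disc = ConstantDiscriminator(0.37)
        for t_state in (0, 1, 3):
            state = [0] * t_state
            q = action_value(state, 1, gen, disc, RolloutConfig(n_rollouts=4), rng)
            assert q == pytest.approx(0.37, abs=1e-12)

    def test_rollout_mean_matches_enumerated_expectation(self):
        gen = tiny_generator(V=2, T=3, seed=7)
        disc = SumDiscriminator(V=2, T=3)
        rng = np.random.default_rng(123)
        N = 10_000
        q_hat = action_value([1], 0, gen, disc, RolloutConfig(n_rollouts=N), rng)
        # exact expectation over the single remaining step
        probs = gen.conditional_probs([1, 0])
        scores = [float(disc.score(np.array([[1, 0, y]]))[0]) for y in range(2)]
        q_exact = sum(p * s for p, s in zip(probs, scores))
        var = sum(p * (s - q_exact) ** 2 for p, s in zip(probs, scores))
        se = math.sqrt(var / N)
        assert abs(q_hat - q_exact) < 3 * se + 1e-12

    def test_beyond_horizon_errors(self, rng):
        gen = tiny_generator(V=2, T=2)
        with pytest.raises(ValueError):
            action_value([0, 1], 0, gen, ConstantDiscriminator(0.5), RolloutConfig(), rng)


class TestGeneratorGradient:
    def test_zero_under_constant_reward(self):
        gen = tiny_generator(V=3, T=4, seed=2)
        disc = ConstantDiscriminator(0.6)
        rng = np.random.default_rng(0)
        grads, _ = generator_gradient(gen, disc, RolloutConfig(n_rollouts=2), 16, rng)
        for g in grads.values():
            assert np.abs(g).max() <= 1e-8

    def test_deterministic_given_seed(self):
        gen = tiny_generator(V=2, T=3, seed=3)
        disc = SumDiscriminator(V=2, T=3)
        g1, _ = generator_gradient(
            gen, disc, RolloutConfig(n_rollouts=3), 8, np.random.default_rng(5)
        )
        g2, _ = generator_gradient(
            gen, disc, RolloutConfig(n_rollouts=3), 8, np.random.default_rng(5)
        )
        for k in g1:
            assert np.array_equal(g1[k], g2[k])

    def test_matches_finite_difference_of_enumerated_objective(self):
        """Averaged policy-gradient estimate vs central finite differences of
        the exactly enumerated objective, on a <=20-parameter toy."""
        gen = tiny_generator(V=2, T=2, seed=11)
        n_params = sum(v.size for v in gen.params.values())
        assert n_params <= 20
        disc = SumDiscriminator(V=2, T=2)
        rng = np.random.default_rng(77)

        B = 4000
        reps = 25  # 100k sampled sequences total
        sums = {k: np.zeros_like(v) for k, v in gen.params.items()}
        sq_sums = {k: np.zeros_like(v) for k, v in gen.params.items()}
        for _ in range(reps):
            grads, _ = generator_gradient(gen, disc, RolloutConfig(n_rollouts=1), B, rng)
            for k in sums:
                sums[k] += grads[k]
                sq_sums[k] += grads[k] ** 2
        eps = 1e-5
        for k in gen.params:
            flat = gen.params[k].reshape(-1)
            for i in range(flat.size):
                orig = flat[i]
                flat[i] = orig + eps
                j_plus = exact_objective(gen, disc)
                flat[i] = orig - eps
                j_minus = exact_objective(gen, disc)
                flat[i] = orig
                fd = (j_plus - j_minus) / (2 * eps)
                mean = sums[k].reshape(-1)[i] / reps
                var = sq_sums[k].reshape(-1)[i] / reps - mean**2
                se = math.sqrt(max(var, 0.0) / reps)
                assert abs(mean - fd) < 3 * se + 1e-6, (k, i, mean, fd, se)


class TestDiscriminatorLoss:
    def test_half_half_closed_form(self):
        disc = ConstantDiscriminator(0.5)
        batch = np.zeros((3, 4), dtype=int)
        loss = discriminator_loss(disc, batch, batch)
        assert loss == pytest.approx(2 * math.log(2), abs=1e-12)

    def test_perfect_discriminator_infimum(self):
        class Perfect:
            def score(self, ids):
                ids = np.atleast_2d(ids)
                return np.where(ids[:, 0] == 1, 1.0 - 1e-12, 1e-12)

        real = np.ones((2, 3), dtype=int)
        fake = np.zeros((2, 3), dtype=int)
        assert discriminator_loss(Perfect(), real, fake) == pytest.approx(0.0, abs=1e-9)

    def test_hand_computed_fixed_outputs(self):
        disc = FirstTokenDiscriminator([0.9, 0.8, 0.1, 0.3])
        real = np.array([[0, 0], [1, 1]])
        fake = np.array([[2, 2], [3, 3]])
        want = -(math.log(0.9) + math.log(0.8)) / 2 - (
            math.log(1 - 0.1) + math.log(1 - 0.3)
        ) / 2
        assert discriminator_loss(disc, real, fake) == pytest.approx(want, abs=1e-12)

    def test_empty_batch_errors(self):
        disc = ConstantDiscriminator(0.5)
        with pytest.raises(ValueError):
            discriminator_loss(disc, np.empty((0, 3), dtype=int), np.zeros((1, 3), dtype=int))


class TestAdversarialTrain:
    def _setup(self, g_steps=1, adv_rounds=3, pretrain_epochs=5, g_lr=0.01):
        gen = GeneratorPolicy(
            tokens=["A", "B", "C", "D"], horizon=8, hidden_size=8, embed_dim=4, seed=0
        )
        rng = np.random.default_rng(0)
        # "real" data: all-identical-token sequences
        real = np.repeat(rng.integers(0, 4, size=(48, 1)), 8, axis=1)
        disc = Discriminator(vocab_size=4, embed_dim=8, kernels_per_height=8, seed=1)
        cfg = GanTrainConfig(
            pretrain_epochs=pretrain_epochs,
            adv_rounds=adv_rounds,
            g_steps=g_steps,
            d_steps=2,
            batch_size=16,
            seed=0,
            g_learning_rate=g_lr,
        )
        return gen, disc, real, cfg

    def test_reward_improves_over_pretrain_baseline(self):
        # weak warm start so the adversarial phase has realism left to gain
        gen, disc, real, cfg = self._setup(
            g_steps=2, adv_rounds=15, pretrain_epochs=1, g_lr=2.0
        )
        pretrain_generator(real, gen, cfg)
        baseline_gen = gen.copy()
        rng = np.random.default_rng(3)
        log = adversarial_train(
            real, gen, disc, cfg, RolloutConfig(n_rollouts=4), rng
        )
        eval_rng = np.random.default_rng(99)
        trained = float(disc.score(gen.sample(64, eval_rng)).mean())
        eval_rng = np.random.default_rng(99)
        base = float(disc.score(baseline_gen.sample(64, eval_rng)).mean())
        assert trained > base

    def test_log_has_one_entry_per_round(self):
        gen, disc, real, cfg = self._setup(adv_rounds=4)
        pretrain_generator(real, gen, cfg)
        log = adversarial_train(real, gen, disc, cfg, RolloutConfig(2), np.random.default_rng(0))
        assert len(log) == 4

    def test_g_steps_zero_leaves_generator_unchanged(self):
        gen, disc, real, cfg = self._setup(g_steps=0, adv_rounds=2)
        pretrain_generator(real, gen, cfg)
        before = {k: v.copy() for k, v in gen.params.items()}
        adversarial_train(real, gen, disc, cfg, RolloutConfig(2), np.random.default_rng(0))
        for k, v in gen.params.items():
            assert np.array_equal(v, before[k])


class TestGenerateSequences:
    def test_valid_dna_output(self, rng):
        gen = GeneratorPolicy(horizon=100, hidden_size=8, embed_dim=4, seed=0)
        seqs = generate_sequences(gen, 5, "strong", rng)
        assert len(seqs) == 5
        for i, s in enumerate(seqs):
            assert len(s.residues) == 200
            assert set(s.residues) <= set("ACGT")
            assert s.id == f"strong|generated|{i}"

    def test_detokenize_inverts_2gram(self, rng):
        for i in range(20):
            seq = random_dna(rng, 2 * int(rng.integers(2, 60)), f"s{i}")
            ws = non_overlapped_2gram(seq)
            ids = sequences_to_token_ids([seq])[0]
            assert detokenize(ids) == seq.residues
            assert [DINUCLEOTIDES[i] for i in ids] == list(ws.words)


class TestPairwiseIdentity:
    def test_identical(self):
        assert pairwise_identity("ACGTACGT", "ACGTACGT") == 1.0

    def test_constructed_half_identity(self, rng):
        a = random_dna(rng, 200).residues
        b = list(a)
        flip = rng.choice(200, size=100, replace=False)
        for i in flip:
            b[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[i]]
        ident = pairwise_identity(a, "".join(b))
        assert ident >= 0.5  # aligned shift gives exactly 0.5; shifts may do better
        assert ident < 0.8

    def test_shifted_copy_detected(self):
        core = "ACGTGCA" * 20
        a = core
        b = "TT" + core[:-2]
        assert pairwise_identity(a, b) > 0.9


class TestRedundancyFilter:
    def test_identical_pair_second_removed(self, rng):
        a = random_dna(rng, 200, "a")
        b = DnaSequence(id="b", residues=a.residues)
        kept = redundancy_filter([a, b], cutoff=0.8)
        assert [s.id for s in kept] == ["a"]

    def test_dissimilar_pair_retained(self, rng):
        a = random_dna(rng, 200, "a")
        chars = list(a.residues)
        flip = rng.choice(200, size=100, replace=False)
        for i in flip:
            chars[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[chars[i]]
        b = DnaSequence(id="b", residues="".join(chars))
        kept = redundancy_filter([a, b], cutoff=0.8)
        assert len(kept) == 2

    def test_reference_screening(self, rng):
        ref = random_dna(rng, 200, "ref")
        dup = DnaSequence(id="dup", residues=ref.residues)
        fresh = random_dna(rng, 200, "fresh")
        kept = redundancy_filter([dup, fresh], cutoff=0.8, reference=[ref])
        assert [s.id for s in kept] == ["fresh"]

    def test_invalid_cutoff_errors(self, rng):
        with pytest.raises(ValueError):
            redundancy_filter([random_dna(rng, 10)], cutoff=1.5)

    def test_retained_set_oracle_on_fixture(self, rng):
        """Exhaustive O(n^2) check: no retained k-mer-sharing pair >= cutoff."""
        base = [random_dna(rng, 120, f"b{i}") for i in range(25)]
        seqs = []
        for i, s in enumerate(base):
            seqs.append(s)
            # near-duplicates with ~10% mutations
            chars = list(s.residues)
            for j in rng.choice(120, size=12, replace=False):
                chars[j] = "ACGT"[int(rng.integers(4))]
            seqs.append(DnaSequence(id=f"m{i}", residues="".join(chars)))
            chars2 = list(s.residues)
            for j in rng.choice(120, size=18, replace=False):
                chars2[j] = "ACGT"[int(rng.integers(4))]
            seqs.append(DnaSequence(id=f"n{i}", residues="".join(chars2)))
        seqs = seqs[:100]
        kept = redundancy_filter(seqs, cutoff=0.8)
        assert len(kept) < len(seqs)  # near-duplicates were removed
        for i in range(len(kept)):
            for j in range(i + 1, len(kept)):
                ident = pairwise_identity(kept[i].residues, kept[j].residues, cutoff=0.8)
                assert ident < 0.8, (kept[i].id, kept[j].id, ident)
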