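import itertools

import numpy as np
import pytest

from signalchains import (
    Language,
    MEANING_SPACE,
    chain_metrics,
    combinatorial_coefficient,
    length_by_size,
    mantel_z,
    self_comprehension_score,
    transmission_error,
)
from signalchains.simulate import SimulationConfig, simulate_chain
from signalchains.transmission import experiment_metrics, signal_length_table
from tests.conftest import random_language


def zero_noise_config(seed=0, **kw):
    return SimulationConfig(
        seed=seed, p_flip=0.0, p_ins=0.0, p_del=0.0, p_comp=0.0, iconicity_beta=0.0, **kw
    )


class TestTransmissionError:
    def test_identical_languages_score_zero(self, compositional_language):
        err = transmission_error(compositional_language, compositional_language)
        assert err.mean == 0.0 and all(v == 0.0 for v in err.per_meaning.values())

    def test_constant_signal_bitflip_scores_one(self):
        """Complementing a constant-run signal forces a substitution at every
        position; nLED is exactly 1.  (For general strings the complement can
        be closer than n edits via shifts, e.g. 0110 -> 1001 in 2 edits.)"""
        parent = Language.from_signals(
            ["0" * k for k in range(1, 9)]
        )
        child = Language(
            {m: s.translate(str.maketrans("01", "10")) for m, s in parent.entries.items()}
        )
        err = transmission_error(parent, child)
        assert err.mean == 1.0 and set(err.per_meaning.values()) == {1.0}

    def test_single_deletion_mean(self, rng):
        parent = random_language(rng)
        entries = dict(parent.entries)
        m0 = MEANING_SPACE[0]
        entries[m0] = "0010"
        parent = Language(entries)
        child_entries = dict(parent.entries)
        child_entries[m0] = "010"
        err = transmission_error(parent, Language(child_entries))
        assert err.per_meaning[m0] == pytest.approx(0.25)
        assert err.mean == pytest.approx(0.25 / 8)

    def test_symmetric(self, rng):
        a, b = random_language(rng), random_language(rng)
        assert transmission_error(a, b).mean == pytest.approx(transmission_error(b, a).mean)

    def test_meaning_mismatch_rejected(self, rng):
        full = random_language(rng)
        partial = Language({m: s for m, s in full.entries.items() if m.id < 7})
        with pytest.raises(ValueError, match="meaning mismatch"):
            transmission_error(full, partial)


class TestSelfComprehension:
    def test_all_correct_scores_zero(self):
        sel = [(m, m) for m in MEANING_SPACE[:4]]
        assert self_comprehension_score(sel) == 0.0

    def test_antipodal_selections_score_three(self):
        sel = [(m, MEANING_SPACE[m.id ^ 7]) for m in MEANING_SPACE[:4]]
        assert self_comprehension_score(sel) == 3.0

    def test_uniform_selection_expectation_is_1_5(self):
        # enumeration: mean Hamming from any meaning to all 8 is 12/8 = 1.5
        sel = [(t, s) for t, s in itertools.product(MEANING_SPACE, MEANING_SPACE)]
        assert self_comprehension_score(sel) == pytest.approx(1.5)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            self_comprehension_score([])


class TestLengthBySize:
    def test_seed_style_language(self):
        # ids 0..3 are small, 4..7 large
        sigs = ["0" * 4] * 4 + ["0" * 6] * 4
        lang = Language.from_signals(dict(enumerate(sigs)))
        assert length_by_size(lang) == (4.0, 6.0, 2.0)

    def test_equal_lengths_no_difference(self, compositional_language):
        assert length_by_size(compositional_language)[2] == 0.0

    def test_hand_computed_means(self):
        sigs = {0: "000", 1: "000", 2: "0000", 3: "0000",
                4: "00000", 5: "000000", 6: "000000", 7: "0000000"}
        assert length_by_size(Language.from_signals(sigs)) == (3.5, 6.0, 2.5)


class TestChainMetrics:
    def test_zero_noise_chain_is_static(self):
        chain = simulate_chain(zero_noise_config(seed=9), seed=9)
        gms = chain_metrics(chain, n_perm=300, seed=1)
        assert len(gms) == chain.n_generations
        assert gms[0].mean_nled_to_parent is None
        for gm in gms[1:]:
            assert gm.mean_nled_to_parent == 0.0
        assert len({gm.cc for gm in gms}) == 1
        zs = {gm.mantel_z for gm in gms if not gm.mantel_degenerate}
        assert len(zs) == 1  # same language + same permutation seed

    def test_consistent_with_direct_metric_calls(self):
        chain = simulate_chain(SimulationConfig(seed=4, n_generations=3), seed=4)
        gms = chain_metrics(chain, n_perm=300, seed=2)
        for rec, gm in zip(chain.records, gms):
            assert gm.cc == pytest.approx(combinatorial_coefficient(rec.language))
            direct = mantel_z(rec.language, n_perm=300, seed=2)
            assert gm.mantel_z == pytest.approx(direct.z, nan_ok=True)

    def test_generation0_has_no_training_or_selections(self):
        chain = simulate_chain(SimulationConfig(seed=4, n_generations=2), seed=4)
        gms = chain_metrics(chain, n_perm=300, seed=2)
        assert gms[0].trials_to_criterion is None
        assert gms[0].mean_self_hamming is None
        assert gms[1].trials_to_criterion is not None
        assert gms[1].mean_self_hamming is not None


class TestPlantedEffects:
    def test_fidelity_decreases_with_flip_noise(self):
        """Mean nLED to parent rises monotonically over a substitution-noise
        grid, at matched seeds."""
        means = []
        for p_flip in (0.02, 0.12, 0.35):
            cfg = SimulationConfig(
                seed=21, p_flip=p_flip, p_ins=0.0, p_del=0.0, p_comp=0.0,
                n_chains=3, n_generations=5,
            )
            nled = []
            for k in range(3):
                chain = simulate_chain(cfg, seed=100 + k)
                for g in range(1, 6):
                    nled.append(
                        transmission_error(
                            chain.records[g - 1].language, chain.records[g].language
                        ).mean
                    )
            means.append(np.mean(nled))
        assert means[0] < means[1] < means[2]

    def test_len_diff_grows_with_iconicity_bias(self):
        diffs = []
        for beta in (0.0, 0.08):
            cfg = SimulationConfig(seed=22, iconicity_beta=beta, n_chains=4)
            vals = []
            for k in range(4):
                chain = simulate_chain(cfg, seed=200 + k)
                for rec in chain.records[1:]:
                    vals.append(length_by_size(rec.language)[2])
            diffs.append(np.mean(vals))
        assert diffs[1] > diffs[0]
        assert diffs[1] > 0.5


class TestTables:
    def test_experiment_metrics_shape(self):
        cfg = SimulationConfig(seed=7, n_chains=2, n_generations=3)
        from signalchains.simulate import simulate_experiment

        chains = simulate_experiment(cfg)
        df = experiment_metrics(chains, n_perm=300, seed=0)
        assert len(df) == len(chains) * 4
        assert df.loc[df.generation == 0, "mean_nled_to_parent"].isna().all()
        assert df.loc[df.generation > 0, "mean_nled_to_parent"].notna().all()

    def test_signal_length_table_is_item_level(self):
        chain = simulate_chain(SimulationConfig(seed=7, n_generations=3), seed=7)
        df = signal_length_table([chain])
        assert len(df) == 4 * 8
        assert set(df["size"]) == {"small", "large"}
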