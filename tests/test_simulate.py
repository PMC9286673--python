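import numpy as np
import pytest

from signalchains import (
    Language,
    mantel_z_exact,
    transmission_error,
    validate_language,
)
from signalchains.simulate import (
    SimulationConfig,
    compositional_signal,
    initial_language,
    simulate_chain,
    simulate_experiment,
    simulate_training,
    transmit,
)
from signalchains.core import MEANING_SPACE


def zero_noise(**kw):
    return SimulationConfig(p_flip=0.0, p_ins=0.0, p_del=0.0, p_comp=0.0, **kw)


class TestInitialLanguage:
    def test_length_design(self):
        for seed in range(20):
            lang = initial_language(seed)
            lengths = sorted(len(s) for s in lang.signals())
            assert lengths == [4, 4, 4, 4, 6, 6, 6, 6]
            assert validate_language(lang, require_unique=True).ok

    def test_deterministic(self):
        assert initial_language(123) == initial_language(123)

    def test_seeds_give_distinct_languages(self):
        langs = [initial_language(s) for s in range(40)]
        pairs = [(a, b) for i, a in enumerate(langs) for b in langs[i + 1 :]]
        assert all(a != b for a, b in pairs)


class TestTransmit:
    def test_noiseless_copy_is_identity(self):
        parent = initial_language(1)
        child = transmit(parent, zero_noise(), seed=5)
        assert child == parent

    def test_full_flip_gives_bitwise_complement(self):
        parent = initial_language(2)
        cfg = SimulationConfig(p_flip=1.0, p_ins=0.0, p_del=0.0, p_comp=0.0)
        child = transmit(parent, cfg, seed=5)
        flip = str.maketrans("01", "10")
        for m in MEANING_SPACE:
            assert child.entries[m] == parent.entries[m].translate(flip)
        # every position substituted; nLED per meaning is high but can dip
        # below 1 where the complement aligns by a shift
        err = transmission_error(parent, child)
        assert all(0.0 < v <= 1.0 for v in err.per_meaning.values())
        assert err.mean > 0.5

    def test_pure_regeneration_is_compositional(self):
        cfg = zero_noise()
        cfg = SimulationConfig(p_flip=0.0, p_ins=0.0, p_del=0.0, p_comp=1.0)
        child = transmit(initial_language(3), cfg, seed=5)
        # every signal equals its feature-chunk concatenation, modulo the
        # uniqueness filter (which cannot trigger: the 8 concatenations differ)
        for m in MEANING_SPACE:
            assert child.entries[m] == compositional_signal(m, cfg.comp_map)
        assert mantel_z_exact(child).z > 1.96

    def test_uniqueness_filter_always_holds(self):
        cfg = SimulationConfig(p_flip=0.3, p_ins=0.1, p_del=0.3, p_comp=0.5)
        parent = initial_language(4)
        for seed in range(30):
            child = transmit(parent, cfg, seed=seed)
            assert validate_language(child, require_unique=True).ok
            parent = child

    def test_deterministic_given_seed(self):
        parent = initial_language(5)
        cfg = SimulationConfig()
        assert transmit(parent, cfg, seed=11) == transmit(parent, cfg, seed=11)


class TestSimulateTraining:
    def test_instant_learner_minimum_16_trials(self):
        res = simulate_training(SimulationConfig(learn_rate=1.0), seed=0)
        assert res.trials_to_criterion == 16

    def test_trials_are_positive_multiples_of_8(self):
        for seed in range(20):
            res = simulate_training(SimulationConfig(learn_rate=0.05), seed=seed)
            assert res.trials_to_criterion > 0
            assert res.trials_to_criterion % 8 == 0

    def test_stricter_criterion_needs_more_training(self):
        t3, t5 = [], []
        for seed in range(300):
            t3.append(
                simulate_training(SimulationConfig(criterion=3), seed=seed).trials_to_criterion
            )
            t5.append(
                simulate_training(SimulationConfig(criterion=5), seed=seed).trials_to_criterion
            )
        assert np.mean(t5) > np.mean(t3)

    def test_zero_learn_rate_rejected(self):
        with pytest.raises(ValueError):
            simulate_training(SimulationConfig(learn_rate=0.0), seed=0)


class TestSimulateChain:
    def test_record_count_is_generations_plus_seed(self):
        chain = simulate_chain(SimulationConfig(seed=1), seed=1)
        assert chain.n_generations == 11
        assert chain.records[0].generation == 0

    def test_zero_noise_languages_never_change(self):
        chain = simulate_chain(zero_noise(seed=2), seed=2)
        seedlang = chain.records[0].language
        assert all(r.language == seedlang for r in chain.records)

    def test_bit_identical_on_rerun(self):
        a = simulate_chain(SimulationConfig(seed=3), seed=3)
        b = simulate_chain(SimulationConfig(seed=3), seed=3)
        for ra, rb in zip(a.records, b.records):
            assert ra.language == rb.language
            assert ra.trials_to_criterion == rb.trials_to_criterion
            assert ra.selections == rb.selections


class TestSimulateExperiment:
    def test_default_two_conditions_24_chains(self):
        chains = simulate_experiment(SimulationConfig(seed=4, n_chains=12))
        assert len(chains) == 24
        assert {c.condition for c in chains} == {"short", "long"}

    def test_condition_overrides_honored(self):
        cfg = SimulationConfig(seed=4)
        assert cfg.for_condition("short").criterion == 3
        assert cfg.for_condition("long").criterion == 5
        chains = simulate_experiment(SimulationConfig(seed=4, n_chains=8))
        trials = {
            cond: np.mean(
                [r.trials_to_criterion for c in chains if c.condition == cond
                 for r in c.records[1:]]
            )
            for cond in ("short", "long")
        }
        assert trials["long"] > trials["short"]

    def test_experiment_is_pure_function_of_config(self):
        a = simulate_experiment(SimulationConfig(seed=6, n_chains=2))
        b = simulate_experiment(SimulationConfig(seed=6, n_chains=2))
        for ca, cb in zip(a, b):
            assert ca.chain_id == cb.chain_id
            assert all(x.language == y.language for x, y in zip(ca.records, cb.records))

    def test_length_declines_when_deletions_dominate(self):
        cfg = SimulationConfig(
            seed=8, p_flip=0.05, p_ins=0.02, p_del=0.10, p_comp=0.0, n_chains=6
        )
        chains = simulate_experiment(cfg)
        first = np.mean([len(s) for c in chains for s in c.records[0].language.signals()])
        last = np.mean([len(s) for c in chains for s in c.records[-1].language.signals()])
        assert last < first


class TestConfigValidation:
    def test_probability_bounds(self):
        with pytest.raises(ValueError):
            SimulationConfig(p_flip=1.5)

    def test_criterion_domain(self):
        with pytest.raises(ValueError):
            SimulationConfig(criterion=4)

    def test_comp_map_chunks(self):
        with pytest.raises(ValueError):
            SimulationConfig(comp_map={"small": "0x"})

    def test_unknown_key_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            SimulationConfig.from_dict({"p_flib": 0.1})
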