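"""Synthetic transmission-chain simulator.

Emulates the iterated-learning design — 8 meanings (2x2x2 feature space),
binary signals seeded as 4 strings of length 4 plus 4 of length 6, chains
of 10 learner generations, a uniqueness filter at production, and training
to a 3- or 5-correct criterion — with a parametric noisy-copy/regenerate
agent in place of human learners.  The agent makes no claim of cognitive
fidelity; it exists to give the structure metrics known ground truth:

* ``p_flip`` / ``p_ins`` / ``p_del`` control reproduction noise (nLED);
* ``p_comp`` plants compositional structure by regenerating a signal from
  a fixed feature -> bigram map instead of copying;
* ``iconicity_beta`` plants relative iconicity by inflating deletions in
  small-referent signals and suppressing them in large-referent ones.

Everything is a pure function of the configuration, including its seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np

from .core import ALPHABET, Chain, GenerationRecord, Language, Meaning, MEANING_SPACE, Signal

#: Default feature-value -> bigram map used by the compositional regeneration
#: branch; values within a feature map to complementary chunks.
DEFAULT_COMP_MAP: dict[str, str] = {
    "small": "00",
    "large": "11",
    "round": "01",
    "spiky": "10",
    "light": "00",
    "dark": "11",
}


@dataclass
class SimulationConfig:
    """All simulator parameters; the experiment is a pure function of this.

    Defaults mirror the study design: 12 chains x 10 generations per
    condition, short/long training criteria of 3 vs 5, and moderate copy
    noise with deletions slightly exceeding insertions so signals shorten
    over transmission.
    """

    n_chains: int = 12
    n_generations: int = 10
    conditions: dict[str, dict] = field(
        default_factory=lambda: {"short": {"criterion": 3}, "long": {"criterion": 5}}
    )
    seed: int = 0
    p_flip: float = 0.12
    p_ins: float = 0.03
    p_del: float = 0.07
    p_comp: float = 0.1
    p_comp_schedule: list[float] | None = None
    comp_map: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_COMP_MAP))
    iconicity_beta: float = 0.0
    max_unique_retries: int = 10
    learn_rate: float = 0.05
    criterion: int = 3

    def __post_init__(self) -> None:
        for name in ("p_flip", "p_ins", "p_del", "p_comp", "iconicity_beta", "learn_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.criterion not in (3, 5):
            raise ValueError(f"criterion must be 3 or 5, got {self.criterion}")
        for k, chunk in self.comp_map.items():
            if len(chunk) != 2 or set(chunk) - set(ALPHABET):
                raise ValueError(f"comp_map[{k!r}] must be a 2-symbol binary chunk")
        if self.p_comp_schedule is not None and any(
            not 0 <= p <= 1 for p in self.p_comp_schedule
        ):
            raise ValueError("p_comp_schedule entries must be in [0, 1]")

    def p_comp_at(self, generation: int) -> float:
        """Compositional-regeneration probability for a given learner generation."""
        if self.p_comp_schedule is None:
            return self.p_comp
        return self.p_comp_schedule[(generation - 1) % len(self.p_comp_schedule)]

    def for_condition(self, condition: str) -> "SimulationConfig":
        return replace(self, **self.conditions.get(condition, {}))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown simulator config keys: {sorted(unknown)}")
        return cls(**d)


def _derive_seeds(seed: int, n: int) -> list[int]:
    """Deterministic child seeds (< 2**31) from a master seed."""
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def initial_language(seed: int | None = None) -> Language:
    """Seed language: 8 distinct uniform-random binary strings, 4 of length
    4 and 4 of length 6, with the length assignment to meanings randomized."""
    rng = np.random.default_rng(seed)
    lengths = np.array([4] * 4 + [6] * 4)
    rng.shuffle(lengths)
    signals: list[str] = []
    for L in lengths:
        while True:
            s = "".join(rng.choice(ALPHABET, size=int(L)))
            if s not in signals:
                signals.append(s)
                break
    return Language.from_signals(signals)


def _apply_noise(signal: str, meaning: Meaning, cfg: SimulationConfig, rng) -> str:
    """Per-position substitution/insertion/deletion noise, with the deletion
    rate shifted by ``iconicity_beta``: up for small referents, down for large."""
    if meaning.size == "small":
        p_del = min(1.0, cfg.p_del + cfg.iconicity_beta)
    else:
        p_del = max(0.0, cfg.p_del - cfg.iconicity_beta)
    out: list[str] = []
    for ch in signal:
        if rng.random() < cfg.p_ins:
            out.append(str(rng.choice(ALPHABET)))
        if rng.random() < p_del:
            continue
        if rng.random() < cfg.p_flip:
            ch = ALPHABET[1 - ALPHABET.index(ch)]
        out.append(ch)
    if rng.random() < cfg.p_ins:
        out.append(str(rng.choice(ALPHABET)))
    if not out:
        out.append(str(rng.choice(ALPHABET)))
    return "".join(out)


def compositional_signal(meaning: Meaning, comp_map: dict[str, str]) -> str:
    """The 6-symbol concatenation comp_map(size) . comp_map(shape) . comp_map(brightness)."""
    return comp_map[meaning.size] + comp_map[meaning.shape] + comp_map[meaning.brightness]


def transmit(
    parent: Language,
    cfg: SimulationConfig,
    seed: int | None = None,
    generation: int | None = None,
) -> Language:
    """One noisy generation of reproduction, honoring the uniqueness filter.

    Per meaning: with probability ``p_comp`` the signal is regenerated from
    the compositional map, otherwise the parent signal is copied; either
    way symbol noise is applied.  Duplicates are resampled up to
    ``max_unique_retries``, then disambiguated by appending random symbols.
    """
    rng = np.random.default_rng(seed)
    p_comp = cfg.p_comp if generation is None else cfg.p_comp_at(generation)
    produced: dict[Meaning, Signal] = {}
    seen: set[str] = set()
    for m in MEANING_SPACE:
        for _ in range(cfg.max_unique_retries + 1):
            if rng.random() < p_comp:
                base = compositional_signal(m, cfg.comp_map)
            else:
                base = str(parent.entries[m])
            cand = _apply_noise(base, m, cfg, rng)
            if cand not in seen:
                break
        while cand in seen:
            cand += str(rng.choice(ALPHABET))
        seen.add(cand)
        produced[m] = Signal(cand)
    return Language(produced)


@dataclass
class TrainingResult:
    trials_to_criterion: int
    comprehension_recall: np.ndarray  # per-meaning recall probability after training


_COMPREHENSION_CHANCE = 1 / 8  # guess among all eight referents
_PRODUCTION_CHANCE = 0.01  # cold production of a correct string is near-impossible

_MAX_ROUNDS = 500  # safety bound; reached only with learn_rate ~ 0


def simulate_training(cfg: SimulationConfig, seed: int | None = None) -> TrainingResult:
    """Simulate alternating comprehension/production rounds of 8 trials each.

    Per-item recall starts at chance (1/8 for comprehension, a 0.01 floor
    for production) and rises by ``learn_rate`` per exposure; exposure is
    credited at presentation, so an instant learner (learn_rate 1) is
    correct from the first trial and finishes in the minimal 16 trials.
    A round with at least ``criterion`` correct earns a star; training
    stops at two stars.  Returns total trials, a positive multiple of 8.
    """
    if not 0.0 < cfg.learn_rate <= 1.0:
        raise ValueError("learn_rate must be in (0, 1]")
    rng = np.random.default_rng(seed)
    exposures = np.zeros(8, dtype=int)
    stars = 0
    trials = 0
    for round_idx in range(_MAX_ROUNDS):
        base = _COMPREHENSION_CHANCE if round_idx % 2 == 0 else _PRODUCTION_CHANCE
        order = rng.permutation(8)
        correct = 0
        for item in order:
            exposures[item] += 1
            p = min(1.0, base + cfg.learn_rate * exposures[item])
            correct += int(rng.random() < p)
            trials += 1
        if correct >= cfg.criterion:
            stars += 1
        if stars >= 2:
            break
    recall = np.minimum(1.0, _COMPREHENSION_CHANCE + cfg.learn_rate * exposures)
    return TrainingResult(trials_to_criterion=trials, comprehension_recall=recall)


def simulate_selections(
    lang: Language,
    recall: np.ndarray,
    rng,
    n_trials: int = 4,
) -> list[tuple[Meaning, Meaning]]:
    """Self-comprehension: for each of ``n_trials`` random targets, the agent
    picks the target with its recall probability, else one of 3 random
    distractors (the experiment presented 4 candidate referents)."""
    targets = rng.choice(8, size=n_trials, replace=False)
    pairs = []
    for t in targets:
        target = MEANING_SPACE[int(t)]
        if rng.random() < recall[int(t)]:
            selected = target
        else:
            others = [i for i in range(8) if i != int(t)]
            distractors = rng.choice(others, size=3, replace=False)
            selected = MEANING_SPACE[int(rng.choice(distractors))]
        pairs.append((target, selected))
    return pairs


def simulate_chain(
    cfg: SimulationConfig,
    chain_id: str = "chain-00",
    condition: str = "short",
    seed: int | None = None,
) -> Chain:
    """One chain: seed language at generation 0, then ``n_generations``
    rounds of train -> transmit -> self-comprehend."""
    seeds = _derive_seeds(cfg.seed if seed is None else seed, 1 + 3 * cfg.n_generations)
    records = [GenerationRecord(generation=0, language=initial_language(seeds[0]))]
    lang = records[0].language
    for g in range(1, cfg.n_generations + 1):
        s_train, s_trans, s_self = seeds[3 * g - 2 : 3 * g + 1]
        training = simulate_training(cfg, seed=s_train)
        lang = transmit(lang, cfg, seed=s_trans, generation=g)
        selections = simulate_selections(
            lang, training.comprehension_recall, np.random.default_rng(s_self)
        )
        records.append(
            GenerationRecord(
                generation=g,
                language=lang,
                trials_to_criterion=training.trials_to_criterion,
                selections=selections,
            )
        )
    return Chain(chain_id=chain_id, condition=condition, records=records)


def simulate_experiment(cfg: SimulationConfig) -> list[Chain]:
    """A full experiment: ``n_chains`` chains per condition, child seeds
    derived deterministically from the master seed."""
    labels = list(cfg.conditions) or ["default"]
    chain_seeds = _derive_seeds(cfg.seed, len(labels) * cfg.n_chains)
    chains = []
    for ci, cond in enumerate(labels):
        ccfg = cfg.for_condition(cond)
        for k in range(cfg.n_chains):
            chains.append(
                simulate_chain(
                    ccfg,
                    chain_id=f"{cond}-{k:02d}",
                    condition=cond,
                    seed=chain_seeds[ci * cfg.n_chains + k],
                )
            )
    return chains
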