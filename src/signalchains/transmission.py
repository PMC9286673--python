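"""Per-generation transmission metrics: fidelity, self-comprehension, iconicity.

Transmission fidelity is measured as the mean length-normalized Levenshtein
distance (nLED) between signals produced for the same meaning in
consecutive generations — higher means less faithful reproduction.
Self-comprehension is the mean Hamming distance (0..3 feature scale)
between the target meaning and the meaning a learner selects for their own
signal.  Relative iconicity is summarized as the difference in mean signal
length between large and small referents (positive = longer signals for
larger referents, the attested direction).
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .combinatorial import best_compression, recombination_index
from .compositional import mantel_z, meaning_hamming, normalized_levenshtein
from .core import Chain, Language, Meaning


@dataclass
class TransmissionError:
    per_meaning: dict[Meaning, float]
    mean: float


def transmission_error(parent: Language, child: Language) -> TransmissionError:
    """Per-meaning nLED between parent and child productions, plus the mean."""
    if set(parent.entries) != set(child.entries):
        missing = set(parent.entries) ^ set(child.entries)
        raise ValueError(f"meaning mismatch between generations: {sorted(m.id for m in missing)}")
    per = {
        m: normalized_levenshtein(parent.entries[m], child.entries[m])
        for m in sorted(parent.entries, key=lambda m: m.id)
    }
    return TransmissionError(per_meaning=per, mean=float(np.mean(list(per.values()))))


def self_comprehension_score(selections: list[tuple[Meaning, Meaning]]) -> float:
    """Mean Hamming distance between target and selected meanings, on the 0..3 scale."""
    if not selections:
        raise ValueError("self-comprehension requires at least one selection")
    return float(np.mean([meaning_hamming(t, s) for t, s in selections]))


def length_by_size(lang: Language) -> tuple[float, float, float]:
    """(mean length over small referents, over large referents, large - small)."""
    small = [len(s) for m, s in lang.entries.items() if m.size == "small"]
    large = [len(s) for m, s in lang.entries.items() if m.size == "large"]
    ms, ml = float(np.mean(small)), float(np.mean(large))
    return ms, ml, ml - ms


@dataclass
class GenerationMetrics:
    """All per-generation summaries for one generation of one chain.

    Parent-relative fields (``mean_nled_to_parent``) are None at generation
    0 — the seed has no parent — never zero.
    """

    chain_id: str
    condition: str
    generation: int
    cc: float
    description_length: int
    n_units: int
    mantel_r: float
    mantel_z: float
    mantel_degenerate: bool
    mean_nled_to_parent: float | None
    mean_self_hamming: float | None
    mean_len_small: float
    mean_len_large: float
    len_diff: float
    trials_to_criterion: int | None


def chain_metrics(chain: Chain, n_perm: int = 1000, seed: int | None = None) -> list[GenerationMetrics]:
    """Compute every per-generation metric along one chain.

    The same permutation seed is reused for every generation's Mantel test,
    so generations with identical languages get identical z.
    """
    out: list[GenerationMetrics] = []
    prev: Language | None = None
    for rec in chain.records:
        lang = rec.language
        cl = best_compression(lang)
        mres = mantel_z(lang, n_perm=n_perm, seed=seed)
        ms, ml, diff = length_by_size(lang)
        nled = transmission_error(prev, lang).mean if prev is not None else None
        self_h = (
            self_comprehension_score(rec.selections) if rec.selections else None
        )
        out.append(
            GenerationMetrics(
                chain_id=chain.chain_id,
                condition=chain.condition,
                generation=rec.generation,
                cc=recombination_index(cl),
                description_length=cl.description_length,
                n_units=len(cl.units),
                mantel_r=mres.r_observed,
                mantel_z=mres.z,
                mantel_degenerate=mres.degenerate,
                mean_nled_to_parent=nled,
                mean_self_hamming=self_h,
                mean_len_small=ms,
                mean_len_large=ml,
                len_diff=diff,
                trials_to_criterion=rec.trials_to_criterion,
            )
        )
        prev = lang
    return out


def experiment_metrics(
    chains: list[Chain], n_perm: int = 1000, seed: int | None = None
) -> pd.DataFrame:
    """Metrics table over an experiment: one row per (chain, generation)."""
    rows = []
    for chain in chains:
        for gm in chain_metrics(chain, n_perm=n_perm, seed=seed):
            rows.append({f.name: getattr(gm, f.name) for f in fields(gm)})
    return pd.DataFrame(rows)


def signal_length_table(chains: list[Chain]) -> pd.DataFrame:
    """Item-level table: one row per (chain, generation, meaning) with signal length.

    Feeds the iconicity growth-curve model (signal length ~ size x condition
    x generation).
    """
    rows = []
    for chain in chains:
        for rec in chain.records:
            for m in sorted(rec.language.entries, key=lambda m: m.id):
                rows.append(
                    {
                        "chain_id": chain.chain_id,
                        "condition": chain.condition,
                        "generation": rec.generation,
                        "meaning_id": m.id,
                        "size": m.size,
                        "signal_length": len(rec.language.entries[m]),
                    }
                )
    return pd.DataFrame(rows)
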