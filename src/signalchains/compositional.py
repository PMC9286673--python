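"""Compositional structure as a Mantel permutation z-score.

A language is compositional when similar meanings receive similar signals.
Following the standard iterated-learning procedure, the 28 pairwise
length-normalized Levenshtein distances between signals are correlated
(Pearson) with the 28 pairwise Hamming distances between the corresponding
meanings, and the observed correlation is standardized against its
distribution under random reassignment of signals to meanings:

    z = (r_observed - mean(r_perm)) / sd(r_perm)

Higher z means more compositional; 1.96 is the conventional two-sided 5%
normal threshold.  The sampled test draws permutations uniformly with
replacement from the 8! reassignments (default 1000); the exact variant
enumerates all 40,320 and serves as an oracle for the sampled one.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import edlib
import numpy as np
from scipy.stats import rankdata

from .core import Language, Meaning, MEANING_SPACE

Z_THRESHOLD = 1.96


def normalized_levenshtein(a: str, b: str) -> float:
    """Unit-cost edit distance divided by the longer sequence's length, in [0, 1]."""
    if len(a) == 0 or len(b) == 0:
        raise ValueError("normalized Levenshtein distance requires non-empty signals")
    d = edlib.align(str(a), str(b), task="distance")["editDistance"]
    return d / max(len(a), len(b))


def meaning_hamming(m1: Meaning, m2: Meaning) -> int:
    """Number of differing features among (size, shape, brightness): 0..3."""
    return sum(x != y for x, y in zip(m1.bits, m2.bits))


@dataclass
class DistanceVectors:
    """The 28 aligned pairwise distances underlying the Mantel statistic."""

    signal_d: np.ndarray
    meaning_d: np.ndarray
    pair_index: list[tuple[int, int]]


def pairwise_distance_vectors(lang: Language) -> DistanceVectors:
    """Pairwise nLED and meaning-Hamming vectors over all C(8,2)=28 meaning pairs,
    in canonical (meaning id) order."""
    meanings = sorted(lang.entries, key=lambda m: m.id)
    if len(meanings) != len(MEANING_SPACE):
        raise ValueError("language must cover all 8 meanings")
    sig, mean_d, pairs = [], [], []
    for i, j in itertools.combinations(range(len(meanings)), 2):
        mi, mj = meanings[i], meanings[j]
        sig.append(normalized_levenshtein(lang.entries[mi], lang.entries[mj]))
        mean_d.append(meaning_hamming(mi, mj))
        pairs.append((mi.id, mj.id))
    return DistanceVectors(
        signal_d=np.asarray(sig, dtype=float),
        meaning_d=np.asarray(mean_d, dtype=float),
        pair_index=pairs,
    )


@dataclass
class MantelResult:
    r_observed: float
    z: float
    n_perm: int
    seed: int | None = None
    degenerate: bool = False


def _signal_distance_matrix(lang: Language) -> np.ndarray:
    meanings = sorted(lang.entries, key=lambda m: m.id)
    n = len(meanings)
    D = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        D[i, j] = D[j, i] = normalized_levenshtein(
            lang.entries[meanings[i]], lang.entries[meanings[j]]
        )
    return D


def _mantel_from_perms(
    lang: Language, perms: np.ndarray, method: str
) -> tuple[float, float, bool]:
    """Observed r and permutation z given an (n_perm, 8) array of reassignments."""
    D = _signal_distance_matrix(lang)
    iu, ju = np.triu_indices(8, k=1)
    x = np.array(
        [meaning_hamming(MEANING_SPACE[i], MEANING_SPACE[j]) for i, j in zip(iu, ju)],
        dtype=float,
    )
    y_obs = D[iu, ju]
    y_perm = D[perms[:, iu], perms[:, ju]]  # (n_perm, 28)

    if method == "spearman":
        x = rankdata(x)
        y_obs = rankdata(y_obs)
        y_perm = np.apply_along_axis(rankdata, 1, y_perm)

    xc = x - x.mean()
    xss = float(xc @ xc)
    if xss == 0 or np.ptp(y_obs) == 0:
        return float("nan"), float("nan"), True

    def pearson(y: np.ndarray) -> np.ndarray:
        yc = y - y.mean(axis=-1, keepdims=True)
        return (yc @ xc) / np.sqrt((yc * yc).sum(axis=-1) * xss)

    r_obs = float(pearson(y_obs[None, :])[0])
    r_perm = pearson(y_perm)
    sd = float(r_perm.std())  # population (n_perm denominator) form
    if sd == 0:
        return r_obs, float("nan"), True
    return r_obs, float((r_obs - r_perm.mean()) / sd), False


def mantel_z(
    lang: Language, n_perm: int = 1000, seed: int | None = None, method: str = "pearson"
) -> MantelResult:
    """Mantel z of the nLED-vs-Hamming association, by sampled permutation.

    Signals are randomly reassigned to meanings ``n_perm`` times (uniformly
    with replacement from the 8! reassignments; the observed assignment is
    not forced into the null sample).  Degenerate inputs — zero variance in
    either distance vector — are flagged and carry no z.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(np.arange(8), (n_perm, 1)), axis=1)
    r_obs, z, degenerate = _mantel_from_perms(lang, perms, method)
    return MantelResult(r_observed=r_obs, z=z, n_perm=n_perm, seed=seed, degenerate=degenerate)


def mantel_z_exact(lang: Language, method: str = "pearson") -> MantelResult:
    """Mantel z with the permutation distribution over all 8! = 40,320 reassignments."""
    perms = np.array(list(itertools.permutations(range(8))), dtype=np.intp)
    r_obs, z, degenerate = _mantel_from_perms(lang, perms, method)
    return MantelResult(
        r_observed=r_obs, z=z, n_perm=len(perms), seed=None, degenerate=degenerate
    )
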