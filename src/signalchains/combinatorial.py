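"""Combinatorial structure via minimum-description-length n-gram compression.

A signaling system is combinatorial when meaningless sub-units (n-grams)
are reused across signals.  The combinatorial coefficient (CC) quantifies
this in two steps:

1. Greedy MDL compression: repeatedly find the n-gram whose substitution
   by a fresh dictionary symbol most shortens the total description
   (recoded signals plus dictionary entries), until no substitution helps.
   For ``L = {0010, 0100, 0011, 0101}`` the bigram ``01`` is substituted
   (``A``), recoding L as ``{A:01, 0A0, A00, 0A1, AA}`` — description
   length 16 -> 15.
2. A recombination index on the compressed language: the mean, over
   dictionary units, of the fraction of other signals sharing that unit,
   ``mean((s_u - 1) / (S - 1))`` with ``s_u`` the number of signals whose
   expansion uses unit ``u`` and ``S`` the number of signals.

CC is 0 for a language whose best compression has an empty dictionary and
1 when every discovered unit recurs in every signal.
"""

from __future__ import annotations

import math
import string
from dataclasses import dataclass
from typing import Iterable, Sequence

from .core import ALPHABET, Language

#: Dictionary symbols in introduction order; never collides with {0, 1}.
UNIT_NAMES = string.ascii_uppercase + string.ascii_lowercase


@dataclass(frozen=True)
class DictionaryUnit:
    """A named n-gram: ``name`` is a single symbol outside the signal alphabet."""

    name: str
    gram: str

    def __post_init__(self) -> None:
        if len(self.name) != 1 or self.name in ALPHABET:
            raise ValueError(f"unit name must be one non-alphabet symbol, got {self.name!r}")
        if len(self.gram) < 2:
            raise ValueError("unit gram must have length >= 2")

    @property
    def cost(self) -> int:
        """Symbols this entry adds to the description: name + delimiter + gram."""
        return 2 + len(self.gram)


@dataclass
class CompressedLanguage:
    """Result of MDL compression: dictionary plus recoded signals.

    ``recoded[i]`` is ``signals[i]`` with unit names substituted; expanding
    all names (latest unit first — earlier grams cannot contain later
    names) recovers ``signals[i]`` exactly.
    """

    signals: list[str]
    units: list[DictionaryUnit]
    recoded: list[str]

    @property
    def description_length(self) -> int:
        return description_length(self)

    def expand(self, recoded_signal: str) -> str:
        s = recoded_signal
        for u in reversed(self.units):
            s = s.replace(u.name, u.gram)
        return s


def _as_signals(lang: "Language | Iterable[str]") -> list[str]:
    if isinstance(lang, Language):
        return [str(s) for s in lang.signals()]
    return [str(s) for s in lang]


def candidate_ngrams(
    signals: Iterable[str], min_len: int = 2, max_len: int | None = None
) -> set[str]:
    """All contiguous substrings of any signal with length in [min_len, max_len]."""
    sigs = _as_signals(signals)
    if min_len < 2:
        raise ValueError("min_len must be >= 2; a length-1 unit is a literal")
    if max_len is None:
        max_len = max((len(s) for s in sigs), default=0)
    grams: set[str] = set()
    for s in sigs:
        for n in range(min_len, min(max_len, len(s)) + 1):
            for i in range(len(s) - n + 1):
                grams.add(s[i : i + n])
    return grams


def recode(signals: Sequence[str], gram: str, name: str) -> list[str]:
    """Replace non-overlapping occurrences of ``gram`` by ``name``, leftmost-greedy."""
    used = set().union(*(set(s) for s in signals)) if signals else set()
    if name in used or name in ALPHABET:
        raise ValueError(f"unit name {name!r} collides with an existing symbol")
    return [s.replace(gram, name) for s in signals]


def description_length(cl: CompressedLanguage) -> int:
    """Total symbol count: recoded signals plus, per unit, name + delimiter + gram."""
    return sum(len(s) for s in cl.recoded) + sum(u.cost for u in cl.units)


def raw_description_length(signals: "Language | Iterable[str]") -> int:
    """Description length of an uncompressed language: the plain sum of signal lengths."""
    return sum(len(s) for s in _as_signals(signals))


def best_compression(lang: "Language | Iterable[str]") -> CompressedLanguage:
    """Greedy MDL search for the best dictionary recoding of a language.

    Each round evaluates every candidate n-gram (length >= 2) over the
    current working alphabet — literals plus previously introduced unit
    names — and applies the substitution giving the minimal description
    length, provided it is a strict improvement.  Ties break toward the
    shorter gram, then lexicographically.  The loop repeats on the recoded
    signals until no substitution shortens the description; the returned
    fixed point is deterministic.
    """
    signals = _as_signals(lang)
    work = list(signals)
    units: list[DictionaryUnit] = []
    name_iter = iter(UNIT_NAMES)

    while True:
        current = sum(len(s) for s in work) + sum(u.cost for u in units)
        try:
            name = next(name_iter)
        except StopIteration:  # pragma: no cover - would need >52 units
            break
        best: tuple[int, int, str] | None = None
        best_recoded: list[str] | None = None
        for gram in sorted(candidate_ngrams(work)):
            recoded = [s.replace(gram, name) for s in work]
            dl = (
                sum(len(s) for s in recoded)
                + sum(u.cost for u in units)
                + 2
                + len(gram)
            )
            key = (dl, len(gram), gram)
            if best is None or key < best:
                best = key
                best_recoded = recoded
        if best is None or best[0] >= current:
            break
        units.append(DictionaryUnit(name=name, gram=best[2]))
        work = best_recoded  # type: ignore[assignment]

    return CompressedLanguage(signals=signals, units=units, recoded=work)


def _units_used(cl: CompressedLanguage, recoded_signal: str) -> set[str]:
    """Names of all units a recoded signal's recursive expansion goes through."""
    by_name = {u.name: u for u in cl.units}
    used: set[str] = set()
    frontier = [recoded_signal]
    while frontier:
        s = frontier.pop()
        for ch in set(s):
            if ch in by_name and ch not in used:
                used.add(ch)
                frontier.append(by_name[ch].gram)
    return used


def recombination_index(cl: CompressedLanguage) -> float:
    """Mean propensity of dictionary units to be reused across signals.

    For each unit ``u``, ``s_u`` counts the distinct signals whose
    expansion uses ``u``; the index is ``mean((s_u - 1) / (S - 1))`` over
    units, 0 for an empty dictionary.  A unit that was absorbed into a
    later unit's gram is credited to every signal using that later unit.
    Returns NaN when fewer than two signals are present (undefined).
    """
    S = len(cl.recoded)
    if S < 2:
        return math.nan
    if not cl.units:
        return 0.0
    usage = [_units_used(cl, r) for r in cl.recoded]
    shares = []
    for u in cl.units:
        s_u = sum(u.name in used for used in usage)
        shares.append((s_u - 1) / (S - 1))
    return float(sum(shares) / len(shares))


def combinatorial_coefficient(lang: "Language | Iterable[str]") -> float:
    """CC: the recombination index of the best-compressed language, in [0, 1].

    The search's lexicographic tie-break is not equivariant under a global
    0<->1 relabeling (complementary grams tie), so the signals are first
    mapped to a canonical labeling — the relabeling whose sorted signal
    list is lexicographically smallest — making CC relabel-invariant.
    """
    sigs = _as_signals(lang)
    flipped = [s.translate(str.maketrans("01", "10")) for s in sigs]
    if sorted(flipped) < sorted(sigs):
        sigs = flipped
    return recombination_index(best_compression(sigs))


def brute_force_description_length(
    signals: Iterable[str], max_units: int = 2
) -> int:
    """Exhaustive oracle: minimal description length over every sequence of
    up to ``max_units`` unit introductions.  Exponential; for tiny inventories
    only (tests)."""
    sigs = _as_signals(signals)

    def search(work: list[str], units: list[DictionaryUnit], depth: int) -> int:
        dl = sum(len(s) for s in work) + sum(u.cost for u in units)
        if depth == 0:
            return dl
        best = dl
        name = UNIT_NAMES[len(units)]
        for gram in candidate_ngrams(work):
            recoded = [s.replace(gram, name) for s in work]
            best = min(
                best,
                search(recoded, units + [DictionaryUnit(name, gram)], depth - 1),
            )
        return best

    return search(sigs, [], max_units)
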