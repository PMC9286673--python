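"""Domain types and chain-table I/O for iterated-learning transmission chains.

The experimental design: eight meanings crossing three binary features
(size, shape, brightness) are paired with binary signal strings over the
alphabet ``{"0", "1"}``.  One learner's eight productions form a
:class:`Language`; the ordered sequence of languages along a lineage of
learners forms a :class:`Chain`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import pandas as pd

ALPHABET = ("0", "1")

SIZES = ("small", "large")
SHAPES = ("round", "spiky")
BRIGHTNESSES = ("light", "dark")


class SignalError(ValueError):
    """A signal string violates the alphabet or length constraints."""


class ChainFormatError(ValueError):
    """A chain table cannot be parsed into valid chains."""


class Signal(str):
    """A binary signal: a non-empty string over ``{"0", "1"}``.

    Subclasses :class:`str`, so all string operations apply; construction
    validates the alphabet.
    """

    def __new__(cls, symbols: str) -> "Signal":
        s = str(symbols)
        if len(s) < 1:
            raise SignalError("signal must contain at least one symbol")
        bad = set(s) - set(ALPHABET)
        if bad:
            raise SignalError(
                f"signal {s!r} contains non-alphabet symbols {sorted(bad)}"
            )
        return super().__new__(cls, s)


@dataclass(frozen=True, order=True)
class Meaning:
    """A point in the 2x2x2 meaning space.

    The integer id is the 3-bit encoding (size, shape, brightness) with
    large/spiky/dark mapping to 1; ``(small, round, light)`` is meaning 0
    and ``(large, spiky, dark)`` is meaning 7.  All pairwise (Hamming)
    structure is invariant to which level of each feature is the reference,
    so the choice is a pure labeling convention.
    """

    size: str
    shape: str
    brightness: str

    def __post_init__(self) -> None:
        if self.size not in SIZES:
            raise ValueError(f"size must be one of {SIZES}, got {self.size!r}")
        if self.shape not in SHAPES:
            raise ValueError(f"shape must be one of {SHAPES}, got {self.shape!r}")
        if self.brightness not in BRIGHTNESSES:
            raise ValueError(
                f"brightness must be one of {BRIGHTNESSES}, got {self.brightness!r}"
            )

    @property
    def bits(self) -> tuple[int, int, int]:
        """3-bit feature vector in fixed order (size, shape, brightness)."""
        return (
            SIZES.index(self.size),
            SHAPES.index(self.shape),
            BRIGHTNESSES.index(self.brightness),
        )

    @property
    def id(self) -> int:
        b = self.bits
        return (b[0] << 2) | (b[1] << 1) | b[2]

    @classmethod
    def from_id(cls, meaning_id: int) -> "Meaning":
        if not 0 <= meaning_id <= 7:
            raise ValueError(f"meaning id must be 0..7, got {meaning_id}")
        return cls(
            size=SIZES[(meaning_id >> 2) & 1],
            shape=SHAPES[(meaning_id >> 1) & 1],
            brightness=BRIGHTNESSES[meaning_id & 1],
        )


#: The full meaning space, in id order 0..7.
MEANING_SPACE: tuple[Meaning, ...] = tuple(
    Meaning(size=s, shape=sh, brightness=b)
    for s, sh, b in itertools.product(SIZES, SHAPES, BRIGHTNESSES)
)


def encode_meaning(m: Meaning) -> tuple[int, int, int]:
    """Encode a meaning as its 3-bit feature vector (size, shape, brightness)."""
    return m.bits


@dataclass
class Language:
    """The eight meaning -> signal pairs produced by one generation."""

    entries: dict[Meaning, Signal]

    def __post_init__(self) -> None:
        self.entries = {m: Signal(s) for m, s in self.entries.items()}

    @classmethod
    def from_signals(cls, signals: "list[str] | dict[int, str]") -> "Language":
        """Build a language from signals given in meaning-id order (or keyed by id)."""
        if isinstance(signals, dict):
            items = signals.items()
        else:
            items = enumerate(signals)
        return cls({Meaning.from_id(i): Signal(s) for i, s in items})

    def signal(self, m: Meaning) -> Signal:
        return self.entries[m]

    def signals(self) -> list[Signal]:
        """Signals in canonical meaning-id order (only present meanings)."""
        return [self.entries[m] for m in sorted(self.entries, key=lambda m: m.id)]

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Language) and self.entries == other.entries


@dataclass
class ValidationReport:
    """Diagnostics from :func:`validate_language`; empty lists mean a clean language."""

    missing_meanings: list[Meaning] = field(default_factory=list)
    duplicate_signals: list[tuple[Signal, list[Meaning]]] = field(default_factory=list)
    empty_signals: list[Meaning] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (self.missing_meanings or self.duplicate_signals or self.empty_signals)


def validate_language(lang: Language, require_unique: bool = True) -> ValidationReport:
    """Diagnose a language against the design constraints.

    Reports missing meanings, empty signals and — when ``require_unique`` —
    signals shared by several meanings (the experiment's ambiguity filter
    forced all eight test-phase productions to be pairwise distinct).
    """
    report = ValidationReport()
    for m in MEANING_SPACE:
        if m not in lang.entries:
            report.missing_meanings.append(m)
        elif len(lang.entries[m]) == 0:  # unreachable via Signal, defensive
            report.empty_signals.append(m)
    if require_unique:
        by_signal: dict[Signal, list[Meaning]] = {}
        for m in sorted(lang.entries, key=lambda m: m.id):
            by_signal.setdefault(lang.entries[m], []).append(m)
        for sig, ms in by_signal.items():
            if len(ms) > 1:
                report.duplicate_signals.append((sig, ms))
    return report


@dataclass
class GenerationRecord:
    """One generation of a chain: the language plus per-generation metadata.

    Generation 0 is the experimenter-seeded language; it has no learner and
    therefore no trials-to-criterion or self-comprehension selections.
    """

    generation: int
    language: Language
    trials_to_criterion: int | None = None
    selections: list[tuple[Meaning, Meaning]] | None = None

    def __post_init__(self) -> None:
        if self.generation < 0:
            raise ValueError("generation must be >= 0")
        if self.generation == 0 and self.trials_to_criterion is not None:
            raise ValueError("generation 0 is the seed language; it has no training")


@dataclass
class Chain:
    """An ordered lineage of generations sharing one condition label."""

    chain_id: str
    condition: str
    records: list[GenerationRecord]

    def __post_init__(self) -> None:
        gens = [r.generation for r in self.records]
        if gens != sorted(gens) or len(set(gens)) != len(gens):
            raise ValueError(f"chain {self.chain_id}: generations must strictly increase")

    @property
    def n_generations(self) -> int:
        return len(self.records)


_CSV_COLUMNS = [
    "chain_id",
    "condition",
    "generation",
    "meaning_id",
    "size",
    "shape",
    "brightness",
    "signal",
    "trials_to_criterion",
]


def write_chain_table(chains: list[Chain], path) -> str:
    """Write chains to a CSV, one row per (chain, generation, meaning).

    Row order is deterministic: chain id, generation, meaning id.  The
    trials-to-criterion cell repeats on each of a generation's eight rows
    and is empty for generation 0.
    """
    rows = []
    for chain in sorted(chains, key=lambda c: str(c.chain_id)):
        for rec in chain.records:
            for m in sorted(rec.language.entries, key=lambda m: m.id):
                rows.append(
                    {
                        "chain_id": chain.chain_id,
                        "condition": chain.condition,
                        "generation": rec.generation,
                        "meaning_id": m.id,
                        "size": m.size,
                        "shape": m.shape,
                        "brightness": m.brightness,
                        "signal": str(rec.language.entries[m]),
                        "trials_to_criterion": rec.trials_to_criterion,
                    }
                )
    df = pd.DataFrame(rows, columns=_CSV_COLUMNS)
    # pandas would otherwise float-format the nullable trials column
    df["trials_to_criterion"] = df["trials_to_criterion"].astype("Int64")
    df.to_csv(path, index=False)
    return str(path)


def read_chain_table(path) -> list[Chain]:
    """Read a chain CSV (schema of :func:`write_chain_table`) into chains.

    Raises
    ------
    ChainFormatError
        If a required column is missing, a signal contains a non-alphabet
        character, or a (chain, generation, meaning) triple is duplicated.
    """
    df = pd.read_csv(path, dtype={"signal": str, "chain_id": str, "condition": str})
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ChainFormatError(f"chain table missing columns: {missing}")

    dup = df.duplicated(subset=["chain_id", "generation", "meaning_id"])
    if dup.any():
        row = int(df.index[dup][0])
        raise ChainFormatError(
            f"duplicate (chain, generation, meaning) at data row {row}: "
            f"{df.loc[row, ['chain_id', 'generation', 'meaning_id']].tolist()}"
        )

    chains: list[Chain] = []
    for chain_id, cdf in df.groupby("chain_id", sort=True):
        conditions = cdf["condition"].unique()
        if len(conditions) != 1:
            raise ChainFormatError(
                f"chain {chain_id} has multiple conditions: {sorted(conditions)}"
            )
        records = []
        for gen, gdf in sorted(cdf.groupby("generation"), key=lambda kv: kv[0]):
            entries = {}
            for idx, row in gdf.iterrows():
                try:
                    sig = Signal(row["signal"])
                except SignalError as exc:
                    raise ChainFormatError(f"data row {idx}: {exc}") from exc
                entries[Meaning.from_id(int(row["meaning_id"]))] = sig
            trials = gdf["trials_to_criterion"].iloc[0]
            trials = None if pd.isna(trials) else int(trials)
            records.append(
                GenerationRecord(
                    generation=int(gen),
                    language=Language(entries),
                    trials_to_criterion=trials if int(gen) > 0 else None,
                )
            )
        chains.append(Chain(chain_id=str(chain_id), condition=str(conditions[0]), records=records))
    return chains
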