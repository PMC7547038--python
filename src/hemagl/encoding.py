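"""Parsing letter sequences into components and encoding them as traces.

A sequence is parsed into components according to a *scheme*:

``bigram``
    The sequence is wrapped in start/end markers and split into its
    adjacent bigrams: ``XXVT`` -> ``sX, XX, XV, VT, Te``.  This is the
    standard-AGL representation (q = 2 with boundary positions).
``repetition``
    The sequence is recoded by whether each adjacent letter pair is an
    immediate repetition (``A``) or not (``B``), wrapped in markers:
    ``XXVT`` -> ``sABBe``.  Components are the single symbols of the
    recoded string (q = 1; each symbol already reflects a bigram of the
    original letters).  Because the recode only depends on *equality* of
    adjacent letters it is invariant under any relabeling of the alphabet,
    which is what carries knowledge across a letter-set change (transfer).
``letters``
    Raw single letters, no markers (q = 1 on the surface string).
``trigram``
    Marker-padded adjacent trigrams (q = 3).

``g`` components are sampled from the parse (without replacement when
possible, with replacement when the sequence has fewer than ``g``
components), each bigram/trigram is bound by directed convolution, the
results are summed, and the sum is degraded by keeping each coordinate with
probability ``L`` (else zeroing it).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .hrr import Lexicon, dirconv

__all__ = [
    "SequenceItem",
    "Component",
    "Trace",
    "SCHEMES",
    "parse_bigrams",
    "recode_repetitions",
    "parse_components",
    "sample_components",
    "encode_trace",
    "read_items",
    "write_items",
]

SCHEMES = ("bigram", "repetition", "letters", "trigram")

START = "s"
END = "e"


@dataclass(frozen=True)
class SequenceItem:
    """One letter string with its grammaticality label and phase."""

    letters: tuple[str, ...]
    label: str = "training"  # training | grammatical | ungrammatical
    phase: str = "train"  # train | test

    def __post_init__(self) -> None:
        if not self.letters:
            raise ValueError("letters must be non-empty")

    @classmethod
    def from_string(cls, s: str, label: str = "training", phase: str = "train"):
        return cls(letters=tuple(s), label=label, phase=phase)

    @property
    def string(self) -> str:
        return "".join(self.letters)

    def __len__(self) -> int:
        return len(self.letters)


@dataclass(frozen=True)
class Component:
    kind: str  # bigram | unigram | trigram
    symbols: tuple[str, ...]

    def __post_init__(self) -> None:
        expected = {"unigram": 1, "bigram": 2, "trigram": 3}[self.kind]
        if len(self.symbols) != expected:
            raise ValueError(f"{self.kind} needs {expected} symbols")


@dataclass(frozen=True)
class Trace:
    """Stored (possibly degraded) vector representation of one sequence."""

    values: np.ndarray
    source: str
    L_applied: float
    components_used: tuple[Component, ...]


def parse_bigrams(item: SequenceItem) -> list[Component]:
    """Marker-padded bigram parse; a length-m string yields m+1 bigrams."""
    padded = (START,) + item.letters + (END,)
    return [
        Component("bigram", (padded[i], padded[i + 1]))
        for i in range(len(padded) - 1)
    ]


def recode_repetitions(item: SequenceItem) -> SequenceItem:
    """Recode adjacent pairs as repetition (A) / non-repetition (B).

    ``XXVT`` becomes ``sABBe``.  Requires at least two letters (one pair).
    """
    if len(item.letters) < 2:
        raise ValueError("repetition recode needs at least 2 letters")
    code = tuple(
        "A" if a == b else "B" for a, b in zip(item.letters, item.letters[1:])
    )
    return SequenceItem(
        letters=(START,) + code + (END,), label=item.label, phase=item.phase
    )


def _parse_trigrams(item: SequenceItem) -> list[Component]:
    padded = (START,) + item.letters + (END,)
    return [
        Component("trigram", padded[i : i + 3]) for i in range(len(padded) - 2)
    ]


def parse_components(item: SequenceItem, scheme: str) -> list[Component]:
    """Parse an item into its components under the given scheme."""
    if scheme == "bigram":
        return parse_bigrams(item)
    if scheme == "repetition":
        recoded = recode_repetitions(item)
        return [Component("unigram", (c,)) for c in recoded.letters]
    if scheme == "letters":
        return [Component("unigram", (c,)) for c in item.letters]
    if scheme == "trigram":
        return _parse_trigrams(item)
    raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")


def sample_components(
    components: list[Component], g: int, rng: np.random.Generator
) -> list[Component]:
    """Sample g components: without replacement if possible, else with."""
    if not components:
        raise ValueError("components must be non-empty")
    if g < 1:
        raise ValueError("g must be >= 1")
    if len(components) >= g:
        idx = rng.permutation(len(components))[:g]
    else:
        idx = rng.integers(0, len(components), size=g)
    return [components[i] for i in idx]


def _bind(component: Component, lex: Lexicon) -> np.ndarray:
    if component.kind == "unigram":
        return lex[component.symbols[0]].copy()
    vec = lex[component.symbols[0]]
    for sym in component.symbols[1:]:
        vec = dirconv(vec, lex[sym], lex)
    return vec


def encode_trace(
    item: SequenceItem,
    scheme: str,
    g: int,
    L: float,
    lex: Lexicon,
    rng: np.random.Generator,
) -> Trace:
    """Parse, sample g components, bind, sum, and degrade into a trace.

    Each coordinate of the summed vector is retained with probability ``L``
    and zeroed otherwise (independent Bernoulli mask per coordinate per
    trace), so a trace keeps an expected proportion L of its features.
    """
    if not 0.0 <= L <= 1.0:
        raise ValueError("L must lie in [0, 1]")
    components = parse_components(item, scheme)
    chosen = sample_components(components, g, rng)
    total = np.zeros(lex.n)
    for comp in chosen:
        total += _bind(comp, lex)
    mask = rng.random(lex.n) < L
    return Trace(
        values=total * mask,
        source=item.string,
        L_applied=L,
        components_used=tuple(chosen),
    )


def read_items(path: str | Path) -> list[SequenceItem]:
    """Read an item list from TSV with columns sequence, label, phase."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = {"sequence", "label", "phase"} - set(df.columns)
    if missing:
        raise ValueError(f"item TSV missing columns: {sorted(missing)}")
    return [
        SequenceItem.from_string(row.sequence, label=row.label, phase=row.phase)
        for row in df.itertuples()
    ]


def write_items(
    items: list[SequenceItem], path: str | Path, header: str | None = None
) -> None:
    """Write items as TSV; ``header`` adds a leading ``#`` provenance line."""
    df = pd.DataFrame(
        {
            "sequence": [it.string for it in items],
            "label": [it.label for it in items],
            "phase": [it.phase for it in items],
        }
    )
    with open(path, "w") as fh:
        if header:
            fh.write(header if header.endswith("\n") else header + "\n")
        df.to_csv(fh, sep="\t", index=False)
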