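"""Synthetic finite-state-grammar materials for AGL simulations.

Generates training strings, grammatical/ungrammatical test strings, and
letter-remapped transfer sets from a small finite-state grammar.  The
default grammar is a 5-state machine over {M, V, X, T, R} whose self-loops
produce immediate letter repetitions, so that repetition coding remains
diagnostic after the letters are remapped.

Ungrammatical items are built from grammatical strings by substituting one
interior letter so that (a) the result contains at least one bigram that
occurs in no accepted string of the sampled length range and (b) the
grammar rejects the result.  Substitutions that perturb the string's
repetition code (its pattern of immediate letter doublings) are preferred:
doubling a letter that the grammar never doubles yields a bigram that is
unattested *and* shifts the item's repetition statistics away from the
training distribution, which keeps violations detectable after a letter
remapping erases all surface overlap.

Two structural properties are asserted at generation time (resampling until
they hold): grammatical test items share more bigram types with the
training set than ungrammatical ones do on average, and the mean
repetition rate of grammatical test items sits closer to the training
items' repetition rate than that of ungrammatical ones.  These are the
similarity asymmetries an exemplar account needs in order to discriminate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .encoding import SequenceItem

__all__ = [
    "Grammar",
    "ItemSet",
    "default_grammar",
    "default_transfer_mapping",
    "generate_items",
    "remap_letters",
]


@dataclass(frozen=True)
class Grammar:
    """Finite-state grammar: transitions are (state, letter, state) triples.

    A string is grammatical iff it labels some path from ``start`` to
    ``end``.  The end state should have no outgoing transitions.
    """

    transitions: tuple[tuple[int, str, int], ...]
    start: int
    end: int
    alphabet: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "alphabet", tuple(sorted({l for _, l, _ in self.transitions}))
        )

    def _out(self, state: int) -> list[tuple[str, int]]:
        return [(l, b) for a, l, b in self.transitions if a == state]

    def accepts(self, s: str) -> bool:
        """Path-membership test by forward state-set propagation."""
        states = {self.start}
        for ch in s:
            states = {b for a, l, b in self.transitions if a in states and l == ch}
            if not states:
                return False
        return self.end in states

    def enumerate_strings(self, min_len: int, max_len: int) -> list[str]:
        """All accepted strings with lengths in [min_len, max_len]."""
        found: list[str] = []

        def dfs(state: int, s: str) -> None:
            if state == self.end and min_len <= len(s) <= max_len:
                found.append(s)
            if len(s) >= max_len:
                return
            for l, b in self._out(state):
                dfs(b, s + l)

        dfs(self.start, "")
        return sorted(set(found))

    def generate(
        self, rng: np.random.Generator, min_len: int, max_len: int,
        max_tries: int = 10_000,
    ) -> str:
        """Random accepted string in the length range, by random walk."""
        for _ in range(max_tries):
            state, s = self.start, ""
            while state != self.end and len(s) <= max_len:
                options = self._out(state)
                if not options:
                    break
                l, state = options[rng.integers(len(options))]
                s += l
            if state == self.end and min_len <= len(s) <= max_len:
                return s
        raise RuntimeError("could not generate a string in the length range")

    def to_dict(self) -> dict:
        return {
            "start": self.start,
            "end": self.end,
            "transitions": [list(t) for t in self.transitions],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Grammar":
        return cls(
            transitions=tuple((int(a), str(l), int(b)) for a, l, b in d["transitions"]),
            start=int(d["start"]),
            end=int(d["end"]),
        )


def default_grammar() -> Grammar:
    """Five-state loop-bearing grammar over {M, V, X, T, R}.

    The self-loops on T and X yield immediate repetitions (TT..., XX...) in
    roughly half of the accepted strings of length 3-8.
    """
    return Grammar(
        transitions=(
            (1, "M", 2),
            (1, "V", 3),
            (2, "T", 2),
            (2, "X", 4),
            (3, "X", 3),
            (3, "R", 4),
            (4, "M", 3),
            (4, "V", 5),
            (4, "T", 5),
        ),
        start=1,
        end=5,
    )


def default_transfer_mapping() -> dict[str, str]:
    """Bijection onto letters unused at training (avoids s, e, A, B)."""
    return {"M": "F", "V": "G", "X": "H", "T": "J", "R": "K"}


@dataclass(frozen=True)
class ItemSet:
    """Training items plus labeled test items under one alphabet mapping."""

    train: tuple[SequenceItem, ...]
    test: tuple[SequenceItem, ...]
    mapping: dict[str, str] | None = None  # None = identity (standard AGL)

    def __post_init__(self) -> None:
        if any(it.label != "training" for it in self.train):
            raise ValueError("train items must all be labeled 'training'")


def _bigram_types(s: str) -> set[str]:
    p = "s" + s + "e"
    return {p[i : i + 2] for i in range(len(p) - 1)}


def _repetition_count(s: str) -> int:
    return sum(1 for a, b in zip(s, s[1:]) if a == b)


def _make_violation(
    s: str,
    grammar: Grammar,
    legal_bigrams: set[str],
    rng: np.random.Generator,
) -> str | None:
    """Substitute one interior letter to create an unattested bigram.

    Candidates that *add* immediate repetitions are preferred: the grammar
    only doubles letters on its self-loops, so a spurious doubling is both
    an unattested bigram and a shift of the item's repetition code away
    from the training distribution (diagnostic under transfer).  Returns
    None if no valid substitution exists for this string.
    """
    base_reps = _repetition_count(s)
    candidates: list[tuple[int, str]] = []
    interior = range(1, len(s) - 1)
    for i in interior:
        for letter in grammar.alphabet:
            if letter == s[i]:
                continue
            t = s[:i] + letter + s[i + 1 :]
            if _bigram_types(t) <= legal_bigrams:
                continue  # all bigrams attested: too weak a violation
            if grammar.accepts(t):
                continue
            candidates.append((_repetition_count(t), t))
    if not candidates:
        return None
    more = [t for r, t in candidates if r > base_reps]
    pool = more or [t for _, t in candidates]
    return pool[rng.integers(len(pool))]


def generate_items(
    grammar: Grammar,
    n_train: int = 20,
    n_test_per_class: int = 16,
    length_range: tuple[int, int] = (3, 8),
    rng: np.random.Generator | None = None,
    max_attempts: int = 50,
) -> ItemSet:
    """Sample a training set and a balanced grammatical/ungrammatical test set.

    Training and grammatical-test strings are distinct draws from the
    grammar's accepted language.  The set is resampled (up to
    ``max_attempts``) until the bigram-overlap and repetition asymmetries
    described in the module docstring hold.
    """
    if rng is None:
        rng = np.random.default_rng()
    lo, hi = length_range
    language = grammar.enumerate_strings(lo, hi)
    needed = n_train + n_test_per_class
    if len(language) < needed:
        raise ValueError(
            f"grammar yields only {len(language)} strings of length {lo}-{hi}; "
            f"{needed} distinct grammatical strings requested"
        )
    legal_bigrams = {bg for s in language for bg in _bigram_types(s)}

    for _ in range(max_attempts):
        chosen = rng.choice(len(language), size=needed, replace=False)
        strings = [language[i] for i in chosen]
        train_strings = strings[:n_train]
        gram_test = strings[n_train:]

        ungram_test: list[str] = []
        source_pool = list(rng.permutation(strings))
        for src in source_pool + strings:  # second pass reuses sources if needed
            v = _make_violation(src, grammar, legal_bigrams, rng)
            if v is not None and v not in ungram_test:
                ungram_test.append(v)
            if len(ungram_test) == n_test_per_class:
                break
        if len(ungram_test) < n_test_per_class:
            continue

        train_bigrams = {bg for s in train_strings for bg in _bigram_types(s)}
        gram_overlap = np.mean(
            [len(_bigram_types(s) & train_bigrams) for s in gram_test]
        )
        ungram_overlap = np.mean(
            [len(_bigram_types(s) & train_bigrams) for s in ungram_test]
        )
        train_rep_rate = np.mean(
            [_repetition_count(s) / (len(s) - 1) for s in train_strings]
        )
        gram_rep_dist = abs(
            np.mean([_repetition_count(s) / (len(s) - 1) for s in gram_test])
            - train_rep_rate
        )
        ungram_rep_dist = abs(
            np.mean([_repetition_count(s) / (len(s) - 1) for s in ungram_test])
            - train_rep_rate
        )
        if gram_overlap <= ungram_overlap or gram_rep_dist >= ungram_rep_dist:
            continue

        train = tuple(
            SequenceItem.from_string(s, "training", "train") for s in train_strings
        )
        test_items = [
            SequenceItem.from_string(s, "grammatical", "test") for s in gram_test
        ] + [
            SequenceItem.from_string(s, "ungrammatical", "test") for s in ungram_test
        ]
        order = rng.permutation(len(test_items))
        test = tuple(test_items[i] for i in order)
        return ItemSet(train=train, test=test, mapping=None)

    raise RuntimeError(
        "could not generate an item set with the required similarity "
        f"structure in {max_attempts} attempts"
    )


def remap_letters(items: ItemSet, mapping: dict[str, str]) -> ItemSet:
    """Apply a bijective letter remapping to the *test* items (transfer).

    The mapping's image must be disjoint from its domain (the whole point of
    transfer is that test letters were unseen at training); labels are
    preserved.  Training items keep the original alphabet.
    """
    if len(set(mapping.values())) != len(mapping):
        raise ValueError("mapping must be a bijection")
    if set(mapping) & set(mapping.values()):
        raise ValueError("mapping image must be disjoint from its domain")
    used = {l for it in items.test for l in it.letters}
    if not used <= set(mapping):
        raise ValueError(f"mapping does not cover letters {sorted(used - set(mapping))}")
    test = tuple(
        SequenceItem(
            letters=tuple(mapping[l] for l in it.letters),
            label=it.label,
            phase=it.phase,
        )
        for it in items.test
    )
    return ItemSet(train=items.train, test=test, mapping=dict(mapping))
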