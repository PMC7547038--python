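"""Exemplar retrieval (echo and intensity), trial loops, and scoring.

The memory model follows the Minerva-II / holographic-exemplar lineage: a
probe activates every stored trace as an odd power of its cosine similarity,
the activation-weighted sum of traces forms the *echo*, and the cosine
between echo and probe — the *intensity* — is the evidence on which a
sequence is called grammatical.  The decision criterion is placed
retrospectively at the percentile of each participant's intensity
distribution that yields a target endorsement rate.

Three model variants cross test learning with probe degradation:

* ``HEM-TC`` — learns at test; the classified probe is degraded by L_test.
* ``HEM-T``  — learns at test; classifies the intact probe, stores a
  degraded copy afterwards.
* ``HEM-C``  — no test learning; the classified probe is degraded by L_test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import engine
from .encoding import SequenceItem, Trace
from .hrr import cosine

__all__ = [
    "MemoryStore",
    "ModelConfig",
    "ParticipantResult",
    "echo_intensity",
    "run_participant",
    "set_criterion",
    "score",
]


@dataclass
class MemoryStore:
    """Ordered, append-only store of traces for one participant."""

    traces: list[Trace] = field(default_factory=list)

    def add(self, trace: Trace) -> None:
        self.traces.append(trace)

    def __len__(self) -> int:
        return len(self.traces)

    def matrix(self) -> np.ndarray:
        if not self.traces:
            raise ValueError("memory store is empty")
        return np.stack([t.values for t in self.traces])


@dataclass(frozen=True)
class ModelConfig:
    """Parameters of one simulated participant group.

    ``q`` selects the representational scheme: 2 = marker-padded bigrams
    (standard AGL), 1 = repetition recode (transfer AGL).
    """

    variant: str
    L_train: float
    L_test: float
    g: int
    q: int = 2
    n: int = 100
    sd: float | None = None
    activation_exponent: int = 3
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.variant not in engine.VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        for name in ("L_train", "L_test"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.activation_exponent % 2 != 1 or self.activation_exponent < 1:
            raise ValueError("activation_exponent must be an odd positive integer")

    @property
    def scheme(self) -> str:
        if self.q == 2:
            return "bigram"
        if self.q == 1:
            return "repetition"
        raise ValueError(f"no engine scheme for q={self.q}")


@dataclass(frozen=True)
class ParticipantResult:
    intensities: tuple[float, ...]
    endorsements: tuple[bool, ...]
    criterion: float
    hit_rate: float
    fa_rate: float
    diff: float
    n_stored: int


def echo_intensity(probe, memory: MemoryStore, exponent: int = 3) -> float:
    """Intensity of a probe against a memory store.

    ``probe`` may be a :class:`Trace` or a plain vector.  Each trace is
    activated by cosine(probe, trace)**exponent, the echo is the
    activation-weighted sum of traces, and the intensity is the cosine
    between echo and probe (0 for an all-zero probe or echo).
    """
    if len(memory) == 0:
        raise ValueError("memory store is empty")
    vec = probe.values if isinstance(probe, Trace) else np.asarray(probe, float)
    mat = memory.matrix()
    acts = np.array([cosine(vec, row) ** exponent for row in mat])
    echo = acts @ mat
    return cosine(echo, vec)


def set_criterion(intensities, rate: float) -> tuple[float, list[bool]]:
    """Place the decision criterion to hit a target endorsement rate.

    Endorses exactly ``round(rate * N)`` items (half-up) with the highest
    intensities, breaking ties by presentation order (earlier first).
    Returns the criterion k (smallest endorsed intensity; +inf if nothing is
    endorsed) and the endorsement vector.
    """
    intensities = list(intensities)
    if not intensities:
        raise ValueError("intensities must be non-empty")
    n = len(intensities)
    k_count = engine.endorse_count(rate, n)
    order = sorted(range(n), key=lambda i: (-intensities[i], i))
    endorsed_idx = order[:k_count]
    endorsements = [False] * n
    for i in endorsed_idx:
        endorsements[i] = True
    k = min((intensities[i] for i in endorsed_idx), default=float("inf"))
    return k, endorsements


def score(endorsements, labels) -> tuple[float, float, float]:
    """Hit rate, false-alarm rate and their difference.

    ``labels`` holds ``"grammatical"`` / ``"ungrammatical"`` per item; a hit
    is an endorsed grammatical item, a false alarm an endorsed ungrammatical
    one.
    """
    endorsements = list(endorsements)
    labels = list(labels)
    if len(endorsements) != len(labels):
        raise ValueError("endorsements and labels must have equal length")
    gram = [lab == "grammatical" for lab in labels]
    n_gram = sum(gram)
    n_ungram = len(gram) - n_gram
    if n_gram == 0 or n_ungram == 0:
        raise ValueError("both label classes must be present")
    hits = sum(e and g for e, g in zip(endorsements, gram))
    fas = sum(e and not g for e, g in zip(endorsements, gram))
    hit_rate = hits / n_gram
    fa_rate = fas / n_ungram
    return hit_rate, fa_rate, hit_rate - fa_rate


def results_to_frame(results, condition: str = ""):
    """Tabulate participant results as CSV-ready rows.

    Columns: participant, condition, hit_rate, fa_rate, diff.
    """
    import pandas as pd

    return pd.DataFrame(
        {
            "participant": range(len(results)),
            "condition": condition,
            "hit_rate": [r.hit_rate for r in results],
            "fa_rate": [r.fa_rate for r in results],
            "diff": [r.diff for r in results],
        }
    )


def run_participant(
    variant: str,
    train_items: list[SequenceItem],
    test_items: list[SequenceItem],
    config: ModelConfig,
    endorsement_rate: float,
    rng: np.random.Generator | None = None,
) -> ParticipantResult:
    """Simulate one participant end to end.

    A fresh lexicon is drawn, training items are encoded with ``L_train``
    and stored, then test items are processed in presentation order under
    the given variant's rules.  Thin wrapper over the batch engine with a
    batch of one, so single- and batch-mode simulations share one trial
    loop (and one random-stream contract: with ``L_test = 1`` HEM-TC and
    HEM-T are identical draw for draw).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    compiled = engine.compile_materials(train_items, test_items, config.scheme)
    out = engine.simulate_participants(
        compiled,
        variant,
        L_train=config.L_train,
        L_test=config.L_test,
        g=config.g,
        rate=endorsement_rate,
        n_participants=1,
        n_dim=config.n,
        sd=config.sd,
        exponent=config.activation_exponent,
        rng=rng,
    )
    return ParticipantResult(
        intensities=tuple(float(x) for x in out["intensities"][0]),
        endorsements=tuple(bool(x) for x in out["endorsements"][0]),
        criterion=float(out["criterion"][0]),
        hit_rate=float(out["hit_rate"][0]),
        fa_rate=float(out["fa_rate"][0]),
        diff=float(out["diff"][0]),
        n_stored=int(out["n_stored"]),
    )
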