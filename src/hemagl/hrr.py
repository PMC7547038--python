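"""Holographic reduced representation (HRR) primitives.

Sequences are represented by binding symbol vectors with a *directed*
(non-commutative) circular convolution and superposing the results.  Binding
is made non-commutative by permuting the two operands with two different
fixed permutations before ordinary circular convolution, a standard
construction in vector-symbolic architectures.  Both permutations belong to
the :class:`Lexicon` so that every binding made by one simulated participant
uses the same pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Lexicon", "make_lexicon", "dirconv", "cosine"]


@dataclass(frozen=True)
class Lexicon:
    """Symbol environment of one simulated participant.

    Maps each symbol (letters plus the boundary markers ``s``/``e`` and, for
    repetition coding, ``A``/``B``) to an i.i.d. normal base vector of
    dimensionality ``n``, and carries the two fixed operand permutations used
    by :func:`dirconv`.
    """

    symbols: tuple[str, ...]
    vectors: np.ndarray  # shape (len(symbols), n)
    left_perm: np.ndarray  # permutation of range(n), applied to the left operand
    right_perm: np.ndarray
    n: int
    sd: float
    seed: int | None = None
    _index: dict[str, int] = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self._index:
            object.__setattr__(
                self, "_index", {s: i for i, s in enumerate(self.symbols)}
            )

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._index

    def __getitem__(self, symbol: str) -> np.ndarray:
        try:
            return self.vectors[self._index[symbol]]
        except KeyError:
            raise KeyError(f"unknown symbol {symbol!r}") from None

    def index(self, symbol: str) -> int:
        if symbol not in self._index:
            raise KeyError(f"unknown symbol {symbol!r}")
        return self._index[symbol]

    def to_state(self) -> dict:
        """Serializable recipe: seed, n and sd regenerate the lexicon exactly."""
        return {
            "symbols": list(self.symbols),
            "n": self.n,
            "sd": self.sd,
            "seed": self.seed,
        }

    @classmethod
    def from_state(cls, state: dict) -> "Lexicon":
        return make_lexicon(
            state["symbols"], n=state["n"], sd=state["sd"], seed=state["seed"]
        )


def make_lexicon(
    symbols,
    n: int = 100,
    sd: float | None = None,
    seed: int | None = None,
) -> Lexicon:
    """Draw base vectors and the two binding permutations.

    Each symbol vector holds ``n`` normal deviates with mean 0 and standard
    deviation ``sd`` (default ``1/n``).  Deterministic given ``seed``.
    """
    symbols = tuple(symbols)
    if not symbols:
        raise ValueError("symbols must be non-empty")
    if len(set(symbols)) != len(symbols):
        raise ValueError("symbols must be distinct")
    if n < 2:
        raise ValueError("n must be at least 2")
    if sd is None:
        sd = 1.0 / n
    if sd <= 0:
        raise ValueError("sd must be positive")
    rng = np.random.default_rng(seed)
    vectors = rng.normal(0.0, sd, size=(len(symbols), n))
    left_perm = rng.permutation(n)
    right_perm = rng.permutation(n)
    return Lexicon(
        symbols=symbols,
        vectors=vectors,
        left_perm=left_perm,
        right_perm=right_perm,
        n=n,
        sd=sd,
        seed=seed,
    )


def dirconv(x: np.ndarray, y: np.ndarray, lex: Lexicon) -> np.ndarray:
    """Directed (non-commutative) circular convolution of two vectors.

    Permutes ``x`` by the lexicon's left permutation and ``y`` by its right
    permutation, then circularly convolves.  The FFT fast path is used; it is
    checked against a direct O(n^2) sum in the test suite.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != (lex.n,) or y.shape != (lex.n,):
        raise ValueError(
            f"operands must have length n={lex.n}, got {x.shape} and {y.shape}"
        )
    fx = np.fft.rfft(x[lex.left_perm])
    fy = np.fft.rfft(y[lex.right_perm])
    return np.fft.irfft(fx * fy, n=lex.n)


def cosine(x: np.ndarray, y: np.ndarray) -> float:
    """Vector cosine similarity; 0 by convention if either vector is all-zero."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx = np.linalg.norm(x)
    ny = np.linalg.norm(y)
    if nx == 0.0 or ny == 0.0:
        return 0.0
    return float(np.dot(x, y) / (nx * ny))
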