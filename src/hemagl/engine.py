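"""Vectorised simulation engine for batches of independent participants.

The trial loop is the same for every model variant:

1. draw a fresh lexicon (base vectors + the two binding permutations) per
   participant;
2. encode each training item with learning rate ``L_train`` and store it;
3. walk through the test list in order; for each item draw one component
   sample and one degradation mask, classify by echo intensity, and store
   a degraded copy if the variant learns at test.

Variants differ only in which probe is classified and whether it is stored:

============  =======================  ==============
variant       probe classified          stored at test
============  =======================  ==============
``HEM-TC``    degraded by ``L_test``    yes (degraded)
``HEM-T``     intact (L = 1)            yes (degraded)
``HEM-C``     degraded by ``L_test``    no
============  =======================  ==============

All random draws happen in an order that does not depend on the variant, so
running two variants from the same seed consumes identical random streams;
with ``L_test = 1`` HEM-TC and HEM-T are then numerically identical.

Everything is vectorised over participants: arrays carry a leading batch
axis ``P``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encoding import SequenceItem, parse_components

__all__ = ["CompiledMaterials", "compile_materials", "simulate_participants",
           "endorse_count", "VARIANTS"]

VARIANTS = ("HEM-TC", "HEM-T", "HEM-C")

_ENGINE_SCHEMES = ("bigram", "repetition")


@dataclass(frozen=True)
class CompiledMaterials:
    """Item lists flattened to integer component indices for the engine."""

    scheme: str
    symbols: tuple[str, ...]
    # bigram scheme: (C, 2) symbol-index pairs; repetition: (C,) symbol indices
    comp_defs: np.ndarray
    train_comps: tuple[np.ndarray, ...]  # per item: indices into comp_defs
    test_comps: tuple[np.ndarray, ...]
    grammatical: np.ndarray  # bool per test item

    @property
    def n_train(self) -> int:
        return len(self.train_comps)

    @property
    def n_test(self) -> int:
        return len(self.test_comps)


def compile_materials(
    train_items: list[SequenceItem],
    test_items: list[SequenceItem],
    scheme: str,
) -> CompiledMaterials:
    """Pre-resolve parses and symbol indices shared by all participants."""
    if scheme not in _ENGINE_SCHEMES:
        raise ValueError(
            f"engine supports schemes {_ENGINE_SCHEMES}, got {scheme!r}"
        )
    if not train_items or not test_items:
        raise ValueError("train and test item lists must be non-empty")

    parses = [parse_components(it, scheme) for it in train_items + test_items]
    symbols = sorted({sym for parse in parses for c in parse for sym in c.symbols})
    sym_idx = {s: i for i, s in enumerate(symbols)}

    comp_key: dict[tuple, int] = {}
    defs: list[tuple] = []
    comp_lists: list[np.ndarray] = []
    for parse in parses:
        idxs = []
        for comp in parse:
            key = tuple(sym_idx[s] for s in comp.symbols)
            if key not in comp_key:
                comp_key[key] = len(defs)
                defs.append(key)
            idxs.append(comp_key[key])
        comp_lists.append(np.array(idxs, dtype=np.intp))

    if scheme == "bigram":
        comp_defs = np.array(defs, dtype=np.intp)  # (C, 2)
    else:
        comp_defs = np.array([d[0] for d in defs], dtype=np.intp)  # (C,)

    grammatical = np.array(
        [it.label == "grammatical" for it in test_items], dtype=bool
    )
    if grammatical.all() or not grammatical.any():
        raise ValueError("test items must include both label classes")
    return CompiledMaterials(
        scheme=scheme,
        symbols=tuple(symbols),
        comp_defs=comp_defs,
        train_comps=tuple(comp_lists[: len(train_items)]),
        test_comps=tuple(comp_lists[len(train_items) :]),
        grammatical=grammatical,
    )


def endorse_count(rate: float, n_items: int) -> int:
    """Half-up rounding of the target endorsement rate to an item count."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0, 1]")
    return int(np.floor(rate * n_items + 0.5))


def _component_matrix(
    base: np.ndarray,
    left_perm: np.ndarray,
    right_perm: np.ndarray,
    comp_defs: np.ndarray,
) -> np.ndarray:
    """Directed-convolution vectors for every bigram in ``comp_defs``.

    base: (P, S, n); perms: (P, n); comp_defs: (C, 2) -> returns (P, C, n).
    """
    n = base.shape[-1]
    base_l = np.take_along_axis(base, left_perm[:, None, :], axis=2)
    base_r = np.take_along_axis(base, right_perm[:, None, :], axis=2)
    fl = np.fft.rfft(base_l, axis=-1)
    fr = np.fft.rfft(base_r, axis=-1)
    return np.fft.irfft(fl[:, comp_defs[:, 0], :] * fr[:, comp_defs[:, 1], :],
                        n=n, axis=-1)


def _encode_sum(
    comp_mat: np.ndarray,
    idxs: np.ndarray,
    g: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sum of g sampled component vectors per participant: (P, n).

    Sampling is without replacement when the item has >= g components and
    with replacement otherwise; each participant draws independently.
    """
    P = comp_mat.shape[0]
    c = len(idxs)
    vecs = comp_mat[:, idxs, :]  # (P, c, n)
    if c >= g:
        order = np.argsort(rng.random((P, c)), axis=1)[:, :g]
    else:
        order = rng.integers(0, c, size=(P, g))
    return np.take_along_axis(vecs, order[:, :, None], axis=1).sum(axis=1)


def _batch_echo_intensity(
    probe: np.ndarray,
    memory: np.ndarray,
    mem_norms: np.ndarray,
    exponent: int,
) -> np.ndarray:
    """Echo intensity of one probe per participant against their memories.

    probe: (P, n); memory: (P, M, n); mem_norms: (P, M) -> intensity (P,).
    Activation is cosine similarity raised to an odd power (sign-preserving);
    the echo is the activation-weighted sum of traces; intensity is the
    cosine between echo and probe.  All-zero probes or traces contribute 0.
    """
    probe_norm = np.linalg.norm(probe, axis=1)  # (P,)
    dots = np.einsum("pmn,pn->pm", memory, probe)
    denom = mem_norms * probe_norm[:, None]
    sims = np.divide(dots, denom, out=np.zeros_like(dots), where=denom > 0)
    acts = sims**exponent
    echo = np.einsum("pm,pmn->pn", acts, memory)
    echo_norm = np.linalg.norm(echo, axis=1)
    edot = np.einsum("pn,pn->p", echo, probe)
    edenom = echo_norm * probe_norm
    return np.divide(edot, edenom, out=np.zeros_like(edot), where=edenom > 0)


def simulate_participants(
    compiled: CompiledMaterials,
    variant: str,
    *,
    L_train: float,
    L_test: float,
    g: int,
    rate: float,
    n_participants: int,
    n_dim: int = 100,
    sd: float | None = None,
    exponent: int = 3,
    keep_arrays: bool = False,
    rng: np.random.Generator,
) -> dict:
    """Simulate a batch of independent participants under one variant.

    Returns a dict with ``intensities`` (P, T), ``endorsements`` (P, T),
    ``criterion`` (P,), ``hit_rate``, ``fa_rate``, ``diff`` (P,) and
    ``n_stored`` (final memory size, same for every participant).  With
    ``keep_arrays`` the classified probes (P, T, n) and the final memory
    (P, n_stored, n) are returned as well, for inspection and testing.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    for name, L in (("L_train", L_train), ("L_test", L_test)):
        if not 0.0 <= L <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    if g < 1:
        raise ValueError("g must be >= 1")
    if sd is None:
        sd = 1.0 / n_dim

    P = n_participants
    S = len(compiled.symbols)
    n = n_dim
    m_train = compiled.n_train
    T = compiled.n_test

    # Fresh lexicon per participant: base vectors then the two permutations.
    base = rng.normal(0.0, sd, size=(P, S, n))
    left_perm = np.argsort(rng.random((P, n)), axis=1)
    right_perm = np.argsort(rng.random((P, n)), axis=1)

    if compiled.scheme == "bigram":
        comp_mat = _component_matrix(base, left_perm, right_perm, compiled.comp_defs)
    else:
        comp_mat = base[:, compiled.comp_defs, :]

    learns = variant in ("HEM-TC", "HEM-T")
    m_max = m_train + (T if learns else 0)
    memory = np.zeros((P, m_max, n))
    mem_norms = np.zeros((P, m_max))

    for j, idxs in enumerate(compiled.train_comps):
        summed = _encode_sum(comp_mat, idxs, g, rng)
        mask = rng.random((P, n)) < L_train
        trace = summed * mask
        memory[:, j] = trace
        mem_norms[:, j] = np.linalg.norm(trace, axis=1)

    intensities = np.empty((P, T))
    probes = np.empty((P, T, n)) if keep_arrays else None
    count = m_train
    for t, idxs in enumerate(compiled.test_comps):
        summed = _encode_sum(comp_mat, idxs, g, rng)
        mask = rng.random((P, n)) < L_test
        degraded = summed * mask
        probe = summed if variant == "HEM-T" else degraded
        if keep_arrays:
            probes[:, t] = probe
        intensities[:, t] = _batch_echo_intensity(
            probe, memory[:, :count], mem_norms[:, :count], exponent
        )
        if learns:
            memory[:, count] = degraded
            mem_norms[:, count] = np.linalg.norm(degraded, axis=1)
            count += 1

    # Retrospective criterion: endorse the top round(rate*T) intensities,
    # ties broken by presentation order (earlier first).
    k = endorse_count(rate, T)
    order = np.argsort(-intensities, axis=1, kind="stable")
    endorsements = np.zeros((P, T), dtype=bool)
    if k > 0:
        np.put_along_axis(endorsements, order[:, :k], True, axis=1)
        criterion = np.take_along_axis(intensities, order[:, k - 1 : k], axis=1)[:, 0]
    else:
        criterion = np.full(P, np.inf)

    gram = compiled.grammatical
    n_gram = int(gram.sum())
    n_ungram = T - n_gram
    hit_rate = (endorsements & gram).sum(axis=1) / n_gram
    fa_rate = (endorsements & ~gram).sum(axis=1) / n_ungram
    out = {
        "intensities": intensities,
        "endorsements": endorsements,
        "criterion": criterion,
        "hit_rate": hit_rate,
        "fa_rate": fa_rate,
        "diff": hit_rate - fa_rate,
        "n_stored": count,
    }
    if keep_arrays:
        out["probes"] = probes
        out["memory"] = memory[:, :count]
    return out
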