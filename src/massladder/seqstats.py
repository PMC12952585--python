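"""Anagram, permutation, riffle-shuffle and selection-probability analysis.

These are the combinatorial tools used to analyse a nonsequential Edman
read-out: treating the residues of the machine's input peptide as a deck of
cards, the output sequence is a permutation whose *rising sequences*
(maximal runs of consecutive face values appearing in order) measure how
many riffle shuffles could have produced it — after s shuffles a deck shows
at most 2^s rising sequences.  A search over cut points and order-preserving
interleavings decides whether one sequence can be riffled into another, and
the Gilbert-Shannon-Reeds model gives the null distribution of signatures
for honestly shuffled decks.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from fractions import Fraction
from itertools import permutations as _permutations
from math import comb, factorial, prod

import numpy as np

from .chem import Peptide

__all__ = [
    "Permutation",
    "ShuffleStep",
    "is_anagram",
    "rising_sequences",
    "riffle_reachable",
    "replay_shuffles",
    "selection_probability",
    "anagram_count",
    "consistent_bijections",
    "gsr_shuffle",
    "gsr_signature_simulation",
]


@dataclass(frozen=True)
class Permutation:
    """Face values: images[i] is the 1-based source index feeding target
    position i+1."""

    images: tuple[int, ...]

    def __post_init__(self) -> None:
        n = len(self.images)
        if sorted(self.images) != list(range(1, n + 1)):
            raise ValueError("images must be a bijection on 1..n")

    def __len__(self) -> int:
        return len(self.images)


@dataclass(frozen=True)
class ShuffleStep:
    """One riffle: cut position and the interleaving pattern (0 = card from
    the top packet, 1 = card from the bottom packet)."""

    cut: int
    pattern: tuple[int, ...]


def _seq(x: Peptide | str) -> str:
    return x.sequence if isinstance(x, Peptide) else x


def is_anagram(a: Peptide | str, b: Peptide | str) -> bool:
    """True iff the residue multisets coincide."""
    return Counter(_seq(a)) == Counter(_seq(b))


def rising_sequences(perm: Permutation | tuple[int, ...]) -> int:
    """Number of maximal runs of consecutive values appearing in order.

    Equals 1 + #{v : position(v+1) < position(v)}.
    """
    images = perm.images if isinstance(perm, Permutation) else Permutation(perm).images
    position = {v: i for i, v in enumerate(images)}
    n = len(images)
    return 1 + sum(1 for v in range(1, n) if position[v + 1] < position[v])


def _apply(deck: str, step: ShuffleStep) -> str:
    top, bottom = deck[: step.cut], deck[step.cut :]
    i = j = 0
    out = []
    for source in step.pattern:
        if source == 0:
            out.append(top[i])
            i += 1
        else:
            out.append(bottom[j])
            j += 1
    if i != len(top) or j != len(bottom):
        raise ValueError("pattern does not consume both packets")
    return "".join(out)


def replay_shuffles(deck: Peptide | str, steps: list[ShuffleStep]) -> str:
    """Apply a shuffle trace forward."""
    current = _seq(deck)
    for step in steps:
        current = _apply(current, step)
    return current


def _merge_patterns(top: str, bottom: str, target: str):
    """Yield one interleaving pattern producing target from the packets, or
    nothing.  DP over (i, j) prefixes."""
    n = len(target)
    if len(top) + len(bottom) != n:
        return None
    # reachable[i][j]: can consume top[:i], bottom[:j] to build target[:i+j]
    reachable = [[False] * (len(bottom) + 1) for _ in range(len(top) + 1)]
    reachable[0][0] = True
    for i in range(len(top) + 1):
        for j in range(len(bottom) + 1):
            if not reachable[i][j]:
                continue
            k = i + j
            if k == n:
                continue
            if i < len(top) and top[i] == target[k]:
                reachable[i + 1][j] = True
            if j < len(bottom) and bottom[j] == target[k]:
                reachable[i][j + 1] = True
    if not reachable[len(top)][len(bottom)]:
        return None
    # reconstruct one pattern walking backwards
    i, j = len(top), len(bottom)
    pattern: list[int] = []
    while i + j > 0:
        k = i + j - 1
        if i > 0 and top[i - 1] == target[k] and reachable[i - 1][j]:
            pattern.append(0)
            i -= 1
        else:
            pattern.append(1)
            j -= 1
    pattern.reverse()
    return tuple(pattern)


def _merges_for_cut(deck: str, cut: int) -> dict[str, tuple[int, ...]]:
    """Every result of riffling at a given cut, each with one pattern."""
    top, bottom = deck[:cut], deck[cut:]
    out: dict[str, tuple[int, ...]] = {}

    def walk(i: int, j: int, built: str, pattern: tuple[int, ...]) -> None:
        if i == len(top) and j == len(bottom):
            out.setdefault(built, pattern)
            return
        if i < len(top):
            walk(i + 1, j, built + top[i], pattern + (0,))
        if j < len(bottom):
            walk(i, j + 1, built + bottom[j], pattern + (1,))

    walk(0, 0, "", ())
    return out


def _one_shuffle_results(deck: str) -> dict[str, ShuffleStep]:
    """Every deck reachable in one riffle, with a witnessing step."""
    out: dict[str, ShuffleStep] = {}
    for cut in range(len(deck) + 1):
        for built, pattern in _merges_for_cut(deck, cut).items():
            out.setdefault(built, ShuffleStep(cut=cut, pattern=pattern))
    return out


def riffle_reachable(
    deck: Peptide | str,
    target: Peptide | str,
    max_shuffles: int = 2,
    cuts: list[int] | None = None,
) -> list[ShuffleStep] | None:
    """A shortest riffle-shuffle trace from deck to target, or ``None``.

    ``cuts`` restricts the search to a fixed cut sequence (one cut per
    shuffle), which checks a specific published transformation.  The search
    enumerates interleavings exactly; a 14-card deck has at most 2^14
    distinct one-shuffle results, so two levels stay cheap.
    """
    d, t = _seq(deck), _seq(target)
    if len(d) != len(t):
        raise ValueError("deck and target lengths differ")
    if Counter(d) != Counter(t):
        raise ValueError("target is not a rearrangement of deck")
    if cuts is not None:

        def search(current: str, remaining: list[int]) -> list[ShuffleStep] | None:
            if not remaining:
                return [] if current == t else None
            cut = remaining[0]
            if len(remaining) == 1:
                pattern = _merge_patterns(current[:cut], current[cut:], t)
                if pattern is None:
                    return None
                return [ShuffleStep(cut=cut, pattern=pattern)]
            for mid, pattern in _merges_for_cut(current, cut).items():
                rest = search(mid, remaining[1:])
                if rest is not None:
                    return [ShuffleStep(cut=cut, pattern=pattern)] + rest
            return None

        return search(d, list(cuts))
    if d == t:
        return []
    # Decks that reach the target in exactly one riffle are its un-riffles:
    # pick any subsequence of the target as the top packet, the complement
    # as the bottom, and concatenate.  2^n candidates, built once.
    n = len(t)
    preimages: set[str] = set()
    for mask in range(1 << n):
        top = [t[i] for i in range(n) if mask >> i & 1]
        bottom = [t[i] for i in range(n) if not mask >> i & 1]
        preimages.add("".join(top + bottom))

    def final_step(deck_state: str) -> ShuffleStep:
        for cut in range(n + 1):
            pattern = _merge_patterns(deck_state[:cut], deck_state[cut:], t)
            if pattern is not None:
                return ShuffleStep(cut=cut, pattern=pattern)
        raise AssertionError("preimage without a merge pattern")

    frontier: dict[str, list[ShuffleStep]] = {d: []}
    for depth in range(1, max_shuffles + 1):
        for deck_state, trace in frontier.items():
            if deck_state in preimages:
                return trace + [final_step(deck_state)]
        if depth == max_shuffles:
            break
        nxt: dict[str, list[ShuffleStep]] = {}
        for deck_state, trace in frontier.items():
            for result, step in _one_shuffle_results(deck_state).items():
                if result not in nxt:
                    nxt[result] = trace + [step]
        frontier = nxt
    return None


def selection_probability(
    deck_size: int = 14,
    charged_count: int = 4,
    class_size: int = 10,
) -> Fraction:
    """Probability that an unordered (charged_count + 1)-draw contains all
    the designated charged residues plus one member of a class of
    ``class_size`` uncharged residues."""
    draw = charged_count + 1
    if class_size < 1:
        raise ValueError("class_size must be >= 1")
    if deck_size < draw or class_size > deck_size - charged_count:
        raise ValueError("infeasible parameters")
    return Fraction(class_size, comb(deck_size, draw))


def anagram_count(sequence_or_n: Peptide | str | int, multiset_aware: bool = False) -> int:
    """Number of arrangements: n! plain, or n!/prod(m_i!) multiset-aware."""
    if isinstance(sequence_or_n, int):
        if sequence_or_n < 0:
            raise ValueError("n must be >= 0")
        if multiset_aware:
            raise ValueError("multiset-aware counting needs a sequence")
        return factorial(sequence_or_n)
    seq = _seq(sequence_or_n)
    total = factorial(len(seq))
    if not multiset_aware:
        return total
    return total // prod(factorial(m) for m in Counter(seq).values())


def consistent_bijections(
    input_seq: Peptide | str, output_seq: Peptide | str
) -> list[tuple[Permutation, int]]:
    """All residue-consistent bijections output-position -> input-position,
    each with its rising-sequence signature.

    A bijection is consistent when every output position maps to an input
    position bearing the same residue; repeated residues multiply the count
    (product of multiplicity factorials).
    """
    inp, out = _seq(input_seq), _seq(output_seq)
    if not is_anagram(inp, out):
        raise ValueError("sequences are not anagrams")
    groups: dict[str, list[int]] = {}
    for i, r in enumerate(inp, start=1):
        groups.setdefault(r, []).append(i)
    residues = sorted(groups)
    results: list[tuple[Permutation, int]] = []

    def assignments(idx: int, mapping: dict[str, tuple[int, ...]]):
        if idx == len(residues):
            counters = {r: iter(mapping[r]) for r in residues}
            images = tuple(next(counters[r]) for r in out)
            perm = Permutation(images)
            results.append((perm, rising_sequences(perm)))
            return
        r = residues[idx]
        for order in _permutations(groups[r]):
            mapping[r] = order
            assignments(idx + 1, mapping)

    assignments(0, {})
    return results


def gsr_shuffle(deck: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One Gilbert-Shannon-Reeds riffle: binomial cut, then sequential drops
    with probability proportional to remaining packet sizes."""
    n = len(deck)
    cut = rng.binomial(n, 0.5)
    top, bottom = deck[:cut], deck[cut:]
    out = np.empty_like(deck)
    i = j = 0
    for k in range(n):
        a, b = len(top) - i, len(bottom) - j
        if rng.random() < a / (a + b):
            out[k] = top[i]
            i += 1
        else:
            out[k] = bottom[j]
            j += 1
    return out


def gsr_signature_simulation(
    n_cards: int,
    n_shuffles: int,
    reps: int,
    seed: int,
) -> dict:
    """Empirical rising-sequence distribution after repeated GSR riffles.

    Returns counts per signature, the mode, and the maximum observed;
    deterministic under the seed.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    counts: Counter[int] = Counter()
    for _ in range(reps):
        deck = np.arange(1, n_cards + 1)
        for _ in range(n_shuffles):
            deck = gsr_shuffle(deck, rng)
        # rising sequences of the value arrangement
        position = np.empty(n_cards + 1, dtype=int)
        position[deck] = np.arange(n_cards)
        sig = 1 + int(np.sum(position[2:] < position[1:-1]))
        counts[sig] += 1
    modal = max(counts, key=lambda s: (counts[s], -s))
    return {
        "n_cards": n_cards,
        "n_shuffles": n_shuffles,
        "reps": reps,
        "counts": dict(sorted(counts.items())),
        "modal_signature": modal,
        "max_signature": max(counts),
    }
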