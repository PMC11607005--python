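"""Group-specific synthetic name generation.

Names are drawn from order-2 character Markov chains (context = previous two
symbols, including a boundary symbol for start/stop).  Each ethno-racial group
gets its own transition tensor, built from a group-seeded Dirichlet draw plus
multiplicative boosts on a short list of "signature" character clusters — e.g.
elevated "kh"/"gh" mass for the MENA-like generator — so that a downstream
classifier has exploitable sub-word statistics while nothing pretends to be a
real name inventory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["NameGeneratorSpec", "make_group_spec", "default_name_specs", "generate_name_pairs"]

_ALPHABET = "abcdefghijklmnopqrstuvwxyz"
_BOUNDARY = len(_ALPHABET)  # start padding and stop symbol
_NSYM = len(_ALPHABET) + 1

# signature clusters per built-in group: cheap stand-ins for the consonant
# clusters and vowel patterns that differ between naming traditions
_GROUP_SIGNATURES: dict[str, list[str]] = {
    "white": ["th", "er", "son", "an", "ch", "ll"],
    "api": ["ng", "ch", "in", "ya", "ee", "wa"],
    "black": ["ja", "sh", "on", "de", "ri"],
    "hispanic": ["ez", "ia", "os", "rr", "gu", "ll"],
    "mena": ["kh", "gh", "ab", "al", "ou", "ir", "am", "az"],
    "other": ["ko", "va", "mi", "en"],
}


@dataclass
class NameGeneratorSpec:
    """Order-2 character transition specification for one group.

    ``transitions[c1, c2]`` is the distribution over the next symbol given the
    previous two (index ``_BOUNDARY`` padding at the start; emitting it ends
    the name).  ``perturb_rate`` injects single-character substitutions or
    adjacent transpositions to emulate transliteration spelling variants.
    """

    transitions: np.ndarray
    perturb_rate: float = 0.05
    min_len: int = 3
    max_len: int = 10

    def __post_init__(self) -> None:
        if self.transitions.shape != (_NSYM, _NSYM, _NSYM):
            raise ValueError("transition tensor must be (27, 27, 27)")
        if not 0.0 <= self.perturb_rate <= 1.0:
            raise ValueError("perturb_rate must lie in [0, 1]")


def make_group_spec(
    seed: int,
    signature_clusters: list[str] | None = None,
    cluster_boost: float = 12.0,
    concentration: float = 0.25,
    perturb_rate: float = 0.05,
) -> NameGeneratorSpec:
    """Build a group spec from a seed and optional signature clusters.

    Identical (seed, clusters, boost) arguments yield identical specs, and two
    groups built with the same arguments are statistically indistinguishable —
    the degenerate case used to check that the classifier finds no signal
    where there is none.
    """
    rng = np.random.default_rng(seed)
    t = rng.gamma(concentration, size=(_NSYM, _NSYM, _NSYM))
    # vowels get a floor everywhere so names stay pronounceable-ish
    vowels = [_ALPHABET.index(v) for v in "aeiou"]
    t[:, :, vowels] += 0.6
    # modest stop mass from any context; length control happens at sampling
    t[:, :, _BOUNDARY] = 0.25
    for cluster in signature_clusters or []:
        idx = [_ALPHABET.index(ch) for ch in cluster]
        for i in range(len(idx) - 1):
            t[:, idx[i], idx[i + 1]] *= cluster_boost
        if len(idx) >= 3:
            t[idx[0], idx[1], idx[2]] *= cluster_boost
    t /= t.sum(axis=2, keepdims=True)
    return NameGeneratorSpec(transitions=t, perturb_rate=perturb_rate)


def default_name_specs(seed: int = 0, perturb_rate: float = 0.05) -> dict[str, NameGeneratorSpec]:
    """One spec per built-in group, each from its own sub-seed and signatures."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(_GROUP_SIGNATURES))
    return {
        group: make_group_spec(
            int(child.generate_state(1)[0] % (2**31)),
            signature_clusters=sigs,
            perturb_rate=perturb_rate,
        )
        for (group, sigs), child in zip(_GROUP_SIGNATURES.items(), children)
    }


def _sample_word(spec: NameGeneratorSpec, rng: np.random.Generator, max_len: int) -> str:
    c1, c2 = _BOUNDARY, _BOUNDARY
    out: list[int] = []
    while len(out) < max_len:
        p = spec.transitions[c1, c2].copy()
        if len(out) < spec.min_len:
            p[_BOUNDARY] = 0.0
            p = p / p.sum()
        nxt = rng.choice(_NSYM, p=p)
        if nxt == _BOUNDARY:
            break
        out.append(int(nxt))
        c1, c2 = c2, nxt
    return "".join(_ALPHABET[i] for i in out)


def _perturb(word: str, rng: np.random.Generator) -> str:
    if len(word) < 2:
        return word
    chars = list(word)
    if rng.random() < 0.5:  # substitution
        i = int(rng.integers(len(chars)))
        chars[i] = _ALPHABET[int(rng.integers(len(_ALPHABET)))]
    else:  # adjacent transposition
        i = int(rng.integers(len(chars) - 1))
        chars[i], chars[i + 1] = chars[i + 1], chars[i]
    return "".join(chars)


def generate_name_pairs(
    spec: NameGeneratorSpec, n: int, rng_seed
) -> list[tuple[str, str]]:
    """Draw ``n`` (given_name, surname) pairs from one group's chain.

    Deterministic for a fixed seed; ``n = 0`` returns an empty list.
    """
    if n < 0:
        raise ValueError("n must be nonnegative")
    rng = np.random.default_rng(rng_seed)
    pairs = []
    for _ in range(n):
        given = _sample_word(spec, rng, spec.max_len - 2)
        surname = _sample_word(spec, rng, spec.max_len)
        if rng.random() < spec.perturb_rate:
            given = _perturb(given, rng)
        if rng.random() < spec.perturb_rate:
            surname = _perturb(surname, rng)
        pairs.append((given, surname))
    return pairs
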