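"""Byte-pair encoding over full-name strings.

Names are normalized (lowercase, accents stripped to ASCII, digits removed,
whitespace collapsed to a separator symbol) and then tokenized into
variable-length character clusters learned by iteratively merging the most
frequent adjacent symbol pair.  Clusters like "kh" or "gh" that are frequent
in one naming tradition but rare elsewhere become single tokens, which is the
signal the downstream sequence classifier consumes.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass, field

__all__ = ["BPEVocab", "normalize_name", "SEP", "BOS", "EOS", "UNK"]

SEP = "_"  # separator between given name and surname (base symbol)
BOS = "<s>"
EOS = "</s>"
UNK = "<unk>"
SPECIALS = (BOS, EOS, UNK)

_KEEP = set("abcdefghijklmnopqrstuvwxyz-'")


def normalize_name(name: str) -> str:
    """Lowercase, strip accents to ASCII, drop digits, collapse whitespace.

    Internal whitespace becomes the separator symbol; hyphens and apostrophes
    are kept (they carry name signal), everything else is dropped.
    """
    s = unicodedata.normalize("NFKD", name).encode("ascii", "ignore").decode("ascii")
    s = s.lower()
    parts = []
    word: list[str] = []
    for ch in s:
        if ch.isspace():
            if word:
                parts.append("".join(word))
                word = []
        elif ch in _KEEP:
            word.append(ch)
    if word:
        parts.append("".join(word))
    return SEP.join(parts)


@dataclass
class BPEVocab:
    """Learned merge table plus token inventory.

    ``merges`` is the ordered list of symbol-pair rules; applying them in
    order to any string over the training alphabet yields tokens drawn from
    ``tokens``.  The separator and the special bracketing/unknown tokens
    never participate in merges.
    """

    merges: list[tuple[str, str]] = field(default_factory=list)
    alphabet: list[str] = field(default_factory=list)
    max_vocab: int = 512

    def __post_init__(self) -> None:
        self.tokens = set(self.alphabet) | {SEP, BOS, EOS, UNK}
        for a, b in self.merges:
            self.tokens.add(a + b)

    # -- training ----------------------------------------------------------
    @classmethod
    def learn(cls, corpus, max_vocab: int = 512) -> "BPEVocab":
        """Learn merges from a corpus of full-name strings.

        Iteratively merges the most frequent adjacent pair (ties broken
        lexicographically on the (left, right) pair, so training is
        deterministic) until the inventory reaches ``max_vocab`` or no pair
        occurs at least twice.
        """
        words: dict[tuple[str, ...], int] = {}
        for name in corpus:
            norm = normalize_name(name)
            if not norm:
                continue
            key = tuple(norm)
            words[key] = words.get(key, 0) + 1
        if not words:
            raise ValueError("corpus is empty after normalization")
        alphabet = sorted({ch for word in words for ch in word if ch != SEP})
        base_size = len(alphabet) + 1 + len(SPECIALS)  # + separator + specials
        if max_vocab < base_size:
            raise ValueError(
                f"max_vocab={max_vocab} is below the base inventory size {base_size}"
            )
        vocab = cls(merges=[], alphabet=alphabet, max_vocab=max_vocab)
        seqs = {w: list(w) for w in words}
        while len(vocab.tokens) < max_vocab:
            counts: dict[tuple[str, str], int] = {}
            for w, seq in seqs.items():
                c = words[w]
                for a, b in zip(seq, seq[1:]):
                    if SEP in (a, b):
                        continue
                    counts[(a, b)] = counts.get((a, b), 0) + c
            if not counts:
                break
            best_pair = min(counts, key=lambda pr: (-counts[pr], pr))
            if counts[best_pair] < 2:
                break
            vocab.merges.append(best_pair)
            vocab.tokens.add(best_pair[0] + best_pair[1])
            for w in seqs:
                seqs[w] = _apply_merge(seqs[w], best_pair)
        return vocab

    # -- tokenization ------------------------------------------------------
    def tokenize(self, full_name: str) -> list[str]:
        """Token sequence for a full name, bracketed by start/stop tokens.

        Characters outside the inventory map to the unknown token; the
        operation is total and deterministic.  Minus specials and with the
        separator mapped back to a space, concatenating the tokens
        reproduces the normalized input (round trip), except where unknown
        tokens were substituted.
        """
        norm = normalize_name(full_name)
        seq = [ch if ch in self.tokens else UNK for ch in norm]
        for pair in self.merges:
            seq = _apply_merge(seq, pair)
        return [BOS] + seq + [EOS]

    def detokenize(self, tokens) -> str:
        return "".join(t for t in tokens if t not in SPECIALS)

    # -- serialization -----------------------------------------------------
    def save(self, path) -> None:
        with open(path, "w", encoding="ascii") as fh:
            fh.write("#namemort-bpe v1\n")
            fh.write(f"max_vocab\t{self.max_vocab}\n")
            fh.write("alphabet\t" + "".join(self.alphabet) + "\n")
            for a, b in self.merges:
                fh.write(f"{a}\t{b}\n")

    @classmethod
    def load(cls, path) -> "BPEVocab":
        with open(path, encoding="ascii") as fh:
            header = fh.readline().strip()
            if header != "#namemort-bpe v1":
                raise ValueError(f"not a namemort BPE vocabulary file: {header!r}")
            max_vocab = int(fh.readline().split("\t")[1])
            alphabet = list(fh.readline().rstrip("\n").split("\t")[1])
            merges = []
            for line in fh:
                a, b = line.rstrip("\n").split("\t")
                merges.append((a, b))
        return cls(merges=merges, alphabet=alphabet, max_vocab=max_vocab)

    def token_ids(self) -> dict[str, int]:
        """Stable token -> integer id map (specials first, then sorted)."""
        ordered = list(SPECIALS) + [SEP] + sorted(self.tokens - set(SPECIALS) - {SEP})
        return {tok: i for i, tok in enumerate(ordered)}


def _apply_merge(seq: list[str], pair: tuple[str, str]) -> list[str]:
    a, b = pair
    out: list[str] = []
    i = 0
    while i < len(seq):
        if i + 1 < len(seq) and seq[i] == a and seq[i + 1] == b:
            out.append(a + b)
            i += 2
        else:
            out.append(seq[i])
            i += 1
    return out
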