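"""Byte-level BPE tokenizer for reaction SMILES.

The transformer recommender tokenizes SMILES with a byte-pair-encoding
vocabulary learned from the pretraining corpus.  The base alphabet is the
256 single bytes, which guarantees that any string — including held-out
SMILES with unseen substructures — encodes with zero unknown tokens;
learned merges compress frequent multi-byte fragments (ring atoms,
bracket atoms, two-character elements) into single tokens.

Special tokens occupy the lowest ids: ``<pad>``, ``<unk>``, ``<s>``
(class start), ``</s>`` (separator) and ``<mask>``.  Training is fully
deterministic given the corpus order: ties between candidate merges are
broken by the lexicographically smallest pair.
"""

from __future__ import annotations

import json
from collections import Counter
from pathlib import Path
from typing import Iterable, Sequence

PAD, UNK, CLS, SEP, MASK = 0, 1, 2, 3, 4
SPECIAL_TOKENS = {"<pad>": PAD, "<unk>": UNK, "<s>": CLS, "</s>": SEP, "<mask>": MASK}
N_SPECIAL = len(SPECIAL_TOKENS)
N_BYTES = 256


class ByteBPETokenizer:
    """Learned byte-pair vocabulary with dense ids.

    ids 0..4 are the special tokens, 5..260 the raw bytes, and higher ids
    the learned merges in the order they were created.
    """

    def __init__(self, merges: Sequence[tuple[bytes, bytes]] | None = None):
        self.merges: list[tuple[bytes, bytes]] = list(merges or [])
        self._rebuild()

    def _rebuild(self) -> None:
        self.token_to_id: dict[bytes, int] = {}
        for b in range(N_BYTES):
            self.token_to_id[bytes([b])] = N_SPECIAL + b
        for i, (a, b) in enumerate(self.merges):
            self.token_to_id[a + b] = N_SPECIAL + N_BYTES + i
        self.id_to_token = {v: k for k, v in self.token_to_id.items()}
        self.merge_ranks: dict[tuple[bytes, bytes], int] = {
            pair: i for i, pair in enumerate(self.merges)
        }

    @property
    def vocab_size(self) -> int:
        return N_SPECIAL + N_BYTES + len(self.merges)

    @property
    def special_ids(self) -> frozenset[int]:
        return frozenset(SPECIAL_TOKENS.values())

    # -- training ----------------------------------------------------------

    @classmethod
    def train(cls, corpus: Iterable[str], vocab_size: int) -> "ByteBPETokenizer":
        """Learn merges until the vocabulary reaches ``vocab_size``.

        Raises on an empty corpus or a vocab_size smaller than the base
        alphabet plus specials.  If the corpus is fully merged before the
        requested size is reached, training stops early.
        """
        sequences = [
            [bytes([b]) for b in text.encode("utf-8")] for text in corpus
        ]
        if not sequences:
            raise ValueError("empty training corpus")
        base = N_SPECIAL + N_BYTES
        if vocab_size <= base:
            raise ValueError(
                f"vocab_size must exceed the {base} special + byte tokens"
            )
        merges: list[tuple[bytes, bytes]] = []
        while base + len(merges) < vocab_size:
            counts: Counter[tuple[bytes, bytes]] = Counter()
            for seq in sequences:
                for a, b in zip(seq, seq[1:]):
                    counts[(a, b)] += 1
            if not counts:
                break
            top = max(counts.values())
            pair = min(p for p, c in counts.items() if c == top)
            merges.append(pair)
            merged = pair[0] + pair[1]
            for si, seq in enumerate(sequences):
                out = []
                i = 0
                while i < len(seq):
                    if i + 1 < len(seq) and seq[i] == pair[0] and seq[i + 1] == pair[1]:
                        out.append(merged)
                        i += 2
                    else:
                        out.append(seq[i])
                        i += 1
                sequences[si] = out
        return cls(merges)

    # -- encode / decode ---------------------------------------------------

    def encode(self, text: str) -> list[int]:
        """Tokenize a string; byte fallback means no unknowns ever occur."""
        seq = [bytes([b]) for b in text.encode("utf-8")]
        while len(seq) > 1:
            ranked = [
                (self.merge_ranks[(a, b)], i)
                for i, (a, b) in enumerate(zip(seq, seq[1:]))
                if (a, b) in self.merge_ranks
            ]
            if not ranked:
                break
            rank, _ = min(ranked)
            pair = self.merges[rank]
            merged = pair[0] + pair[1]
            out = []
            i = 0
            while i < len(seq):
                if i + 1 < len(seq) and seq[i] == pair[0] and seq[i + 1] == pair[1]:
                    out.append(merged)
                    i += 2
                else:
                    out.append(seq[i])
                    i += 1
            seq = out
        return [self.token_to_id[tok] for tok in seq]

    def decode(self, ids: Sequence[int]) -> str:
        """Inverse of encode for non-special ids; specials are dropped."""
        chunks = [
            self.id_to_token[i] for i in ids if i not in self.special_ids
        ]
        return b"".join(chunks).decode("utf-8", errors="replace")

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        payload = {
            "special_tokens": SPECIAL_TOKENS,
            "merges": [[a.hex(), b.hex()] for a, b in self.merges],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "ByteBPETokenizer":
        payload = json.loads(Path(path).read_text())
        merges = [(bytes.fromhex(a), bytes.fromhex(b)) for a, b in payload["merges"]]
        return cls(merges)


def train_tokenizer(corpus: Iterable[str], vocab_size: int) -> ByteBPETokenizer:
    """Functional wrapper around :meth:`ByteBPETokenizer.train`."""
    return ByteBPETokenizer.train(corpus, vocab_size)
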