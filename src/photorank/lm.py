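"""Masked-language-model pretraining and classification fine-tuning on
reaction SMILES.

The pipeline mirrors a RoBERTa-style encoder at desk scale.  Every input
is a *two-sentence* sequence: sentence A is the reaction-core SMILES,
sentence B the full reaction SMILES, laid out as::

    <s> core-tokens </s> reaction-tokens </s> <pad> ...

Pretraining statically masks 15% of the non-special tokens (each position
drawn once per corpus build, not re-sampled every epoch) and trains the
encoder to reconstruct them — teaching it the grammar of reaction SMILES
and where the reacting atoms sit, before any catalyst label is seen.
Fine-tuning attaches a linear head to the first-position representation
and trains the whole stack to classify reactions over the photocatalyst
registry; pretraining demonstrably helps when labeled data is scarce.

Model dimensions are configuration: the default is a small encoder
(4 layers, 4 heads, embedding 128, input length 128) that pretrains and
fine-tunes on a CPU in minutes; an input length of 1024 and larger stacks
are reachable through :class:`LMConfig` alone.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from . import autodiff as ad
from .autodiff import Tensor
from .mlp import class_weights
from .tokenizer import CLS, MASK, PAD, SEP, ByteBPETokenizer

IGNORE = -100


@dataclass
class LMConfig:
    """Transformer and training hyperparameters.

    ``max_len`` bounds the two-sentence input (pad/truncate target);
    ``mask_rate`` is the fraction of non-special tokens statically masked
    during pretraining.  Pretraining runs 2 epochs and fine-tuning 10 by
    default.
    """

    max_len: int = 128
    mask_rate: float = 0.15
    pretrain_epochs: int = 2
    finetune_epochs: int = 10
    n_layers: int = 4
    n_heads: int = 4
    embed_dim: int = 128
    ffn_dim: int | None = None
    batch_size: int = 16
    learning_rate: float = 3e-4
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.mask_rate < 1:
            raise ValueError("mask_rate must be in [0, 1)")
        if self.embed_dim % self.n_heads:
            raise ValueError("embed_dim must be divisible by n_heads")
        if self.ffn_dim is None:
            self.ffn_dim = 4 * self.embed_dim


def encode_two_sentence(
    core_smiles: str,
    reaction_smiles: str,
    tok: ByteBPETokenizer,
    max_len: int,
) -> np.ndarray:
    """Token ids in the layout ``<s> core </s> reaction </s> <pad>...``.

    An empty core (identity reaction) degenerates to ``<s></s> reaction
    </s>``.  Over-length inputs are truncated from the right of sentence
    B, never sentence A; both separators always survive.
    """
    a = tok.encode(core_smiles) if core_smiles else []
    b = tok.encode(reaction_smiles)
    budget = max_len - 3 - len(a)
    if budget < 0:
        raise ValueError(
            f"core sentence ({len(a)} tokens) alone exceeds max_len={max_len}"
        )
    if len(b) > budget:
        b = b[:budget]
    ids = [CLS] + a + [SEP] + b + [SEP]
    ids += [PAD] * (max_len - len(ids))
    return np.asarray(ids, dtype=np.int64)


@dataclass
class MaskedBatch:
    """Statically masked inputs and their reconstruction targets."""

    input_ids: np.ndarray  # with <mask> substitutions
    labels: np.ndarray  # original ids at masked positions, IGNORE elsewhere
    mask_positions: list[np.ndarray]

    @property
    def n_masked(self) -> int:
        return int((self.labels != IGNORE).sum())


def apply_static_mask(
    ids: np.ndarray,
    tok: ByteBPETokenizer,
    mask_rate: float = 0.15,
    seed: int = 0,
    bert_style: bool = False,
) -> MaskedBatch:
    """Mask a fraction of non-special tokens, once, deterministically.

    Every non-special position is selected independently with probability
    ``mask_rate`` and replaced by the mask token (the literal static
    scheme; ``bert_style`` enables the 80/10/10 mask/random/keep split
    instead).  The same seed always reproduces the same positions.
    """
    ids = np.atleast_2d(np.asarray(ids, dtype=np.int64))
    rng = np.random.default_rng(seed)
    special = np.isin(ids, list(tok.special_ids))
    input_ids = ids.copy()
    labels = np.full_like(ids, IGNORE)
    positions: list[np.ndarray] = []
    for row in range(ids.shape[0]):
        eligible = np.where(~special[row])[0]
        if eligible.size == 0:
            positions.append(np.empty(0, dtype=np.int64))
            continue
        chosen = eligible[rng.random(eligible.size) < mask_rate]
        labels[row, chosen] = ids[row, chosen]
        if bert_style:
            r = rng.random(chosen.size)
            mask_part = chosen[r < 0.8]
            rand_part = chosen[(r >= 0.8) & (r < 0.9)]
            input_ids[row, mask_part] = MASK
            input_ids[row, rand_part] = rng.integers(
                len(tok.special_ids), tok.vocab_size, size=rand_part.size
            )
        else:
            input_ids[row, chosen] = MASK
        positions.append(chosen)
    return MaskedBatch(input_ids, labels, positions)


# -- the encoder -----------------------------------------------------------


class TransformerEncoder:
    """Pre-LN transformer encoder over token-id matrices."""

    def __init__(self, config: LMConfig, vocab_size: int, rng: np.random.Generator):
        self.config = config
        self.vocab_size = vocab_size
        c, f = config.embed_dim, config.ffn_dim
        p: dict[str, Tensor] = {}
        p["tok_emb"] = Tensor(rng.normal(0, 0.02, (vocab_size, c)), requires_grad=True)
        p["pos_emb"] = Tensor(rng.normal(0, 0.02, (config.max_len, c)), requires_grad=True)
        for layer in range(config.n_layers):
            pre = f"l{layer}_"
            p[pre + "ln1_g"] = ad.ones_parameter((c,))
            p[pre + "ln1_b"] = ad.zeros_parameter((c,))
            for name in ("wq", "wk", "wv", "wo"):
                p[pre + name] = ad.parameter(rng, (c, c))
                p[pre + name.replace("w", "b")] = ad.zeros_parameter((c,))
            p[pre + "ln2_g"] = ad.ones_parameter((c,))
            p[pre + "ln2_b"] = ad.zeros_parameter((c,))
            p[pre + "w_ff1"] = ad.parameter(rng, (c, f))
            p[pre + "b_ff1"] = ad.zeros_parameter((f,))
            p[pre + "w_ff2"] = ad.parameter(rng, (f, c))
            p[pre + "b_ff2"] = ad.zeros_parameter((c,))
        p["lnf_g"] = ad.ones_parameter((c,))
        p["lnf_b"] = ad.zeros_parameter((c,))
        self.params = p

    def forward(self, ids: np.ndarray) -> Tensor:
        """Hidden states (B, T, C); pad positions are masked out of the
        attention."""
        cfg = self.config
        p = self.params
        ids = np.atleast_2d(ids)
        batch, t = ids.shape
        heads, c = cfg.n_heads, cfg.embed_dim
        hd = c // heads
        pad_mask = np.where(ids == PAD, -1e9, 0.0)[:, None, None, :]  # (B,1,1,T)

        x = ad.add(
            ad.embedding(p["tok_emb"], ids),
            ad.embedding(p["pos_emb"], np.broadcast_to(np.arange(t), (batch, t))),
        )
        scale = Tensor(1.0 / np.sqrt(hd))
        for layer in range(cfg.n_layers):
            pre = f"l{layer}_"
            h = ad.layer_norm(x, p[pre + "ln1_g"], p[pre + "ln1_b"])
            q = ad.linear(h, p[pre + "wq"], p[pre + "bq"])
            k = ad.linear(h, p[pre + "wk"], p[pre + "bk"])
            v = ad.linear(h, p[pre + "wv"], p[pre + "bv"])
            q = ad.transpose(ad.reshape(q, (batch, t, heads, hd)), (0, 2, 1, 3))
            k = ad.transpose(ad.reshape(k, (batch, t, heads, hd)), (0, 2, 3, 1))
            v = ad.transpose(ad.reshape(v, (batch, t, heads, hd)), (0, 2, 1, 3))
            scores = ad.add(ad.mul(ad.matmul(q, k), scale), Tensor(pad_mask))
            att = ad.softmax(scores, axis=-1)
            ctx = ad.matmul(att, v)
            ctx = ad.reshape(ad.transpose(ctx, (0, 2, 1, 3)), (batch, t, c))
            x = ad.add(x, ad.linear(ctx, p[pre + "wo"], p[pre + "bo"]))
            h2 = ad.layer_norm(x, p[pre + "ln2_g"], p[pre + "ln2_b"])
            ff = ad.linear(
                ad.gelu(ad.linear(h2, p[pre + "w_ff1"], p[pre + "b_ff1"])),
                p[pre + "w_ff2"],
                p[pre + "b_ff2"],
            )
            x = ad.add(x, ff)
        return ad.layer_norm(x, p["lnf_g"], p["lnf_b"])

    def copy(self) -> "TransformerEncoder":
        clone = object.__new__(TransformerEncoder)
        clone.config = copy.deepcopy(self.config)
        clone.vocab_size = self.vocab_size
        clone.params = {
            k: Tensor(v.data.copy(), requires_grad=True) for k, v in self.params.items()
        }
        return clone


def _trim(ids: np.ndarray) -> np.ndarray:
    """Drop all-pad tail columns (cheap compute win, identical math)."""
    keep = max(int((ids != PAD).any(axis=0).nonzero()[0].max()) + 1, 2)
    return ids[:, :keep]


@dataclass
class PretrainedLM:
    """Encoder + reconstruction head produced by masked pretraining."""

    encoder: TransformerEncoder
    mlm_w: Tensor
    mlm_b: Tensor
    history: list[dict] = field(default_factory=list)

    def masked_loss(self, batch: MaskedBatch) -> float:
        ids = _trim(batch.input_ids)
        hidden = self.encoder.forward(ids)
        flat = ad.reshape(hidden, (-1, self.encoder.config.embed_dim))
        logits = ad.linear(flat, self.mlm_w, self.mlm_b)
        labels = batch.labels[:, : ids.shape[1]].reshape(-1)
        return float(ad.cross_entropy(logits, labels, ignore_index=IGNORE).data)

    def masked_accuracy(self, batch: MaskedBatch) -> float:
        ids = _trim(batch.input_ids)
        hidden = self.encoder.forward(ids)
        logits = (
            hidden.data.reshape(-1, self.encoder.config.embed_dim) @ self.mlm_w.data
            + self.mlm_b.data
        )
        labels = batch.labels[:, : ids.shape[1]].reshape(-1)
        keep = labels != IGNORE
        if not keep.any():
            return float("nan")
        return float((logits[keep].argmax(-1) == labels[keep]).mean())

    def save(self, path: str | Path) -> None:
        arrays = {f"enc_{k}": v.data for k, v in self.encoder.params.items()}
        arrays["mlm_w"] = self.mlm_w.data
        arrays["mlm_b"] = self.mlm_b.data
        meta = {
            "config": asdict(self.encoder.config),
            "vocab_size": self.encoder.vocab_size,
            "history": self.history,
        }
        np.savez(
            path,
            __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            **arrays,
        )

    @classmethod
    def load(cls, path: str | Path) -> "PretrainedLM":
        with np.load(path) as archive:
            meta = json.loads(bytes(archive["__meta__"]).decode())
            config = LMConfig(**meta["config"])
            rng = np.random.default_rng(0)
            encoder = TransformerEncoder(config, meta["vocab_size"], rng)
            for k in encoder.params:
                encoder.params[k] = Tensor(archive[f"enc_{k}"], requires_grad=True)
            model = cls(
                encoder,
                Tensor(archive["mlm_w"], requires_grad=True),
                Tensor(archive["mlm_b"], requires_grad=True),
                history=meta["history"],
            )
        return model


def build_masked_corpus(
    pairs: Sequence[tuple[str, str]],
    tok: ByteBPETokenizer,
    config: LMConfig,
    seed: int | None = None,
) -> MaskedBatch:
    """Encode two-sentence pairs and apply the one-time static mask."""
    ids = np.stack(
        [encode_two_sentence(core, rxn, tok, config.max_len) for core, rxn in pairs]
    )
    return apply_static_mask(
        ids, tok, config.mask_rate, seed=config.seed if seed is None else seed
    )


def pretrain_mlm(
    train_pairs: Sequence[tuple[str, str]],
    heldout_pairs: Sequence[tuple[str, str]],
    tok: ByteBPETokenizer,
    config: LMConfig,
) -> PretrainedLM:
    """Masked-token pretraining; tracks held-out loss per epoch.

    Aborts if the training loss diverges beyond 10x its initial value.
    The returned history starts with the held-out loss of the untrained
    (randomly initialized) model, so the pretraining benefit is measured
    against an explicit epoch-0 baseline.
    """
    if not train_pairs:
        raise ValueError("empty pretraining corpus")
    rng = np.random.default_rng(config.seed)
    encoder = TransformerEncoder(config, tok.vocab_size, rng)
    model = PretrainedLM(
        encoder,
        ad.parameter(rng, (config.embed_dim, tok.vocab_size)),
        ad.zeros_parameter((tok.vocab_size,)),
    )
    train_batch = build_masked_corpus(train_pairs, tok, config, seed=config.seed)
    heldout_batch = build_masked_corpus(heldout_pairs, tok, config, seed=config.seed + 1)

    model.history.append({"epoch": 0, "heldout_loss": model.masked_loss(heldout_batch)})
    params = list(encoder.params.values()) + [model.mlm_w, model.mlm_b]
    opt = ad.Adam(params, lr=config.learning_rate)
    n = train_batch.input_ids.shape[0]
    initial_loss = None
    for epoch in range(config.pretrain_epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            ids = _trim(train_batch.input_ids[idx])
            hidden = encoder.forward(ids)
            flat = ad.reshape(hidden, (-1, config.embed_dim))
            logits = ad.linear(flat, model.mlm_w, model.mlm_b)
            labels = train_batch.labels[idx][:, : ids.shape[1]].reshape(-1)
            if not (labels != IGNORE).any():
                continue
            loss = ad.cross_entropy(logits, labels, ignore_index=IGNORE)
            if initial_loss is None:
                initial_loss = float(loss.data)
            if float(loss.data) > 10 * initial_loss:
                raise FloatingPointError("pretraining diverged; lower the learning rate")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
        model.history.append(
            {
                "epoch": epoch + 1,
                "train_loss": float(np.mean(epoch_losses)),
                "heldout_loss": model.masked_loss(heldout_batch),
            }
        )
    return model


# -- classification fine-tuning --------------------------------------------


class TransformerRecommender(BaseEstimator, ClassifierMixin):
    """Transformer classifier over the catalyst registry.

    ``X`` is a sequence of (core SMILES, reaction SMILES) pairs; ``y`` an
    array of registry indices.  With ``pretrained`` set, fine-tuning
    starts from the pretrained encoder (copied, so the original is left
    untouched); otherwise the encoder is trained from scratch.  The
    classification head reads the first-position (``<s>``) representation.
    """

    def __init__(
        self,
        tokenizer: ByteBPETokenizer | None = None,
        pretrained: PretrainedLM | None = None,
        registry_size: int | None = None,
        config: LMConfig | None = None,
        weighted: bool = False,
        random_state: int = 0,
    ):
        self.tokenizer = tokenizer
        self.pretrained = pretrained
        self.registry_size = registry_size
        self.config = config
        self.weighted = weighted
        self.random_state = random_state

    def _encode(self, X: Sequence[tuple[str, str]], config: LMConfig) -> np.ndarray:
        return np.stack(
            [
                encode_two_sentence(core, rxn, self.tokenizer, config.max_len)
                for core, rxn in X
            ]
        )

    def fit(self, X: Sequence[tuple[str, str]], y) -> "TransformerRecommender":
        if self.tokenizer is None:
            raise ValueError("a trained tokenizer is required")
        y = np.asarray(y, dtype=np.int64)
        if self.pretrained is not None:
            config = self.pretrained.encoder.config
            if self.config is not None and asdict(self.config) != asdict(config):
                raise ValueError("config conflicts with the pretrained checkpoint")
            encoder = self.pretrained.encoder.copy()
            if self.pretrained.encoder.vocab_size != self.tokenizer.vocab_size:
                raise ValueError("tokenizer does not match the pretrained checkpoint")
        else:
            config = self.config or LMConfig(seed=self.random_state)
            encoder = TransformerEncoder(
                config, self.tokenizer.vocab_size, np.random.default_rng(self.random_state)
            )
        n_out = self.registry_size or int(y.max()) + 1
        rng = np.random.default_rng(self.random_state)
        head_w = ad.parameter(rng, (config.embed_dim, n_out))
        head_b = ad.zeros_parameter((n_out,))

        ids = self._encode(X, config)
        counts = np.bincount(y, minlength=n_out)
        sample_w = class_weights(counts)[y] if self.weighted else None

        params = list(encoder.params.values()) + [head_w, head_b]
        opt = ad.Adam(params, lr=config.learning_rate)
        n = len(y)
        report = []
        for _ in range(config.finetune_epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, config.batch_size):
                idx = order[start : start + config.batch_size]
                batch_ids = _trim(ids[idx])
                hidden = encoder.forward(batch_ids)
                pooled = ad.select_position(hidden, 0)
                logits = ad.linear(pooled, head_w, head_b)
                loss = ad.cross_entropy(
                    logits,
                    y[idx],
                    sample_weights=None if sample_w is None else sample_w[idx],
                )
                if not np.isfinite(loss.data):
                    raise FloatingPointError("non-finite fine-tuning loss")
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
            report.append(float(np.mean(losses)))
        self.encoder_ = encoder
        self.head_w_, self.head_b_ = head_w, head_b
        self.classes_ = np.arange(n_out)
        self.training_report_ = report
        self.config_ = config
        return self

    def predict_proba(self, X: Sequence[tuple[str, str]]) -> np.ndarray:
        ids = self._encode(X, self.config_)
        out = []
        bs = self.config_.batch_size
        for start in range(0, len(ids), bs):
            batch_ids = _trim(ids[start : start + bs])
            hidden = self.encoder_.forward(batch_ids)
            logits = hidden.data[:, 0, :] @ self.head_w_.data + self.head_b_.data
            z = logits - logits.max(axis=-1, keepdims=True)
            e = np.exp(z)
            out.append(e / e.sum(axis=-1, keepdims=True))
        return np.vstack(out)

    def predict(self, X) -> np.ndarray:
        return np.argmax(self.predict_proba(X), axis=-1)

    def save(self, path: str | Path) -> None:
        """Self-contained checkpoint: encoder + head + config + tokenizer."""
        arrays = {f"enc_{k}": v.data for k, v in self.encoder_.params.items()}
        arrays["head_w"] = self.head_w_.data
        arrays["head_b"] = self.head_b_.data
        meta = {
            "kind": "lm",
            "config": asdict(self.config_),
            "vocab_size": self.encoder_.vocab_size,
            "registry_size": int(len(self.classes_)),
            "merges": [[a.hex(), b.hex()] for a, b in self.tokenizer.merges],
        }
        np.savez(
            path,
            __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            **arrays,
        )

    @classmethod
    def load(cls, path: str | Path) -> "TransformerRecommender":
        with np.load(path) as archive:
            meta = json.loads(bytes(archive["__meta__"]).decode())
            config = LMConfig(**meta["config"])
            tok = ByteBPETokenizer(
                [(bytes.fromhex(a), bytes.fromhex(b)) for a, b in meta["merges"]]
            )
            model = cls(tokenizer=tok, registry_size=meta["registry_size"])
            encoder = object.__new__(TransformerEncoder)
            encoder.config = config
            encoder.vocab_size = meta["vocab_size"]
            encoder.params = {
                k[4:]: Tensor(archive[k], requires_grad=True)
                for k in archive.files
                if k.startswith("enc_")
            }
            model.encoder_ = encoder
            model.head_w_ = Tensor(archive["head_w"], requires_grad=True)
            model.head_b_ = Tensor(archive["head_b"], requires_grad=True)
            model.classes_ = np.arange(meta["registry_size"])
            model.config_ = config
        return model


def finetune_classifier(
    pretrained: PretrainedLM | None,
    pairs: Sequence[tuple[str, str]],
    labels: Sequence[int],
    tok: ByteBPETokenizer,
    registry_size: int,
    config: LMConfig | None = None,
    weighted: bool = False,
    random_state: int = 0,
) -> TransformerRecommender:
    """Functional wrapper: fine-tune a classifier on (core, reaction) pairs."""
    model = TransformerRecommender(
        tokenizer=tok,
        pretrained=pretrained,
        registry_size=registry_size,
        config=config,
        weighted=weighted,
        random_state=random_state,
    )
    return model.fit(pairs, np.asarray(labels))
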