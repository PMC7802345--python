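"""Encoder–decoder translator over fragment sentences.

A stacked (optionally bidirectional) LSTM encoder reads the product
sentence; a stacked unidirectional LSTM decoder emits the reactant
sentence token by token, attending to the encoder states through Luong
attention with the "general" bilinear score — or, in local mode, to a
Gaussian-weighted window around a predicted center position.  Decoding is
greedy argmax, so the model is deterministic: the same input always yields
the same prediction.

The bidirectionality flag applies to the encoder; an autoregressive
decoder is necessarily unidirectional, so the two encoder directions'
final states are concatenated and linearly bridged to initialize it.
Built on the package's own NumPy reverse-mode autodiff
(:mod:`fragretro.autodiff`).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .autodiff import (Tensor, concat, cross_entropy_sum, embedding, index_time,
                       lstm_cell, softmax)
from .vocab import SPECIAL_TOKENS

__all__ = ["ModelConfig", "Seq2SeqModel", "build_model", "attention_context",
           "count_parameters", "PAD_ID", "SOS_ID", "EOS_ID", "SEP_ID"]

PAD_ID, SOS_ID, EOS_ID, SEP_ID = range(4)


@dataclass
class ModelConfig:
    embedding_dim: int = 126
    hidden_units: int = 2000
    num_layers: int = 2
    bidirectional: bool = True
    attention: str = "global"          # global | local
    local_window: int = 10
    dropout: float = 0.1
    # encoder and decoder read/write the same fragment language, so sharing
    # one embedding (and reusing it as the output projection when shapes
    # allow) pools the evidence for rare words across all three roles
    tie_embeddings: bool = False
    tie_output: bool = False           # requires embedding_dim == hidden_units

    def __post_init__(self):
        if min(self.embedding_dim, self.hidden_units, self.num_layers) <= 0:
            raise ValueError("embedding_dim, hidden_units, num_layers must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0,1)")
        if self.attention not in ("global", "local"):
            raise ValueError(f"unknown attention mode {self.attention!r}")
        if self.local_window <= 0:
            raise ValueError("local_window must be positive")
        if self.tie_output and self.embedding_dim != self.hidden_units:
            raise ValueError("tie_output requires embedding_dim == hidden_units")


def attention_context(decoder_state, encoder_states, mode: str = "global",
                      window: int = 10, W_a: np.ndarray | None = None,
                      center=None) -> tuple[np.ndarray, np.ndarray]:
    """Reference attention computation on raw arrays (no gradients).

    ``decoder_state`` is (H,) or (B, H); ``encoder_states`` (T, He) or
    (B, T, He).  Scores are dot products, or bilinear through ``W_a``
    (He, H) when given.  Global mode attends every source position; local
    mode keeps the ``2*window+1`` positions around ``center`` (default:
    middle of the source), reweights them with a Gaussian of std
    ``window/2`` and renormalizes, so the weights always form a
    probability distribution.  Returns ``(context, weights)``.
    """
    h = np.atleast_2d(np.asarray(decoder_state, dtype=float))
    enc = np.asarray(encoder_states, dtype=float)
    squeeze = enc.ndim == 2
    if squeeze:
        enc = enc[None]
    T = enc.shape[1]
    if T == 0:
        raise ValueError("encoder_states must be nonempty")
    keys = enc @ W_a if W_a is not None else enc
    scores = np.einsum("bth,bh->bt", keys, h)
    pos = np.arange(T)[None, :]
    if mode == "local":
        c = (np.full(h.shape[0], (T - 1) / 2.0) if center is None
             else np.atleast_1d(np.asarray(center, dtype=float)))
        inside = np.abs(pos - c[:, None]) <= window
        scores = np.where(inside, scores, -np.inf)
        w = np.exp(scores - scores.max(axis=1, keepdims=True))
        sigma = window / 2.0
        w = w * np.exp(-((pos - c[:, None]) ** 2) / (2.0 * sigma * sigma))
    elif mode == "global":
        w = np.exp(scores - scores.max(axis=1, keepdims=True))
    else:
        raise ValueError(f"unknown attention mode {mode!r}")
    w = w / w.sum(axis=1, keepdims=True)
    ctx = np.einsum("bt,bth->bh", w, enc)
    return (ctx[0], w[0]) if squeeze else (ctx, w)


def _uniform(rng: np.random.Generator, shape, scale: float = 0.1) -> Tensor:
    return Tensor(rng.uniform(-scale, scale, size=shape), requires_grad=True)


class Seq2SeqModel:
    """Stacked-LSTM encoder–decoder with Luong attention."""

    def __init__(self, vocab_size: int, config: ModelConfig, seed: int = 0):
        if vocab_size < len(SPECIAL_TOKENS):
            raise ValueError("vocab_size must include the special tokens")
        self.vocab_size = vocab_size
        self.config = config
        self.seed = seed
        rng = np.random.default_rng(seed)
        E, H, L = config.embedding_dim, config.hidden_units, config.num_layers
        self.enc_dim = 2 * H if config.bidirectional else H
        p: dict[str, Tensor] = {}
        p["src_embed"] = _uniform(rng, (vocab_size, E))
        if config.tie_embeddings:
            p["tgt_embed"] = p["src_embed"]
        else:
            p["tgt_embed"] = _uniform(rng, (vocab_size, E))
        directions = ("fw", "bw") if config.bidirectional else ("fw",)
        for layer in range(L):
            in_enc = E if layer == 0 else self.enc_dim
            for d in directions:
                p[f"enc{layer}_{d}_Wx"] = _uniform(rng, (in_enc, 4 * H))
                p[f"enc{layer}_{d}_Wh"] = _uniform(rng, (H, 4 * H))
                p[f"enc{layer}_{d}_b"] = Tensor(np.zeros(4 * H), requires_grad=True)
            in_dec = E if layer == 0 else H
            p[f"dec{layer}_Wx"] = _uniform(rng, (in_dec, 4 * H))
            p[f"dec{layer}_Wh"] = _uniform(rng, (H, 4 * H))
            p[f"dec{layer}_b"] = Tensor(np.zeros(4 * H), requires_grad=True)
            if config.bidirectional:
                p[f"bridge{layer}_Wh"] = _uniform(rng, (2 * H, H))
                p[f"bridge{layer}_Wc"] = _uniform(rng, (2 * H, H))
        p["attn_Wa"] = _uniform(rng, (self.enc_dim, H))
        p["attn_Wc"] = _uniform(rng, (H + self.enc_dim, H))
        if not config.tie_output:
            p["out_W"] = _uniform(rng, (H, vocab_size))
        p["out_b"] = Tensor(np.zeros(vocab_size), requires_grad=True)
        if config.attention == "local":
            p["loc_Wp"] = _uniform(rng, (H, H))
            p["loc_vp"] = _uniform(rng, (H, 1))
        self.params = p
        self._dropout_rng = np.random.default_rng(seed + 1)

    # ------------------------------------------------------------------
    def named_unique_parameters(self) -> dict[str, Tensor]:
        """Parameters with tied tensors listed once (first name wins)."""
        seen: set[int] = set()
        out = {}
        for name, t in self.params.items():
            if id(t) not in seen:
                seen.add(id(t))
                out[name] = t
        return out

    def n_parameters(self) -> int:
        return sum(t.data.size for t in self.named_unique_parameters().values())

    def zero_grad(self) -> None:
        for t in self.params.values():
            t.grad = None

    def _dropout(self, x: Tensor, train: bool) -> Tensor:
        rate = self.config.dropout
        if not train or rate == 0.0:
            return x
        keep = (self._dropout_rng.random(x.shape) >= rate) / (1.0 - rate)
        return x * Tensor(keep)

    # ------------------------------------------------------------------
    def _run_lstm(self, inputs: Tensor, prefix: str, lengths: np.ndarray,
                  reverse: bool = False,
                  init: tuple[Tensor, Tensor] | None = None
                  ) -> tuple[Tensor, Tensor, Tensor]:
        """One LSTM pass over (B, T, in) inputs.

        ``reverse`` runs over each row's valid prefix back-to-front but
        returns outputs realigned to original time order.  Final states are
        taken at each row's true last step.  Returns (outputs (B,T,H),
        final_h (B,H), final_c (B,H)).
        """
        p = self.params
        B, T, _ = inputs.shape
        H = self.config.hidden_units
        idx = None
        if reverse:
            idx = np.zeros((B, T), dtype=int)
            for b, n in enumerate(lengths):
                idx[b, :n] = np.arange(n - 1, -1, -1)
                idx[b, n:] = np.arange(n, T)
            inputs = index_time(inputs, idx)
        gates_x = inputs @ p[f"{prefix}_Wx"] + p[f"{prefix}_b"]
        if init is None:
            h = Tensor(np.zeros((B, H)))
            c = Tensor(np.zeros((B, H)))
        else:
            h, c = init
        hs, cs = [], []
        for t in range(T):
            g = gates_x[:, t, :] + h @ p[f"{prefix}_Wh"]
            hc = lstm_cell(g, c)
            h = hc[:, :H]
            c = hc[:, H:]
            hs.append(h.reshape(B, 1, H))
            cs.append(c.reshape(B, 1, H))
        out = concat(hs, axis=1)
        call = concat(cs, axis=1)
        last = np.clip(lengths - 1, 0, None)[:, None]
        final_h = index_time(out, last)[:, 0, :]
        final_c = index_time(call, last)[:, 0, :]
        if reverse:
            out = index_time(out, idx)
        return out, final_h, final_c

    def encode(self, src_ids: np.ndarray, lengths: np.ndarray, train: bool = False
               ) -> tuple[Tensor, list[tuple[Tensor, Tensor]]]:
        """Encode padded source ids (B, T) into attended states and the
        decoder's initial states (one (h, c) pair per layer)."""
        cfg = self.config
        p = self.params
        x = embedding(p["src_embed"], src_ids)
        init_states: list[tuple[Tensor, Tensor]] = []
        out = x
        for layer in range(cfg.num_layers):
            prefix = f"enc{layer}"
            fw, fh, fc = self._run_lstm(out, f"{prefix}_fw", lengths)
            if cfg.bidirectional:
                bw, bh, bc = self._run_lstm(out, f"{prefix}_bw", lengths, reverse=True)
                out = concat([fw, bw], axis=2)
                h0 = (concat([fh, bh], axis=1) @ p[f"bridge{layer}_Wh"]).tanh()
                c0 = concat([fc, bc], axis=1) @ p[f"bridge{layer}_Wc"]
            else:
                out = fw
                h0, c0 = fh, fc
            init_states.append((h0, c0))
            if layer < cfg.num_layers - 1:
                out = self._dropout(out, train)
        return out, init_states

    # ------------------------------------------------------------------
    def _predict_center(self, h_top: Tensor, lengths: np.ndarray) -> np.ndarray:
        """Local attention's predicted alignment position (non-differentiated)."""
        p = self.params
        v = np.tanh(h_top.data @ p["loc_Wp"].data) @ p["loc_vp"].data
        return (lengths - 1) * (1.0 / (1.0 + np.exp(-v[:, 0])))

    def _attend(self, h_top: Tensor, enc_out: Tensor, enc_keys: Tensor,
                src_mask: np.ndarray, lengths: np.ndarray) -> tuple[Tensor, Tensor]:
        """Luong attention step: (B,H) state against (B,T,enc_dim) states."""
        cfg = self.config
        B, T, _ = enc_out.shape
        H = cfg.hidden_units
        scores = (enc_keys @ h_top.reshape(B, H, 1)).reshape(B, T)
        mask = src_mask.astype(bool)
        if cfg.attention == "local":
            center = self._predict_center(h_top, lengths)
            pos = np.arange(T)[None, :]
            inside = np.abs(pos - center[:, None]) <= cfg.local_window
            mask = mask & inside
            weights = softmax(scores, mask=mask)
            sigma = cfg.local_window / 2.0
            gauss = np.exp(-((pos - center[:, None]) ** 2) / (2.0 * sigma * sigma))
            weights = weights * Tensor(gauss)
            weights = weights / weights.sum(axis=1, keepdims=True)
        else:
            weights = softmax(scores, mask=mask)
        ctx = (weights.reshape(B, 1, T) @ enc_out).reshape(B, -1)
        return ctx, weights

    def _decode_step(self, y_ids: np.ndarray, states: list[tuple[Tensor, Tensor]],
                     enc_out: Tensor, enc_keys: Tensor, src_mask: np.ndarray,
                     lengths: np.ndarray, train: bool
                     ) -> tuple[Tensor, list[tuple[Tensor, Tensor]], Tensor]:
        cfg = self.config
        p = self.params
        H = cfg.hidden_units
        x = embedding(p["tgt_embed"], y_ids)
        new_states = []
        for layer in range(cfg.num_layers):
            h, c = states[layer]
            g = x @ p[f"dec{layer}_Wx"] + h @ p[f"dec{layer}_Wh"] + p[f"dec{layer}_b"]
            hc = lstm_cell(g, c)
            h = hc[:, :H]
            c = hc[:, H:]
            new_states.append((h, c))
            x = self._dropout(h, train) if layer < cfg.num_layers - 1 else h
        h_top = new_states[-1][0]
        ctx, weights = self._attend(h_top, enc_out, enc_keys, src_mask, lengths)
        attn_h = (concat([ctx, h_top], axis=1) @ p["attn_Wc"]).tanh()
        attn_h = self._dropout(attn_h, train)
        out_w = p["tgt_embed"].transpose() if cfg.tie_output else p["out_W"]
        logits = attn_h @ out_w + p["out_b"]
        return logits, new_states, weights

    # ------------------------------------------------------------------
    def loss(self, src_ids: np.ndarray, src_lengths: np.ndarray,
             tgt_in: np.ndarray, tgt_out: np.ndarray, train: bool = True
             ) -> tuple[Tensor, int]:
        """Teacher-forced masked cross-entropy over a padded batch.

        ``tgt_in`` starts with SOS; ``tgt_out`` ends with EOS; both padded
        with PAD.  Returns (mean token loss, number of real tokens).
        """
        B, T_src = src_ids.shape
        # length-based mask (an all-empty source still attends its one pad slot
        # rather than producing a degenerate all-masked softmax)
        src_lengths = np.maximum(src_lengths, 1)
        src_mask = np.arange(T_src)[None, :] < src_lengths[:, None]
        enc_out, states = self.encode(src_ids, src_lengths, train)
        enc_keys = enc_out @ self.params["attn_Wa"]
        total = None
        n_tokens = int((tgt_out != PAD_ID).sum())
        for t in range(tgt_in.shape[1]):
            logits, states, _ = self._decode_step(
                tgt_in[:, t], states, enc_out, enc_keys, src_mask, src_lengths, train)
            step = cross_entropy_sum(logits, tgt_out[:, t], (tgt_out[:, t] != PAD_ID)
                                     .astype(float))
            total = step if total is None else total + step
        return total * (1.0 / max(n_tokens, 1)), n_tokens

    def translate_ids(self, src_ids: np.ndarray, src_lengths: np.ndarray,
                      max_len: int = 102, grammar_mask: bool = True
                      ) -> list[list[int]]:
        """Greedy argmax decoding of a padded batch; returns token-id lists
        without SOS/EOS.

        With ``grammar_mask`` (default) decoding is constrained to
        well-formed fragment sentences: within a segment, words must be
        unique and in ascending rank (word ids are rank-ordered, so legal
        words are exactly ids above the last emitted one); at most one
        separator is allowed, and only after at least one word.  The argmax
        is taken over the legal continuations.
        """
        B, T_src = src_ids.shape
        src_lengths = np.maximum(src_lengths, 1)
        src_mask = np.arange(T_src)[None, :] < src_lengths[:, None]
        enc_out, states = self.encode(src_ids, src_lengths, train=False)
        enc_keys = enc_out @ self.params["attn_Wa"]
        y = np.full(B, SOS_ID, dtype=int)
        done = np.zeros(B, dtype=bool)
        last_word = np.full(B, SEP_ID, dtype=int)   # words legal iff id > this
        sep_used = np.zeros(B, dtype=bool)
        segment_empty = np.ones(B, dtype=bool)
        outputs: list[list[int]] = [[] for _ in range(B)]
        all_ids = np.arange(self.vocab_size)
        for _ in range(max_len):
            logits, states, _ = self._decode_step(
                y, states, enc_out, enc_keys, src_mask, src_lengths, train=False)
            z = logits.data.copy()
            if grammar_mask:
                illegal = all_ids[None, :] <= last_word[:, None]
                illegal[:, PAD_ID] = True
                illegal[:, SOS_ID] = True
                illegal[:, EOS_ID] = False
                illegal[:, SEP_ID] = sep_used | segment_empty
                z[illegal] = -np.inf
            else:
                z[:, PAD_ID] = -np.inf
                z[:, SOS_ID] = -np.inf
            y = z.argmax(axis=1)
            y[done] = PAD_ID
            for b in range(B):
                if done[b]:
                    continue
                tok = int(y[b])
                if tok == EOS_ID:
                    done[b] = True
                elif tok == SEP_ID:
                    outputs[b].append(tok)
                    sep_used[b] = True
                    segment_empty[b] = True
                    last_word[b] = SEP_ID
                elif tok != PAD_ID:
                    outputs[b].append(tok)
                    segment_empty[b] = False
                    last_word[b] = tok
            if done.all():
                break
        return outputs

    # ------------------------------------------------------------------
    def save(self, path) -> None:
        meta = {"vocab_size": self.vocab_size, "config": asdict(self.config),
                "seed": self.seed}
        arrays = {k: t.data for k, t in self.params.items()}
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path) -> "Seq2SeqModel":
        with np.load(path) as npz:
            meta = json.loads(bytes(npz["__meta__"]).decode())
            model = cls(meta["vocab_size"], ModelConfig(**meta["config"]),
                        seed=meta.get("seed", 0))
            for k in model.params:
                model.params[k].data = npz[k].astype(np.float64)
        return model


def build_model(vocab_size: int, config: ModelConfig, seed: int = 0) -> Seq2SeqModel:
    return Seq2SeqModel(vocab_size, config, seed=seed)


def count_parameters(vocab_size: int, config: ModelConfig) -> int:
    """Closed-form parameter count of :class:`Seq2SeqModel`."""
    E, H, L = config.embedding_dim, config.hidden_units, config.num_layers
    enc_dim = 2 * H if config.bidirectional else H
    ndir = 2 if config.bidirectional else 1
    n = (1 if config.tie_embeddings else 2) * vocab_size * E  # embeddings
    for layer in range(L):
        in_enc = E if layer == 0 else enc_dim
        n += ndir * (in_enc * 4 * H + H * 4 * H + 4 * H)
        in_dec = E if layer == 0 else H
        n += in_dec * 4 * H + H * 4 * H + 4 * H
        if config.bidirectional:
            n += 2 * (2 * H * H)                 # h and c bridges
    n += enc_dim * H                             # attention W_a
    n += (H + enc_dim) * H                       # attention W_c
    if config.tie_output:
        n += vocab_size                          # only the output bias
    else:
        n += H * vocab_size + vocab_size         # output layer
    if config.attention == "local":
        n += H * H + H
    return n
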