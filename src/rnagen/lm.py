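"""Compact decoder-only autoregressive language model over RNA tokens.

A GPT-style causal transformer with rotary position encoding (applied to
queries and keys inside every attention layer, or once to the token
embeddings in "overall" mode), RMS normalization in the blocks, weight
tying between the embedding and the output head, and padding excluded
from every loss and perplexity. Training uses AdamW with a linear (or
cosine) learning-rate decay and early stopping on validation loss.

All computation is NumPy (float32) via the in-package autograd engine;
the models are deliberately small and CPU-sized.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._autograd import AdamW, Tensor, cat, masked_cross_entropy
from .sequence_io import NucleotideSequence
from .tokenizer import TokenizerSpec, encode as tok_encode


@dataclass
class LMConfig:
    context_window: int = 384
    n_layers: int = 18
    n_heads: int = 6
    d_embed: int = 300
    dropout: float = 0.0
    rope_mode: str = "per_layer"  # or "overall"
    norm: str = "rms"

    def __post_init__(self):
        if self.d_embed % self.n_heads:
            raise ValueError(
                f"d_embed={self.d_embed} not divisible by n_heads={self.n_heads}"
            )
        if self.context_window < 2:
            raise ValueError("context window must be >= 2")
        if self.rope_mode not in ("per_layer", "overall"):
            raise ValueError(f"unknown rope_mode {self.rope_mode!r}")

    @classmethod
    def tiny(cls, context_window: int = 384) -> "LMConfig":
        return cls(context_window=context_window, n_layers=2, n_heads=2, d_embed=64)


@dataclass
class TrainConfig:
    lr_start: float = 5e-5
    lr_end: float = 5e-6
    decay_iters: int = 100_000
    schedule: str = "linear"  # or "cosine"
    beta2: float = 0.998
    batch_size: int = 18
    max_iters: int = 2000
    eval_interval: int = 100
    eval_batches: int | None = 8  # None: evaluate the full validation set
    early_stop_patience: int = 5
    weight_decay: float = 0.01
    rng_seed: int = 0

    def __post_init__(self):
        if self.lr_end > self.lr_start:
            raise ValueError("lr_end must be <= lr_start")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")

    def lr_at(self, it: int) -> float:
        t = min(it, self.decay_iters) / self.decay_iters
        if self.schedule == "cosine":
            return self.lr_end + 0.5 * (self.lr_start - self.lr_end) * (1 + math.cos(math.pi * t))
        return self.lr_start + (self.lr_end - self.lr_start) * t


@dataclass
class GenerationConfig:
    seed_prefix: str
    temperature: float = 0.5
    n_sequences: int = 100
    max_nucleotides: int = 400
    rng_seed: int = 0

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("generation temperature must be > 0")


@dataclass
class TrainReport:
    history: list[dict] = field(default_factory=list)
    best_iteration: int = -1
    best_val_nll: float = float("inf")
    notes: list[str] = field(default_factory=list)
    parent_checkpoint: str | None = None

    @property
    def best_val_perplexity(self) -> float:
        return float(np.exp(self.best_val_nll))


def _rope_tables(T: int, dim: int) -> tuple[np.ndarray, np.ndarray]:
    half = dim // 2
    freqs = 1.0 / (10000.0 ** (np.arange(half) / half))
    ang = np.outer(np.arange(T), freqs)  # (T, half)
    ang = np.concatenate([ang, ang], axis=-1)
    return np.cos(ang).astype(np.float32), np.sin(ang).astype(np.float32)


def _rotate_half(x: Tensor) -> Tensor:
    d = x.shape[-1]
    x1 = x[..., : d // 2]
    x2 = x[..., d // 2 :]
    return cat([-x2, x1], axis=-1)


class RnaLM:
    """Decoder-only causal transformer over an n-gram token vocabulary."""

    def __init__(self, cfg: LMConfig, spec: TokenizerSpec, rng_seed: int = 0):
        self.cfg = cfg
        self.spec = spec
        self.rng_seed = rng_seed
        self.provenance: dict = {"rng_seed": rng_seed}
        rng = np.random.default_rng(rng_seed)
        d, V = cfg.d_embed, spec.vocab_size
        p: dict[str, Tensor] = {}
        p["tok_emb"] = Tensor(rng.normal(0, 0.02, size=(V, d)), requires_grad=True)
        for li in range(cfg.n_layers):
            for name, shape in (
                ("q", (d, d)), ("k", (d, d)), ("v", (d, d)), ("o", (d, d)),
                ("f1", (d, 4 * d)), ("f2", (4 * d, d)),
            ):
                scale = 0.02 if name != "o" else 0.02 / np.sqrt(2 * cfg.n_layers)
                p[f"l{li}_{name}"] = Tensor(
                    rng.normal(0, scale, size=shape), requires_grad=True
                )
            p[f"l{li}_g1"] = Tensor(np.ones(d), requires_grad=True)
            p[f"l{li}_g2"] = Tensor(np.ones(d), requires_grad=True)
        p["out_g"] = Tensor(np.ones(d), requires_grad=True)
        self.params = p
        hd = d // cfg.n_heads
        self._cos_h, self._sin_h = _rope_tables(cfg.context_window, hd)
        self._cos_d, self._sin_d = _rope_tables(cfg.context_window, d)

    # -- forward ---------------------------------------------------------------
    @staticmethod
    def _rms(x: Tensor, g: Tensor) -> Tensor:
        scale = ((x * x).mean(axis=-1, keepdims=True) + 1e-6) ** -0.5
        return x * scale * g

    def forward(self, ids: np.ndarray, train: bool = False,
                drop_rng: np.random.Generator | None = None) -> Tensor:
        """ids: (B, T) int; returns logits Tensor (B, T, V)."""
        cfg = self.cfg
        p = self.params
        B, T = ids.shape
        if T > cfg.context_window:
            raise ValueError(f"input length {T} exceeds context window")
        d, H = cfg.d_embed, cfg.n_heads
        hd = d // H
        x = p["tok_emb"][ids]  # (B, T, d)
        if cfg.rope_mode == "overall":
            x = x * Tensor(self._cos_d[:T]) + _rotate_half(x) * Tensor(self._sin_d[:T])
        causal = np.triu(np.full((T, T), -1e9, dtype=np.float32), k=1)[None, None]
        cos = Tensor(self._cos_h[:T])
        sin = Tensor(self._sin_h[:T])
        use_drop = train and cfg.dropout > 0 and drop_rng is not None

        for li in range(cfg.n_layers):
            hn = self._rms(x, p[f"l{li}_g1"])
            q = (hn @ p[f"l{li}_q"]).reshape(B, T, H, hd).transpose(0, 2, 1, 3)
            k = (hn @ p[f"l{li}_k"]).reshape(B, T, H, hd).transpose(0, 2, 1, 3)
            v = (hn @ p[f"l{li}_v"]).reshape(B, T, H, hd).transpose(0, 2, 1, 3)
            if cfg.rope_mode == "per_layer":
                q = q * cos + _rotate_half(q) * sin
                k = k * cos + _rotate_half(k) * sin
            scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(hd))
            scores = scores + Tensor(causal)
            w = scores.softmax(axis=-1)
            if use_drop:
                keep = (drop_rng.random(w.shape) >= cfg.dropout) / (1 - cfg.dropout)
                w = w * Tensor(keep.astype(np.float32))
            ctx = (w @ v).transpose(0, 2, 1, 3).reshape(B, T, d)
            x = x + ctx @ p[f"l{li}_o"]
            hn = self._rms(x, p[f"l{li}_g2"])
            ff = (hn @ p[f"l{li}_f1"]).gelu() @ p[f"l{li}_f2"]
            if use_drop:
                keep = (drop_rng.random(ff.shape) >= cfg.dropout) / (1 - cfg.dropout)
                ff = ff * Tensor(keep.astype(np.float32))
            x = x + ff
        x = self._rms(x, p["out_g"])
        return x @ p["tok_emb"].swapaxes(0, 1)  # weight-tied head

    def loss(self, ids: np.ndarray, train: bool = False,
             drop_rng: np.random.Generator | None = None) -> tuple[Tensor, int]:
        """Next-token cross entropy over non-PAD targets.

        Returns (mean-NLL Tensor, number of scored tokens)."""
        inputs, targets = ids[:, :-1], ids[:, 1:]
        mask = (targets != self.spec.pad_id).reshape(-1)
        logits = self.forward(inputs, train=train, drop_rng=drop_rng)
        B, T, V = logits.shape
        loss = masked_cross_entropy(
            logits.reshape(B * T, V), targets.reshape(-1), mask
        )
        return loss, int(mask.sum())

    # -- pure-NumPy inference (no autograd graph) ------------------------------
    @staticmethod
    def _rms_np(x: np.ndarray, g: np.ndarray) -> np.ndarray:
        scale = 1.0 / np.sqrt((x * x).mean(axis=-1, keepdims=True) + 1e-6)
        return x * scale * g

    @staticmethod
    def _gelu_np(x: np.ndarray) -> np.ndarray:
        c = np.float32(np.sqrt(2.0 / np.pi))
        return np.float32(0.5) * x * (1.0 + np.tanh(c * (x + np.float32(0.044715) * x * x * x)))

    @staticmethod
    def _rot_half_np(x: np.ndarray) -> np.ndarray:
        h = x.shape[-1] // 2
        return np.concatenate([-x[..., h:], x[..., :h]], axis=-1)

    def logits_np(self, ids: np.ndarray) -> np.ndarray:
        """Inference logits as a plain array (matches forward(), no dropout)."""
        cfg = self.cfg
        p = {k: v.data for k, v in self.params.items()}
        B, T = ids.shape
        if T > cfg.context_window:
            raise ValueError(f"input length {T} exceeds context window")
        d, H = cfg.d_embed, cfg.n_heads
        hd = d // H
        x = p["tok_emb"][ids]
        if cfg.rope_mode == "overall":
            x = x * self._cos_d[:T] + self._rot_half_np(x) * self._sin_d[:T]
        cos, sin = self._cos_h[:T], self._sin_h[:T]
        causal = np.triu(np.full((T, T), -1e9, dtype=np.float32), k=1)
        for li in range(cfg.n_layers):
            hn = self._rms_np(x, p[f"l{li}_g1"])
            q = (hn @ p[f"l{li}_q"]).reshape(B, T, H, hd).transpose(0, 2, 1, 3)
            k = (hn @ p[f"l{li}_k"]).reshape(B, T, H, hd).transpose(0, 2, 1, 3)
            v = (hn @ p[f"l{li}_v"]).reshape(B, T, H, hd).transpose(0, 2, 1, 3)
            if cfg.rope_mode == "per_layer":
                q = q * cos + self._rot_half_np(q) * sin
                k = k * cos + self._rot_half_np(k) * sin
            scores = (q @ k.swapaxes(-1, -2)) * np.float32(1.0 / np.sqrt(hd)) + causal
            scores -= scores.max(axis=-1, keepdims=True)
            w = np.exp(scores)
            w /= w.sum(axis=-1, keepdims=True)
            ctx = (w @ v).transpose(0, 2, 1, 3).reshape(B, T, d)
            x = x + ctx @ p[f"l{li}_o"]
            hn = self._rms_np(x, p[f"l{li}_g2"])
            x = x + self._gelu_np(hn @ p[f"l{li}_f1"]) @ p[f"l{li}_f2"]
        x = self._rms_np(x, p["out_g"])
        return x @ p["tok_emb"].T

    def _prefill(self, ids: np.ndarray) -> tuple[np.ndarray, list]:
        """Run the prefix through the model, returning last-position logits
        and a per-layer KV cache for incremental decoding."""
        cfg = self.cfg
        p = {k: v.data for k, v in self.params.items()}
        B, T = ids.shape
        d, H = cfg.d_embed, cfg.n_heads
        hd = d // H
        x = p["tok_emb"][ids]
        if cfg.rope_mode == "overall":
            x = x * self._cos_d[:T] + self._rot_half_np(x) * self._sin_d[:T]
        cos, sin = self._cos_h[:T], self._sin_h[:T]
        causal = np.triu(np.full((T, T), -1e9, dtype=np.float32), k=1)
        cache = []
        for li in range(cfg.n_layers):
            hn = self._rms_np(x, p[f"l{li}_g1"])
            q = (hn @ p[f"l{li}_q"]).reshape(B, T, H, hd).transpose(0, 2, 1, 3)
            k = (hn @ p[f"l{li}_k"]).reshape(B, T, H, hd).transpose(0, 2, 1, 3)
            v = (hn @ p[f"l{li}_v"]).reshape(B, T, H, hd).transpose(0, 2, 1, 3)
            if cfg.rope_mode == "per_layer":
                q = q * cos + self._rot_half_np(q) * sin
                k = k * cos + self._rot_half_np(k) * sin
            cache.append([k, v])
            scores = (q @ k.swapaxes(-1, -2)) * np.float32(1.0 / np.sqrt(hd)) + causal
            scores -= scores.max(axis=-1, keepdims=True)
            w = np.exp(scores)
            w /= w.sum(axis=-1, keepdims=True)
            ctx = (w @ v).transpose(0, 2, 1, 3).reshape(B, T, d)
            x = x + ctx @ p[f"l{li}_o"]
            hn = self._rms_np(x, p[f"l{li}_g2"])
            x = x + self._gelu_np(hn @ p[f"l{li}_f1"]) @ p[f"l{li}_f2"]
        x = self._rms_np(x[:, -1], p["out_g"])
        return x @ p["tok_emb"].T, cache

    def _decode_step(self, ids_new: np.ndarray, pos: int, cache: list) -> np.ndarray:
        """One incremental decoding step: ids_new (B,), absolute position
        `pos`; appends to the KV cache and returns next-token logits."""
        cfg = self.cfg
        p = {k: v.data for k, v in self.params.items()}
        B = ids_new.shape[0]
        d, H = cfg.d_embed, cfg.n_heads
        hd = d // H
        x = p["tok_emb"][ids_new]  # (B, d)
        if cfg.rope_mode == "overall":
            x = x * self._cos_d[pos] + self._rot_half_np(x) * self._sin_d[pos]
        for li in range(cfg.n_layers):
            hn = self._rms_np(x, p[f"l{li}_g1"])
            q = (hn @ p[f"l{li}_q"]).reshape(B, H, 1, hd)
            k = (hn @ p[f"l{li}_k"]).reshape(B, H, 1, hd)
            v = (hn @ p[f"l{li}_v"]).reshape(B, H, 1, hd)
            if cfg.rope_mode == "per_layer":
                q = q * self._cos_h[pos] + self._rot_half_np(q) * self._sin_h[pos]
                k = k * self._cos_h[pos] + self._rot_half_np(k) * self._sin_h[pos]
            K = np.concatenate([cache[li][0], k], axis=2)
            V = np.concatenate([cache[li][1], v], axis=2)
            cache[li][0], cache[li][1] = K, V
            scores = (q @ K.swapaxes(-1, -2)) * np.float32(1.0 / np.sqrt(hd))
            scores -= scores.max(axis=-1, keepdims=True)
            w = np.exp(scores)
            w /= w.sum(axis=-1, keepdims=True)
            ctx = (w @ V).reshape(B, d)
            x = x + ctx @ p[f"l{li}_o"]
            hn = self._rms_np(x, p[f"l{li}_g2"])
            x = x + self._gelu_np(hn @ p[f"l{li}_f1"]) @ p[f"l{li}_f2"]
        x = self._rms_np(x, p["out_g"])
        return x @ p["tok_emb"].T

    def clone(self) -> "RnaLM":
        other = RnaLM(self.cfg, self.spec, self.rng_seed)
        for k, v in self.params.items():
            other.params[k].data = v.data.copy()
        other.provenance = dict(self.provenance)
        return other

    # -- persistence ------------------------------------------------------------
    def save(self, path) -> None:
        import json

        meta = {
            "config": self.cfg.__dict__,
            "tokenizer": {"n": self.spec.n, "step": self.spec.step,
                          "vocab": self.spec.vocab},
            "provenance": self.provenance,
        }
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **{k: v.data for k, v in self.params.items()})

    @classmethod
    def load(cls, path) -> "RnaLM":
        import json

        with np.load(path) as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            cfg = LMConfig(**meta["config"])
            spec = TokenizerSpec(n=meta["tokenizer"]["n"],
                                 vocab=meta["tokenizer"]["vocab"],
                                 step=meta["tokenizer"]["step"])
            model = cls(cfg, spec)
            model.provenance = meta.get("provenance", {})
            for k in model.params:
                model.params[k].data = z[k].astype(np.float32)
        return model


def init_model(cfg: LMConfig, spec: TokenizerSpec, rng_seed: int = 0) -> RnaLM:
    return RnaLM(cfg, spec, rng_seed=rng_seed)


# ---------------------------------------------------------------------------
# batching, training, evaluation
# ---------------------------------------------------------------------------


def make_batch(token_lists: list[list[int]], idx: np.ndarray, pad_id: int,
               max_len: int, rng: np.random.Generator) -> np.ndarray:
    """Left-aligned, PAD-tailed batch; sequences beyond max_len get a
    random contiguous crop."""
    chosen = []
    for i in idx:
        ids = token_lists[i]
        if len(ids) > max_len:
            start = int(rng.integers(0, len(ids) - max_len + 1))
            ids = ids[start : start + max_len]
        chosen.append(ids)
    width = max(len(c) for c in chosen)
    batch = np.full((len(chosen), width), pad_id, dtype=np.int64)
    for r, ids in enumerate(chosen):
        batch[r, : len(ids)] = ids
    return batch


def evaluate_nll(model: RnaLM, token_lists: list[list[int]],
                 batch_size: int = 32, max_batches: int | None = None) -> float:
    """Mean NLL per non-PAD token over a dataset (deterministic).

    Sequences longer than the context window are scored in overlapping
    chunks with each token scored exactly once (see `_score_encoded`).
    """
    if max_batches is not None:
        token_lists = token_lists[: max_batches * batch_size]
    scored = _score_encoded(model, token_lists, batch_size)
    total = sum(lp for lp, _, _ in scored)
    count = sum(n for _, n, _ in scored)
    return -total / max(count, 1)


def _windows(ids: list[int], cw: int) -> list[list[int]]:
    if len(ids) <= cw + 1:
        return [ids]
    out = [ids[: cw + 1]]
    pos = cw + 1
    overlap = cw // 2
    while pos < len(ids):
        start = pos - overlap
        out.append(ids[start : start + cw + 1])
        pos = start + cw + 1
    return out


def train(
    model: RnaLM,
    train_tokens: list[list[int]],
    val_tokens: list[list[int]],
    cfg: TrainConfig,
) -> tuple[RnaLM, TrainReport]:
    """Train with AdamW, decayed LR, and early stopping on validation NLL.

    Returns the best-validation model (parameters restored in place)."""
    if not train_tokens:
        raise ValueError("empty training dataset")
    rng = np.random.default_rng(cfg.rng_seed)
    drop_rng = np.random.default_rng(rng.integers(2**31))
    opt = AdamW(model.params, lr=cfg.lr_start, betas=(0.9, cfg.beta2),
                weight_decay=cfg.weight_decay)
    report = TrainReport()
    best_params = {k: v.data.copy() for k, v in model.params.items()}
    stall = 0
    cw = model.cfg.context_window
    for it in range(1, cfg.max_iters + 1):
        idx = rng.integers(0, len(train_tokens), size=cfg.batch_size)
        batch = make_batch(train_tokens, idx, model.spec.pad_id, cw + 1, rng)
        loss, _ = model.loss(batch, train=True, drop_rng=drop_rng)
        opt.zero_grad()
        loss.backward()
        opt.lr = cfg.lr_at(it)
        opt.step()
        if it % cfg.eval_interval == 0 or it == cfg.max_iters:
            val_nll = evaluate_nll(model, val_tokens, batch_size=cfg.batch_size,
                                   max_batches=cfg.eval_batches)
            report.history.append(
                {"iteration": it, "train_nll": float(loss.data),
                 "val_nll": val_nll, "val_perplexity": float(np.exp(val_nll))}
            )
            if val_nll < report.best_val_nll - 1e-4:
                report.best_val_nll = val_nll
                report.best_iteration = it
                best_params = {k: v.data.copy() for k, v in model.params.items()}
                stall = 0
            else:
                stall += 1
                if stall >= cfg.early_stop_patience:
                    break
    for k, v in model.params.items():
        v.data = best_params[k]
    if report.best_val_nll == float("inf") and val_tokens:
        report.best_val_nll = evaluate_nll(model, val_tokens)
    return model, report


def finetune(
    model: RnaLM,
    finetune_tokens: list[list[int]],
    val_tokens: list[list[int]],
    cfg: TrainConfig,
    train_ids: list[str] | None = None,
    pretrain_val_ids: set[str] | None = None,
) -> tuple[RnaLM, TrainReport]:
    """Continue training from a pretrained model on a subpopulation.

    The finetuning split should respect the pretraining partition; if row
    ids are provided, any finetune-train sequence that belonged to the
    pretraining validation set is recorded as a partition violation."""
    parent = model.provenance.get("checkpoint_id", "parent")
    child = model.clone()
    child.provenance["parent_checkpoint"] = parent
    report_notes = []
    if train_ids is not None and pretrain_val_ids:
        bad = sorted(set(train_ids) & pretrain_val_ids)
        if bad:
            report_notes.append(
                f"partition violation: {len(bad)} finetuning sequences were in "
                f"the pretraining validation set (e.g. {bad[:3]})"
            )
    if cfg.max_iters == 0:
        report = TrainReport(notes=report_notes, parent_checkpoint=parent)
        if val_tokens:
            report.best_val_nll = evaluate_nll(child, val_tokens)
        return child, report
    child, report = train(child, finetune_tokens, val_tokens, cfg)
    report.notes.extend(report_notes)
    report.parent_checkpoint = parent
    return child, report


# ---------------------------------------------------------------------------
# likelihood and generation
# ---------------------------------------------------------------------------


@dataclass
class LogProbResult:
    logp: float
    n_scored_tokens: int
    windowed: bool


def _token_logps(model: RnaLM, batch: np.ndarray) -> np.ndarray:
    """log p(token_t | tokens_<t) for t >= 1; (B, T-1)."""
    logits = model.logits_np(batch[:, :-1]).astype(np.float64)
    z = logits - logits.max(axis=-1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=-1, keepdims=True))
    tgt = batch[:, 1:]
    B, Tm1 = tgt.shape
    return logp[np.arange(B)[:, None], np.arange(Tm1)[None, :], tgt]


def sequence_log_probability(
    model: RnaLM, seq: NucleotideSequence | str
) -> LogProbResult:
    return sequence_log_probabilities(model, [seq])[0]


def _score_encoded(
    model: RnaLM, encoded: list[list[int]], batch_size: int = 64,
    skip_tokens: int = 0
) -> list[tuple[float, int, bool]]:
    """Sum of token log-probabilities for each encoded sequence.

    Sequences longer than context+1 tokens are scored in chunks that
    overlap by half a window: a later chunk's first cw//2 tokens are
    conditioning context only, so every token is scored exactly once.
    `skip_tokens` leaves the first that many scored tokens (e.g. a
    generation seed) out of the sum. Returns (logp, n_scored_tokens,
    windowed) per sequence."""
    cw = model.cfg.context_window
    pad = model.spec.pad_id
    overlap = cw // 2
    results: list[tuple[float, int, bool]] = []
    for s in range(0, len(encoded), batch_size):
        group = encoded[s : s + batch_size]
        window_lists = [_windows(ids, cw) for ids in group]
        n_win = max(len(w) for w in window_lists)
        totals = np.zeros(len(group))
        counts = np.zeros(len(group), dtype=int)
        for wi in range(n_win):
            members = [gi for gi, wl in enumerate(window_lists) if wi < len(wl)]
            chunks = [window_lists[gi][wi] for gi in members]
            width = max(len(c) for c in chunks)
            batch = np.full((len(chunks), width), pad, dtype=np.int64)
            for r, c in enumerate(chunks):
                batch[r, : len(c)] = c
            lp = _token_logps(model, batch)  # lp[:, j] scores chunk[j+1]
            for r, gi in enumerate(members):
                chunk = window_lists[gi][wi]
                lo = 0 if wi == 0 else overlap - 1
                n_score = (len(chunk) - 1) if wi == 0 else (len(chunk) - overlap)
                if wi == 0 and skip_tokens:
                    lo += skip_tokens
                    n_score = max(0, n_score - skip_tokens)
                totals[gi] += lp[r, lo : lo + n_score].sum()
                counts[gi] += n_score
        for gi in range(len(group)):
            results.append(
                (float(totals[gi]), int(counts[gi]), len(window_lists[gi]) > 1)
            )
    return results


def sequence_log_probabilities(
    model: RnaLM, seqs: list[NucleotideSequence | str], batch_size: int = 64,
    skip_seed_tokens: int = 0
) -> list[LogProbResult]:
    """Total log probability (body + EOS tokens, conditioned from BOS) for
    each sequence; deterministic. Sequences longer than the context window
    are scored with half-window-overlap chunks (flagged `windowed`).
    `skip_seed_tokens` excludes the first that many scored tokens, for
    sensitivity analyses that leave the generation seed out of the sum."""
    encoded = [tok_encode(s, model.spec).ids for s in seqs]
    return [
        LogProbResult(logp=lp, n_scored_tokens=n, windowed=w)
        for lp, n, w in _score_encoded(model, encoded, batch_size,
                                       skip_tokens=skip_seed_tokens)
    ]


@dataclass
class GenerationResult:
    sequences: list[NucleotideSequence]
    inconsistency_counts: list[int]


def generate(model: RnaLM, gcfg: GenerationConfig) -> GenerationResult:
    """Temperature-scaled ancestral sampling seeded with a 5'-prefix.

    Logits are divided by T before the softmax; sampling stops at EOS or
    at max_nucleotides. With step-1 tokenization each sampled token reveals
    one new nucleotide (its last character); adjacent sampled tokens whose
    (n-1)-overlap disagrees are counted per sequence, and the revealed
    last character wins, so every output begins with the seed prefix."""
    spec = model.spec
    n = spec.n
    if len(gcfg.seed_prefix) < n:
        raise ValueError("seed prefix shorter than the n-gram size")
    rng = np.random.default_rng(gcfg.rng_seed)
    seed_ids = tok_encode(gcfg.seed_prefix, spec).ids[:-1]  # drop EOS
    cw = model.cfg.context_window
    B = gcfg.n_sequences
    max_body = gcfg.max_nucleotides - n + 1
    seqs = np.tile(np.array(seed_ids, dtype=np.int64), (B, 1))
    done = np.zeros(B, dtype=bool)
    logits, cache = model._prefill(seqs[:, -cw:])
    while seqs.shape[1] - 1 < max_body and not done.all():
        logits = logits.astype(np.float64)
        logits[:, spec.pad_id] = -np.inf  # only nucleotide tokens or EOS
        logits[:, spec.bos_id] = -np.inf
        logits /= gcfg.temperature
        logits -= logits.max(axis=-1, keepdims=True)
        probs = np.exp(logits)
        probs /= probs.sum(axis=-1, keepdims=True)
        u = rng.random((B, 1))
        nxt = (probs.cumsum(axis=-1) > u).argmax(axis=-1)
        nxt[done] = spec.pad_id
        seqs = np.concatenate([seqs, nxt[:, None]], axis=1)
        done |= nxt == spec.eos_id
        if seqs.shape[1] - 1 >= max_body or done.all():
            break
        if seqs.shape[1] < cw:
            logits = model._decode_step(nxt, seqs.shape[1] - 1, cache)
        else:
            # context window exceeded: slide the window (no cache reuse)
            logits = model.logits_np(seqs[:, -cw:])[:, -1, :]
    rev = spec.id_to_token()
    n_seed_tokens = len(seed_ids)
    sequences, counts = [], []
    for r in range(B):
        ids = [t for t in seqs[r].tolist() if t != spec.pad_id]
        if ids[-1] == spec.eos_id:
            ids = ids[:-1]
        grams = [rev[t] for t in ids[1:]]
        bad = sum(1 for a, b in zip(grams, grams[1:]) if a[1:] != b[:-1])
        residues = gcfg.seed_prefix + "".join(
            g[-1] for g in grams[n_seed_tokens - 1 :]
        )
        sequences.append(
            NucleotideSequence(
                id=f"gen_{r:04d}",
                residues=residues,
                description=f"T={gcfg.temperature} seed={len(gcfg.seed_prefix)}nt",
            )
        )
        counts.append(bad)
    return GenerationResult(sequences=sequences, inconsistency_counts=counts)
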