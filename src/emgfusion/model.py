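"""Dual-branch attention-fusion classifier for trunk-motion intention.

Architecture, in pipeline order:

1. **Image branch** — a VGG16-style convolutional stack (the canonical
   2-2-3-3-3 block layout with 3x3 kernels and 2x2 max pooling, widths
   configurable) over the 6-plane GAF stack, ending in the usual two
   fully-connected layers; a final linear map brings it to ``d_model``.
2. **Sequence branch** — a single-layer LSTM over the per-window VMD/Welch
   feature vectors; the final hidden state is projected to ``d_model``.
3. **FRIM** — fine-grained relationship inference: multi-head scaled
   dot-product self-attention (Q = W_Q x, K = W_K x, V = W_V x;
   scores = Q K^T / sqrt(d_k); row softmax; context = weights V), then a
   feature-fusion linear + ReLU with a residual add of the input and layer
   normalisation. By default it runs over a 3-token sequence: the two
   branch embeddings plus a learned projection of their concatenation.
4. **Cross-attention fusion** — bidirectional single-token cross-attention
   with tied projections (query from one modality, key/value from the
   other, and vice versa) through the same fusion/residual/normalisation
   machinery; the two refined views are averaged into one fused embedding.
5. **Heads** — an auxiliary linear soft-max head provides the
   differentiable cross-entropy objective for end-to-end Adam training; a
   random forest fitted post hoc on the fused embeddings of the
   best-validation checkpoint produces the reported class probabilities
   (vote fractions).

The ablation variants mirror the model-component study: ``vgg_only``,
``lstm_only``, ``vgg_lstm_no_cam`` (concatenated branches + FRIM, no
cross-attention) and ``full``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import f1_score

from . import nn
from .config import ModelConfig, PipelineConfig, derive_seed
from .features import build_feature_sequence
from .gaf import encode_stack
from .io_core import MovementLabel, Recording
from .preprocess import ActiveSegment, preprocess_recording, segment_recording

CLASSES: Tuple[MovementLabel, ...] = MovementLabel.movement_classes()
VARIANTS = ("vgg_only", "lstm_only", "vgg_lstm_no_cam", "full")


# ---------------------------------------------------------------------------
# attention building blocks

class MultiHeadAttention(nn.Module):
    """Scaled dot-product attention with learned Q/K/V projections.

    Supports self-attention (``kv`` omitted) and cross-attention (separate
    key/value source). ``last_weights`` keeps the most recent attention
    weight array, shape (B, heads, T_q, T_kv); every row is a probability
    distribution.
    """

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        if d_model % n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        self.d_model = d_model
        self.n_heads = n_heads
        self.d_k = d_model // n_heads
        self.w_q = nn.Linear(d_model, d_model, rng, bias=False)
        self.w_k = nn.Linear(d_model, d_model, rng, bias=False)
        self.w_v = nn.Linear(d_model, d_model, rng, bias=False)
        self.last_weights: Optional[np.ndarray] = None

    def _split(self, x: nn.Tensor, B: int, T: int) -> nn.Tensor:
        return (x.reshape(B, T, self.n_heads, self.d_k)
                .transpose(0, 2, 1, 3)
                .reshape(B * self.n_heads, T, self.d_k))

    def __call__(self, x: nn.Tensor, kv: Optional[nn.Tensor] = None) -> nn.Tensor:
        kv = x if kv is None else kv
        B, Tq, _ = x.data.shape
        Tk = kv.data.shape[1]
        q = self._split(self.w_q(x), B, Tq)
        k = self._split(self.w_k(kv), B, Tk)
        v = self._split(self.w_v(kv), B, Tk)
        scores = (q @ k.transpose(0, 2, 1)) * (1.0 / np.sqrt(self.d_k))
        weights = scores.softmax(axis=-1)
        self.last_weights = weights.data.reshape(B, self.n_heads, Tq, Tk).copy()
        context = weights @ v
        return (context.reshape(B, self.n_heads, Tq, self.d_k)
                .transpose(0, 2, 1, 3)
                .reshape(B, Tq, self.d_model))


class FRIM(nn.Module):
    """Fine-grained relationship inference: attention + fusion + residual.

    ``out = LayerNorm(ReLU(W_fusion context) + x)``, with the context from
    multi-head self-attention (or cross-attention when ``kv`` is given).
    """

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        self.attn = MultiHeadAttention(d_model, n_heads, rng)
        self.fusion = nn.Linear(d_model, d_model, rng)
        self.norm = nn.LayerNorm(d_model)

    def __call__(self, x: nn.Tensor, kv: Optional[nn.Tensor] = None) -> nn.Tensor:
        context = self.attn(x, kv)
        return self.norm(self.fusion(context).relu() + x)


def frim_forward(x: np.ndarray, frim: FRIM) -> np.ndarray:
    """Apply a FRIM block to a (tokens, d_model) array."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected (tokens, d_model)")
    if x.shape[0] < 1:
        raise ValueError("need at least one token")
    if x.shape[1] != frim.fusion.weight.data.shape[0]:
        raise ValueError("d_model mismatch")
    out = frim(nn.Tensor(x[None]))
    return out.data[0]


class CrossAttentionFusion(nn.Module):
    """Bidirectional single-token cross-attention with tied projections.

    Direction A queries with the image embedding against the signal
    embedding; direction B reverses the roles. Both directions share the
    same projection and fusion weights, pass through the FRIM fusion
    machinery, and are averaged into one ``d_model`` vector.
    """

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        self.frim = FRIM(d_model, n_heads, rng)

    def __call__(self, img: nn.Tensor, sig: nn.Tensor) -> nn.Tensor:
        """img, sig: (B, d_model) -> fused (B, d_model)."""
        B, d = img.data.shape
        a = self.frim(img.reshape(B, 1, d), sig.reshape(B, 1, d))
        b = self.frim(sig.reshape(B, 1, d), img.reshape(B, 1, d))
        return (a + b).reshape(B, d) * 0.5


# ---------------------------------------------------------------------------
# branches

class ImageBranch(nn.Module):
    """VGG16-topology convolutional feature extractor over GAF stacks."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.convs: List[nn.Conv2d] = []
        c_in = cfg.n_input_planes
        for width, depth in zip(cfg.conv_widths, cfg.conv_depths):
            for _ in range(depth):
                self.convs.append(nn.Conv2d(c_in, width, rng))
                c_in = width
        spatial = cfg.image_size // 2 ** len(cfg.conv_widths)
        if spatial < 1:
            raise ValueError("image_size too small for 5 pooling stages")
        self.flat_dim = c_in * spatial * spatial
        dims = [self.flat_dim] + list(cfg.fc_dims)
        self.fcs = [nn.Linear(dims[i], dims[i + 1], rng) for i in range(len(dims) - 1)]
        self.proj = nn.Linear(dims[-1], cfg.d_model, rng)
        self.dropout_p = 0.5
        self._rng = rng

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        """x: (B, planes, N, N) -> (B, d_model)."""
        if x.data.shape[1:] != (self.cfg.n_input_planes, self.cfg.image_size,
                                self.cfg.image_size):
            raise ValueError(f"bad image stack shape {x.data.shape}")
        h = x
        i = 0
        for depth in self.cfg.conv_depths:
            for _ in range(depth):
                h = self.convs[i](h).relu()
                i += 1
            h = nn.maxpool2d(h, 2)
        h = h.reshape(h.data.shape[0], self.flat_dim)
        for fc in self.fcs:
            h = nn.dropout(fc(h).relu(), self.dropout_p, self._rng, self.training)
        return self.proj(h)


class SequenceBranch(nn.Module):
    """LSTM over windowed feature vectors, projected to d_model."""

    def __init__(self, d_feat: int, cfg: ModelConfig, rng: np.random.Generator):
        self.lstm = nn.LSTM(d_feat, cfg.lstm_hidden, rng)
        self.proj = nn.Linear(cfg.lstm_hidden, cfg.d_model, rng)

    def __call__(self, seq: nn.Tensor) -> nn.Tensor:
        """seq: (B, T, d_feat) -> (B, d_model)."""
        if seq.data.shape[1] < 1:
            raise ValueError("empty feature sequence")
        return self.proj(self.lstm(seq))


# ---------------------------------------------------------------------------
# full network

class FusionNet(nn.Module):
    """The complete dual-branch network for one ablation variant."""

    def __init__(self, d_feat: int, cfg: ModelConfig, variant: str = "full",
                 seed: int = 0):
        if variant not in VARIANTS:
            raise ValueError(f"unknown variant {variant!r}")
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.variant = variant
        d = cfg.d_model
        self.image_branch = (ImageBranch(cfg, rng)
                             if variant != "lstm_only" else None)
        self.seq_branch = (SequenceBranch(d_feat, cfg, rng)
                           if variant != "vgg_only" else None)
        if variant in ("full", "vgg_lstm_no_cam"):
            self.concat_proj = nn.Linear(2 * d, d, rng)
            self.frim = FRIM(d, cfg.n_heads, rng)
        else:
            self.concat_proj = None
            self.frim = None
        self.cross = (CrossAttentionFusion(d, cfg.n_heads, rng)
                      if variant == "full" else None)
        self.head = nn.Linear(d, cfg.n_classes, rng)
        self.dropout_p = 0.5
        self._rng = rng

    def forward(self, img: Optional[nn.Tensor], seq: Optional[nn.Tensor]
                ) -> Tuple[nn.Tensor, nn.Tensor]:
        """Return (fused embedding (B, d_model), logits (B, n_classes))."""
        if self.variant == "vgg_only":
            fused = self.image_branch(img)
        elif self.variant == "lstm_only":
            fused = self.seq_branch(seq)
        else:
            iv = self.image_branch(img)
            sv = self.seq_branch(seq)
            B, d = iv.data.shape
            joint = self.concat_proj(nn.concat([iv, sv], axis=1))
            if self.cfg.frim_tokens == "triple":
                tokens = nn.stack([iv, sv, joint], axis=1)  # (B, 3, d)
                refined = self.frim(tokens)
                iv2, sv2, joint2 = (refined[:, 0, :], refined[:, 1, :],
                                    refined[:, 2, :])
            else:
                refined = self.frim(joint.reshape(B, 1, d))
                iv2, sv2, joint2 = iv, sv, refined.reshape(B, d)
            if self.variant == "full":
                fused = self.cross(iv2, sv2)
            else:
                fused = joint2
        dropped = nn.dropout(fused, self.dropout_p, self._rng, self.training)
        return fused, self.head(dropped)


# ---------------------------------------------------------------------------
# sample preparation (recording -> model inputs)

@dataclass
class Sample:
    """One prepared training/evaluation example."""

    image: np.ndarray              # (planes, N, N) GAF stack
    sequence: np.ndarray           # (T, d_feat) feature vectors
    label: Optional[int]           # index into CLASSES
    trial_id: str = ""
    subject_id: str = ""


def _best_segment(rec: Recording, cfg: PipelineConfig) -> Optional[ActiveSegment]:
    seg_cfg = cfg.segment
    segs = segment_recording(
        rec, seg_cfg.window_n, seg_cfg.threshold, None,
        seg_cfg.min_duration_s, seg_cfg.merge_gap_s, seg_cfg.source,
    )
    if not segs:
        return None
    return max(segs, key=lambda s: s.peak_mas)


def prepare_sample(rec: Recording, cfg: PipelineConfig) -> Optional[Sample]:
    """Preprocess, segment and encode one recording; None when inactive."""
    pp = cfg.preprocess
    clean = preprocess_recording(rec, pp.wavelet, pp.levels, pp.threshold_rule,
                                 tuple(pp.band), pp.order)
    seg = _best_segment(clean, cfg)
    if seg is None:
        return None
    win = int(round(cfg.features.window_len * rec.fs))
    if seg.n_samples < win:
        return None
    img = encode_stack(clean.signal[:, seg.start:seg.end], cfg.gaf.size,
                       cfg.gaf.kind, cfg.gaf.rescale_mode,
                       list(clean.channel_names))
    fseq = build_feature_sequence(clean, seg, cfg.features.window_len,
                                  cfg.features.stride, cfg.features.vmd,
                                  cfg.features.welch)
    label = (CLASSES.index(rec.movement_label)
             if rec.movement_label in CLASSES else None)
    return Sample(image=img, sequence=fseq.vectors, label=label,
                  trial_id=rec.trial_id, subject_id=rec.subject_id)


def prepare_samples(recs: Sequence[Recording], cfg: PipelineConfig) -> List[Sample]:
    out = []
    for rec in recs:
        s = prepare_sample(rec, cfg)
        if s is not None:
            out.append(s)
    return out


def _pad_sequences(seqs: List[np.ndarray]) -> np.ndarray:
    """Front-pad with zeros to the batch maximum length."""
    tmax = max(s.shape[0] for s in seqs)
    d = seqs[0].shape[1]
    out = np.zeros((len(seqs), tmax, d))
    for i, s in enumerate(seqs):
        out[i, tmax - s.shape[0]:] = s
    return out


# ---------------------------------------------------------------------------
# training

@dataclass
class TrainedModel:
    """A trained network plus its forest head and normalisation state."""

    net: FusionNet
    forest: RandomForestClassifier
    feat_mean: np.ndarray
    feat_sd: np.ndarray
    pipeline: PipelineConfig
    variant: str = "full"
    history: pd.DataFrame = field(default_factory=pd.DataFrame)

    # -- inference ----------------------------------------------------------
    def _normalise(self, seq: np.ndarray) -> np.ndarray:
        return (seq - self.feat_mean) / self.feat_sd

    def embed(self, samples: Sequence[Sample]) -> np.ndarray:
        """Fused embeddings, deterministic (eval mode)."""
        self.net.eval()
        imgs = nn.Tensor(np.stack([s.image for s in samples]))
        seqs = nn.Tensor(_pad_sequences([self._normalise(s.sequence)
                                         for s in samples]))
        fused, _ = self.net.forward(
            imgs if self.net.variant != "lstm_only" else None,
            seqs if self.net.variant != "vgg_only" else None)
        return fused.data

    def predict_samples(self, samples: Sequence[Sample]) -> np.ndarray:
        """Forest class probabilities, rows in canonical class order."""
        emb = self.embed(samples)
        probs = np.zeros((len(samples), len(CLASSES)))
        probs[:, self.forest.classes_] = self.forest.predict_proba(emb)
        return probs

    def predict(self, rec: Recording) -> "ClassProbabilities":
        """Full pipeline on a raw recording."""
        s = prepare_sample(rec, self.pipeline)
        if s is None:
            return ClassProbabilities(
                probs=np.full(len(CLASSES), 1.0 / len(CLASSES)),
                predicted=None, active=False)
        p = self.predict_samples([s])[0]
        return ClassProbabilities(probs=p, predicted=CLASSES[int(p.argmax())],
                                  active=True)

    # -- persistence --------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Write a versioned checkpoint directory."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        np.savez(path / "weights.npz",
                 *[p.data for p in self.net.parameters()])
        np.savez(path / "norm.npz", mean=self.feat_mean, sd=self.feat_sd)
        joblib.dump(self.forest, path / "forest.joblib")
        self.pipeline.save(path / "pipeline.yaml")
        cfg_digest = hashlib.sha256(
            (path / "pipeline.yaml").read_bytes()).hexdigest()
        meta = {"format_version": 1, "variant": self.variant,
                "config_digest": cfg_digest,
                "classes": [c.value for c in CLASSES]}
        (path / "meta.json").write_text(json.dumps(meta, indent=1))
        if len(self.history):
            self.history.to_csv(path / "history.csv", index=False)

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        path = Path(path)
        meta = json.loads((path / "meta.json").read_text())
        pipeline = PipelineConfig.load(path / "pipeline.yaml")
        norm = np.load(path / "norm.npz")
        d_feat = norm["mean"].shape[0]
        net = FusionNet(d_feat, pipeline.model, meta["variant"])
        weights = np.load(path / "weights.npz")
        net.load_state_dict([weights[k] for k in weights.files])
        hist_path = path / "history.csv"
        return cls(net=net, forest=joblib.load(path / "forest.joblib"),
                   feat_mean=norm["mean"], feat_sd=norm["sd"],
                   pipeline=pipeline, variant=meta["variant"],
                   history=pd.read_csv(hist_path) if hist_path.exists()
                   else pd.DataFrame())


def train_on_samples(
    samples: Sequence[Sample],
    cfg: PipelineConfig,
    variant: str = "full",
) -> TrainedModel:
    """Train the neural stages end-to-end, then fit the forest head.

    Training uses Adam with cross-entropy on the auxiliary soft-max head
    (initial lr, decay factor and step, epoch cap, batch size and dropout
    from ``cfg.train``). A stratified validation slice is carved from the
    training samples for checkpoint selection; the best-validation weights
    are restored before the random forest is fitted on the fused
    embeddings of all training samples.
    """
    labels = np.array([s.label for s in samples])
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least 2 classes to train")
    tcfg = cfg.train
    rng = np.random.default_rng(derive_seed(tcfg.seed, "train"))

    # normalisation over every training window
    allv = np.concatenate([s.sequence for s in samples], axis=0)
    feat_mean = allv.mean(axis=0)
    feat_sd = np.where(allv.std(axis=0) > 1e-12, allv.std(axis=0), 1.0)

    # stratified validation split for checkpointing
    val_idx: List[int] = []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        k = max(1, int(round(tcfg.val_fraction * idx.size)))
        val_idx.extend(rng.permutation(idx)[:k])
    val_mask = np.zeros(len(samples), dtype=bool)
    val_mask[val_idx] = True
    tr_idx = np.flatnonzero(~val_mask)
    va_idx = np.flatnonzero(val_mask)

    d_feat = samples[0].sequence.shape[1]
    net = FusionNet(d_feat, cfg.model, variant,
                    seed=derive_seed(tcfg.seed, "model_init"))
    net.dropout_p = tcfg.dropout
    if net.image_branch is not None:
        net.image_branch.dropout_p = tcfg.dropout
    opt = nn.Adam(net.parameters(), lr=tcfg.lr,
                  decay_factor=tcfg.lr_decay_factor,
                  decay_step=tcfg.lr_decay_step)

    def batch_tensors(idx: np.ndarray):
        imgs = nn.Tensor(np.stack([samples[i].image for i in idx]))
        seqs = nn.Tensor(_pad_sequences(
            [(samples[i].sequence - feat_mean) / feat_sd for i in idx]))
        return (imgs if variant != "lstm_only" else None,
                seqs if variant != "vgg_only" else None,
                labels[idx])

    best_state = net.state_dict()
    best_val = -1.0
    rows = []
    for epoch in range(tcfg.max_epochs):
        opt.set_epoch(epoch)
        net.train()
        order = rng.permutation(tr_idx)
        losses = []
        for b0 in range(0, order.size, tcfg.batch_size):
            bidx = order[b0: b0 + tcfg.batch_size]
            img, seq, y = batch_tensors(bidx)
            _, logits = net.forward(img, seq)
            loss = nn.cross_entropy(logits, y)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        net.eval()
        img, seq, yv = batch_tensors(va_idx)
        _, logits = net.forward(img, seq)
        val_acc = float((logits.data.argmax(axis=1) == yv).mean())
        rows.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                     "val_acc": val_acc, "lr": opt.lr})
        if val_acc >= best_val:
            best_val = val_acc
            best_state = net.state_dict()

    net.load_state_dict(best_state)
    model = TrainedModel(net=net, forest=None, feat_mean=feat_mean,
                         feat_sd=feat_sd, pipeline=cfg, variant=variant,
                         history=pd.DataFrame(rows))
    emb = model.embed(list(samples))
    forest = RandomForestClassifier(
        n_estimators=cfg.model.forest_trees, random_state=tcfg.seed % (2**31))
    forest.fit(emb, labels)
    model.forest = forest
    return model


def train(train_recs: Sequence[Recording], cfg: PipelineConfig,
          variant: str = "full") -> TrainedModel:
    """Prepare recordings and train (see :func:`train_on_samples`)."""
    samples = prepare_samples(train_recs, cfg)
    return train_on_samples(samples, cfg, variant)


def evaluate_on_samples(model: TrainedModel, samples: Sequence[Sample]
                        ) -> Dict[str, float]:
    """Accuracy and macro-F1 of the forest head on prepared samples."""
    probs = model.predict_samples(samples)
    pred = probs.argmax(axis=1)
    y = np.array([s.label for s in samples])
    return {"accuracy": float((pred == y).mean()),
            "macro_f1": float(f1_score(y, pred, average="macro",
                                       labels=np.arange(len(CLASSES)),
                                       zero_division=0))}


def run_ablation(
    train_samples: Sequence[Sample],
    test_samples: Sequence[Sample],
    cfg: PipelineConfig,
    variants: Sequence[str] = VARIANTS,
) -> pd.DataFrame:
    """Train every variant on the identical split/seed; one metrics row each."""
    rows = []
    for variant in variants:
        m = train_on_samples(train_samples, cfg, variant)
        metrics = evaluate_on_samples(m, test_samples)
        rows.append({"variant": variant, **metrics})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# actuation policy

@dataclass
class ClassProbabilities:
    """Forest vote fractions over the 5 movement classes.

    ``active=False`` marks a recording with no detected activity: the
    probabilities fall back to uniform and ``predicted`` is None.
    """

    probs: np.ndarray
    predicted: Optional[MovementLabel]
    active: bool = True

    def prob(self, label: MovementLabel | str) -> float:
        label = MovementLabel(label)
        return float(self.probs[CLASSES.index(label)])


@dataclass(frozen=True)
class ActuationCommand:
    """Pneumatic-muscle commands derived from rotation-intention probabilities."""

    left_pam: str = "none"     # "contract_70" or "none"
    right_pam: str = "none"    # "dilate_30" or "none"


def actuation_policy(
    p: ClassProbabilities,
    threshold: float = 0.8,
    left_label: MovementLabel = MovementLabel.LT,
    right_label: MovementLabel = MovementLabel.RT,
) -> ActuationCommand:
    """Threshold rule for the assist actuators.

    P_left/P_right default to the left/right twist class probabilities;
    when a probability exceeds the 0.8 threshold the corresponding
    pneumatic muscle is commanded (left contracts by 70%, right dilates by
    30%); otherwise no command is issued.
    """
    if not p.active:
        return ActuationCommand()
    p_left = p.prob(left_label)
    p_right = p.prob(right_label)
    return ActuationCommand(
        left_pam="contract_70" if p_left > threshold else "none",
        right_pam="dilate_30" if p_right > threshold else "none",
    )
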