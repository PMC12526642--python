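"""Parallel multi-layer sensor fusion of EMG and EEG.

Each modality passes through its own convolutional branch; the pooled
branch features are concatenated and mixed by a shared multi-layer head
that produces a single L2-normalized embedding. The fused model plugs into
exactly the same contrastive training and reference-set classification
machinery as the unimodal encoders, so EMG-only / EEG-only / fusion are a
clean ablation triplet.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np

from ._nn import ConvStack, Dense, Param, ReLU, l2_normalize, l2_normalize_backward
from .errors import ValidationError
from .snn import EncoderConfig


@dataclass
class FusionConfig:
    """Fusion architecture: one conv branch per modality plus a shared head.

    ``branch`` configures both convolutional branches (they have separate
    weights but the same shape); ``head_layers`` are optional hidden widths
    of the shared fusion head. The default is a single linear mixing layer
    (empty ``head_layers``): the parallel branches are already multi-layer,
    and a deeper nonlinear head trains noticeably less reliably at the pair
    counts this pipeline sees.
    """

    branch: EncoderConfig = field(default_factory=EncoderConfig)
    head_layers: Tuple[int, ...] = ()
    embedding_dim: int = 64

    def __post_init__(self) -> None:
        if self.embedding_dim <= 0:
            raise ValidationError("embedding_dim must be > 0")

    # the training loop and segment plumbing read these off any config
    @property
    def input_length(self) -> int:
        return self.branch.input_length

    @property
    def margin(self) -> float:
        return self.branch.margin

    @property
    def lr(self) -> float:
        return self.branch.lr

    @property
    def epochs(self) -> int:
        return self.branch.epochs

    @property
    def batch_size(self) -> int:
        return self.branch.batch_size

    @property
    def seed(self) -> int:
        return self.branch.seed

    @property
    def temperature(self) -> float:
        return self.branch.temperature

    @property
    def n_pos_refs(self) -> int:
        return self.branch.n_pos_refs

    @property
    def n_neg_refs(self) -> int:
        return self.branch.n_neg_refs


class FusedEncoder:
    """Two parallel conv branches -> concatenated features -> shared
    multi-layer head -> L2-normalized embedding."""

    n_channels = 2

    def __init__(self, config: FusionConfig, rng: np.random.Generator):
        self.config = config
        b = config.branch
        self.branch_emg = ConvStack(1, b.channels, b.kernel_size, rng)
        self.branch_eeg = ConvStack(1, b.channels, b.kernel_size, rng)
        n_feat = self.branch_emg.out_channels + self.branch_eeg.out_channels
        self.head: List[Dense] = []
        prev = n_feat
        for width in config.head_layers:
            self.head.append(Dense(prev, width, rng))
            prev = width
        self.out = Dense(prev, config.embedding_dim, rng)

    def params(self) -> List[Param]:
        ps = self.branch_emg.params() + self.branch_eeg.params()
        for layer in self.head:
            ps += layer.params()
        return ps + self.out.params()

    def forward(self, x: np.ndarray) -> Tuple[np.ndarray, tuple]:
        # x: (B, 2, L) with row 0 = EMG, row 1 = EEG
        if x.ndim != 3 or x.shape[1] != 2:
            raise ValidationError("fused encoder expects (B, 2, L) paired segments")
        f_emg, c_emg = self.branch_emg.forward(x[:, 0:1, :])
        f_eeg, c_eeg = self.branch_eeg.forward(x[:, 1:2, :])
        h = np.concatenate([f_emg, f_eeg], axis=1)
        head_caches = []
        for layer in self.head:
            h, d_cache = layer.forward(h)
            h, mask = ReLU.forward(h)
            head_caches.append((d_cache, mask))
        z, out_cache = self.out.forward(h)
        emb, n_cache = l2_normalize(z)
        split = f_emg.shape[1]
        return emb, (c_emg, c_eeg, head_caches, out_cache, n_cache, split)

    def backward(self, cache: tuple, demb: np.ndarray) -> None:
        c_emg, c_eeg, head_caches, out_cache, n_cache, split = cache
        dz = l2_normalize_backward(n_cache, demb)
        dh = self.out.backward(out_cache, dz)
        for layer, (d_cache, mask) in zip(reversed(self.head), reversed(head_caches)):
            dh = ReLU.backward(mask, dh)
            dh = layer.backward(d_cache, dh)
        self.branch_emg.backward(c_emg, dh[:, :split])
        self.branch_eeg.backward(c_eeg, dh[:, split:])


def encode_fused(model, emg_segment: np.ndarray, eeg_segment: np.ndarray) -> np.ndarray:
    """Embed a paired segment with a fusion model.

    Both modalities must be present and of the model's input length; a
    fusion model never silently degrades to a unimodal one.
    """
    if model.modality != "fusion":
        raise ValidationError("encode_fused requires a fusion model")
    emg_segment = np.asarray(emg_segment, dtype=float)
    eeg_segment = np.asarray(eeg_segment, dtype=float)
    if emg_segment.shape != eeg_segment.shape or emg_segment.ndim != 1:
        raise ValidationError("EMG and EEG segments must be 1-D and equal length")
    return model.encode(np.stack([emg_segment, eeg_segment]))
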