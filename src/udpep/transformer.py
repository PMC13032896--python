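"""Optional transformer regression backend (requires torch).

Architecture: a 6-layer encoder, 8 attention heads of dimension 64 each
(model width 512), feed-forward width 2048, followed by a 5-layer MLP head
512 -> 256 -> 64 -> 32 -> 1 with batch-norm and dropout 0.3.  Optimised by
SGD with momentum 0.9 under a linear learning-rate warmup from 0.001 to a
configurable peak (default 0.2).  All dimensions and rates are config.

The backend is capability-gated: importing this module is always safe, and
:func:`train_transformer` raises :class:`~udpep.errors.CapabilityError`
when torch is not installed, leaving the classical backends unaffected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import CapabilityError, DomainError
from .peptide_space import AA_INDEX, Q, validate_sequence

__all__ = ["TransformerConfig", "train_transformer", "torch_available"]


@dataclass(frozen=True)
class TransformerConfig:
    n_layers: int = 6
    n_heads: int = 8
    head_dim: int = 64
    ff_dim: int = 2048
    embed_dim: int = 512
    mlp_dims: tuple[int, ...] = (512, 256, 64, 32)
    dropout: float = 0.3
    momentum: float = 0.9
    warmup_start_lr: float = 0.001
    peak_lr: float = 0.2
    warmup_steps: int = 100
    epochs: int = 30
    batch_size: int = 64
    seed: int = 0

    @property
    def model_dim(self) -> int:
        return self.n_heads * self.head_dim


def torch_available() -> bool:
    try:
        import torch  # noqa: F401

        return True
    except ImportError:
        return False


def _build_model(cfg: TransformerConfig, k: int):
    import torch
    from torch import nn

    class SeqRegressor(nn.Module):
        def __init__(self):
            super().__init__()
            self.embed = nn.Embedding(Q, cfg.embed_dim)
            self.proj = (
                nn.Linear(cfg.embed_dim, cfg.model_dim)
                if cfg.embed_dim != cfg.model_dim
                else nn.Identity()
            )
            layer = nn.TransformerEncoderLayer(
                d_model=cfg.model_dim,
                nhead=cfg.n_heads,
                dim_feedforward=cfg.ff_dim,
                dropout=cfg.dropout,
                batch_first=True,
            )
            self.encoder = nn.TransformerEncoder(layer, num_layers=cfg.n_layers)
            dims = (cfg.model_dim,) + tuple(cfg.mlp_dims)
            blocks = []
            for a, b in zip(dims[:-1], dims[1:]):
                blocks += [nn.Linear(a, b), nn.BatchNorm1d(b), nn.ReLU(), nn.Dropout(cfg.dropout)]
            blocks.append(nn.Linear(dims[-1], 1))
            self.head = nn.Sequential(*blocks)

        def forward(self, tokens):  # (batch, k) int64
            h = self.proj(self.embed(tokens))
            h = self.encoder(h).mean(dim=1)
            return self.head(h)

    return SeqRegressor()


def train_transformer(
    sequences: Sequence[str], y: Sequence[float], cfg: TransformerConfig | None = None
):
    """Fit the transformer backend; returns (model, predict_fn, history).

    Raises :class:`CapabilityError` when torch is unavailable.
    """
    if not torch_available():
        raise CapabilityError(
            "the transformer backend requires torch, which is not installed; "
            "classical backends (random_forest, support_vector, gbdt) remain available"
        )
    import torch

    cfg = cfg or TransformerConfig()
    seqs = list(sequences)
    if not seqs:
        raise DomainError("no training sequences")
    k = len(seqs[0])
    tokens = torch.tensor(
        [[AA_INDEX[c] for c in validate_sequence(s, k)] for s in seqs], dtype=torch.long
    )
    target = torch.tensor(np.asarray(list(y), dtype=np.float32)).unsqueeze(1)
    torch.manual_seed(cfg.seed)
    model = _build_model(cfg, k)
    opt = torch.optim.SGD(model.parameters(), lr=cfg.warmup_start_lr, momentum=cfg.momentum)
    loss_fn = torch.nn.MSELoss()
    history = []
    step = 0
    n = tokens.shape[0]
    g = torch.Generator().manual_seed(cfg.seed)
    for epoch in range(cfg.epochs):
        perm = torch.randperm(n, generator=g)
        total = 0.0
        model.train()
        for i0 in range(0, n, cfg.batch_size):
            sel = perm[i0 : i0 + cfg.batch_size]
            if sel.numel() < 2:  # batch-norm needs >= 2 samples
                continue
            frac = min(1.0, (step + 1) / cfg.warmup_steps)
            lr = cfg.warmup_start_lr + frac * (cfg.peak_lr - cfg.warmup_start_lr)
            for group in opt.param_groups:
                group["lr"] = lr
            opt.zero_grad()
            out = model(tokens[sel])
            loss = loss_fn(out, target[sel])
            loss.backward()
            opt.step()
            total += float(loss) * sel.numel()
            step += 1
        history.append(total / n)

    def predict(seq_list: Sequence[str]) -> np.ndarray:
        model.eval()
        with torch.no_grad():
            tk = torch.tensor(
                [[AA_INDEX[c] for c in validate_sequence(s, k)] for s in seq_list],
                dtype=torch.long,
            )
            return model(tk).squeeze(1).numpy()

    return model, predict, history
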