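"""Residual U-Net for striosome segmentation.

Encoder-decoder with skip connections; every resolution level is a residual
block (two 3x3 convolutions with group normalization, plus an identity or
1x1-projected shortcut). Channels double per level from ``base_channels``.
Inference takes a single gray-level channel (the MOR1 reference image,
normalized) and emits per-pixel class logits (default 2: striosome vs rest).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import nn


@dataclass
class UNetSpec:
    depth: int = 4
    base_channels: int = 16
    residual_blocks: bool = True
    n_classes: int = 2
    in_channels: int = 1
    groupnorm_groups: int = 8

    def __post_init__(self) -> None:
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.base_channels < 4:
            raise ValueError("base_channels must be >= 4")

    @property
    def divisor(self) -> int:
        """Input tile sides must be divisible by 2**(depth-1)."""
        return 2 ** (self.depth - 1)


class _Block(nn.Module):
    """conv3-GN-ReLU-conv3-GN (+ shortcut) -ReLU. The shortcut is the
    identity when channel counts match, else a 1x1 projection; omitted
    entirely when ``residual`` is off."""

    def __init__(self, cin: int, cout: int, spec: UNetSpec, rng):
        g = spec.groupnorm_groups
        self.conv1 = nn.Conv2d(cin, cout, 3, rng)
        self.gn1 = nn.GroupNorm(cout, g)
        self.relu1 = nn.ReLU()
        self.conv2 = nn.Conv2d(cout, cout, 3, rng)
        self.gn2 = nn.GroupNorm(cout, g)
        self.relu2 = nn.ReLU()
        self.residual = spec.residual_blocks
        self.proj = nn.Conv2d(cin, cout, 1, rng) if (self.residual and cin != cout) else None

    def params(self):
        mods = [self.conv1, self.gn1, self.conv2, self.gn2]
        if self.proj is not None:
            mods.append(self.proj)
        return [p for m in mods for p in m.params()]

    def forward(self, x):
        h = self.relu1.forward(self.gn1.forward(self.conv1.forward(x)))
        h = self.gn2.forward(self.conv2.forward(h))
        if self.residual:
            h = h + (self.proj.forward(x) if self.proj is not None else x)
        return self.relu2.forward(h)

    def backward(self, dy):
        dh = self.relu2.backward(dy)
        dx_res = None
        if self.residual:
            dx_res = self.proj.backward(dh) if self.proj is not None else dh
        dh = self.conv2.backward(self.gn2.backward(dh))
        dx = self.conv1.backward(self.gn1.backward(self.relu1.backward(dh)))
        if dx_res is not None:
            dx = dx + dx_res
        return dx


class ResidualUNet(nn.Module):
    def __init__(self, spec: UNetSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        ch = [spec.base_channels * 2**d for d in range(spec.depth)]
        self.enc = []
        cin = spec.in_channels
        for d in range(spec.depth):
            self.enc.append(_Block(cin, ch[d], spec, rng))
            cin = ch[d]
        self.pools = [nn.MaxPool2() for _ in range(spec.depth - 1)]
        self.ups = []
        self.dec = []
        for d in range(spec.depth - 2, -1, -1):
            self.ups.append(nn.Upsample2())
            self.dec.append(_Block(ch[d + 1] + ch[d], ch[d], spec, rng))
        self.head = nn.Conv2d(ch[0], spec.n_classes, 1, rng)

    def params(self):
        mods = self.enc + self.dec + [self.head]
        return [p for m in mods for p in m.params()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (N, H, W, in_channels) with H, W divisible by 2**(depth-1)."""
        n, h, w, _ = x.shape
        d = self.spec.divisor
        if h % d or w % d:
            raise ValueError(f"tile sides must be divisible by {d}")
        skips = []
        for lev in range(self.spec.depth - 1):
            x = self.enc[lev].forward(x)
            skips.append(x)
            x = self.pools[lev].forward(x)
        x = self.enc[-1].forward(x)
        self._skip_ch = []
        for i, lev in enumerate(range(self.spec.depth - 2, -1, -1)):
            x = self.ups[i].forward(x)
            skip = skips[lev]
            self._skip_ch.append((x.shape[-1], skip.shape[-1]))
            x = np.concatenate([x, skip], axis=-1)
            x = self.dec[i].forward(x)
        return self.head.forward(x)

    def backward(self, dlogits: np.ndarray) -> None:
        dx = self.head.backward(dlogits)
        dskips = {}
        for i in range(len(self.dec) - 1, -1, -1):
            lev = self.spec.depth - 2 - i
            dcat = self.dec[i].backward(dx)
            c_up, _ = self._skip_ch[i]
            dskips[lev] = dcat[..., c_up:]
            dx = self.ups[i].backward(dcat[..., :c_up])
        dx = self.enc[-1].backward(dx)
        for lev in range(self.spec.depth - 2, -1, -1):
            dx = self.pools[lev].backward(dx)
            dx = dx + dskips[lev]
            dx = self.enc[lev].backward(dx)

    # -- checkpointing ------------------------------------------------------
    def state_dict(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        params = self.params()
        if len(state) != len(params):
            raise ValueError("state does not match the architecture")
        for p, v in zip(params, state):
            if p.value.shape != v.shape:
                raise ValueError("parameter shape mismatch")
            p.value[...] = v

    def save(self, path: str | Path, sidecar: dict | None = None) -> None:
        """Weights as .npz with a JSON sidecar carrying the UNetSpec plus
        any training metadata (selected epoch, train config)."""
        path = Path(path)
        np.savez(path, *self.state_dict())
        meta = {"spec": asdict(self.spec)}
        meta.update(sidecar or {})
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> tuple["ResidualUNet", dict]:
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        spec = UNetSpec(**meta["spec"])
        model = cls(spec)
        with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as z:
            model.load_state_dict([z[k] for k in z.files])
        return model, meta
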