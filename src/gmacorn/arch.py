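"""Detector assembly and complexity profiling.

Two variants are built from one declarative :class:`ArchConfig`:

* ``baseline_v8n`` — the stock YOLOv8n graph (CSP backbone with C2f blocks,
  SPPF, FPN+PAN neck, anchor-free decoupled head) at width 0.25 / depth 0.33.
* ``gma`` — the lightweight variant: a Ghost-HGNetV2 backbone (two stride-2
  stem convs, four Ghost-HGBlock stages joined by depthwise stride-2
  downsampling, SPPF, SimAM at the P5 position), an FPN+PAN neck whose C2f
  blocks are replaced by MLCA-gated CM blocks, the same decoupled lead head,
  and an optional auxiliary head used only at training time.

Complexity is reported as exact learnable-parameter counts and GFLOPs at a
given square input, counting 2 FLOPs per multiply-accumulate over conv and
linear layers only (the fused-model convention).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .attention import SimAM
from .autograd import Tensor, concat, profiler, no_grad, upsample_nearest2x
from .blocks import C2f, CM, Detect, GhostHGBlock
from .layers import Conv, DWConv, Module, SPPF, set_init_rng

__all__ = ["ArchConfig", "ComplexityReport", "build_model",
           "count_parameters", "estimate_flops", "complexity_report"]

# Ghost-HGNetV2 stage table (cm, out) per stage and stem/neck widths.
# The printed footprint of the published variant (2.3M params / 6.8 GFLOPs
# at 640, single class) is the specification these widths were tuned to;
# see docs/methods.md.
GMA_DEFAULT_WIDTHS = {
    "stem": [32, 32],
    "stages": [[12, 48], [32, 64], [66, 128], [114, 256]],
    "neck": [64, 128, 256],
}


@dataclass
class ArchConfig:
    variant: str = "gma"                  # {"baseline_v8n", "gma"}
    num_classes: int = 1
    input_size: int = 640
    width: float = 1.0                    # extra multiplier on stage widths
    depth: float = 1.0
    widths: dict = field(default_factory=lambda: None)
    simam_lambda: float = 1e-4
    include_aux_head: bool = False
    init_seed: int = 0

    def __post_init__(self):
        if self.variant not in ("baseline_v8n", "gma"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.num_classes < 1:
            raise ValueError("num_classes must be >= 1")
        if self.input_size % 32:
            raise ValueError("input_size must be divisible by 32")
        if self.widths is None:
            self.widths = {k: [list(v) if isinstance(v, list) else v for v in vv]
                           if isinstance(vv, list) else vv
                           for k, vv in GMA_DEFAULT_WIDTHS.items()}
        if self.variant == "gma" and not self.widths.get("stages"):
            raise ValueError("empty stage table")

    @classmethod
    def from_yaml(cls, path) -> "ArchConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def scaled(self, c: int) -> int:
        return max(8, int(round(c * self.width / 4)) * 4) if self.width != 1.0 else c


@dataclass
class ComplexityReport:
    parameter_count: int
    gflops: float
    size_mb: float          # half-precision serialization estimate only
    input_size: int
    variant: str

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


# ---------------------------------------------------------------------------
# Baseline YOLOv8n
# ---------------------------------------------------------------------------

class BaselineV8(Module):
    def __init__(self, cfg: ArchConfig, w=0.25, d=0.33, max_ch=1024):
        super().__init__()
        self.cfg = cfg
        def cw(c):
            return cfg.scaled(int(math.ceil(c * w)))
        def dn(n):
            return max(round(n * d), 1)
        c1, c2, c3, c4, c5 = cw(64), cw(128), cw(256), cw(512), cw(min(1024, max_ch))
        self.stem = Conv(3, c1, 3, 2)
        self.down1 = Conv(c1, c2, 3, 2)
        self.s1 = C2f(c2, c2, dn(3), shortcut=True)
        self.down2 = Conv(c2, c3, 3, 2)
        self.s2 = C2f(c3, c3, dn(6), shortcut=True)
        self.down3 = Conv(c3, c4, 3, 2)
        self.s3 = C2f(c4, c4, dn(6), shortcut=True)
        self.down4 = Conv(c4, c5, 3, 2)
        self.s4 = C2f(c5, c5, dn(3), shortcut=True)
        self.sppf = SPPF(c5, c5)
        self._neck_and_head(cfg, (c3, c4, c5), dn(3), block=C2f)

    def _neck_and_head(self, cfg, chs, n, block):
        p3, p4, p5 = chs
        self.up_c2f1 = block(p5 + p4, p4, n)
        self.up_c2f2 = block(p4 + p3, p3, n)
        self.pan_conv1 = Conv(p3, p3, 3, 2)
        self.pan_c2f1 = block(p3 + p4, p4, n)
        self.pan_conv2 = Conv(p4, p4, 3, 2)
        self.pan_c2f2 = block(p4 + p5, p5, n)
        self.head = Detect(cfg.num_classes, (p3, p4, p5))
        self.aux_head = (Detect(cfg.num_classes, (p3, p4, p5))
                         if cfg.include_aux_head else None)

    def backbone(self, x):
        x = self.down1(self.stem(x))
        x = self.s1(x)
        p3 = self.s2(self.down2(x))
        p4 = self.s3(self.down3(p3))
        p5 = self.sppf(self.s4(self.down4(p4)))
        return p3, p4, p5

    def neck(self, p3, p4, p5):
        t4 = self.up_c2f1(concat([upsample_nearest2x(p5), p4]))
        o3 = self.up_c2f2(concat([upsample_nearest2x(t4), p3]))
        o4 = self.pan_c2f1(concat([self.pan_conv1(o3), t4]))
        o5 = self.pan_c2f2(concat([self.pan_conv2(o4), p5]))
        return o3, o4, o5

    def forward(self, x):
        feats = self.neck(*self.backbone(x))
        out = {"lead": self.head(list(feats))}
        if self.training and self.aux_head is not None:
            out["aux"] = self.aux_head(list(feats))
        return out


# ---------------------------------------------------------------------------
# GMA-YOLOv8
# ---------------------------------------------------------------------------

class GMAYolo(BaselineV8):
    def __init__(self, cfg: ArchConfig):
        Module.__init__(self)
        self.cfg = cfg
        tw = cfg.widths
        s0, s1 = (cfg.scaled(c) for c in tw["stem"])
        stages = [(cfg.scaled(cm), cfg.scaled(co)) for cm, co in tw["stages"]]
        self.stem1 = Conv(3, s0, 3, 2)
        self.stem2 = Conv(s0, s1, 3, 2)
        cin = s1
        hg, dw = [], []
        for i, (cm, co) in enumerate(stages):
            if i > 0:
                dw.append(DWConv(cin, cin, 3, 2, act=False))
            hg.append(GhostHGBlock(cin, cm, co, shortcut=cin == co))
            cin = co
        self.hg = hg
        self.dw = dw
        o2, o3, o4 = stages[1][1], stages[2][1], stages[3][1]
        self.sppf = SPPF(o4, o4)
        self.simam = SimAM(cfg.simam_lambda)
        n3, n4, n5 = (cfg.scaled(c) for c in tw["neck"])
        self._gma_neck(cfg, (o2, o3, o4), (n3, n4, n5))

    def _gma_neck(self, cfg, bb, nk):
        p3, p4, p5 = bb
        n3, n4, n5 = nk
        self.up_c2f1 = CM(p5 + p4, n4)
        self.up_c2f2 = CM(n4 + p3, n3)
        self.pan_conv1 = Conv(n3, n3, 3, 2)
        self.pan_c2f1 = CM(n3 + n4, n4)
        self.pan_conv2 = Conv(n4, n4, 3, 2)
        self.pan_c2f2 = CM(n4 + p5, n5)
        self.head = Detect(cfg.num_classes, (n3, n4, n5))
        self.aux_head = (Detect(cfg.num_classes, (n3, n4, n5))
                         if cfg.include_aux_head else None)

    def backbone(self, x):
        x = self.stem2(self.stem1(x))
        x = self.hg[0](x)
        p3 = self.hg[1](self.dw[0](x))
        p4 = self.hg[2](self.dw[1](p3))
        p5 = self.hg[3](self.dw[2](p4))
        p5 = self.simam(self.sppf(p5))
        return p3, p4, p5


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

def build_model(config: ArchConfig) -> Module:
    """Construct the requested detector variant (weights freshly initialized)."""
    set_init_rng(config.init_seed)
    if config.variant == "baseline_v8n":
        return BaselineV8(config)
    return GMAYolo(config)


def count_parameters(model: Module, mode: str = "deploy") -> int:
    """Exact learnable-scalar count; ``deploy`` excludes the aux head."""
    total = sum(p.size for p in model.parameters())
    if mode == "deploy" and getattr(model, "aux_head", None) is not None:
        total -= sum(p.size for p in model.aux_head.parameters())
    return int(total)


def estimate_flops(model: Module, input_size: int | None = None) -> float:
    """GFLOPs of a deploy-mode forward at ``input_size`` (2 x MAC)."""
    input_size = input_size or model.cfg.input_size
    if input_size % 32:
        raise ValueError("input size must be divisible by 32")
    x = Tensor(np.zeros((1, 3, input_size, input_size), dtype=np.float32))
    was_training = model.training
    model.eval()
    with no_grad(), profiler() as p:
        model(x)
    if was_training:
        model.train()
    return 2.0 * p.macs / 1e9


def complexity_report(config: ArchConfig) -> ComplexityReport:
    model = build_model(config)
    model.eval()
    n = count_parameters(model, "deploy")
    g = estimate_flops(model, config.input_size)
    return ComplexityReport(
        parameter_count=n,
        gflops=round(g, 1),
        size_mb=round(n * 2 / 2 ** 20, 2),
        input_size=config.input_size,
        variant=config.variant,
    )
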