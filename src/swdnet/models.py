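"""The four compared detector architectures and their layer reports.

The flagship ``resnet_bigru`` is a residual CNN encoder (four residual
blocks, channel plan 19->32->64->128->64, pooling only along the feature
axis so the 64-frame sequence is preserved) feeding a two-layer
bidirectional GRU head that emits one seizure probability per frame.
The encoder's convolution parameter counts and the first bidirectional
layer's count are construction-asserted against their published values;
building a model whose counts drift is a hard error, not a warning.

Comparison variants: ``cnn_only`` (shortcut-free conv stack + per-frame
dense head), ``gru_only`` (raw per-frame features straight into the
recurrent head), ``cnn_gru`` (shortcut-free conv stack + recurrent head).
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .preprocess import N_CHANNELS, N_FEATURES, N_FRAMES

__all__ = [
    "ModelConfig", "LayerReport", "VARIANTS",
    "build_resnet_encoder", "build_bigru_head", "build_variant",
    "layer_report", "save_model", "load_model",
    "EXPECTED_CONV_PARAMS", "EXPECTED_BIGRU1_PARAMS",
]

VARIANTS = ("cnn_only", "gru_only", "cnn_gru", "resnet_bigru")

#: Published per-convolution trainable parameter counts of the encoder.
#: 3x3 convolutions are bias-free (batch norm absorbs the offset); the
#: 1x1 projections carry a bias — the convention these counts force.
EXPECTED_CONV_PARAMS = {
    "conv2d_1": 5472,     # 3x3, 19->32
    "conv2d_2": 9216,     # 3x3, 32->32
    "conv2d": 640,        # 1x1, 19->32 (+bias)
    "conv2d_3": 2112,     # 1x1, 32->64 (+bias)
    "conv2d_4": 18432,    # 3x3, 32->64
    "conv2d_5": 36864,    # 3x3, 64->64
    "conv2d_6": 8320,     # 1x1, 64->128 (+bias)
    "conv2d_7": 73728,    # 3x3, 64->128
    "conv2d_8": 147456,   # 3x3, 128->128
    "conv2d_9": 8256,     # 1x1, 128->64 (+bias)
    "conv2d_10": 73728,   # 3x3, 128->64
    "conv2d_11": 36864,   # 3x3, 64->64
}

#: First bidirectional GRU layer, dual-bias gates:
#: 2 directions * 3 gates * (1024*128 + 128*128 + 2*128).
EXPECTED_BIGRU1_PARAMS = 886_272


class ConstructionError(AssertionError):
    """A built layer's parameter count deviates from its published value."""


@dataclass(frozen=True)
class ModelConfig:
    variant: str = "resnet_bigru"
    input_shape: tuple[int, int, int] = (N_FRAMES, N_FEATURES, N_CHANNELS)
    gru_units: int = 128
    dense_units: int = 128
    dropout_rate: float = 0.3
    l2_weight: float = 1e-4
    output_activation: str = "sigmoid"  # "relu" available but not default
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; choose from {VARIANTS}")
        if self.output_activation not in ("sigmoid", "relu"):
            raise ValueError("output_activation must be 'sigmoid' or 'relu'")


@dataclass
class LayerReport:
    """Ordered per-layer records mirroring the published parameter tables."""

    rows: list[dict] = field(default_factory=list)

    COLUMNS = ("layer", "name", "activation", "output_size",
               "kernel_size", "filters", "parameters")

    def add(self, name: str, activation: str, output_size: str,
            kernel_size: str, filters, parameters: int) -> None:
        self.rows.append({
            "layer": len(self.rows),
            "name": name,
            "activation": activation,
            "output_size": output_size,
            "kernel_size": kernel_size,
            "filters": filters,
            "parameters": int(parameters),
        })

    def total_parameters(self) -> int:
        return sum(r["parameters"] for r in self.rows)

    def by_name(self) -> dict[str, dict]:
        return {r["name"]: r for r in self.rows}

    def to_csv(self, path: str | Path | None = None) -> str:
        buf = io.StringIO()
        writer = csv.DictWriter(buf, fieldnames=self.COLUMNS, lineterminator="\n")
        writer.writeheader()
        writer.writerows(self.rows)
        text = buf.getvalue()
        if path is not None:
            Path(path).write_text(text)
        return text


def _shape_str(frames: int, width: int, channels: int) -> str:
    return f"{frames} x {width} x {channels}"


def _check_count(name: str, got: int) -> None:
    want = EXPECTED_CONV_PARAMS.get(name)
    if want is not None and got != want:
        raise ConstructionError(
            f"{name}: built parameter count {got} != published {want}")


_ENCODER_PLAN = [
    # (cin, cout, main1, main2, proj, projection_first)
    (19, 32, "conv2d_1", "conv2d_2", "conv2d", False),
    (32, 64, "conv2d_4", "conv2d_5", "conv2d_3", True),
    (64, 128, "conv2d_7", "conv2d_8", "conv2d_6", True),
    (128, 64, "conv2d_10", "conv2d_11", "conv2d_9", True),
]


def build_resnet_encoder(cfg: ModelConfig = ModelConfig(),
                         rng: np.random.Generator | None = None
                         ) -> tuple[nn.Sequential, LayerReport]:
    """Four-residual-block encoder: (64, 256, 19) -> (64, 16, 64)."""
    frames, width, channels = cfg.input_shape
    if channels != _ENCODER_PLAN[0][0] and cfg.variant == "resnet_bigru":
        pass  # non-canonical shapes allowed for small-scale testing
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    blocks = []
    cin = channels
    plan = _ENCODER_PLAN if channels == 19 else [
        (channels, 32, "conv2d_1", "conv2d_2", "conv2d", False),
        *_ENCODER_PLAN[1:],
    ]
    for cin_p, cout, n1, n2, nproj, proj_first in plan:
        block = nn.ResidualBlock(cin, cout, (n1, n2, nproj), rng,
                                 projection_first=proj_first)
        if channels == 19:
            for conv in (block.conv1, block.conv2, block.proj):
                _check_count(conv.name, conv.param_count())
        blocks.append(block)
        cin = cout
    model = nn.Sequential(blocks, name="resnet_encoder")
    report = _encoder_report(blocks, frames, width, channels)
    return model, report


def _encoder_report(blocks, frames: int, width: int, channels: int) -> LayerReport:
    rep = LayerReport()
    rep.add("input", "-", _shape_str(frames, width, channels), "-", "-", 0)
    w = width
    for block in blocks:
        cout = block.conv1.cout
        for lyr in block.sublayers():
            if isinstance(lyr, nn.Conv2D):
                kh, kw = lyr.ksize
                act = lyr.activation
                rep.add(lyr.name, act, _shape_str(frames, w, cout),
                        f"{kh} x {kw}", cout, lyr.param_count())
            elif isinstance(lyr, nn._Add):
                rep.add("Add+RELU", "RELU", _shape_str(frames, w, cout), "-", "-", 0)
            elif isinstance(lyr, nn.MaxPool1x2):
                w //= 2
                rep.add("Max_pooling", "-", _shape_str(frames, w, cout), "-", "-", 0)
    return rep


def build_bigru_head(cfg: ModelConfig = ModelConfig(),
                     in_shape: tuple[int, int, int] | None = None,
                     rng: np.random.Generator | None = None
                     ) -> tuple[nn.Sequential, LayerReport]:
    """Recurrent head: (64, 16, 64) -> per-frame probability (64, 1).

    Frames are flattened to width 1024, passed through two bidirectional
    GRU layers (128 units per direction, sequence-returning, dual-bias
    gates) and two per-frame dense layers. The first recurrent layer's
    parameter count is construction-asserted.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    frames, w, c = in_shape if in_shape is not None else (N_FRAMES, 16, 64)
    din = w * c
    u = cfg.gru_units
    gru1 = nn.BiGRU(din, u, "Bidirectional", rng)
    if din == 1024 and u == 128 and gru1.param_count() != EXPECTED_BIGRU1_PARAMS:
        raise ConstructionError(
            f"Bidirectional: built parameter count {gru1.param_count()} "
            f"!= published {EXPECTED_BIGRU1_PARAMS}")
    gru2 = nn.BiGRU(2 * u, u, "Bidirectional_1", rng)
    dense1 = nn.FrameDense(2 * u, cfg.dense_units, "Time_distributed", rng,
                           activation="RELU")
    dense2 = nn.FrameDense(cfg.dense_units, 1, "Time_distributed_1", rng)
    layers = [
        nn.FrameFlatten(),
        gru1,
        nn.Dropout(cfg.dropout_rate, rng, "dropout_gru1"),
        gru2,
        nn.Dropout(cfg.dropout_rate, rng, "dropout_gru2"),
        dense1,
        nn.Dropout(cfg.dropout_rate, rng, "dropout_dense"),
        dense2,
    ]
    if cfg.output_activation == "sigmoid":
        layers.append(nn.Sigmoid("Output"))
    else:
        layers.append(nn.ReLU("Output"))
    model = nn.Sequential(layers, name="bigru_head")

    rep = LayerReport()
    rep.add("RNN_input", "-", _shape_str(frames, w, c), "-", "-", 0)
    rep.add("Reshape", "-", f"{frames} x {din}", "-", "-", 0)
    rep.add("Bidirectional", "tanh", f"{frames} x {2 * u}", "-", u,
            gru1.param_count())
    rep.add("Bidirectional_1", "tanh", f"{frames} x {2 * u}", "-", u,
            gru2.param_count())
    rep.add("Time_distributed", "RELU", f"{frames} x {cfg.dense_units}", "-",
            cfg.dense_units, dense1.param_count())
    rep.add("Time_distributed_1", "-", f"{frames} x 1", "-", 1,
            dense2.param_count())
    rep.add("Output", cfg.output_activation, f"{frames} x 1", "-", "-", 0)
    return model, rep


def _plain_conv_stack(cfg: ModelConfig, rng: np.random.Generator) -> list[nn.Layer]:
    """Shortcut-free four-stage conv stack (the non-residual comparison)."""
    channels = cfg.input_shape[2]
    plan = [(channels, 32), (32, 64), (64, 128), (128, 64)]
    return [nn.PlainConvBlock(cin, cout, (f"conv2d_{2*i+1}", f"conv2d_{2*i+2}"), rng)
            for i, (cin, cout) in enumerate(plan)]


def _dense_head(cfg: ModelConfig, din: int, rng: np.random.Generator) -> list[nn.Layer]:
    layers: list[nn.Layer] = [
        nn.FrameFlatten(),
        nn.FrameDense(din, cfg.dense_units, "Dense", rng, activation="RELU"),
        nn.Dropout(cfg.dropout_rate, rng, "dropout_dense"),
        nn.FrameDense(cfg.dense_units, 1, "Dense_1", rng),
    ]
    layers.append(nn.Sigmoid("Output") if cfg.output_activation == "sigmoid"
                  else nn.ReLU("Output"))
    return layers


def build_variant(cfg: ModelConfig) -> nn.Sequential:
    """Build one of the four compared architectures.

    Every variant maps (64, 256, 19) input to a (64, 1) per-frame output;
    the sequence axis is never shortened.
    """
    rng = np.random.default_rng(cfg.seed)
    frames, width, channels = cfg.input_shape
    pooled_w = width // 16  # four (1,2) poolings
    if cfg.variant == "resnet_bigru":
        encoder, _ = build_resnet_encoder(cfg, rng)
        head, _ = build_bigru_head(cfg, (frames, pooled_w, 64), rng)
        return nn.Sequential(encoder.layers + head.layers, name="resnet_bigru")
    if cfg.variant == "cnn_only":
        stack = _plain_conv_stack(cfg, rng)
        return nn.Sequential(stack + _dense_head(cfg, pooled_w * 64, rng),
                             name="cnn_only")
    if cfg.variant == "cnn_gru":
        stack = _plain_conv_stack(cfg, rng)
        head, _ = build_bigru_head(cfg, (frames, pooled_w, 64), rng)
        return nn.Sequential(stack + head.layers, name="cnn_gru")
    if cfg.variant == "gru_only":
        head, _ = build_bigru_head(cfg, (frames, width, channels), rng)
        return nn.Sequential(head.layers, name="gru_only")
    raise ValueError(f"unknown variant {cfg.variant!r}")


def layer_report(model: nn.Sequential,
                 input_shape: tuple[int, int, int] | None = None) -> LayerReport:
    """Per-layer name/shape/kernel/filters/parameter-count in forward order.

    The report's summed counts equal the model's total trainable
    parameters (batch-norm scale/shift included as their own rows, as
    they are trainable but outside the published conv counts).
    """
    if input_shape is None:
        input_shape = (N_FRAMES, N_FEATURES, N_CHANNELS)
    rep = LayerReport()
    frames, w, c = input_shape
    rep.add("input", "-", _shape_str(frames, w, c), "-", "-", 0)
    for lyr in model.layers:
        if isinstance(lyr, nn.ResidualBlock):
            cout = lyr.conv1.cout
            for sub in lyr.sublayers():
                if isinstance(sub, nn.Conv2D):
                    kh, kw = sub.ksize
                    rep.add(sub.name, sub.activation, _shape_str(frames, w, cout),
                            f"{kh} x {kw}", cout, sub.param_count())
                elif isinstance(sub, nn._Add):
                    rep.add("Add+RELU", "RELU", _shape_str(frames, w, cout),
                            "-", "-", 0)
                elif isinstance(sub, nn.MaxPool1x2):
                    w //= 2
                    rep.add("Max_pooling", "-", _shape_str(frames, w, cout),
                            "-", "-", 0)
            for bn in (lyr.bn1, lyr.bn2):
                rep.add(bn.name, "-", _shape_str(frames, w, cout), "-", "-",
                        bn.param_count())
            c = cout
        elif isinstance(lyr, nn.PlainConvBlock):
            cout = lyr.conv1.cout
            for sub in lyr.sublayers():
                if isinstance(sub, nn.Conv2D):
                    kh, kw = sub.ksize
                    rep.add(sub.name, sub.activation, _shape_str(frames, w, cout),
                            f"{kh} x {kw}", cout, sub.param_count())
                elif isinstance(sub, nn.MaxPool1x2):
                    w //= 2
                    rep.add("Max_pooling", "-", _shape_str(frames, w, cout),
                            "-", "-", 0)
            for bn in (lyr.bn1, lyr.bn2):
                rep.add(bn.name, "-", _shape_str(frames, w, cout), "-", "-",
                        bn.param_count())
            c = cout
        elif isinstance(lyr, nn.FrameFlatten):
            rep.add("Reshape", "-", f"{frames} x {w * c}", "-", "-", 0)
            w, c = w * c, 1
        elif isinstance(lyr, nn.BiGRU):
            w = 2 * lyr.units
            rep.add(lyr.name, "tanh", f"{frames} x {w}", "-", lyr.units,
                    lyr.param_count())
        elif isinstance(lyr, nn.FrameDense):
            w = lyr.dout
            rep.add(lyr.name, lyr.activation, f"{frames} x {w}", "-", w,
                    lyr.param_count())
        elif isinstance(lyr, (nn.Sigmoid, nn.ReLU)):
            rep.add(lyr.name or "Output", lyr.activation, f"{frames} x {w}",
                    "-", "-", 0)
        elif isinstance(lyr, nn.Dropout):
            continue
        else:
            rep.add(lyr.name, lyr.activation, "-", "-", "-", lyr.param_count())
    return rep


def count_convolutions(model: nn.Sequential) -> int:
    n = 0
    for lyr in model.layers:
        if isinstance(lyr, nn.ResidualBlock):
            n += 3
        elif isinstance(lyr, nn.PlainConvBlock):
            n += 2
    return n


def total_parameters(model: nn.Sequential) -> int:
    return sum(p.size for p in model.params())


def save_model(model: nn.Sequential, cfg: ModelConfig, path: str | Path) -> None:
    """Native checkpoint (npz of parameter arrays) + JSON architecture manifest."""
    manifest = {
        "variant": cfg.variant,
        "input_shape": list(cfg.input_shape),
        "gru_units": cfg.gru_units,
        "dense_units": cfg.dense_units,
        "dropout_rate": cfg.dropout_rate,
        "l2_weight": cfg.l2_weight,
        "output_activation": cfg.output_activation,
        "seed": cfg.seed,
        "total_parameters": total_parameters(model),
    }
    model.save(Path(path), manifest=manifest)


def load_model(path: str | Path) -> tuple[nn.Sequential, ModelConfig]:
    path = Path(path)
    manifest = json.loads(path.with_suffix(".json").read_text())
    cfg = ModelConfig(
        variant=manifest["variant"],
        input_shape=tuple(manifest["input_shape"]),
        gru_units=manifest["gru_units"],
        dense_units=manifest["dense_units"],
        dropout_rate=manifest["dropout_rate"],
        l2_weight=manifest["l2_weight"],
        output_activation=manifest["output_activation"],
        seed=manifest["seed"],
    )
    model = build_variant(cfg)
    with np.load(path.with_suffix(".npz")) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model, cfg
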