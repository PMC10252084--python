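"""Analytic per-layer parameter and FLOPs accounting.

Two independent routes exist for parameters and are cross-checked in the
test suite: :func:`count_parameters` enumerates every trainable array the
model actually allocated, while the ``profile`` pass recomputes the same
totals from closed-form per-layer formulas during shape propagation.

FLOPs reporting convention
--------------------------
``GFLOPs = (2 * conv MACs + 4 * batch-normalised output elements) / 1e9``
at the stated square input.  Convolution MACs are ``k*k*C_in/groups``
multiply-accumulates per output element (bias adds ignored); each
batch-norm output element contributes two elementwise operations which the
doubling also applies to.  By default the detection head is evaluated at
the architecture's reference 80-class width, because that is the
convention under which the published model summaries for this family of
detectors are produced (parameter counts, by contrast, are always reported
for the model as built).  Pass ``reference_head=False`` for the FLOPs of
the exact model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .blocks import ProfileAccumulator
from .models import Detector, ModelConfig, build_model

__all__ = ["ProfileReport", "count_parameters", "count_flops",
           "profile_model", "reduction_report", "comparison_table"]

REFERENCE_NC = 80  # class count of the upstream reference summaries


@dataclass
class ProfileReport:
    """Per-layer and total accounting for one model at one input size."""

    name: str
    input_size: int
    per_layer: list[tuple[str, int, int]]  # (layer, params, macs)
    total_params: int
    total_macs: int
    total_flops_g: float
    model_size_mb: float

    def __post_init__(self):
        if self.total_params != sum(p for _, p, _ in self.per_layer):
            raise ValueError("per-layer params do not sum to total")


def count_parameters(model: Detector) -> int:
    """Exact count of trainable scalars (conv weights, BN scale/shift,
    head biases) by enumerating allocated arrays."""
    return int(sum(p.data.size for p in model.parameters()))


def _profile_pass(model: Detector, input_size: int) -> ProfileAccumulator:
    if input_size % 32:
        raise ValueError("input size must be divisible by 32")
    acc = ProfileAccumulator()
    model.profile((3, input_size, input_size), acc)
    return acc


def count_flops(model: Detector, input_size: int = 640,
                reference_head: bool = True) -> float:
    """Analytic GFLOPs at a square input (see module docstring for the
    exact reporting convention)."""
    acc = _profile_pass(model, input_size)
    macs = acc.total_macs
    if reference_head:
        own = 3 * (model.cfg.nc + 5)
        ref = 3 * (REFERENCE_NC + 5)
        head_macs = sum(m for n, _, m in acc.rows if n.startswith("head."))
        macs = macs - head_macs + head_macs * ref // own
    return (2 * macs + 4 * acc.bn_elements) / 1e9


def profile_model(model: Detector, input_size: int = 640,
                  name: str = "model") -> ProfileReport:
    acc = _profile_pass(model, input_size)
    total_params = count_parameters(model)
    if total_params != acc.total_params:
        raise AssertionError(
            f"analytic parameter formulas ({acc.total_params}) disagree with "
            f"allocated arrays ({total_params})")
    return ProfileReport(
        name=name,
        input_size=input_size,
        per_layer=list(acc.rows),
        total_params=total_params,
        total_macs=acc.total_macs,
        total_flops_g=count_flops(model, input_size),
        # informational estimate: half-precision serialised checkpoint
        model_size_mb=total_params * 2 / 1e6,
    )


def reduction_report(ref: ProfileReport, new: ProfileReport):
    """Relative drops of a lightweight variant against a reference.

    Returns (param_drop_pct, flops_drop_pct, param_delta, flops_delta_g);
    percentages are rounded to one decimal for display, deltas are exact.
    """
    if ref.total_params <= 0 or ref.total_flops_g <= 0:
        raise ValueError("reference totals must be positive")
    param_delta = ref.total_params - new.total_params
    flops_delta = ref.total_flops_g - new.total_flops_g
    return (round(100.0 * param_delta / ref.total_params, 1),
            round(100.0 * flops_delta / ref.total_flops_g, 1),
            int(param_delta),
            flops_delta)


def comparison_table(reports: list[ProfileReport], fmt: str = "table") -> str:
    """Render several profiles as an ablation-style comparison."""
    ref = reports[0]
    rows = []
    for r in reports:
        dp, df, _, _ = (0.0, 0.0, 0, 0.0) if r is ref else reduction_report(ref, r)
        rows.append((r.name, r.total_params, round(r.total_flops_g, 1),
                     round(r.model_size_mb, 1), dp, df))
    if fmt == "csv":
        out = ["model,parameters,flops_g,model_size_mb,param_drop_pct,flops_drop_pct"]
        out += [",".join(str(v) for v in row) for row in rows]
        return "\n".join(out)
    if fmt == "json":
        import json
        keys = ("model", "parameters", "flops_g", "model_size_mb",
                "param_drop_pct", "flops_drop_pct")
        return json.dumps([dict(zip(keys, row)) for row in rows], indent=2)
    w = max(len(r[0]) for r in rows) + 2
    head = (f"{'Model':<{w}}{'Params':>11}{'FLOPs(G)':>10}{'Size(MB)':>10}"
            f"{'dParams%':>10}{'dFLOPs%':>9}")
    lines = [head, "-" * len(head)]
    for name, p, f, mb, dp, df in rows:
        lines.append(f"{name:<{w}}{p:>11,}{f:>10.1f}{mb:>10.1f}{dp:>10.1f}{df:>9.1f}")
    return "\n".join(lines)
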