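"""Outcome transformations applied to cognitive scores before regression.

Response times (ms) from the computerized battery are base-10 log
transformed; accuracy proportions are arcsine-square-root transformed
(the variance-stabilising convention for proportions); maze error counts
enter untransformed; Stroop interference is expressed as the relative
slow-down between matched forms, (B-A)/A and (D-C)/C, and modelled
untransformed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "OUTCOMES",
    "OutcomeSpec",
    "inverse_accuracy",
    "inverse_speed",
    "stroop_ratio",
    "transform_accuracy",
    "transform_column",
    "transform_speed",
]


class TransformError(ValueError):
    """Input outside a transform's domain."""


def _asarray(x):
    arr = np.asarray(x, dtype=float)
    return arr, arr.ndim == 0


def transform_speed(rt_ms):
    """log10 of a positive mean response time in milliseconds."""
    arr, scalar = _asarray(rt_ms)
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0):
        raise TransformError("response time must be finite and > 0 ms")
    out = np.log10(arr)
    return float(out) if scalar else out


def inverse_speed(x):
    arr, scalar = _asarray(x)
    out = np.power(10.0, arr)
    return float(out) if scalar else out


def transform_accuracy(p):
    """arcsin(sqrt(p)) in radians for an accuracy proportion p in [0, 1].

    Percentages must be divided by 100 upstream; ``transform_column``
    does this for percent-scaled accuracy columns.
    """
    arr, scalar = _asarray(p)
    if np.any(~np.isfinite(arr)) or np.any(arr < 0) or np.any(arr > 1):
        raise TransformError("accuracy proportion must lie in [0, 1]")
    out = np.arcsin(np.sqrt(arr))
    return float(out) if scalar else out


def inverse_accuracy(x):
    arr, scalar = _asarray(x)
    out = np.sin(arr) ** 2
    return float(out) if scalar else out


def stroop_ratio(t_first, t_second):
    """Relative interference (t_second - t_first) / t_first between matched forms."""
    a, scalar_a = _asarray(t_first)
    b, scalar_b = _asarray(t_second)
    if np.any(~np.isfinite(a)) or np.any(a <= 0):
        raise TransformError("first-form time must be finite and > 0")
    out = (b - a) / a
    return float(out) if (scalar_a and scalar_b) else out


@dataclass(frozen=True)
class OutcomeSpec:
    """One modelled cognitive outcome: its metric and its transform."""

    name: str
    metric: str  # speed_ms | accuracy_pct | error_count | time_ratio
    transform: str  # log10 | arcsine_sqrt | identity
    label: str = ""

    def __post_init__(self) -> None:
        required = {
            "speed_ms": "log10",
            "accuracy_pct": "arcsine_sqrt",
            "error_count": "identity",
            "time_ratio": "identity",
        }
        if self.metric not in required:
            raise TransformError(f"unknown metric {self.metric!r}")
        if self.transform != required[self.metric]:
            raise TransformError(
                f"metric {self.metric!r} requires transform {required[self.metric]!r}"
            )


def _spec(name: str, metric: str, label: str) -> OutcomeSpec:
    transform = {"speed_ms": "log10", "accuracy_pct": "arcsine_sqrt"}.get(metric, "identity")
    return OutcomeSpec(name, metric, transform, label)


#: The twelve modelled outcomes: five tasks x (speed, accuracy), maze
#: errors, and the two Stroop interference ratios.
OUTCOMES: dict[str, OutcomeSpec] = {
    s.name: s
    for s in (
        _spec("detection_speed", "speed_ms", "Detection task speed"),
        _spec("detection_accuracy", "accuracy_pct", "Detection task accuracy"),
        _spec("identification_speed", "speed_ms", "Identification task speed"),
        _spec("identification_accuracy", "accuracy_pct", "Identification task accuracy"),
        _spec("one_back_speed", "speed_ms", "One-back memory task speed"),
        _spec("one_back_accuracy", "accuracy_pct", "One-back memory task accuracy"),
        _spec("one_card_speed", "speed_ms", "One card learning task speed"),
        _spec("one_card_accuracy", "accuracy_pct", "One card learning task accuracy"),
        _spec("go_nogo_speed", "speed_ms", "Go/No Go task speed"),
        _spec("go_nogo_accuracy", "accuracy_pct", "Go/No Go task accuracy"),
        _spec("groton_maze_errors", "error_count", "Groton maze total errors"),
        _spec("stroop_ab_ratio", "time_ratio", "Stroop (B-A)/A time ratio"),
        _spec("stroop_cd_ratio", "time_ratio", "Stroop (D-C)/C time ratio"),
    )
}


def transform_column(spec: OutcomeSpec, values):
    """Apply the outcome's transform to a raw column.

    Percent-scaled accuracy is divided by 100 before the arcsine
    square-root; speeds are log10-transformed; error counts and time
    ratios pass through unchanged.
    """
    if spec.transform == "log10":
        return transform_speed(values)
    if spec.transform == "arcsine_sqrt":
        arr, scalar = _asarray(values)
        out = transform_accuracy(arr / 100.0)
        return float(out) if scalar else out
    arr, scalar = _asarray(values)
    return float(arr) if scalar else arr
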