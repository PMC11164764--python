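"""Result serialization with reproducibility metadata.

Every artifact written by the CLI gets a JSON sidecar (``<name>.meta.json``)
recording the package version, seed, and every convention knob in effect —
enough to reproduce the file exactly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Mapping, Optional

import pandas as pd

from . import __version__
from .abstention import AbstentionCurve
from .metrics import AgeBin, ErrorSummary

__all__ = [
    "write_with_metadata",
    "write_curve",
    "write_error_report",
    "write_abstention_curve",
]


def _meta_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_with_metadata(
    df: pd.DataFrame,
    path: str | Path,
    metadata: Optional[Mapping[str, Any]] = None,
    float_format: Optional[str] = "%.6g",
) -> None:
    """Write a CSV plus a JSON metadata sidecar.

    ``float_format=None`` writes full precision (the ``--full-precision``
    CLI flag); the default keeps files readable at 6 significant digits.
    """
    path = Path(path)
    df.to_csv(path, index=False, float_format=float_format)
    meta = {"package": "clavage", "version": __version__}
    meta.update(metadata or {})
    _meta_path(path).write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")


def write_curve(
    curve: pd.DataFrame,
    path: str | Path,
    metadata: Optional[Mapping[str, Any]] = None,
    float_format: Optional[str] = "%.6g",
) -> None:
    """Write an AE(x) curve as CSV ``age,ae_years`` with metadata sidecar."""
    write_with_metadata(curve, path, metadata, float_format)


def _summary_row(label: str, s: ErrorSummary) -> dict[str, Any]:
    return {"group": label, **s.to_dict()}


def write_error_report(
    overall: ErrorSummary,
    per_bin: Mapping[AgeBin, ErrorSummary],
    path: str | Path,
    metadata: Optional[Mapping[str, Any]] = None,
    float_format: Optional[str] = "%.6g",
) -> None:
    """Write overall + per-bin summaries as a flat CSV (MAE, max, p90 order)."""
    rows = [_summary_row("overall", overall)]
    rows += [_summary_row(b.label(), s) for b, s in sorted(per_bin.items())]
    df = pd.DataFrame(rows)[["group", "n", "mae", "sd_ae", "max_ae", "p90_ae"]]
    write_with_metadata(df, path, metadata, float_format)


def write_abstention_curve(
    curve: AbstentionCurve,
    path: str | Path,
    metadata: Optional[Mapping[str, Any]] = None,
    float_format: Optional[str] = "%.6g",
) -> None:
    """Write an abstention curve as CSV ``rate,retained_n,mae,sd_ae,max_ae,p90_ae``."""
    write_with_metadata(curve.to_frame(), path, metadata, float_format)
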