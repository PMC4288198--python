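"""YAML configuration loading for scanner, screen and fold-call parameters.

A config file is a mapping with any of the top-level keys ``scan``,
``screen``, ``fold_call``; unknown keys inside a section are rejected so that
typos do not silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Any, Mapping

import yaml

from .aso_design import ScreenThresholds
from .assay_stats import FoldCallThresholds
from .g4scan import ScanParams


def _build(cls, section: Mapping[str, Any] | None, name: str):
    section = section or {}
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - valid
    if unknown:
        raise ValueError(f"unknown keys in {name!r} config section: {sorted(unknown)}")
    return cls(**section)


def load_config(path: str | Path | None) -> dict[str, Any]:
    """Return {'scan': ScanParams, 'screen': ScreenThresholds,
    'fold_call': FoldCallThresholds} with defaults where unspecified."""
    raw: Mapping[str, Any] = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    return {
        "scan": _build(ScanParams, raw.get("scan"), "scan"),
        "screen": _build(ScreenThresholds, raw.get("screen"), "screen"),
        "fold_call": _build(FoldCallThresholds, raw.get("fold_call"), "fold_call"),
    }
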