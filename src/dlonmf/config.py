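"""YAML config plumbing for the CLI.

A config file is a flat key/value mapping mirroring the CLI flags (keys use
underscores, e.g. ``lambda_u: 1.0``). Values given on the command line
override the config file.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any, Mapping

import yaml

from .errors import FormatError


def load_config(path: str | Path) -> dict[str, Any]:
    """Load a flat YAML key/value config file."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        return {}
    if not isinstance(raw, dict):
        raise FormatError(f"{path}: config must be a key/value mapping")
    return {str(k).replace("-", "_"): v for k, v in raw.items()}


def merge_config(
    config: Mapping[str, Any], overrides: Mapping[str, Any]
) -> dict[str, Any]:
    """Overlay CLI values on a config; a None override means 'not given'."""
    merged = dict(config)
    for key, value in overrides.items():
        if value is not None:
            merged[key] = value
    return merged
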