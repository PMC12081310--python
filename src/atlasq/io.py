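"""Readers for gene-set (GMT) and taxonomy (JSON) files."""

from __future__ import annotations

import json
from pathlib import Path

from .exceptions import FormatError


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Parse a GMT file into ``{set_name: [genes...]}``.

    Standard layout: one set per line, tab-separated, second field is a
    description and is discarded.
    """
    path = Path(path)
    sets: dict[str, list[str]] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
        name, _desc, *genes = fields
        sets[name] = [g for g in genes if g]
    if not sets:
        raise FormatError(f"{path}: empty GMT file")
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path) -> Path:
    path = Path(path)
    lines = [f"{name}\tna\t" + "\t".join(genes) for name, genes in sets.items()]
    path.write_text("\n".join(lines) + "\n")
    return path


def read_taxonomy_json(path: str | Path) -> dict:
    """Load the nested taxonomy JSON used by the annotation module."""
    path = Path(path)
    try:
        return json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: invalid taxonomy JSON ({exc})") from exc
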