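"""Minimal third-party plug-in contract for the command line.

A plug-in is a small YAML/JSON descriptor file naming a subcommand and
a discoverable callable (``package.module:function``); the callable
receives the argv tail of its subcommand.  Developer attribution is
mandatory and is echoed in the subcommand's help text and run logs, so
contributors keep the credit for their plug-ins.  Name collisions with
built-ins or earlier plug-ins are rejected with a logged warning.
"""

from __future__ import annotations

import importlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, List, Sequence

import yaml

__all__ = ["PluginDescriptor", "discover_plugins", "load_entry", "BUILTIN_COMMANDS"]

log = logging.getLogger("evokit.plugins")

BUILTIN_COMMANDS = frozenset(
    {"simulate", "sumstats", "dist", "nj", "boot", "vcf", "fst", "maf", "ssn",
     "convert"}
)


@dataclass(frozen=True)
class PluginDescriptor:
    name: str
    version: str
    attribution: str  # developer credit, shown in help and logs
    subcommand: str
    entry: str  # "package.module:function"

    def validate(self) -> None:
        if not self.name or not self.subcommand:
            raise ValueError("plug-in needs a name and a subcommand")
        if not self.attribution.strip():
            raise ValueError(f"plug-in {self.name!r}: attribution must be non-empty")
        if ":" not in self.entry:
            raise ValueError(
                f"plug-in {self.name!r}: entry must look like 'module:callable'"
            )


def _parse_descriptor(path: Path) -> PluginDescriptor:
    text = path.read_text()
    doc = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: descriptor must be a mapping")
    return PluginDescriptor(
        name=str(doc.get("name", "")),
        version=str(doc.get("version", "0")),
        attribution=str(doc.get("attribution", "")),
        subcommand=str(doc.get("subcommand", doc.get("name", ""))),
        entry=str(doc.get("entry", "")),
    )


def discover_plugins(search_spec: Iterable) -> List[PluginDescriptor]:
    """Scan directories for ``*.plugin.yaml|yml|json`` descriptors.

    Well-formed descriptors are returned in deterministic (path-sorted)
    order; malformed ones and subcommand collisions are skipped with a
    logged warning, never an exception.
    """
    taken = set(BUILTIN_COMMANDS)
    found: List[PluginDescriptor] = []
    paths: List[Path] = []
    for root in search_spec:
        root = Path(root)
        if not root.is_dir():
            continue
        for pat in ("*.plugin.yaml", "*.plugin.yml", "*.plugin.json"):
            paths.extend(root.glob(pat))
    for path in sorted(paths):
        try:
            desc = _parse_descriptor(path)
            desc.validate()
        except (ValueError, yaml.YAMLError, json.JSONDecodeError) as exc:
            log.warning("ignoring malformed plug-in descriptor %s: %s", path, exc)
            continue
        if desc.subcommand in taken:
            log.warning(
                "plug-in %r rejected: subcommand %r already taken",
                desc.name, desc.subcommand,
            )
            continue
        taken.add(desc.subcommand)
        found.append(desc)
    return found


def load_entry(desc: PluginDescriptor) -> Callable[[Sequence[str]], int]:
    """Resolve the descriptor's ``module:callable`` entry point."""
    mod_name, func_name = desc.entry.split(":", 1)
    mod = importlib.import_module(mod_name)
    func = getattr(mod, func_name)
    if not callable(func):
        raise TypeError(f"plug-in {desc.name!r}: entry {desc.entry!r} is not callable")
    return func
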