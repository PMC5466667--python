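"""YAML (de)serialization of network + physics + scenario configs.

Round-trip (load -> dump -> load) is lossless for every block produced by
``synthetic.default_parameter_set``.
"""

from __future__ import annotations

from pathlib import Path

import yaml

__all__ = ["load_config", "dump_config", "loads_config", "dumps_config"]


def dumps_config(config: dict) -> str:
    return yaml.safe_dump(config, sort_keys=True, default_flow_style=False)


def loads_config(text: str) -> dict:
    out = yaml.safe_load(text)
    if not isinstance(out, dict):
        raise ValueError("config must be a mapping")
    return out


def dump_config(config: dict, path: str | Path) -> None:
    Path(path).write_text(dumps_config(config))


def load_config(path: str | Path) -> dict:
    return loads_config(Path(path).read_text())
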