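"""Package configuration: unit aliases, salt tables, class boundaries.

Defaults ship as YAML inside the package; callers may load an override
file with the same structure and pass it where a ``config`` argument is
accepted.
"""
from __future__ import annotations

import functools
from importlib.resources import files

import yaml


@functools.lru_cache(maxsize=1)
def load_default_config() -> dict:
    """Load the packaged default configuration."""
    text = files("llps_pscreen.data").joinpath("defaults.yaml").read_text()
    return yaml.safe_load(text)


def load_config(path: str | None = None) -> dict:
    """Load configuration from *path*, falling back to packaged defaults."""
    if path is None:
        return load_default_config()
    with open(path) as fh:
        return yaml.safe_load(fh)
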