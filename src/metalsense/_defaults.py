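"""Load the package-wide default constants from ``defaults.toml``."""

from __future__ import annotations

import tomllib
from functools import lru_cache
from importlib import resources
from typing import Any


@lru_cache(maxsize=1)
def load_defaults() -> dict[str, Any]:
    """Parsed contents of the bundled ``defaults.toml`` (cached)."""
    text = resources.files("metalsense").joinpath("defaults.toml").read_text()
    return tomllib.loads(text)
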