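"""Structure-name normalization, including laterality handling.

Clinical structure sets spell laterality inconsistently ("Lens_L",
"L Lens", "Lens (L)", "left lens" ...).  ``normalize_name`` maps all of
these onto one canonical key (``lens_l``) so AI and clinical inventories
can be matched case-insensitively; ``base_name`` additionally strips the
laterality suffix so left/right pairs can be grouped.  The default token
table can be extended by callers.
"""

from __future__ import annotations

import re

__all__ = ["normalize_name", "base_name", "is_ptv"]

_LEFT_TOKENS = {"l", "lt", "left"}
_RIGHT_TOKENS = {"r", "rt", "right"}


def _tokens(name: str) -> list[str]:
    return [t for t in re.split(r"[^a-z0-9]+", name.lower()) if t]


def normalize_name(name: str) -> str:
    """Canonical key for a structure name: lowercase, underscore-joined,
    with any laterality token moved to a trailing ``_l`` / ``_r``."""
    toks = _tokens(name)
    side = None
    body = []
    for t in toks:
        if t in _LEFT_TOKENS:
            side = "l"
        elif t in _RIGHT_TOKENS:
            side = "r"
        else:
            body.append(t)
    key = "_".join(body) if body else "_".join(toks)
    return f"{key}_{side}" if side and body else key


def base_name(name: str) -> str:
    """Canonical key with any laterality suffix removed (groups L/R pairs)."""
    key = normalize_name(name)
    return re.sub(r"_(l|r)$", "", key)


def is_ptv(name: str) -> bool:
    """True for planning-target-volume names (``PTV*``), False for OARs."""
    return normalize_name(name).startswith("ptv")
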