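"""Ceramide nomenclature parsing.

Ceramide species are labelled ``CER[X(a)Y(b)]`` where ``X`` is the
fatty-acid class — N (non-hydroxy) or A (alpha-hydroxy) — with ``a``
carbons, and ``Y`` is the sphingoid base — S (sphingosine) or DS
(dihydrosphingosine) — with ``b`` carbons.  The four structural classes
NS, NDS, AS and ADS are the units at which rhythmic species are counted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = ["CeramideName", "CeramideParseError", "parse_ceramide_name", "is_ceramide_label"]

_CER_RE = re.compile(r"^CER\[(?P<fa>[NA])\((?P<fa_c>\d+)\)(?P<base>DS|S)\((?P<base_c>\d+)\)\]$")


class CeramideParseError(ValueError):
    """Raised when a label does not follow ceramide nomenclature."""


@dataclass(frozen=True)
class CeramideName:
    raw_label: str
    fa_class: str  # "N" or "A"
    fa_carbons: int
    base: str  # "S" or "DS"
    base_carbons: int

    @property
    def class_code(self) -> str:
        """Structural class: fatty-acid class + sphingoid base (NS/NDS/AS/ADS)."""
        return self.fa_class + self.base

    def format(self) -> str:
        return f"CER[{self.fa_class}({self.fa_carbons}){self.base}({self.base_carbons})]"


def is_ceramide_label(label: str) -> bool:
    return _CER_RE.match(label) is not None


def parse_ceramide_name(label: str, lenient: bool = False) -> CeramideName | None:
    """Parse a ``CER[X(a)Y(b)]`` label into its structural fields.

    In lenient mode non-matching labels (eicosanoids, endocannabinoids,
    e.g. ``9-HODE``) are passed through as ``None`` rather than raised.
    """
    m = _CER_RE.match(label)
    if m is None:
        if lenient:
            return None
        raise CeramideParseError(f"not a ceramide label: {label!r}")
    return CeramideName(
        raw_label=label,
        fa_class=m.group("fa"),
        fa_carbons=int(m.group("fa_c")),
        base=m.group("base"),
        base_carbons=int(m.group("base_c")),
    )
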