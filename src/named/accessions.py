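"""Functional-annotation accession identifiers (KO, COG, EC).

Three identifier namespaces occur in MAG functional annotations:

* KEGG Orthology (KO) numbers, ``K`` followed by five digits (``K02588``);
* NCBI Clusters of Orthologous Genes, ``COG`` followed by digits
  (``COG1348``) — canonicalised here by zero-padding the numeric part to
  four digits, so the shorthand ``COG347`` and the canonical ``COG0347``
  compare equal;
* Enzyme Commission numbers, one to four dot-separated fields, each a
  positive integer or a wildcard marker (``1.4.1.2``, ``1.4.*``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = ["Accession", "parse_accession", "AccessionError"]

_KO_RE = re.compile(r"^K\d{5}$")
_COG_RE = re.compile(r"^COG\s?(\d+)$", re.IGNORECASE)
_EC_FIELD_RE = re.compile(r"^(?:\d+|[-*])$")


class AccessionError(ValueError):
    """Raised for a token that is not a valid KO, COG, or EC identifier."""


@dataclass(frozen=True, order=True)
class Accession:
    """One functional identifier: ``source`` is ``KO``, ``COG`` or ``EC``."""

    source: str
    code: str

    def __str__(self) -> str:  # pragma: no cover - convenience repr
        return self.code


def _normalise_ec(code: str) -> str:
    fields = code.split(".")
    if not 1 <= len(fields) <= 4:
        raise AccessionError(f"EC code {code!r} must have 1-4 dot-separated fields")
    out = []
    for f in fields:
        if not _EC_FIELD_RE.match(f):
            raise AccessionError(f"EC code {code!r} has invalid field {f!r}")
        out.append("*" if f in ("-", "*") else str(int(f)))
    return ".".join(out)


def parse_accession(token: str) -> Accession:
    """Parse a raw token into an :class:`Accession`.

    Accepts an optional ``EC:`` prefix on EC numbers and the spaced /
    unpadded COG shorthand used in running text (``COG 347``).
    """
    token = token.strip()
    if not token:
        raise AccessionError("empty accession token")
    if _KO_RE.match(token):
        return Accession("KO", token)
    m = _COG_RE.match(token)
    if m:
        return Accession("COG", f"COG{int(m.group(1)):04d}")
    if token.upper().startswith("EC:"):
        token = token[3:]
    if "." in token or token.isdigit():
        return Accession("EC", _normalise_ec(token))
    raise AccessionError(f"unrecognised accession token {token!r}")
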