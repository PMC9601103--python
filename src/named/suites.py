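"""Gene-suite screens: named accession lists with an ANY-gene presence rule.

A suite (e.g. "Ammonification Hydrolases", or a dissolved-organic-matter
transporter set) is a list of accession patterns — exact KO/COG codes or
EC wildcards like ``1.4.*``.  A MAG is scored present for the suite when
any of its annotations matches any pattern.  EC wildcards match
field-wise (``1.4.*`` matches ``1.4.1.2`` but not ``1.14.13.25``), never
as string prefixes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

from .accessions import Accession, AccessionError, parse_accession
from .annotations import MagAnnotationSet

__all__ = [
    "GeneSuite",
    "SuiteResult",
    "match_ec_wildcard",
    "match_pattern",
    "screen_suite",
    "load_suites",
    "normalize_pattern",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSuite:
    suite_name: str
    patterns: tuple[str, ...]  # normalised; rule is fixed = ANY

    def __post_init__(self):
        if not self.patterns:
            raise ValueError("suite must contain at least one pattern")


@dataclass
class SuiteResult:
    suite_name: str
    mag_id: str
    present: bool
    matched_accessions: set[Accession]


def normalize_pattern(pattern: str) -> str:
    """Validate and canonicalise one pattern (KO, COG, or EC wildcard)."""
    pattern = pattern.strip()
    if pattern.upper().startswith("EC:"):
        pattern = pattern[3:]
    if "." in pattern or "*" in pattern or pattern.replace("-", "").isdigit():
        fields = pattern.split(".")
        if not 1 <= len(fields) <= 4:
            raise ValueError(f"EC pattern {pattern!r} must have 1-4 fields")
        norm = []
        for i, f in enumerate(fields):
            if f in ("*", "-"):
                if i != len(fields) - 1:
                    raise ValueError(
                        f"EC pattern {pattern!r}: wildcard allowed only as the last field"
                    )
                norm.append("*")
            elif f.isdigit():
                norm.append(str(int(f)))
            else:
                raise ValueError(f"EC pattern {pattern!r} has invalid field {f!r}")
        return ".".join(norm)
    return parse_accession(pattern).code


def match_ec_wildcard(pattern: str, ec: str) -> bool:
    """Field-wise prefix match of an EC pattern against a concrete EC code.

    Every specified pattern field must equal the corresponding code field;
    a trailing ``*`` covers all remaining fields.  Patterns without a
    wildcard require full equality.
    """
    pattern = normalize_pattern(pattern)
    if not ("." in pattern or "*" in pattern or pattern.isdigit()):
        raise ValueError(f"{pattern!r} is not an EC pattern")
    pfields = pattern.split(".")
    efields = ec.split(".")
    wildcard = pfields[-1] == "*"
    specified = pfields[:-1] if wildcard else pfields
    if not wildcard and len(specified) != len(efields):
        return False
    if len(specified) > len(efields):
        return False
    return all(p == e for p, e in zip(specified, efields))


def match_pattern(pattern: str, accession: Accession) -> bool:
    """True if the accession satisfies the (already normalised) pattern."""
    if "." in pattern or "*" in pattern:
        return accession.source == "EC" and match_ec_wildcard(pattern, accession.code)
    return accession.code == pattern


def screen_suite(suite: GeneSuite, mag: MagAnnotationSet) -> SuiteResult:
    """ANY-gene rule: present iff any annotation matches any pattern."""
    matched = {
        ann.accession
        for ann in mag.annotations
        for pattern in suite.patterns
        if match_pattern(pattern, ann.accession)
    }
    return SuiteResult(
        suite_name=suite.suite_name,
        mag_id=mag.mag_id,
        present=bool(matched),
        matched_accessions=matched,
    )


def load_suites(path: str | Path) -> list[GeneSuite]:
    """Read a two-column TSV (suite_name, pattern) into grouped suites.

    Patterns are normalised (``EC:`` prefix stripped, COG codes padded);
    duplicate (suite, pattern) rows are dropped with a warning; an invalid
    pattern raises naming the offending line.
    """
    path = Path(path)
    grouped: dict[str, list[str]] = {}
    with path.open(encoding="utf-8") as fh:
        header = fh.readline()
        if not header.strip():
            raise ValueError(f"{path}: empty suites file")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
            name, raw = parts[0].strip(), parts[1].strip()
            try:
                pattern = normalize_pattern(raw)
            except (ValueError, AccessionError) as exc:
                raise ValueError(f"{path}:{lineno}: invalid pattern {raw!r}: {exc}")
            bucket = grouped.setdefault(name, [])
            if pattern in bucket:
                logger.warning("%s:%d: duplicate pattern %s in suite %s; dropped",
                               path, lineno, pattern, name)
                continue
            bucket.append(pattern)
    if not grouped:
        raise ValueError(f"{path}: no suite rows found")
    return [GeneSuite(name, tuple(patterns)) for name, patterns in grouped.items()]
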