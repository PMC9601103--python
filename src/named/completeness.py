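"""Module-completeness scoring for MAG gene complements.

A module definition expands to alternative *paths* — sequences of reaction
steps, each demanding a set of gene accessions (a complex demands all its
subunits).  Completeness of a genome for a module is the best fraction of
satisfied steps over any alternative path, and a metabolism is called
present when that fraction reaches the detection threshold (default 2/3,
the exact-fraction reading of the conventional 67% criterion).

The evaluator never enumerates paths explicitly.  Each subtree is reduced
to the Pareto frontier of achievable ``(satisfied, total)`` step counts:
AND nodes combine children by Minkowski sum, OR nodes take the union, and
dominated pairs (fewer satisfied at no fewer total steps) are pruned.
Pruning is sound because the root objective ``(s + S) / (t + T)`` is
monotone in ``s`` and antitone in ``t`` for any non-negative context
``(S, T)``, so the frontier evaluation equals exhaustive enumeration
exactly — in rational arithmetic, with no float drift.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable

import pandas as pd

from .accessions import Accession
from .annotations import MagAnnotationSet, accessions_present, filter_by_evalue
from .grammar import GAP_STEP, DefinitionNode, ModuleDefinition, StepPath, _expand

__all__ = [
    "CompletenessResult",
    "DEFAULT_THRESHOLD",
    "THRESHOLD_EPSILON",
    "path_completeness",
    "module_completeness",
    "detect_metabolism",
    "score_all",
    "format_path",
]

#: Present/absent cutoff: the exact two-thirds fraction behind "67%".
DEFAULT_THRESHOLD = Fraction(2, 3)

#: Guard against float round-off when a user passes e.g. 0.6667.
THRESHOLD_EPSILON = 1e-9


@dataclass
class CompletenessResult:
    """Outcome of scoring one (module, MAG) pair."""

    module_id: str
    mag_id: str
    completeness: Fraction
    best_path: StepPath
    satisfied_steps: int
    total_steps: int
    present: bool
    threshold: Fraction


def _step_counts(step: frozenset, present: frozenset, count_mode: str) -> tuple[int, int]:
    """(satisfied, total) contribution of one step-set; gaps never satisfy."""
    if step == GAP_STEP:
        return 0, 1
    if count_mode == "genes":
        return len(step & present), len(step)
    return (1, 1) if step <= present else (0, 1)


def path_completeness(
    path: StepPath, present: Iterable[Accession], count_mode: str = "steps"
) -> tuple[int, int]:
    """Count satisfied and total steps of one path against a gene set."""
    if not path:
        raise ValueError("path must contain at least one step")
    present = frozenset(present)
    sat = tot = 0
    for step in path:
        s, t = _step_counts(step, present, count_mode)
        sat += s
        tot += t
    return sat, tot


def _path_key(path: StepPath) -> tuple:
    """Deterministic ordering key for tie-breaking between witness paths."""
    return tuple(tuple(sorted((a.source, a.code) for a in step)) for step in path)


# A frontier entry: (satisfied, total, witness_path).
_Entry = tuple[int, int, StepPath]


def _prune(entries: list[_Entry]) -> list[_Entry]:
    """Keep the Pareto frontier: max satisfied per total, dedup by key."""
    entries.sort(key=lambda e: (e[1], -e[0], _path_key(e[2])))
    kept: list[_Entry] = []
    best_sat = -1
    for sat, tot, path in entries:
        if sat > best_sat:
            kept.append((sat, tot, path))
            best_sat = sat
    return kept


def _frontier(node: DefinitionNode, present: frozenset, count_mode: str) -> list[_Entry]:
    if node.kind == "LEAF":
        step = frozenset({node.accession})
        s, t = _step_counts(step, present, count_mode)
        return [(s, t, (step,))]
    if node.kind == "GAP":
        return [(0, 1, (GAP_STEP,))]
    if node.kind == "OPTIONAL":
        return [(0, 0, ())]
    if node.kind == "OR":
        merged: list[_Entry] = []
        for c in node.children:
            merged.extend(_frontier(c, present, count_mode))
        return _prune(merged)
    if node.kind == "AND":
        acc: list[_Entry] = [(0, 0, ())]
        for c in node.children:
            child = _frontier(c, present, count_mode)
            acc = _prune(
                [
                    (s1 + s2, t1 + t2, p1 + p2)
                    for s1, t1, p1 in acc
                    for s2, t2, p2 in child
                ]
            )
        return acc
    if node.kind == "COMPLEX":
        # A complex is a single step; expand its (typically few) candidate
        # subunit sets and score each as one step.
        entries: list[_Entry] = []
        for path in _expand(node):
            if not path:
                entries.append((0, 0, ()))
                continue
            s, t = path_completeness(path, present, count_mode)
            entries.append((s, t, path))
        return _prune(entries)
    raise ValueError(f"unknown node kind {node.kind}")  # pragma: no cover


def _ratio(sat: int, tot: int) -> Fraction:
    return Fraction(sat, tot) if tot else Fraction(0)


def module_completeness(
    root: DefinitionNode,
    present: Iterable[Accession],
    count_mode: str = "steps",
) -> tuple[Fraction, StepPath, int, int]:
    """Best completeness fraction over all alternative paths, with witness.

    Returns ``(completeness, best_path, satisfied, total)``.  Ties between
    paths of equal completeness break toward fewer total steps, then the
    lexicographically smallest path, making the witness deterministic.
    A module whose only path is all-optional (zero scorable steps) scores 0.
    """
    if count_mode not in ("steps", "genes"):
        raise ValueError("count_mode must be 'steps' or 'genes'")
    present = frozenset(present)
    entries = _frontier(root, present, count_mode)
    best = min(entries, key=lambda e: (-_ratio(e[0], e[1]), e[1], _path_key(e[2])))
    sat, tot, path = best
    return _ratio(sat, tot), path, sat, tot


def detect_metabolism(
    module: ModuleDefinition,
    mag: MagAnnotationSet,
    threshold: float | Fraction = DEFAULT_THRESHOLD,
    count_mode: str = "steps",
    evalue_thresholds: dict[str, float] | None = None,
) -> CompletenessResult:
    """Score one MAG against one module and call presence at the threshold."""
    threshold = Fraction(threshold)
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    if evalue_thresholds:
        mag = filter_by_evalue(mag, evalue_thresholds)
    present_set = accessions_present(mag)
    completeness, path, sat, tot = module_completeness(module.root, present_set, count_mode)
    is_present = float(completeness) >= float(threshold) - THRESHOLD_EPSILON
    return CompletenessResult(
        module_id=module.module_id,
        mag_id=mag.mag_id,
        completeness=completeness,
        best_path=path,
        satisfied_steps=sat,
        total_steps=tot,
        present=is_present,
        threshold=threshold,
    )


def format_path(path: StepPath) -> str:
    """Render a path as ``step;step`` with ``+``-joined complex members."""
    out = []
    for step in path:
        if step == GAP_STEP:
            out.append("--")
        else:
            out.append("+".join(sorted(a.code for a in step)))
    return ";".join(out)


def score_all(
    mags: list[MagAnnotationSet],
    modules: list[ModuleDefinition],
    threshold: float | Fraction = DEFAULT_THRESHOLD,
    count_mode: str = "steps",
    evalue_thresholds: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Score every MAG against every module; rows sorted by (mag, module)."""
    if not mags or not modules:
        raise ValueError("mags and modules must be non-empty")
    ids = [m.mag_id for m in mags]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate mag_id(s): {', '.join(dupes)}")
    rows = []
    name_by_id = {m.module_id: m.name for m in modules}
    for mag in mags:
        for module in modules:
            r = detect_metabolism(module, mag, threshold, count_mode, evalue_thresholds)
            rows.append(
                {
                    "mag_id": r.mag_id,
                    "module_id": r.module_id,
                    "module_name": name_by_id[r.module_id],
                    "completeness": float(r.completeness),
                    "satisfied_steps": r.satisfied_steps,
                    "total_steps": r.total_steps,
                    "present": r.present,
                    "best_path": format_path(r.best_path),
                }
            )
    df = pd.DataFrame(rows)
    return df.sort_values(["mag_id", "module_id"], kind="mergesort").reset_index(drop=True)
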