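"""Boolean metabolism-by-MAG matrix assembly and serialisation.

Rows are features (metabolic modules called by the completeness engine,
gene suites under the ANY rule, and the nitrogen-fixation screen), grouped
by who plausibly benefits from the metabolism (host vs microbe).  Columns
are MAGs ordered by oxygen exposure, host species, tissue, then id, so the
layout is a pure function of the metadata.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .annotations import MagAnnotationSet
from .nif import NifScreenResult
from .suites import SuiteResult

__all__ = ["MetabolismMatrix", "build_matrix", "write_matrix", "read_matrix",
           "NIF_FEATURE_NAME", "render_heatmap"]

logger = logging.getLogger(__name__)

NIF_FEATURE_NAME = "Nitrogen Fixation (nifH+nifD)"
BENEFIT_GROUPS = ("hosts_benefit", "microbes_benefit")
_META_FIELDS = ("sample_id", "host_species", "tissue_type", "oxygen_class")


@dataclass
class MetabolismMatrix:
    #: (feature_name, feature_kind in {module, suite, nif}, benefit_group)
    feature_rows: list[tuple[str, str, str]]
    #: (mag_id, sample_id, host_species, tissue_type, oxygen_class)
    mag_columns: list[tuple[str, str, str, str, str]]
    values: list[list[bool]]

    def __post_init__(self):
        if len(self.values) != len(self.feature_rows):
            raise ValueError("grid row count does not match feature list")
        for row in self.values:
            if len(row) != len(self.mag_columns):
                raise ValueError("grid column count does not match MAG list")

    def true_count(self) -> int:
        return sum(sum(row) for row in self.values)


def build_matrix(
    completeness: pd.DataFrame,
    suites: list[SuiteResult],
    nif: list[NifScreenResult],
    metadata: list[MagAnnotationSet],
    groups: dict[str, str] | None = None,
) -> MetabolismMatrix:
    """Assemble the Boolean grid from the three screens.

    ``groups`` maps feature names to a benefit group; unmapped features
    default to ``microbes_benefit``.  Results referencing a MAG absent
    from ``metadata`` are an input error; (feature, MAG) pairs with no
    result are filled FALSE with a warning.
    """
    groups = groups or {}
    meta_by_mag = {m.mag_id: m for m in metadata}

    cells: dict[tuple[str, str], bool] = {}
    kinds: dict[str, str] = {}

    def put(feature: str, kind: str, mag_id: str, value: bool):
        if mag_id not in meta_by_mag:
            raise ValueError(f"result references unknown MAG {mag_id!r}")
        kinds[feature] = kind
        cells[(feature, mag_id)] = bool(value)

    for row in completeness.itertuples(index=False):
        feature = row.module_name if row.module_name else row.module_id
        put(feature, "module", row.mag_id, row.present)
    for s in suites:
        put(s.suite_name, "suite", s.mag_id, s.present)
    for n in nif:
        put(NIF_FEATURE_NAME, "nif", n.mag_id, n.passes)

    mag_columns = sorted(
        (
            (m.mag_id, m.sample_id, m.host_species, m.tissue_type, m.oxygen_class)
            for m in metadata
        ),
        key=lambda c: (c[4], c[2], c[3], c[0]),
    )
    kind_order = {"module": 0, "suite": 1, "nif": 2}
    feature_rows = sorted(
        (
            (name, kind, groups.get(name, "microbes_benefit"))
            for name, kind in kinds.items()
        ),
        key=lambda r: (r[2], kind_order[r[1]], r[0]),
    )

    values = []
    for name, kind, _group in feature_rows:
        row = []
        for col in mag_columns:
            key = (name, col[0])
            if key not in cells:
                logger.warning("no result for feature %r on MAG %s; filled FALSE", name, col[0])
            row.append(cells.get(key, False))
        values.append(row)
    return MetabolismMatrix(feature_rows, mag_columns, values)


def write_matrix(matrix: MetabolismMatrix, path: str | Path, format: str = "tsv") -> None:
    """Write the matrix: a mag-id header, a column-metadata block, 0/1 rows."""
    path = Path(path)
    if format == "tsv":
        lines = []
        mag_ids = [c[0] for c in matrix.mag_columns]
        lines.append("\t".join(["feature_name", "feature_kind", "benefit_group"] + mag_ids))
        for i, field in enumerate(_META_FIELDS, start=1):
            lines.append("\t".join([f"#{field}", "", ""] + [c[i] for c in matrix.mag_columns]))
        for (name, kind, group), row in zip(matrix.feature_rows, matrix.values):
            lines.append("\t".join([name, kind, group] + ["1" if v else "0" for v in row]))
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    elif format == "json":
        payload = {
            "feature_rows": [list(r) for r in matrix.feature_rows],
            "mag_columns": [list(c) for c in matrix.mag_columns],
            "values": [[int(v) for v in row] for row in matrix.values],
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    else:
        raise ValueError("format must be 'tsv' or 'json'")


def read_matrix(path: str | Path, format: str = "tsv") -> MetabolismMatrix:
    """Inverse of :func:`write_matrix`."""
    path = Path(path)
    if format == "json":
        payload = json.loads(path.read_text(encoding="utf-8"))
        return MetabolismMatrix(
            [tuple(r) for r in payload["feature_rows"]],
            [tuple(c) for c in payload["mag_columns"]],
            [[bool(v) for v in row] for row in payload["values"]],
        )
    lines = path.read_text(encoding="utf-8").splitlines()
    header = lines[0].split("\t")
    mag_ids = header[3:]
    meta: dict[str, list[str]] = {}
    feature_rows: list[tuple[str, str, str]] = []
    values: list[list[bool]] = []
    for line in lines[1:]:
        cols = line.split("\t")
        if cols[0].startswith("#"):
            meta[cols[0][1:]] = cols[3:]
            continue
        feature_rows.append((cols[0], cols[1], cols[2]))
        values.append([c == "1" for c in cols[3:]])
    mag_columns = [
        (
            mag_ids[i],
            meta.get("sample_id", [""] * len(mag_ids))[i],
            meta.get("host_species", [""] * len(mag_ids))[i],
            meta.get("tissue_type", [""] * len(mag_ids))[i],
            meta.get("oxygen_class", [""] * len(mag_ids))[i],
        )
        for i in range(len(mag_ids))
    ]
    return MetabolismMatrix(feature_rows, mag_columns, values)


def render_heatmap(matrix: MetabolismMatrix, png_path: str | Path) -> None:
    """Optional raster rendering; the TSV is the contract, not the image."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(
        figsize=(max(4, 0.3 * len(matrix.mag_columns)), max(3, 0.3 * len(matrix.feature_rows)))
    )
    grid = [[1 if v else 0 for v in row] for row in matrix.values]
    ax.imshow(grid, aspect="auto", cmap="Greys", vmin=0, vmax=1)
    ax.set_xticks(range(len(matrix.mag_columns)))
    ax.set_xticklabels([c[0] for c in matrix.mag_columns], rotation=90, fontsize=6)
    ax.set_yticks(range(len(matrix.feature_rows)))
    ax.set_yticklabels([r[0] for r in matrix.feature_rows], fontsize=6)
    fig.tight_layout()
    fig.savefig(png_path, dpi=150)
    plt.close(fig)
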