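"""Per-MAG gene annotation tables, e-value filtering, and MAG quality bands.

Consumes the anvi'o-style export formats: a functions TSV (one row per
functional hit on a gene call), a contig-to-bin map, and an optional MAG
metadata table (sample, host, tissue, oxygen exposure, completion and
redundancy estimates from single-copy genes).  Genes on contigs missing
from the bin map are collected under the reserved MAG id ``UNBINNED``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from .accessions import Accession, AccessionError, parse_accession

__all__ = [
    "GeneAnnotation",
    "MagAnnotationSet",
    "UNBINNED_MAG_ID",
    "TISSUE_TYPES",
    "OXYGEN_CLASSES",
    "read_annotations",
    "write_annotations",
    "filter_by_evalue",
    "classify_mag_quality",
    "accessions_present",
]

logger = logging.getLogger(__name__)

UNBINNED_MAG_ID = "UNBINNED"
TISSUE_TYPES = ("blade", "rhizome", "sediment", "bulb")
OXYGEN_CLASSES = ("water_column", "low_oxygen")

_FUNCTIONS_COLUMNS = ("gene_callers_id", "contig", "source", "accession", "e_value")
_BINS_COLUMNS = ("contig", "bin_name")
_METADATA_COLUMNS = (
    "bin_name",
    "sample_id",
    "host_species",
    "tissue_type",
    "oxygen_class",
    "completion_pct",
    "redundancy_pct",
)

#: Annotation-source labels normalised per accession namespace.
_SOURCE_BY_NAMESPACE = {"KO": "KOfam", "COG": "COG", "EC": "EC"}


@dataclass(frozen=True)
class GeneAnnotation:
    """One functional hit on one gene call."""

    gene_id: str
    contig_id: str
    gene_order_on_contig: int
    source: str  # KOfam | COG | EC
    accession: Accession
    function_text: str
    e_value: float

    def __post_init__(self):
        if self.e_value < 0:
            raise ValueError("e_value must be non-negative")


@dataclass
class MagAnnotationSet:
    """All functional hits belonging to one MAG, with sample metadata."""

    mag_id: str
    annotations: list[GeneAnnotation] = field(default_factory=list)
    contig_ids: set[str] = field(default_factory=set)
    sample_id: str = ""
    host_species: str = ""
    tissue_type: str = ""
    oxygen_class: str = ""
    completion_pct: float = 0.0
    redundancy_pct: float = 0.0


def _require_columns(df: pd.DataFrame, required, path) -> None:
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column '{col}'")


def read_annotations(
    functions_path: str | Path,
    bins_path: str | Path,
    metadata_path: str | Path | None = None,
) -> list[MagAnnotationSet]:
    """Load functions + bin map (+ metadata) into per-MAG annotation sets.

    Gene order on each contig is assigned 0-based from file order; hits
    whose accession token is unparseable are dropped with a warning.
    """
    functions = pd.read_csv(functions_path, sep="\t", dtype=str)
    _require_columns(functions, _FUNCTIONS_COLUMNS, functions_path)
    bins = pd.read_csv(bins_path, sep="\t", dtype=str)
    _require_columns(bins, _BINS_COLUMNS, bins_path)
    contig_to_mag = dict(zip(bins["contig"], bins["bin_name"]))

    meta_by_mag: dict[str, dict] = {}
    if metadata_path is not None:
        meta = pd.read_csv(metadata_path, sep="\t")
        _require_columns(meta, _METADATA_COLUMNS, metadata_path)
        for row in meta.to_dict("records"):
            meta_by_mag[str(row["bin_name"])] = row

    mags: dict[str, MagAnnotationSet] = {}
    order_counter: dict[tuple[str, str], int] = {}
    seen_order: dict[tuple[str, str], int] = {}
    warned_contigs: set[str] = set()

    for row in functions.itertuples(index=False):
        contig = str(row.contig)
        mag_id = contig_to_mag.get(contig)
        if mag_id is None:
            if contig not in warned_contigs:
                logger.warning(
                    "contig %s absent from bin map; routing its genes to %s",
                    contig, UNBINNED_MAG_ID,
                )
                warned_contigs.add(contig)
            mag_id = UNBINNED_MAG_ID
        try:
            acc = parse_accession(str(row.accession))
        except AccessionError as exc:
            logger.warning("dropping annotation on gene %s: %s", row.gene_callers_id, exc)
            continue
        gene_key = (contig, str(row.gene_callers_id))
        if gene_key not in seen_order:
            seen_order[gene_key] = order_counter.get(contig, 0)
            order_counter[contig] = seen_order[gene_key] + 1
        ann = GeneAnnotation(
            gene_id=str(row.gene_callers_id),
            contig_id=contig,
            gene_order_on_contig=seen_order[gene_key],
            source=_SOURCE_BY_NAMESPACE[acc.source],
            accession=acc,
            function_text=str(getattr(row, "function", "")),
            e_value=float(row.e_value),
        )
        mag = mags.setdefault(mag_id, MagAnnotationSet(mag_id=mag_id))
        mag.annotations.append(ann)
        mag.contig_ids.add(contig)

    # MAGs present in the bin map but with no annotated genes still exist.
    for contig, mag_id in contig_to_mag.items():
        mag = mags.setdefault(mag_id, MagAnnotationSet(mag_id=mag_id))
        mag.contig_ids.add(contig)

    for mag_id, row in meta_by_mag.items():
        mag = mags.get(mag_id)
        if mag is None:
            continue
        mag.sample_id = str(row["sample_id"])
        mag.host_species = str(row["host_species"])
        mag.tissue_type = str(row["tissue_type"])
        mag.oxygen_class = str(row["oxygen_class"])
        mag.completion_pct = float(row["completion_pct"])
        mag.redundancy_pct = float(row["redundancy_pct"])

    return sorted(mags.values(), key=lambda m: m.mag_id)


def write_annotations(
    mags: list[MagAnnotationSet],
    functions_path: str | Path,
    bins_path: str | Path,
    metadata_path: str | Path | None = None,
) -> None:
    """Inverse of :func:`read_annotations`, for round-trips and fixtures."""
    func_rows, bin_rows, meta_rows = [], [], []
    for mag in sorted(mags, key=lambda m: m.mag_id):
        for ann in mag.annotations:
            func_rows.append(
                {
                    "gene_callers_id": ann.gene_id,
                    "contig": ann.contig_id,
                    "source": ann.source,
                    "accession": ann.accession.code,
                    "function": ann.function_text,
                    "e_value": f"{ann.e_value:.6g}",
                }
            )
        for contig in sorted(mag.contig_ids):
            if mag.mag_id != UNBINNED_MAG_ID:
                bin_rows.append({"contig": contig, "bin_name": mag.mag_id})
        if mag.mag_id != UNBINNED_MAG_ID and metadata_path is not None:
            meta_rows.append(
                {
                    "bin_name": mag.mag_id,
                    "sample_id": mag.sample_id,
                    "host_species": mag.host_species,
                    "tissue_type": mag.tissue_type,
                    "oxygen_class": mag.oxygen_class,
                    "completion_pct": f"{mag.completion_pct:.1f}",
                    "redundancy_pct": f"{mag.redundancy_pct:.1f}",
                }
            )
    pd.DataFrame(func_rows, columns=["gene_callers_id", "contig", "source",
                                     "accession", "function", "e_value"]
                 ).to_csv(functions_path, sep="\t", index=False)
    pd.DataFrame(bin_rows, columns=list(_BINS_COLUMNS)).to_csv(bins_path, sep="\t", index=False)
    if metadata_path is not None:
        pd.DataFrame(meta_rows, columns=list(_METADATA_COLUMNS)).to_csv(
            metadata_path, sep="\t", index=False
        )


def filter_by_evalue(
    mag: MagAnnotationSet, thresholds: dict[str, float]
) -> MagAnnotationSet:
    """Drop hits at or above their source's cutoff (strict ``e < threshold``).

    Sources absent from ``thresholds`` pass through unfiltered; an empty
    map is the identity.
    """
    for source, cutoff in thresholds.items():
        if cutoff < 0:
            raise ValueError(f"negative e-value threshold for source {source!r}")
    kept = [
        ann
        for ann in mag.annotations
        if ann.source not in thresholds or ann.e_value < thresholds[ann.source]
    ]
    return replace(mag, annotations=kept, contig_ids=set(mag.contig_ids))


def classify_mag_quality(completion_pct: float, redundancy_pct: float) -> str:
    """Band a MAG as ``high``, ``medium`` or ``unclassified``.

    High quality demands completion above 90% with redundancy
    (contamination) below 10%; medium quality spans completion 42-90%
    inclusive with redundancy 0-11% inclusive.  The high rule is applied
    first, so the bands are disjoint.
    """
    for name, v in (("completion_pct", completion_pct), ("redundancy_pct", redundancy_pct)):
        if not 0 <= v <= 100:
            raise ValueError(f"{name} must lie in [0, 100], got {v}")
    if completion_pct > 90 and redundancy_pct < 10:
        return "high"
    if 42 <= completion_pct <= 90 and 0 <= redundancy_pct <= 11:
        return "medium"
    return "unclassified"


def accessions_present(mag: MagAnnotationSet) -> set[Accession]:
    """Deduplicated accession set across all genes and sources of a MAG."""
    return {ann.accession for ann in mag.annotations}
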