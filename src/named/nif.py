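"""Nitrogen-fixation screen over MAG annotations.

A MAG is flagged as a candidate diazotroph when it carries both
nitrogenase marker genes — nifH (K02588) and nifD (K02586) — as
KOfam hits with e-values strictly below 1e-100.  The COG family
containing nifH (COG1348) also contains the homologous light-independent
protochlorophyllide reductases from pigment synthesis, so COG1348 hits
are reported only as an advisory and never substitute for the KO
evidence.  For MAGs that pass, accessory nitrogen-fixation genes
(nifD/COG2710, the PII regulator/COG0347, nifB/COG0535) co-located on a
nifH-bearing contig are reported with their gene-order distance to nifH.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .accessions import Accession, parse_accession
from .annotations import MagAnnotationSet

__all__ = ["NifScreenConfig", "NifScreenResult", "NifHit", "screen_nif", "contig_cooccurrence"]


@dataclass(frozen=True)
class NifHit:
    gene_id: str
    contig_id: str
    e_value: float
    gene_order: int


def _default_accessory() -> tuple[Accession, ...]:
    # Literal labels from annotation exports drop leading zeros
    # ("COG 2710", "COG 347", "COG 535"); parse_accession canonicalises.
    return tuple(parse_accession(c) for c in ("COG 2710", "COG 347", "COG 535"))


@dataclass(frozen=True)
class NifScreenConfig:
    nifH_ko: Accession = Accession("KO", "K02588")
    nifD_ko: Accession = Accession("KO", "K02586")
    e_max: float = 1e-100
    accessory: tuple[Accession, ...] = field(default_factory=_default_accessory)
    exclude: tuple[Accession, ...] = (Accession("COG", "COG1348"),)

    def __post_init__(self):
        if self.e_max <= 0:
            raise ValueError("e_max must be positive")
        if self.nifH_ko == self.nifD_ko:
            raise ValueError("nifH and nifD markers must differ")


@dataclass
class NifScreenResult:
    mag_id: str
    passes: bool
    nifH_hits: list[NifHit]
    nifD_hits: list[NifHit]
    homolog_advisory: list[NifHit]
    cooccurring_accessory: dict[str, list[tuple[Accession, str, int]]] = field(
        default_factory=dict
    )


def _marker_hits(mag: MagAnnotationSet, marker: Accession, e_max: float) -> list[NifHit]:
    hits = [
        NifHit(a.gene_id, a.contig_id, a.e_value, a.gene_order_on_contig)
        for a in mag.annotations
        if a.source == "KOfam" and a.accession == marker and a.e_value < e_max
    ]
    return sorted(hits, key=lambda h: (h.e_value, h.contig_id, h.gene_id))


def screen_nif(
    mag: MagAnnotationSet,
    cfg: NifScreenConfig = NifScreenConfig(),
    same_contig: bool = False,
) -> NifScreenResult:
    """Flag a MAG that carries both nifH and nifD under the strict cutoff.

    Only KOfam hits below ``cfg.e_max`` (strict inequality, mirroring the
    "<1e-100" criterion) count.  With ``same_contig=True`` both markers
    must additionally share a contig.  Homolog (COG1348) hits are listed
    in an advisory field regardless of the outcome.
    """
    nifH = _marker_hits(mag, cfg.nifH_ko, cfg.e_max)
    nifD = _marker_hits(mag, cfg.nifD_ko, cfg.e_max)
    homolog = sorted(
        (
            NifHit(a.gene_id, a.contig_id, a.e_value, a.gene_order_on_contig)
            for a in mag.annotations
            if a.accession in cfg.exclude
        ),
        key=lambda h: (h.e_value, h.contig_id, h.gene_id),
    )
    passes = bool(nifH) and bool(nifD)
    if passes and same_contig:
        passes = bool({h.contig_id for h in nifH} & {h.contig_id for h in nifD})
    result = NifScreenResult(
        mag_id=mag.mag_id,
        passes=passes,
        nifH_hits=nifH,
        nifD_hits=nifD,
        homolog_advisory=homolog,
    )
    return contig_cooccurrence(mag, result, cfg)


def contig_cooccurrence(
    mag: MagAnnotationSet, result: NifScreenResult, cfg: NifScreenConfig = NifScreenConfig()
) -> NifScreenResult:
    """List accessory nif genes on each qualifying nifH contig.

    Reporting is same-contig only; each entry carries the gene-order
    distance to the nearest qualifying nifH gene on that contig.  MAGs
    that fail the screen get an empty map.
    """
    result.cooccurring_accessory = {}
    if not result.passes:
        return result
    accessory_set = set(cfg.accessory)
    nifh_by_contig: dict[str, list[NifHit]] = {}
    for h in result.nifH_hits:
        nifh_by_contig.setdefault(h.contig_id, []).append(h)
    for contig, nifh_hits in sorted(nifh_by_contig.items()):
        found: list[tuple[Accession, str, int]] = []
        for a in mag.annotations:
            if a.contig_id != contig or a.accession not in accessory_set:
                continue
            dist = min(abs(a.gene_order_on_contig - h.gene_order) for h in nifh_hits)
            found.append((a.accession, a.gene_id, dist))
        result.cooccurring_accessory[contig] = sorted(
            found, key=lambda t: (t[2], t[0].code, t[1])
        )
    return result
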