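"""End-to-end orchestration: detect -> suites -> nif screen -> matrix.

Outputs are written atomically (temp file in the destination directory,
then rename), and the whole run is a pure function of its inputs and
configuration: rerunning on the same files yields byte-identical outputs.
"""

from __future__ import annotations

import logging
import os
import tempfile
from pathlib import Path

import pandas as pd

from .annotations import UNBINNED_MAG_ID, read_annotations
from .completeness import score_all
from .config import RunConfig
from .grammar import read_kegg_module_file
from .matrix import build_matrix, write_matrix
from .nif import NifScreenConfig, screen_nif
from .suites import load_suites, screen_suite

__all__ = ["run_pipeline", "load_groups", "atomic_write_text"]

logger = logging.getLogger(__name__)


def atomic_write_text(path: Path, text: str) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w", encoding="utf-8") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def load_groups(path: str | Path) -> dict[str, str]:
    """Two-column TSV (feature_name, benefit_group) -> mapping."""
    df = pd.read_csv(path, sep="\t")
    for col in ("feature_name", "benefit_group"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column '{col}'")
    return dict(zip(df["feature_name"].astype(str), df["benefit_group"].astype(str)))


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
        return wrapped
    return deco


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run all stages in order and return the paths of the written outputs."""
    config.validate(check_paths=True)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    modules = _stage("kegg_grammar")(read_kegg_module_file)(config.modules)
    mags = _stage("annotation_store")(read_annotations)(
        config.annotations, config.bins, config.metadata
    )
    binned = [m for m in mags if m.mag_id != UNBINNED_MAG_ID]

    results = _stage("completeness_engine")(score_all)(
        binned, modules, config.threshold, config.count_mode,
        config.evalue_thresholds or None,
    )

    suites = _stage("gene_suites")(load_suites)(config.suites) if config.suites else []
    suite_results = [screen_suite(s, mag) for mag in binned for s in suites]

    nif_cfg = NifScreenConfig(e_max=config.nif_emax)
    nif_results = [_stage("nif_screen")(screen_nif)(mag, nif_cfg) for mag in binned]

    groups = load_groups(config.groups) if config.groups else {}
    matrix = _stage("heatmap_report")(build_matrix)(
        results, suite_results, nif_results, binned, groups
    )

    outputs: dict[str, Path] = {}

    detect_path = out_dir / "completeness.tsv"
    atomic_write_text(detect_path, results.to_csv(sep="\t", index=False))
    outputs["completeness"] = detect_path

    suites_path = out_dir / "suites.tsv"
    suite_rows = [
        {
            "mag_id": r.mag_id,
            "suite_name": r.suite_name,
            "present": r.present,
            "matched_accessions": ";".join(sorted(a.code for a in r.matched_accessions)),
        }
        for r in sorted(suite_results, key=lambda r: (r.mag_id, r.suite_name))
    ]
    atomic_write_text(
        suites_path,
        pd.DataFrame(suite_rows, columns=["mag_id", "suite_name", "present",
                                          "matched_accessions"]).to_csv(sep="\t", index=False),
    )
    outputs["suites"] = suites_path

    nif_path = out_dir / "nif_report.tsv"
    nif_rows = [
        {
            "mag_id": r.mag_id,
            "passes": r.passes,
            "nifH_best_e": min((h.e_value for h in r.nifH_hits), default=""),
            "nifD_best_e": min((h.e_value for h in r.nifD_hits), default=""),
            "nifH_contigs": ";".join(sorted({h.contig_id for h in r.nifH_hits})),
            "accessory_found": ";".join(
                sorted({acc.code for lst in r.cooccurring_accessory.values()
                        for acc, _, _ in lst})
            ),
        }
        for r in sorted(nif_results, key=lambda r: r.mag_id)
    ]
    atomic_write_text(
        nif_path,
        pd.DataFrame(nif_rows, columns=["mag_id", "passes", "nifH_best_e", "nifD_best_e",
                                        "nifH_contigs", "accessory_found"]
                     ).to_csv(sep="\t", index=False),
    )
    outputs["nif"] = nif_path

    matrix_path = out_dir / "matrix.tsv"
    tmp = out_dir / ".matrix.tsv.tmp"
    write_matrix(matrix, tmp, "tsv")
    os.replace(tmp, matrix_path)
    outputs["matrix"] = matrix_path

    config.write_provenance(out_dir / "run_config.yaml")
    logger.info("pipeline complete: %d MAGs x %d modules", len(binned), len(modules))
    return outputs
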