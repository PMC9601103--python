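"""Synthetic MAG annotation communities with planted, known ground truth.

The generator emits the exact file formats the pipeline consumes — a
functions TSV, a contig-to-bin map, and a MAG metadata table — for a set
of per-MAG plant specifications: target module completeness along a chosen
alternative path, suite genes, a diazotroph marker pair (nifH+nifD), the
COG1348 protochlorophyllide-homolog trap, and distractor genes drawn from
an accession pool disjoint from everything planted.

Ground truth is computed at generation time by exhaustive path
enumeration and subset counting over the planted accession set — a route
independent of the frontier evaluator the engine uses — so recovery tests
compare two genuinely different computations.

E-value model (generator design, not an empirical fit): planted hits draw
log10(e) uniformly on [-180, -20]; nitrogenase markers and the homolog
trap on [-180, -110] so they sit below the strict 1e-100 screen; distractor
decoys on [-90, -5].  All randomness flows from one generator per spec.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
import yaml

from .accessions import Accession
from .annotations import (
    GeneAnnotation,
    MagAnnotationSet,
    TISSUE_TYPES,
    write_annotations,
)
from .grammar import (
    GAP_STEP,
    DefinitionNode,
    ModuleDefinition,
    enumerate_paths,
    serialize_definition,
    write_kegg_module_file,
)
from .suites import GeneSuite, match_pattern

__all__ = [
    "PlantSpec",
    "GroundTruth",
    "generate_community",
    "generate_module_fixtures",
    "random_definition_tree",
    "load_plant_specs",
    "example_specs",
]

_HOSTS = (
    "Phyllospadix scouleri",
    "Phyllospadix serrulatus",
    "Zostera marina",
    "Nereocystis luetkeana",
    "Laminaria setchellii",
)

NIFH = Accession("KO", "K02588")
NIFD = Accession("KO", "K02586")
_NIF_ACCESSORY = (Accession("COG", "COG2710"), Accession("COG", "COG0347"),
                  Accession("COG", "COG0535"))
_HOMOLOG_TRAP = Accession("COG", "COG1348")

# log10 e-value windows (generator design, see module docstring)
_EVALUE_PLANT = (-180.0, -20.0)
_EVALUE_MARKER = (-180.0, -110.0)
_EVALUE_DECOY = (-90.0, -5.0)


@dataclass
class PlantSpec:
    """What to plant into one synthetic MAG."""

    mag_id: str
    planted_modules: list[tuple[str, float, int]] = field(default_factory=list)
    planted_suites: list[tuple[str, int]] = field(default_factory=list)
    plant_diazotroph: bool = False
    include_homolog_trap: bool = False
    n_distractor_genes: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.n_distractor_genes < 0:
            raise ValueError("n_distractor_genes must be >= 0")
        for mid, f, _ in self.planted_modules:
            if not 0 <= f <= 1:
                raise ValueError(f"target completeness for {mid} must lie in [0, 1]")


@dataclass
class GroundTruth:
    """Expected pipeline outcomes, derived deterministically from the specs."""

    #: exact attainable completeness per (mag_id, module_id)
    module_completeness: dict[tuple[str, str], Fraction]
    #: fraction of the designated path actually planted
    realized_fraction: dict[tuple[str, str], Fraction]
    suite_present: dict[tuple[str, str], bool]
    nif_pass: dict[str, bool]


def _oracle_completeness(root: DefinitionNode, present: set[Accession]) -> Fraction:
    """Exhaustive-enumeration completeness: the generator's independent route."""
    paths, truncated = enumerate_paths(root, max_paths=200_000)
    if truncated:  # pragma: no cover - generator never emits such modules
        raise ValueError("module too branched for exhaustive ground truth")
    best = Fraction(0)
    for path in paths:
        if not path:
            continue
        sat = sum(1 for step in path if step != GAP_STEP and step <= present)
        best = max(best, Fraction(sat, len(path)))
    return best


def _concrete_ec_for(pattern: str, rng: np.random.Generator) -> Accession:
    fields = pattern.split(".")
    out = []
    for f in fields:
        out.append(str(int(rng.integers(1, 30))) if f == "*" else f)
    while len(out) < 4:
        out.append(str(int(rng.integers(1, 30))))
    return Accession("EC", ".".join(out))


def _draw_evalue(rng: np.random.Generator, window: tuple[float, float]) -> float:
    return float(10.0 ** rng.uniform(*window))


def generate_community(
    specs: list[PlantSpec],
    modules: list[ModuleDefinition],
    suites: list[GeneSuite],
    out_dir: str | Path,
) -> tuple[dict[str, Path], GroundTruth]:
    """Generate annotation files plus ground truth for a list of plant specs.

    Writes ``functions.tsv``, ``bins.tsv`` and ``metadata.tsv`` under
    ``out_dir`` and returns their paths with the :class:`GroundTruth`.
    Identical specs (including seeds) produce byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    modules_by_id = {m.module_id: m for m in modules}
    suites_by_name = {s.suite_name: s for s in suites}

    mags: list[MagAnnotationSet] = []
    truth = GroundTruth({}, {}, {}, {})

    for spec in specs:
        rng = np.random.default_rng(spec.seed)
        n_contigs = int(rng.integers(1, 4))
        contigs = [f"{spec.mag_id}_c{i:02d}" for i in range(n_contigs)]
        mag = MagAnnotationSet(mag_id=spec.mag_id, contig_ids=set(contigs))
        gene_counter = 0
        order: dict[str, int] = {c: 0 for c in contigs}
        planted_accessions: set[Accession] = set()

        def add_gene(accession: Accession, e_value: float, contig: str,
                     function_text: str) -> None:
            nonlocal gene_counter
            source = {"KO": "KOfam", "COG": "COG", "EC": "EC"}[accession.source]
            mag.annotations.append(
                GeneAnnotation(
                    gene_id=f"{spec.mag_id}_g{gene_counter:05d}",
                    contig_id=contig,
                    gene_order_on_contig=order[contig],
                    source=source,
                    accession=accession,
                    function_text=function_text,
                    e_value=e_value,
                )
            )
            gene_counter += 1
            order[contig] += 1

        # --- module plants -------------------------------------------------
        for module_id, target_f, path_index in spec.planted_modules:
            module = modules_by_id[module_id]
            paths, _ = enumerate_paths(module.root)
            path = [p for p in paths if p][path_index % len([p for p in paths if p])]
            total = len(path)
            nongap = [i for i, step in enumerate(path) if step != GAP_STEP]
            n_plant = min(math.ceil(target_f * total), len(nongap))
            chosen = sorted(rng.choice(nongap, size=n_plant, replace=False)) if n_plant else []
            for i in chosen:
                for acc in sorted(path[i]):
                    contig = contigs[int(rng.integers(0, n_contigs))]
                    add_gene(acc, _draw_evalue(rng, _EVALUE_PLANT), contig,
                             f"planted gene for {module_id}")
                    planted_accessions.add(acc)
            truth.realized_fraction[(spec.mag_id, module_id)] = Fraction(n_plant, total)

        # --- suite plants --------------------------------------------------
        for suite_name, n_genes in spec.planted_suites:
            suite = suites_by_name[suite_name]
            for k in range(n_genes):
                pattern = suite.patterns[k % len(suite.patterns)]
                if "." in pattern or "*" in pattern:
                    acc = _concrete_ec_for(pattern, rng)
                else:
                    acc = Accession("KO" if pattern.startswith("K") else "COG", pattern)
                contig = contigs[int(rng.integers(0, n_contigs))]
                add_gene(acc, _draw_evalue(rng, _EVALUE_PLANT), contig,
                         f"planted gene for suite {suite_name}")
                planted_accessions.add(acc)

        # --- nitrogen-fixation plants -------------------------------------
        nif_contig = contigs[0]
        if spec.plant_diazotroph:
            add_gene(NIFH, _draw_evalue(rng, _EVALUE_MARKER), nif_contig, "nifH nitrogenase")
            add_gene(NIFD, _draw_evalue(rng, _EVALUE_MARKER),
                     contigs[int(rng.integers(0, n_contigs))], "nifD nitrogenase")
            for acc in _NIF_ACCESSORY:
                add_gene(acc, _draw_evalue(rng, _EVALUE_PLANT), nif_contig,
                         "nitrogen fixation accessory")
            planted_accessions |= {NIFH, NIFD, *_NIF_ACCESSORY}
        if spec.include_homolog_trap:
            add_gene(_HOMOLOG_TRAP, _draw_evalue(rng, _EVALUE_MARKER), nif_contig,
                     "protochlorophyllide reductase homolog (COG1348)")
            planted_accessions.add(_HOMOLOG_TRAP)

        # --- distractors (reserved K9xxxx / COG9xxx pools) -----------------
        for _ in range(spec.n_distractor_genes):
            if rng.random() < 0.7:
                acc = Accession("KO", f"K9{int(rng.integers(0, 10000)):04d}")
            else:
                acc = Accession("COG", f"COG9{int(rng.integers(100, 1000)):03d}")
            assert acc not in planted_accessions, "distractor pool collided with a plant"
            contig = contigs[int(rng.integers(0, n_contigs))]
            add_gene(acc, _draw_evalue(rng, _EVALUE_DECOY), contig, "synthetic distractor")

        # --- metadata ------------------------------------------------------
        host = _HOSTS[int(rng.integers(0, len(_HOSTS)))]
        tissue = TISSUE_TYPES[int(rng.integers(0, len(TISSUE_TYPES)))]
        mag.host_species = host
        mag.tissue_type = tissue
        mag.oxygen_class = "water_column" if tissue == "blade" else "low_oxygen"
        mag.sample_id = f"{host.split()[0][:3].upper()}_{tissue.upper()[:3]}"
        mag.completion_pct = round(float(rng.uniform(45, 99)), 1)
        mag.redundancy_pct = round(float(rng.uniform(0, 9)), 1)
        mags.append(mag)

        # --- ground truth --------------------------------------------------
        present = {a.accession for a in mag.annotations}
        for module_id, _, _ in spec.planted_modules:
            truth.module_completeness[(spec.mag_id, module_id)] = _oracle_completeness(
                modules_by_id[module_id].root, present
            )
        for module in modules:
            truth.module_completeness.setdefault(
                (spec.mag_id, module.module_id),
                _oracle_completeness(module.root, present),
            )
        for suite in suites:
            truth.suite_present[(spec.mag_id, suite.suite_name)] = any(
                match_pattern(p, acc) for p in suite.patterns for acc in present
            )
        truth.nif_pass[spec.mag_id] = spec.plant_diazotroph

    paths = {
        "functions": out_dir / "functions.tsv",
        "bins": out_dir / "bins.tsv",
        "metadata": out_dir / "metadata.tsv",
    }
    write_annotations(mags, paths["functions"], paths["bins"], paths["metadata"])
    return paths, truth


# ---------------------------------------------------------------------------
# Random module fixtures


def _random_leaf(counter: list[int]) -> DefinitionNode:
    acc = Accession("KO", f"K{30000 + counter[0]:05d}")
    counter[0] += 1
    return DefinitionNode("LEAF", accession=acc)


def _random_unit(rng: np.random.Generator, counter: list[int], or_depth: int) -> DefinitionNode:
    roll = rng.random()
    if roll < 0.55 or or_depth >= 3:
        return _random_leaf(counter)
    if roll < 0.75:
        branches = tuple(
            _random_branch(rng, counter, or_depth + 1) for _ in range(int(rng.integers(2, 4)))
        )
        return DefinitionNode("OR", branches)
    if roll < 0.92:
        subunits = tuple(_random_leaf(counter) for _ in range(int(rng.integers(2, 4))))
        return DefinitionNode("COMPLEX", subunits)
    return DefinitionNode("OPTIONAL", (_random_leaf(counter),))


def _random_branch(rng: np.random.Generator, counter: list[int], or_depth: int) -> DefinitionNode:
    roll = rng.random()
    if roll < 0.6:
        return _random_leaf(counter)
    if roll < 0.8:
        units = tuple(_random_unit(rng, counter, or_depth) for _ in range(2))
        if any(u.kind == "AND" for u in units):  # keep normal form
            return units[0]
        return DefinitionNode("AND", units)
    subunits = tuple(_random_leaf(counter) for _ in range(2))
    return DefinitionNode("COMPLEX", subunits)


def generate_module_fixtures(
    n: int, seed: int, path: str | Path | None = None
) -> list[ModuleDefinition]:
    """Generate ``n`` random valid modules spanning all grammar features.

    The first module always contains an OR (multiple alternative paths)
    and the last contains a gap step; OR nesting depth stays <= 3.
    Optionally writes a KEGG-dialect flat file to ``path``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    counter = [0]
    modules = []
    for i in range(n):
        units = [_random_unit(rng, counter, 0) for _ in range(int(rng.integers(3, 7)))]
        if i == 0 and not any(u.kind == "OR" for u in units):
            branches = (_random_leaf(counter), _random_leaf(counter))
            units[0] = DefinitionNode("OR", branches)
        if i == n - 1 and n > 1:
            units.append(DefinitionNode("GAP"))
        root = DefinitionNode("AND", tuple(units)) if len(units) > 1 else units[0]
        raw = serialize_definition(root)
        modules.append(
            ModuleDefinition(
                module_id=f"MS{i:04d}",
                name=f"Synthetic pathway {i}",
                raw_definition=raw,
                root=root,
            )
        )
    if path is not None:
        write_kegg_module_file(modules, path)
    return modules


def random_definition_tree(
    rng: np.random.Generator, pool_size: int = 30, max_units: int = 4
) -> DefinitionNode:
    """A random normalised definition tree over a small shared KO pool.

    Unlike the fixture generator (which allocates fresh accessions per
    module), leaves here repeat across the tree, so random presence sets
    exercise shared-gene interactions between alternative branches.
    """

    def leaf() -> DefinitionNode:
        return DefinitionNode(
            "LEAF", accession=Accession("KO", f"K{int(rng.integers(0, pool_size)):05d}")
        )

    def unit(or_depth: int) -> DefinitionNode:
        roll = rng.random()
        if roll < 0.45 or or_depth >= 3:
            return leaf()
        if roll < 0.70:
            return DefinitionNode(
                "OR", tuple(branch(or_depth + 1) for _ in range(int(rng.integers(2, 4))))
            )
        if roll < 0.85:
            subunits = [leaf()]
            for _ in range(int(rng.integers(1, 3))):
                sub = leaf()
                if rng.random() < 0.2:
                    sub = DefinitionNode("OPTIONAL", (sub,))
                subunits.append(sub)
            return DefinitionNode("COMPLEX", tuple(subunits))
        if roll < 0.95:
            return DefinitionNode("OPTIONAL", (leaf(),))
        return DefinitionNode("GAP")

    def branch(or_depth: int) -> DefinitionNode:
        if rng.random() < 0.6:
            return leaf()
        units = [unit(or_depth) for _ in range(2)]
        units = [u for u in units if u.kind != "AND"]
        if len(units) < 2:
            return units[0] if units else leaf()
        return DefinitionNode("AND", tuple(units))

    units = [unit(0) for _ in range(int(rng.integers(1, max_units + 1)))]
    return DefinitionNode("AND", tuple(units)) if len(units) > 1 else units[0]


def example_specs(
    modules: list[ModuleDefinition],
    suites: list[GeneSuite],
    n_mags: int,
    seed: int,
) -> list[PlantSpec]:
    """A standard mixed community: varied targets, one diazotroph, one trap."""
    rng = np.random.default_rng(seed)
    specs = []
    targets = [0.0, 0.25, 0.5, 2 / 3, 0.75, 1.0]
    for i in range(n_mags):
        planted = []
        for m in modules:
            t = targets[int(rng.integers(0, len(targets)))]
            planted.append((m.module_id, t, int(rng.integers(0, 4))))
        planted_suites = [
            (s.suite_name, int(rng.integers(0, 3))) for s in suites
        ]
        specs.append(
            PlantSpec(
                mag_id=f"MAG{i:03d}",
                planted_modules=planted,
                planted_suites=planted_suites,
                plant_diazotroph=(i % 3 == 0),
                include_homolog_trap=(i % 3 == 1),
                n_distractor_genes=int(rng.integers(5, 25)),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return specs


def load_plant_specs(path: str | Path) -> list[PlantSpec]:
    """Read plant specs from a YAML file (a list of PlantSpec mappings)."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, list) or not raw:
        raise ValueError(f"{path}: expected a non-empty list of plant specs")
    specs = []
    for entry in raw:
        specs.append(
            PlantSpec(
                mag_id=entry["mag_id"],
                planted_modules=[tuple(t) for t in entry.get("planted_modules", [])],
                planted_suites=[tuple(t) for t in entry.get("planted_suites", [])],
                plant_diazotroph=bool(entry.get("plant_diazotroph", False)),
                include_homolog_trap=bool(entry.get("include_homolog_trap", False)),
                n_distractor_genes=int(entry.get("n_distractor_genes", 0)),
                seed=int(entry.get("seed", 0)),
            )
        )
    return specs
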