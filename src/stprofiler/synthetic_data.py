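"""Synthetic expression cohorts with known ground-truth pathway activity.

Cohorts are built from *archetypes*: templates assigning each pathway a
latent activity level in [0, 1] (the probability scale at which target genes
respond).  For a sample with activity ``a`` on a pathway, each up-regulated
target's log2 expression is ``baseline + a * effect * weight + noise`` and
each down-regulated target's is the mirror image; per-gene baselines are
drawn once per cohort pair around 8 on the log2 scale, emulating microarray
intensities.  Replicates of one entity share the latent state and differ
only by measurement noise.  Crucially the generator emits *expression*, never
scores, so recovery tests exercise the whole scoring path.

Noise is generated as ``noise_sd * standard_normal`` from the seeded stream,
so runs at different noise levels under the same seed share the same noise
shape and differ only in amplitude — which is what makes degradation-with-
noise checks well posed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort_io import ANALYSIS_PATHWAYS
from .stp_model import PathwayDefinition, TargetGene

__all__ = [
    "Archetype",
    "DEFAULT_ARCHETYPES",
    "DEFAULT_HISTOLOGY_MAP",
    "MatchedCohorts",
    "generate_pathway_definitions",
    "generate_cohort",
    "generate_matched_cohorts",
]

_HIGH, _LOW, _MID = 0.9, 0.1, 0.5


@dataclass(frozen=True)
class Archetype:
    """A ground-truth activity template: pathway -> level in [0, 1]."""

    name: str
    levels: dict = field(hash=False)

    def __post_init__(self) -> None:
        if not self.levels:
            raise ValueError(f"archetype {self.name!r}: needs >= 1 pathway level")
        bad = {p: v for p, v in self.levels.items() if not (0.0 <= v <= 1.0)}
        if bad:
            raise ValueError(f"archetype {self.name!r}: levels outside [0,1]: {bad}")

    def level(self, pathway: str) -> float:
        return self.levels.get(pathway, _MID)


def _archetype(name: str, high=(), low=()) -> Archetype:
    levels = {p: _MID for p in ANALYSIS_PATHWAYS}
    levels.update({p: _HIGH for p in high})
    levels.update({p: _LOW for p in low})
    return Archetype(name=name, levels=levels)


#: Seven test-fixture archetypes over the analysis pathways — qualitative
#: high/low templates of the kinds of profile clusters seen in ovarian-cancer
#: cell-line panels (hormonal-high, hormonal-low, HH-driven, Wnt/HH, ...).
DEFAULT_ARCHETYPES = (
    _archetype("C1", high=("AR", "ER", "TGFB")),
    _archetype("C2", low=("AR", "ER")),
    _archetype("C3", high=("AR",), low=("HH",)),
    _archetype("C4", high=("HH",), low=("NFKB",)),
    _archetype("C5", high=("WNT", "HH")),
    _archetype("C6", low=("TGFB", "NOTCH", "WNT")),
    _archetype("C7", high=("AR", "ER"), low=("HH",)),
)

#: Default archetype -> tumor-histology assignment for matched cohorts.
DEFAULT_HISTOLOGY_MAP = {
    "C1": "LGOC", "C2": "HGSOC", "C3": "HGSOC", "C4": "HGSOC",
    "C5": "LGOC", "C6": "HGSOC", "C7": "SBOT",
}


def generate_pathway_definitions(
    n_pathways: int = 7,
    genes_per_pathway: tuple[int, int] | int = (25, 35),
    seed: int = 0,
    down_fraction: float = 0.2,
) -> list[PathwayDefinition]:
    """Synthetic pathway definitions with unique gene ids.

    Gene counts are drawn uniformly from ``genes_per_pathway`` (a range or a
    fixed int), evidence weights from Uniform(0.3, 1), and about 20% of
    targets are down-regulated.  Pathway names follow the analysis set
    (AR, ER, ...) then ``P8``, ``P9``, ... Deterministic per seed.
    """
    if n_pathways < 1:
        raise ValueError("n_pathways must be >= 1")
    rng = np.random.default_rng(seed)
    if isinstance(genes_per_pathway, int):
        lo = hi = genes_per_pathway
    else:
        lo, hi = genes_per_pathway
    names = list(ANALYSIS_PATHWAYS[:n_pathways])
    names += [f"P{i + 1}" for i in range(len(names), n_pathways)]
    defs = []
    for name in names:
        n_genes = int(rng.integers(lo, hi + 1))
        weights = rng.uniform(0.3, 1.0, size=n_genes)
        down = rng.random(n_genes) < down_fraction
        targets = [
            TargetGene(
                gene_id=f"{name}_T{i:03d}",
                direction="down" if down[i] else "up",
                weight=float(weights[i]),
            )
            for i in range(n_genes)
        ]
        defs.append(PathwayDefinition(name=name, targets=targets))
    return defs


def _baselines(definitions, rng) -> pd.Series:
    genes = [t.gene_id for d in definitions for t in d.targets]
    return pd.Series(rng.normal(8.0, 1.0, size=len(genes)), index=genes)


def _build_cohort(
    definitions,
    archetypes,
    n_per_archetype,
    noise_sd,
    replicate_spec,
    rng,
    baselines,
    dataset_id,
    tissue_class,
    entity_prefix,
    histology_map=None,
    effect: float = 3.0,
):
    if not archetypes:
        raise ValueError("empty archetype list")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if isinstance(n_per_archetype, int):
        n_per_archetype = {a.name: n_per_archetype for a in archetypes}
    reps = replicate_spec if replicate_spec else 1

    genes = list(baselines.index)
    columns, meta_rows, truth_rows = [], [], []
    data = []
    for arch in archetypes:
        for i in range(n_per_archetype.get(arch.name, 0)):
            entity = f"{entity_prefix}{arch.name}_{i:02d}"
            n_rep = reps[entity] if isinstance(reps, dict) else reps
            # latent state is per entity; replicates share it
            shift = np.zeros(len(genes))
            pos = 0
            for d in definitions:
                a = arch.level(d.name)
                for t in d.targets:
                    s = a * effect * t.weight
                    shift[pos] = s if t.direction == "up" else -s
                    pos += 1
            for r in range(n_rep):
                sid = f"{entity}_r{r}" if n_rep > 1 else entity
                noise = noise_sd * rng.standard_normal(len(genes))
                data.append(baselines.to_numpy() + shift + noise)
                columns.append(sid)
                histology = (
                    histology_map[arch.name] if histology_map is not None
                    else "other"
                )
                meta_rows.append(
                    {"sample_id": sid, "entity_name": entity,
                     "dataset_id": dataset_id, "tissue_class": tissue_class,
                     "histology_of_origin": histology,
                     "treated": False, "contaminated": False,
                     "non_ovarian": False}
                )
                truth_rows.append(
                    {"sample_id": sid, "archetype": arch.name,
                     "entity_name": entity, "dataset_id": dataset_id,
                     "replicate": r,
                     "histology": histology,
                     **{f"level_{d.name}": arch.level(d.name) for d in definitions}}
                )
    values = (
        np.array(data).T if data else np.empty((len(genes), 0))
    )
    matrix = pd.DataFrame(
        values, index=pd.Index(genes, name="gene_id"), columns=columns
    )
    metadata = (
        pd.DataFrame(meta_rows).set_index("sample_id")
        if meta_rows
        else pd.DataFrame(columns=[c for c in
                                   ("entity_name", "dataset_id", "tissue_class",
                                    "histology_of_origin", "treated",
                                    "contaminated", "non_ovarian")],
                          index=pd.Index([], name="sample_id"))
    )
    truth = (
        pd.DataFrame(truth_rows).set_index("sample_id")
        if truth_rows
        else pd.DataFrame(index=pd.Index([], name="sample_id"))
    )
    return matrix, metadata, truth


def generate_cohort(
    definitions: list[PathwayDefinition],
    archetypes=DEFAULT_ARCHETYPES,
    n_per_archetype: "int | dict" = 4,
    noise_sd: float = 1.0,
    replicate_spec: "int | dict | None" = None,
    seed: int = 0,
    dataset_id: str = "SYN1",
    tissue_class: str = "cell_line",
    effect: float = 3.0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """One cohort: (expression matrix, sample metadata, ground truth).

    ``replicate_spec`` gives replicate counts (an int for all entities or a
    dict per entity); replicates share the entity's latent activity and
    differ only by noise.  Bit-identical output per seed.
    """
    rng = np.random.default_rng(seed)
    baselines = _baselines(definitions, rng)
    return _build_cohort(
        definitions, list(archetypes), n_per_archetype, noise_sd,
        replicate_spec, rng, baselines, dataset_id, tissue_class,
        entity_prefix="CL_", effect=effect,
    )


@dataclass
class MatchedCohorts:
    """A cell-line cohort and a tumor cohort drawn from shared archetypes.

    The ground-truth "correct match" for a tumor is any cell line of the
    same archetype.  Both cohorts share per-gene baselines, so their
    expression is directly comparable.
    """

    cellline_expression: pd.DataFrame
    cellline_metadata: pd.DataFrame
    cellline_truth: pd.DataFrame
    tumor_expression: pd.DataFrame
    tumor_metadata: pd.DataFrame
    tumor_truth: pd.DataFrame

    def combined_expression(self) -> pd.DataFrame:
        return pd.concat([self.cellline_expression, self.tumor_expression], axis=1)

    def combined_metadata(self) -> pd.DataFrame:
        return pd.concat([self.cellline_metadata, self.tumor_metadata], axis=0)


def generate_matched_cohorts(
    definitions: list[PathwayDefinition],
    archetypes=DEFAULT_ARCHETYPES,
    n_celllines: int = 2,
    n_tumors: int = 6,
    histology_map: dict | None = None,
    noise_sd: float = 1.0,
    seed: int = 0,
    effect: float = 3.0,
) -> MatchedCohorts:
    """Paired cell-line and tumor cohorts sharing archetypes.

    ``n_celllines`` / ``n_tumors`` are per archetype.  ``histology_map``
    must assign every archetype a tumor histology (SBOT / HGSOC / LGOC);
    the default map covers the seven default archetypes.
    """
    archetypes = list(archetypes)
    histology_map = dict(
        DEFAULT_HISTOLOGY_MAP if histology_map is None else histology_map
    )
    missing = [a.name for a in archetypes if a.name not in histology_map]
    if missing:
        raise ValueError(f"histology_map lacks archetypes: {missing}")
    rng = np.random.default_rng(seed)
    baselines = _baselines(definitions, rng)
    cl = _build_cohort(
        definitions, archetypes, n_celllines, noise_sd, None, rng, baselines,
        dataset_id="SYN_CL", tissue_class="cell_line", entity_prefix="CL_",
        histology_map=histology_map, effect=effect,
    )
    tm = _build_cohort(
        definitions, archetypes, n_tumors, noise_sd, None, rng, baselines,
        dataset_id="SYN_TM", tissue_class="tumor", entity_prefix="TM_",
        histology_map=histology_map, effect=effect,
    )
    return MatchedCohorts(*cl, *tm)
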