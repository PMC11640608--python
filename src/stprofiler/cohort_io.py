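"""Expression-matrix and sample-metadata i/o, eligibility filtering,
replicate averaging and pathway selection.

Expression matrices are plain TSV (gene id in the first column, one column
per sample, optional ``#`` comment lines).  Metadata travels as a sidecar CSV
joined on ``sample_id`` with the columns documented in
:data:`METADATA_COLUMNS`; absent boolean flags default to false.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .stp_model import STPProfile

__all__ = [
    "METADATA_COLUMNS",
    "DEFAULT_EXCLUDED_PATHWAYS",
    "ANALYSIS_PATHWAYS",
    "ExclusionLog",
    "read_expression_matrix",
    "read_sample_metadata",
    "filter_samples",
    "average_replicates",
    "select_pathways",
]

METADATA_COLUMNS = [
    "sample_id",
    "entity_name",      # cell line name or patient id
    "dataset_id",       # e.g. a GEO series accession
    "tissue_class",     # "cell_line" | "tumor"
    "histology_of_origin",
    "treated",
    "contaminated",
    "non_ovarian",
]

_FLAG_COLUMNS = ["treated", "contaminated", "non_ovarian"]

#: Growth-factor pathways whose activity tracks culture conditions (serum
#: levels etc.), hence excluded from cell-line/tumor comparisons by default.
DEFAULT_EXCLUDED_PATHWAYS = frozenset({"MAPK", "PI3K", "JAK-STAT3"})

#: The seven pathways retained for the analysis by default.
ANALYSIS_PATHWAYS = ("AR", "ER", "HH", "NFKB", "NOTCH", "TGFB", "WNT")


def read_expression_matrix(path) -> pd.DataFrame:
    """Parse a genes × samples TSV of log2 intensities.

    Duplicate gene rows are collapsed by mean with a warning.  Ragged rows or
    non-numeric cells raise with the offending coordinates.
    """
    try:
        df = pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype=str)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty expression file") from None
    if df.empty and len(df.columns) == 0:
        raise ValueError(f"{path}: empty expression file")
    if df.isna().any().any():
        gene = df.index[df.isna().any(axis=1)][0]
        raise ValueError(f"{path}: ragged/missing value at gene {gene!r}")
    try:
        values = df.astype(float)
    except ValueError:
        for col in df.columns:
            bad = pd.to_numeric(df[col], errors="coerce").isna()
            if bad.any():
                gene = df.index[bad][0]
                raise ValueError(
                    f"{path}: non-numeric cell at gene {gene!r}, sample {col!r}: "
                    f"{df.loc[gene, col]!r}"
                ) from None
        raise
    if values.index.duplicated().any():
        dupes = sorted(set(values.index[values.index.duplicated()]))
        warnings.warn(
            f"{path}: {len(dupes)} duplicated gene row(s) collapsed by mean: "
            f"{dupes[:5]}",
            stacklevel=2,
        )
        values = values.groupby(level=0, sort=False).mean()
    if values.columns.duplicated().any():
        raise ValueError(f"{path}: duplicate sample columns")
    values.index.name = "gene_id"
    return values


def read_sample_metadata(path) -> pd.DataFrame:
    """Read the metadata sidecar CSV, indexed by sample_id.

    Missing flag columns are added as all-false; flag cells accept
    true/false, 1/0, yes/no (case-insensitive).
    """
    meta = pd.read_csv(path, dtype=str)
    if "sample_id" not in meta.columns:
        raise ValueError(f"{path}: metadata must have a 'sample_id' column")
    meta = meta.set_index("sample_id")
    for col in _FLAG_COLUMNS:
        if col not in meta.columns:
            meta[col] = False
        else:
            meta[col] = (
                meta[col]
                .fillna("false")
                .str.strip()
                .str.lower()
                .map({"true": True, "1": True, "yes": True,
                      "false": False, "0": False, "no": False})
            )
            if meta[col].isna().any():
                raise ValueError(f"{path}: unparseable boolean in column {col!r}")
    return meta


@dataclass
class ExclusionLog:
    """Per-rule exclusion counts from eligibility filtering."""

    counts: dict = field(default_factory=dict)
    n_input: int = 0
    n_eligible: int = 0

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_eligible": self.n_eligible,
            "excluded": dict(self.counts),
        }


def filter_samples(meta: pd.DataFrame) -> tuple[pd.Index, ExclusionLog]:
    """Apply the eligibility rules: drop treated, contaminated and
    non-ovarian samples.

    A sample failing several rules is counted once under each rule it fails;
    the eligible set is rule-order independent.  Returns the eligible sample
    index and a per-rule exclusion log.
    """
    log = ExclusionLog(n_input=len(meta))
    excluded = pd.Series(False, index=meta.index)
    for rule in _FLAG_COLUMNS:
        flag = meta[rule].fillna(False).astype(bool) if rule in meta.columns else (
            pd.Series(False, index=meta.index)
        )
        log.counts[rule] = int(flag.sum())
        excluded |= flag
    eligible = meta.index[~excluded]
    log.n_eligible = len(eligible)
    if log.n_eligible == 0:
        warnings.warn("no samples remain after eligibility filtering", stacklevel=2)
    return eligible, log


def average_replicates(profile: STPProfile, meta: pd.DataFrame) -> STPProfile:
    """Average replicate STP profiles within each (entity, dataset) group.

    Aggregation acts on activity scores, not on expression: replicates of the
    same cell line within one dataset are replaced by their per-pathway mean.
    The same entity measured in different datasets keeps one row per dataset
    — that separation is what makes cross-laboratory comparison possible.
    The averaged row is named ``entity@dataset`` when groups collapse,
    otherwise the original sample id is kept.
    """
    meta = meta.loc[profile.sample_ids]
    key = list(zip(meta["entity_name"], meta["dataset_id"]))
    groups: dict[tuple, list[str]] = {}
    for sid, k in zip(profile.sample_ids, key):
        groups.setdefault(k, []).append(sid)

    rows_s, rows_l, idx, meta_rows = [], [], [], []
    for (entity, dataset), sids in groups.items():
        rows_s.append(profile.scores.loc[sids].mean(axis=0))
        rows_l.append(profile.log2odds.loc[sids].mean(axis=0))
        idx.append(sids[0] if len(sids) == 1 else f"{entity}@{dataset}")
        meta_rows.append(meta.loc[sids[0]])
    index = pd.Index(idx, name="sample_id")
    new_meta = pd.DataFrame(meta_rows)
    new_meta.index = index
    return STPProfile(
        scores=pd.DataFrame(rows_s, index=index),
        log2odds=pd.DataFrame(rows_l, index=index),
        metadata=new_meta,
    )


def select_pathways(
    profile: STPProfile, excluded: frozenset | set = DEFAULT_EXCLUDED_PATHWAYS
) -> STPProfile:
    """Drop excluded pathways from a profile.

    Unknown names in ``excluded`` warn; removing every pathway is an error.
    """
    unknown = set(excluded) - set(profile.pathways)
    if unknown:
        warnings.warn(
            f"excluded pathway(s) not present in profile: {sorted(unknown)}",
            stacklevel=2,
        )
    keep = [p for p in profile.pathways if p not in excluded]
    if not keep:
        raise ValueError("pathway exclusion leaves zero pathways")
    return STPProfile(
        scores=profile.scores[keep],
        log2odds=profile.log2odds[keep],
        metadata=profile.metadata,
    )
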