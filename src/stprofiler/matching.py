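"""Nearest-neighbor matching of tumor STP profiles to cell lines, match
composition summaries, and representative-cell-line ranking.

Each tumor sample is matched to the cell line minimizing the sum of squared
pathway-score differences over a configurable pathway subset.  Matched cell
lines are then summarized by the histology of the tumors they attracted,
expressed as integer percentages, and ranked as candidate laboratory models
per histology.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .stp_model import STPProfile

__all__ = [
    "DEFAULT_MATCHING_PATHWAYS",
    "TUMOR_HISTOLOGIES",
    "MatchTable",
    "match_nearest",
    "summarize_composition",
    "histology_coverage",
    "rank_representatives",
    "export_radar",
]

#: Pathway subset used for tumor/cell-line matching by default: the hormonal
#: (AR, ER) and developmental (HH, Notch, TGF-β) pathways.  NF-κB and Wnt are
#: left out of the default matching set (they remain in the clustering set).
DEFAULT_MATCHING_PATHWAYS = ("AR", "ER", "HH", "NOTCH", "TGFB")

#: Recognized tumor histology groups for composition summaries.
TUMOR_HISTOLOGIES = ("SBOT", "HGSOC", "LGOC")


def _round_half_up(x) -> np.ndarray:
    return np.floor(np.asarray(x, dtype=float) + 0.5).astype(int)


@dataclass
class MatchTable:
    """Per-tumor nearest cell line with the pathway subset used."""

    table: pd.DataFrame        # index tumor id; columns cell_line, sq_distance, tie
    pathways: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.table)

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out["pathways_used"] = "|".join(self.pathways)
        out.to_csv(path, index_label="tumor_sample")


def match_nearest(
    tumors: STPProfile,
    celllines: STPProfile,
    pathways: tuple[str, ...] = DEFAULT_MATCHING_PATHWAYS,
) -> MatchTable:
    """Match each tumor to its least-squares nearest cell line.

    ``match(t) = argmin_c sum_p (S_tp - S_cp)^2`` over the requested pathway
    subset.  Exact ties are broken by lexicographic cell-line id and
    flagged.  The result records the subset used, so narrowing it is always
    an explicit, visible choice.
    """
    pathways = tuple(pathways)
    if not pathways:
        raise ValueError("empty pathway subset")
    if not celllines.sample_ids:
        raise ValueError("empty cell-line profile")
    for name, prof in (("tumor", tumors), ("cell-line", celllines)):
        missing = set(pathways) - set(prof.pathways)
        if missing:
            raise ValueError(f"{name} profile lacks pathways: {sorted(missing)}")
    # lexicographic cell-line order makes argmin's first-minimum the tie rule
    order = sorted(celllines.sample_ids)
    C = celllines.scores.loc[order, list(pathways)].to_numpy(dtype=float)
    T = tumors.scores[list(pathways)].to_numpy(dtype=float)
    d2 = ((T[:, None, :] - C[None, :, :]) ** 2).sum(axis=2)
    best = d2.argmin(axis=1)
    tie = (d2 == d2.min(axis=1, keepdims=True)).sum(axis=1) > 1
    table = pd.DataFrame(
        {
            "cell_line": [order[i] for i in best],
            "sq_distance": d2[np.arange(len(T)), best],
            "tie": tie,
        },
        index=tumors.scores.index,
    )
    return MatchTable(table=table, pathways=pathways)


def summarize_composition(
    matches: MatchTable,
    histology: pd.Series,
    histologies: tuple[str, ...] = TUMOR_HISTOLOGIES,
) -> pd.DataFrame:
    """Histology composition of each matched cell line.

    Returns one row per cell line with >= 1 match: total matched samples,
    per-histology counts ``n_<h>`` and integer-rounded percentages
    ``pct_<h>`` (``round(100 * count / total)``).  Cell lines that attracted
    no tumors are omitted.  A matched tumor with a histology outside
    ``histologies`` is an error naming the sample.
    """
    histology = histology.reindex(matches.table.index)
    bad = histology.isna() | ~histology.isin(histologies)
    if bad.any():
        sample = matches.table.index[bad][0]
        raise ValueError(
            f"sample {sample!r}: histology {histology[sample]!r} not in "
            f"{histologies}"
        )
    rows = []
    for cl, grp in matches.table.groupby("cell_line", sort=True):
        counts = histology.loc[grp.index].value_counts()
        total = int(counts.sum())
        row = {"cell_line": cl, "total_matched": total}
        for h in histologies:
            n = int(counts.get(h, 0))
            row[f"n_{h}"] = n
            row[f"pct_{h}"] = int(_round_half_up(100.0 * n / total))
        rows.append(row)
    return pd.DataFrame(rows).set_index("cell_line")


def histology_coverage(
    matches: MatchTable,
    histology: pd.Series,
    cohort_sizes: dict[str, int],
    histologies: tuple[str, ...] = TUMOR_HISTOLOGIES,
) -> pd.DataFrame:
    """Share of each histology cohort captured by each cell line.

    ``share = round(100 * count_{c,h} / cohort_size_h)`` — e.g. a cell line
    matching 11 of 50 high-grade serous tumors covers 22% of that cohort.
    Cohort sizes are inputs (they may exceed the matched counts when some
    cohort members were not scored).
    """
    comp = summarize_composition(matches, histology, histologies)
    rows = []
    for h in histologies:
        size = cohort_sizes.get(h, 0)
        matched_total = int(comp[f"n_{h}"].sum())
        if size <= 0:
            if matched_total > 0:
                raise ValueError(f"zero cohort size for histology {h!r}")
            continue
        if matched_total > size:
            raise ValueError(
                f"histology {h!r}: matched count {matched_total} exceeds "
                f"cohort size {size}"
            )
        for cl in comp.index:
            n = int(comp.loc[cl, f"n_{h}"])
            rows.append(
                {
                    "cell_line": cl,
                    "histology": h,
                    "count": n,
                    "cohort_size": size,
                    "share_pct": int(_round_half_up(100.0 * n / size)),
                }
            )
    return pd.DataFrame(rows)


def rank_representatives(
    summary: pd.DataFrame,
    histology: str,
    rule: str = "majority-then-count",
) -> pd.DataFrame:
    """Rank matched cell lines as candidate models for one tumor histology.

    Default rule (``majority-then-count``): tier 1 holds cell lines whose
    matched samples are mostly (> 50%) of the target histology, ordered by
    that histology's matched count descending; tier 2 holds the remaining
    cell lines with >= 1 match of the histology, same ordering.  Ties break
    by total matches (descending) then lexicographic id, and are flagged.
    The rule identifier travels with the result because no single obvious
    statistic fully determines a recommendation order.
    """
    if rule != "majority-then-count":
        raise ValueError(f"unknown ranking rule {rule!r}")
    if summary.empty:
        warnings.warn("empty composition summary", stacklevel=2)
        return pd.DataFrame(
            columns=["cell_line", "rank", "tier", "n", "pct", "tie", "rule"]
        )
    ncol, pcol = f"n_{histology}", f"pct_{histology}"
    if ncol not in summary.columns:
        raise ValueError(f"summary lacks histology {histology!r}")
    cand = summary[summary[ncol] > 0]
    if cand.empty:
        warnings.warn(f"no cell line matched any {histology} sample", stacklevel=2)
        return pd.DataFrame(
            columns=["cell_line", "rank", "tier", "n", "pct", "tie", "rule"]
        )
    rows = []
    for cl, r in cand.iterrows():
        tier = 1 if r[pcol] > 50 else 2
        rows.append(
            {"cell_line": cl, "tier": tier, "n": int(r[ncol]),
             "pct": int(r[pcol]), "total": int(r["total_matched"])}
        )
    df = pd.DataFrame(rows)
    df = df.sort_values(
        by=["tier", "n", "total", "cell_line"],
        ascending=[True, False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    df["rank"] = range(1, len(df) + 1)
    key = list(zip(df["tier"], df["n"], df["total"]))
    df["tie"] = [key.count(k) > 1 for k in key]
    df["rule"] = rule
    return df[["cell_line", "rank", "tier", "n", "pct", "tie", "rule"]]


def export_radar(
    matches: MatchTable,
    tumors: STPProfile,
    celllines: STPProfile,
    out_dir,
    histology: pd.Series | None = None,
) -> list[Path]:
    """Write radar-map data: per matched cell line, one CSV holding the cell
    line's reference scores plus each matched tumor's scores over the
    matching pathway subset, tagged by role and histology.

    Returns the written paths (plus a small JSON index).  No matches → no
    files, with a warning.
    """
    out_dir = Path(out_dir)
    if len(matches) == 0:
        warnings.warn("no matches: no radar files written", stacklevel=2)
        return []
    out_dir.mkdir(parents=True, exist_ok=True)
    cols = list(matches.pathways)
    written: list[Path] = []
    index = {}
    for cl, grp in matches.table.groupby("cell_line", sort=True):
        rows = [{"sample": cl, "role": "cell_line", "histology": "",
                 **celllines.scores.loc[cl, cols].to_dict()}]
        for t in grp.index:
            h = "" if histology is None else str(histology.get(t, ""))
            rows.append({"sample": t, "role": "tumor", "histology": h,
                         **tumors.scores.loc[t, cols].to_dict()})
        safe = str(cl).replace("/", "_").replace(" ", "_")
        path = out_dir / f"radar_{safe}.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        written.append(path)
        index[str(cl)] = path.name
    index_path = out_dir / "radar_index.json"
    with open(index_path, "w") as fh:
        json.dump({"pathways": cols, "files": index}, fh, indent=1)
    written.append(index_path)
    return written
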