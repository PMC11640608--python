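"""Two-layer Bayesian network scoring of signal-transduction-pathway (STP) activity.

An STP model is a naive-Bayes network with one latent binary node T (the
pathway's terminal transcription factor: active / inactive) and one observed
binary node per direct target gene (up-expressed / not).  Observed log2
expression enters as soft evidence ``e`` — the probability that the gene is in
its up-expressed state — via a logistic transform around a per-gene threshold.
The posterior odds of activity factorize over genes, so each gene contributes
one likelihood ratio; the log2 posterior odds are mapped linearly onto a
0–100 score whose endpoints are anchored at reference fully-inactive and
fully-active profiles.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TargetGene",
    "CalibrationAnchors",
    "PathwayDefinition",
    "STPProfile",
    "DEFAULT_KAPPA",
    "discretize_expression",
    "gene_likelihood_ratio",
    "infer_pathway_log2odds",
    "extreme_anchors",
    "normalize_score",
    "score_cohort",
    "load_pathway_definitions",
    "save_pathway_definitions",
]

#: Scale of the conditional-probability-table entries: P(gene up | T) = 0.5 ± kappa * weight.
#: Bounds CPT probabilities away from 0 and 1 so likelihood ratios stay finite.
DEFAULT_KAPPA = 0.45


class PathwayValidationError(ValueError):
    """A pathway definition violates the schema or an invariant."""


@dataclass(frozen=True)
class TargetGene:
    """A direct transcriptional target of the pathway's transcription factor.

    Parameters
    ----------
    gene_id
        Gene identifier (must be unique within a pathway).
    direction
        ``"up"`` if the gene is induced when the pathway is active,
        ``"down"`` if it is repressed.
    weight
        Literature-evidence weight in (0, 1]; scales how informative the
        gene is about pathway state.
    """

    gene_id: str
    direction: str
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise PathwayValidationError(
                f"target {self.gene_id!r}: direction must be 'up' or 'down', "
                f"got {self.direction!r}"
            )
        if not (0.0 < self.weight <= 1.0):
            raise PathwayValidationError(
                f"target {self.gene_id!r}: weight must be in (0, 1], got {self.weight}"
            )


@dataclass(frozen=True)
class CalibrationAnchors:
    """Reference log2-odds mapped to the 0 and 100 ends of the score scale."""

    log2odds_inactive: float
    log2odds_active: float

    def __post_init__(self) -> None:
        if not (self.log2odds_active > self.log2odds_inactive):
            raise PathwayValidationError(
                "calibration anchors degenerate: log2odds_active "
                f"({self.log2odds_active}) must exceed log2odds_inactive "
                f"({self.log2odds_inactive})"
            )


@dataclass
class PathwayDefinition:
    """A named STP with its target genes and score calibration.

    ``calibration`` may be ``None``, in which case anchors are derived from
    the extreme evidence profiles (see :func:`extreme_anchors`) at scoring
    time.  Study-realistic definitions carry roughly 25–35 targets, but any
    non-empty target list is accepted.
    """

    name: str
    targets: list[TargetGene]
    prior_active: float = 0.5
    calibration: CalibrationAnchors | None = None

    def __post_init__(self) -> None:
        if not self.targets:
            raise PathwayValidationError(f"pathway {self.name!r}: needs >= 1 target gene")
        if not (0.0 < self.prior_active < 1.0):
            raise PathwayValidationError(
                f"pathway {self.name!r}: prior_active must be in (0, 1), "
                f"got {self.prior_active}"
            )
        ids = [t.gene_id for t in self.targets]
        if len(set(ids)) != len(ids):
            dupes = sorted({g for g in ids if ids.count(g) > 1})
            raise PathwayValidationError(
                f"pathway {self.name!r}: duplicate target gene ids {dupes}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return [t.gene_id for t in self.targets]

    @property
    def prior_log2odds(self) -> float:
        return math.log2(self.prior_active / (1.0 - self.prior_active))


@dataclass
class STPProfile:
    """Per-sample pathway activity scores on the normalized 0–100 scale.

    Attributes
    ----------
    scores
        DataFrame, rows = samples, columns = pathways, values in [0, 100].
    log2odds
        Companion raw log2-odds on the same index/columns.
    metadata
        Optional per-sample annotation (histology, dataset id, ...) indexed
        by sample id; carried through downstream operations untouched.
    """

    scores: pd.DataFrame
    log2odds: pd.DataFrame
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not self.scores.index.equals(self.log2odds.index) or not list(
            self.scores.columns
        ) == list(self.log2odds.columns):
            raise ValueError("scores and log2odds must share index and columns")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.index)

    @property
    def pathways(self) -> list[str]:
        return list(self.scores.columns)

    def to_csv(self, path) -> None:
        """Write scores plus ``<pathway>_log2odds`` companion columns."""
        out = self.scores.copy()
        for p in self.log2odds.columns:
            out[f"{p}_log2odds"] = self.log2odds[p]
        out.to_csv(path, index_label="sample_id")

    @classmethod
    def from_csv(cls, path, metadata: pd.DataFrame | None = None) -> "STPProfile":
        df = pd.read_csv(path, index_col="sample_id")
        lo_cols = [c for c in df.columns if c.endswith("_log2odds")]
        score_cols = [c for c in df.columns if c not in lo_cols]
        lo = df[lo_cols].rename(columns={c: c[: -len("_log2odds")] for c in lo_cols})
        return cls(scores=df[score_cols], log2odds=lo[score_cols], metadata=metadata)


# ---------------------------------------------------------------------------
# observation layer


def discretize_expression(
    matrix: pd.DataFrame,
    thresholds: pd.Series | str = "median",
    slope: float = 1.0,
) -> pd.DataFrame:
    """Soft-threshold log2 expression into per-gene up-state probabilities.

    ``e = logistic(slope * (x - t_g))`` where ``t_g`` is the per-gene
    threshold.  The default policy takes the cohort median of each gene,
    which is scale-robust across platforms; explicit per-gene thresholds may
    be supplied as a Series indexed by gene id.

    A zero-variance gene under the median policy has its threshold at the
    constant value, so its evidence is exactly 0.5 everywhere (uninformative).
    """
    if slope <= 0:
        raise ValueError(f"slope must be positive, got {slope}")
    if isinstance(thresholds, str):
        if thresholds != "median":
            raise ValueError(f"unknown threshold policy {thresholds!r}")
        t = matrix.median(axis=1)
    else:
        t = thresholds.reindex(matrix.index)
        if t.isna().any():
            missing = list(t.index[t.isna()])
            raise ValueError(f"no threshold supplied for genes: {missing[:10]}")
    z = slope * matrix.sub(t, axis=0)
    e = 1.0 / (1.0 + np.exp(-z))
    return e


# ---------------------------------------------------------------------------
# latent layer


def _cpt(target: TargetGene, kappa: float) -> tuple[float, float]:
    """(P(up | active), P(up | inactive)) for one target gene."""
    hi = 0.5 + kappa * target.weight
    lo = 0.5 - kappa * target.weight
    if target.direction == "up":
        return hi, lo
    return lo, hi


def gene_likelihood_ratio(e, target: TargetGene, kappa: float = DEFAULT_KAPPA):
    """Likelihood ratio P(evidence | active) / P(evidence | inactive) for one gene.

    Soft evidence ``e`` (probability the gene is up-expressed) is marginalized
    over the gene's binary state under each hypothesis.  Accepts scalars or
    arrays.
    """
    p_a, p_i = _cpt(target, kappa)
    e = np.asarray(e, dtype=float)
    return (e * p_a + (1.0 - e) * (1.0 - p_a)) / (e * p_i + (1.0 - e) * (1.0 - p_i))


def infer_pathway_log2odds(
    evidence: pd.DataFrame,
    definition: PathwayDefinition,
    kappa: float = DEFAULT_KAPPA,
) -> pd.Series:
    """Posterior log2-odds of pathway activity per sample.

    ``log2 odds = log2(prior odds) + sum_g log2 LR_g`` over the definition's
    target genes present in ``evidence`` (rows = genes, columns = samples).
    A target gene absent from the evidence contributes likelihood ratio 1
    (neutral) and is reported once via a warning.
    """
    if not (0.0 < kappa < 0.5):
        raise ValueError(f"kappa must be in (0, 0.5), got {kappa}")
    present = [t for t in definition.targets if t.gene_id in evidence.index]
    missing = [t.gene_id for t in definition.targets if t.gene_id not in evidence.index]
    if missing:
        warnings.warn(
            f"pathway {definition.name!r}: {len(missing)} target gene(s) absent "
            f"from the expression matrix (contribute LR=1): {missing[:5]}",
            stacklevel=2,
        )
    total = pd.Series(definition.prior_log2odds, index=evidence.columns, dtype=float)
    if not present:
        warnings.warn(
            f"pathway {definition.name!r}: no target gene measured; "
            "log2-odds equal the prior",
            stacklevel=2,
        )
        return total
    for t in present:
        lr = gene_likelihood_ratio(evidence.loc[t.gene_id].to_numpy(), t, kappa)
        total = total + np.log2(lr)
    return total


def extreme_anchors(
    definition: PathwayDefinition, kappa: float = DEFAULT_KAPPA
) -> CalibrationAnchors:
    """Calibration anchors from the extreme evidence profiles.

    The active anchor is the log2-odds when every target sits fully in its
    activity-consistent state (e = 1 for up-targets, e = 0 for down-targets);
    the inactive anchor is the mirror profile.  These are the minimum and
    maximum attainable log2-odds, so scores calibrated this way always fall
    in [0, 100] before clipping.
    """
    lo = definition.prior_log2odds
    hi = definition.prior_log2odds
    for t in definition.targets:
        e_active = 1.0 if t.direction == "up" else 0.0
        hi += math.log2(gene_likelihood_ratio(e_active, t, kappa))
        lo += math.log2(gene_likelihood_ratio(1.0 - e_active, t, kappa))
    return CalibrationAnchors(log2odds_inactive=lo, log2odds_active=hi)


def normalize_score(log2odds, calibration: CalibrationAnchors):
    """Map log2-odds linearly onto [0, 100] and clip.

    The inactive anchor maps to 0, the active anchor to 100; values outside
    the anchor range saturate.  Accepts scalars or arrays.
    """
    span = calibration.log2odds_active - calibration.log2odds_inactive
    # divide before scaling so the anchors map to exactly 0 and 100
    raw = 100.0 * (
        (np.asarray(log2odds, dtype=float) - calibration.log2odds_inactive) / span
    )
    clipped = np.clip(raw, 0.0, 100.0)
    if np.isscalar(log2odds) or np.ndim(log2odds) == 0:
        return float(clipped)
    return clipped


# ---------------------------------------------------------------------------
# cohort scoring


@dataclass(frozen=True)
class ScoringConfig:
    """Knobs of the observation layer and CPT parameterization."""

    slope: float = 1.0
    threshold_policy: str = "median"  # or per-gene thresholds via `thresholds`
    thresholds: pd.Series | None = field(default=None, compare=False)
    kappa: float = DEFAULT_KAPPA


def score_cohort(
    matrix: pd.DataFrame,
    definitions: list[PathwayDefinition],
    config: ScoringConfig | None = None,
    metadata: pd.DataFrame | None = None,
) -> STPProfile:
    """Score every sample on every pathway: discretize → infer → normalize.

    Deterministic given inputs and config.  Raises if no pathway has any
    target gene in the matrix.
    """
    if matrix.empty:
        raise ValueError("expression matrix is empty")
    if not definitions:
        raise ValueError("need at least one pathway definition")
    config = config or ScoringConfig()
    thr = config.thresholds if config.thresholds is not None else config.threshold_policy
    evidence = discretize_expression(matrix, thresholds=thr, slope=config.slope)

    covered = any(
        any(t.gene_id in matrix.index for t in d.targets) for d in definitions
    )
    if not covered:
        raise ValueError("no pathway has any target gene in the expression matrix")

    scores = {}
    log2odds = {}
    for d in definitions:
        L = infer_pathway_log2odds(evidence, d, kappa=config.kappa)
        cal = d.calibration or extreme_anchors(d, kappa=config.kappa)
        scores[d.name] = normalize_score(L.to_numpy(), cal)
        log2odds[d.name] = L.to_numpy()
    idx = pd.Index(matrix.columns, name="sample_id")
    return STPProfile(
        scores=pd.DataFrame(scores, index=idx),
        log2odds=pd.DataFrame(log2odds, index=idx),
        metadata=metadata,
    )


# ---------------------------------------------------------------------------
# pathway-definition JSON i/o
#
# Schema: {"pathways": [{name, prior_active, targets: [{gene_id, direction,
# weight}], calibration: {mode: "extremes"} | {mode: "explicit",
# log2odds_inactive, log2odds_active}}]}


def _definition_from_dict(obj: dict, where: str) -> PathwayDefinition:
    try:
        name = obj["name"]
        raw_targets = obj["targets"]
    except KeyError as exc:
        raise PathwayValidationError(f"{where}: missing field {exc}") from None
    targets = []
    for i, t in enumerate(raw_targets):
        try:
            targets.append(
                TargetGene(
                    gene_id=t["gene_id"],
                    direction=t["direction"],
                    weight=float(t.get("weight", 1.0)),
                )
            )
        except KeyError as exc:
            raise PathwayValidationError(
                f"{where} target #{i}: missing field {exc}"
            ) from None
    cal_obj = obj.get("calibration", {"mode": "extremes"})
    mode = cal_obj.get("mode", "extremes")
    if mode == "extremes":
        calibration = None
    elif mode == "explicit":
        try:
            calibration = CalibrationAnchors(
                log2odds_inactive=float(cal_obj["log2odds_inactive"]),
                log2odds_active=float(cal_obj["log2odds_active"]),
            )
        except KeyError as exc:
            raise PathwayValidationError(
                f"{where} calibration: explicit mode requires {exc}"
            ) from None
    else:
        raise PathwayValidationError(f"{where}: unknown calibration mode {mode!r}")
    return PathwayDefinition(
        name=name,
        targets=targets,
        prior_active=float(obj.get("prior_active", 0.5)),
        calibration=calibration,
    )


def load_pathway_definitions(path) -> list[PathwayDefinition]:
    """Read and validate pathway definitions from JSON.

    Rejects duplicate pathway names, weights outside (0, 1], unknown
    directions and degenerate calibrations with field-level messages.
    """
    with open(path) as fh:
        doc = json.load(fh)
    raw = doc["pathways"] if isinstance(doc, dict) else doc
    defs = [
        _definition_from_dict(obj, where=f"pathway #{i}") for i, obj in enumerate(raw)
    ]
    names = [d.name for d in defs]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise PathwayValidationError(f"duplicate pathway names: {dupes}")
    return defs


def save_pathway_definitions(definitions: list[PathwayDefinition], path) -> None:
    doc = {"pathways": []}
    for d in definitions:
        if d.calibration is None:
            cal = {"mode": "extremes"}
        else:
            cal = {
                "mode": "explicit",
                "log2odds_inactive": d.calibration.log2odds_inactive,
                "log2odds_active": d.calibration.log2odds_active,
            }
        doc["pathways"].append(
            {
                "name": d.name,
                "prior_active": d.prior_active,
                "targets": [
                    {"gene_id": t.gene_id, "direction": t.direction, "weight": t.weight}
                    for t in d.targets
                ],
                "calibration": cal,
            }
        )
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
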