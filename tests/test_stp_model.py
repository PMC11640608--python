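"""Unit and property tests for the two-layer Bayesian pathway scorer."""

import math
from itertools import product

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stprofiler import (
    CalibrationAnchors,
    PathwayDefinition,
    ScoringConfig,
    TargetGene,
    discretize_expression,
    extreme_anchors,
    infer_pathway_log2odds,
    load_pathway_definitions,
    normalize_score,
    save_pathway_definitions,
    score_cohort,
)
from stprofiler.stp_model import PathwayValidationError, gene_likelihood_ratio

KAPPA = 0.45


def enumeration_log2odds(e_values, definition, kappa=KAPPA):
    """Independent oracle: exhaustive joint enumeration of the two-layer
    network over all 2^n gene-state configurations."""
    joint = {True: 0.0, False: 0.0}
    n = len(definition.targets)
    for states in product([0, 1], repeat=n):
        for active in (True, False):
            p = definition.prior_active if active else 1 - definition.prior_active
            for t, s, e in zip(definition.targets, states, e_values):
                hi, lo = 0.5 + kappa * t.weight, 0.5 - kappa * t.weight
                if t.direction == "up":
                    p_up = hi if active else lo
                else:
                    p_up = lo if active else hi
                p *= (p_up if s else 1 - p_up) * (e if s else 1 - e)
            joint[active] += p
    return math.log2(joint[True] / joint[False])


def as_evidence(e_values, definition, samples=("s0",)):
    return pd.DataFrame(
        {s: list(e_values) for s in samples},
        index=[t.gene_id for t in definition.targets],
    )


# ---------------------------------------------------------------------------
# observation layer


class TestDiscretize:
    def test_logistic_midpoint_and_closed_form(self):
        # gene at its threshold -> 0.5; slope=1, x-t=2 -> 1/(1+exp(-2))
        m = pd.DataFrame({"a": [5.0, 7.0], "b": [5.0, 3.0]}, index=["g1", "g2"])
        e = discretize_expression(m, thresholds=pd.Series({"g1": 5.0, "g2": 5.0}))
        assert e.loc["g1", "a"] == 0.5
        assert e.loc["g2", "a"] == pytest.approx(1 / (1 + math.exp(-2)), abs=1e-12)
        assert e.loc["g2", "b"] == pytest.approx(1 / (1 + math.exp(2)), abs=1e-12)

    def test_limits_and_monotonicity(self):
        x = np.linspace(-30, 30, 61)  # beyond ~|37| the logistic saturates in float64
        m = pd.DataFrame({f"s{i}": [v] for i, v in enumerate(x)}, index=["g"])
        e = discretize_expression(m, thresholds=pd.Series({"g": 0.0}), slope=1.0)
        vals = e.loc["g"].to_numpy()
        assert np.all(np.diff(vals) > 0)
        assert vals[0] < 1e-9 and vals[-1] > 1 - 1e-9

    def test_median_policy_zero_variance_gene(self):
        m = pd.DataFrame({"a": [4.0], "b": [4.0], "c": [4.0]}, index=["g"])
        e = discretize_expression(m)  # threshold = the constant -> e = 0.5
        assert (e.loc["g"] == 0.5).all()

    def test_rejects_nonpositive_slope(self):
        m = pd.DataFrame({"a": [1.0]}, index=["g"])
        with pytest.raises(ValueError, match="slope"):
            discretize_expression(m, slope=0.0)


# ---------------------------------------------------------------------------
# latent layer


class TestInference:
    def test_neutral_evidence_gives_prior_odds(self, three_gene_pathway):
        ev = as_evidence([0.5, 0.5, 0.5], three_gene_pathway)
        L = infer_pathway_log2odds(ev, three_gene_pathway)
        assert L["s0"] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("e_values", [
        (0.9, 0.2, 0.7),
        (0.01, 0.99, 0.5),
        (1.0, 0.0, 1.0),
    ])
    def test_matches_enumeration_oracle(self, three_gene_pathway, e_values):
        ev = as_evidence(e_values, three_gene_pathway)
        L = infer_pathway_log2odds(ev, three_gene_pathway)
        expected = enumeration_log2odds(e_values, three_gene_pathway)
        assert L["s0"] == pytest.approx(expected, abs=1e-9)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.data())
    def test_oracle_equivalence_up_to_8_targets(self, data):
        """Factorized inference equals exhaustive joint enumeration."""
        n = data.draw(st.integers(1, 8))
        weights = data.draw(
            st.lists(st.floats(0.05, 1.0), min_size=n, max_size=n)
        )
        dirs = data.draw(
            st.lists(st.sampled_from(["up", "down"]), min_size=n, max_size=n)
        )
        e_values = data.draw(
            st.lists(st.floats(0.0, 1.0), min_size=n, max_size=n)
        )
        prior = data.draw(st.floats(0.05, 0.95))
        d = PathwayDefinition(
            name="H",
            targets=[TargetGene(f"g{i}", dirs[i], weights[i]) for i in range(n)],
            prior_active=prior,
        )
        L = infer_pathway_log2odds(as_evidence(e_values, d), d)
        assert L["s0"] == pytest.approx(
            enumeration_log2odds(e_values, d), abs=1e-9
        )

    def test_direction_flip_negates_log2odds(self, rng):
        targets = [
            TargetGene(f"g{i}", "up" if i % 2 else "down", w)
            for i, w in enumerate(rng.uniform(0.1, 1, 5))
        ]
        flipped = [
            TargetGene(t.gene_id, "down" if t.direction == "up" else "up", t.weight)
            for t in targets
        ]
        d1 = PathwayDefinition("A", targets)
        d2 = PathwayDefinition("A", flipped)
        e_values = rng.uniform(0, 1, 5)
        L1 = infer_pathway_log2odds(as_evidence(e_values, d1), d1)
        L2 = infer_pathway_log2odds(as_evidence(e_values, d2), d2)
        assert L1["s0"] == pytest.approx(-L2["s0"], abs=1e-9)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        e_lo=st.floats(0.0, 1.0), delta=st.floats(0.0, 1.0),
        weight=st.floats(0.05, 1.0),
        direction=st.sampled_from(["up", "down"]),
    )
    def test_monotone_in_evidence(self, e_lo, delta, weight, direction):
        """More up-evidence never decreases (up) / increases (down) the odds."""
        e_hi = min(e_lo + delta, 1.0)
        t = TargetGene("g", direction, weight)
        lr_lo, lr_hi = gene_likelihood_ratio(e_lo, t), gene_likelihood_ratio(e_hi, t)
        if direction == "up":
            assert lr_hi >= lr_lo - 1e-12
        else:
            assert lr_hi <= lr_lo + 1e-12

    def test_missing_gene_is_neutral(self, three_gene_pathway):
        full = as_evidence([0.9, 0.5, 0.3], three_gene_pathway)
        partial = full.drop(index="g2")  # e(g2)=0.5 has LR=1, so same result
        with pytest.warns(UserWarning, match="absent"):
            L_partial = infer_pathway_log2odds(partial, three_gene_pathway)
        L_full = infer_pathway_log2odds(full, three_gene_pathway)
        assert L_partial["s0"] == pytest.approx(L_full["s0"], abs=1e-12)

    def test_no_genes_measured_returns_prior(self, three_gene_pathway):
        ev = pd.DataFrame({"s0": [0.5]}, index=["unrelated_gene"])
        with pytest.warns(UserWarning, match="no target gene"):
            L = infer_pathway_log2odds(ev, three_gene_pathway)
        assert L["s0"] == pytest.approx(0.0)


# ---------------------------------------------------------------------------
# normalization


class TestNormalize:
    def test_anchor_endpoints_and_midpoint(self):
        cal = CalibrationAnchors(log2odds_inactive=-12.0, log2odds_active=20.0)
        assert normalize_score(-12.0, cal) == 0.0
        assert normalize_score(20.0, cal) == 100.0
        assert normalize_score(4.0, cal) == pytest.approx(50.0)

    def test_clipping_saturates_out_of_range_odds(self):
        cal = CalibrationAnchors(log2odds_inactive=0.0, log2odds_active=10.0)
        assert normalize_score(-5.0, cal) == 0.0
        assert normalize_score(15.0, cal) == 100.0

    def test_non_decreasing_in_log2odds(self):
        cal = CalibrationAnchors(log2odds_inactive=-3.0, log2odds_active=3.0)
        xs = np.linspace(-10, 10, 201)
        s = normalize_score(xs, cal)
        assert np.all(np.diff(s) >= 0)

    def test_degenerate_anchors_rejected(self):
        with pytest.raises(PathwayValidationError, match="degenerate"):
            CalibrationAnchors(log2odds_inactive=1.0, log2odds_active=1.0)

    def test_extreme_anchors_bound_all_profiles(self, three_gene_pathway, rng):
        """Any evidence profile lands inside the direction-aware extremes."""
        cal = extreme_anchors(three_gene_pathway)
        for _ in range(50):
            e = rng.uniform(0, 1, 3)
            L = infer_pathway_log2odds(
                as_evidence(e, three_gene_pathway), three_gene_pathway
            )["s0"]
            assert cal.log2odds_inactive - 1e-9 <= L <= cal.log2odds_active + 1e-9


# ---------------------------------------------------------------------------
# cohort scoring


class TestScoreCohort:
    def test_all_genes_at_threshold_scores_50(self, definitions, rng):
        genes = [t.gene_id for d in definitions for t in d.targets]
        base = pd.Series(rng.normal(8, 1, len(genes)), index=genes)
        m = pd.DataFrame({f"s{i}": base for i in range(4)})
        m["s_hi"] = base + 1.0  # break zero variance so medians = base
        m["s_lo"] = base - 1.0
        prof = score_cohort(m, definitions)
        # symmetric anchors at prior 0.5 put log2odds=0 at score 50
        for p in prof.pathways:
            assert prof.log2odds.loc["s0", p] == pytest.approx(0.0, abs=1e-9)
            assert prof.scores.loc["s0", p] == pytest.approx(50.0, abs=1e-9)

    def test_active_group_scores_above_inactive(self, definitions, rng):
        genes = [t.gene_id for d in definitions for t in d.targets]
        direction = {
            t.gene_id: (1 if t.direction == "up" else -1)
            for d in definitions for t in d.targets
        }
        base = pd.Series(rng.normal(8, 1, len(genes)), index=genes)
        sign = pd.Series([direction[g] for g in genes], index=genes)
        cols = {}
        for i in range(5):
            cols[f"act{i}"] = base + 2.0 * sign + rng.normal(0, 0.3, len(genes))
            cols[f"ina{i}"] = base - 2.0 * sign + rng.normal(0, 0.3, len(genes))
        prof = score_cohort(pd.DataFrame(cols), definitions)
        act = prof.scores.loc[[f"act{i}" for i in range(5)]].mean()
        ina = prof.scores.loc[[f"ina{i}" for i in range(5)]].mean()
        assert (act > ina).all()

    def test_single_sample_bounds(self, definitions, rng):
        genes = [t.gene_id for d in definitions for t in d.targets]
        m = pd.DataFrame({"only": rng.normal(8, 2, len(genes))}, index=genes)
        prof = score_cohort(m, definitions)
        assert prof.scores.shape == (1, 7)
        assert ((prof.scores >= 0) & (prof.scores <= 100)).all().all()

    def test_deterministic(self, definitions, rng):
        genes = [t.gene_id for d in definitions for t in d.targets]
        m = pd.DataFrame(
            rng.normal(8, 1, (len(genes), 6)),
            index=genes, columns=[f"s{i}" for i in range(6)],
        )
        p1 = score_cohort(m, definitions, config=ScoringConfig())
        p2 = score_cohort(m, definitions, config=ScoringConfig())
        assert p1.scores.equals(p2.scores) and p1.log2odds.equals(p2.log2odds)

    def test_no_covered_pathway_errors(self, definitions):
        m = pd.DataFrame({"s0": [1.0]}, index=["not_a_target"])
        with pytest.raises(ValueError, match="no pathway"):
            score_cohort(m, definitions)

    def test_empty_matrix_errors(self, definitions):
        with pytest.raises(ValueError, match="empty"):
            score_cohort(pd.DataFrame(), definitions)


# ---------------------------------------------------------------------------
# definition i/o


class TestDefinitionIO:
    def test_round_trip_preserves_fields(self, definitions, tmp_path):
        path = tmp_path / "defs.json"
        save_pathway_definitions(definitions, path)
        loaded = load_pathway_definitions(path)
        assert loaded == definitions

    def test_explicit_calibration_round_trip(self, tmp_path):
        d = PathwayDefinition(
            "X", [TargetGene("g", "up", 0.5)],
            calibration=CalibrationAnchors(-2.0, 3.0),
        )
        path = tmp_path / "d.json"
        save_pathway_definitions([d], path)
        assert load_pathway_definitions(path) == [d]

    @pytest.mark.parametrize("weight", [0.0, -0.5, 1.5])
    def test_invalid_weight_rejected(self, weight):
        with pytest.raises(PathwayValidationError, match="weight"):
            TargetGene("g", "up", weight)

    def test_thirty_targets_accepted(self):
        d = PathwayDefinition(
            "BIG", [TargetGene(f"g{i}", "up", 0.5) for i in range(30)]
        )
        assert len(d.targets) == 30

    def test_duplicate_pathway_names_rejected(self, tmp_path):
        d = PathwayDefinition("X", [TargetGene("g", "up", 0.5)])
        path = tmp_path / "dup.json"
        save_pathway_definitions([d, d], path)
        with pytest.raises(PathwayValidationError, match="duplicate pathway"):
            load_pathway_definitions(path)

    def test_duplicate_gene_ids_rejected(self):
        with pytest.raises(PathwayValidationError, match="duplicate target"):
            PathwayDefinition(
                "X", [TargetGene("g", "up", 0.5), TargetGene("g", "down", 0.5)]
            )

    def test_missing_calibration_field_reported(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text(
            '{"pathways": [{"name": "X", "targets": '
            '[{"gene_id": "g", "direction": "up", "weight": 0.5}], '
            '"calibration": {"mode": "explicit", "log2odds_active": 1.0}}]}'
        )
        with pytest.raises(PathwayValidationError, match="log2odds_inactive"):
            load_pathway_definitions(path)
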