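"""Reporter-metabolite scoring: transforms, neighborhoods, calibration."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from cobracore import fixtures as fx
from cobracore.core import Model, Reaction, UnknownIdError, add_reactions
from cobracore.topology import (
    metabolite_neighborhood,
    p_to_z,
    reporter_scores,
)


class TestPToZ:
    def test_median_maps_to_zero(self):
        assert p_to_z(0.5) == pytest.approx(0.0, abs=1e-12)

    def test_small_p_matches_normal_quantile(self):
        assert float(p_to_z(0.05)) == pytest.approx(stats.norm.ppf(0.95), abs=1e-9)
        assert float(p_to_z(0.001)) == pytest.approx(3.0902, abs=1e-3)

    def test_antisymmetry(self):
        for p in (0.01, 0.2, 0.4):
            assert float(p_to_z(p)) == pytest.approx(-float(p_to_z(1 - p)), abs=1e-9)

    def test_extreme_values_clamped_finite(self):
        assert np.isfinite(p_to_z(0.0))
        assert np.isfinite(p_to_z(1.0))


class TestNeighborhood:
    def test_diamond_branch_point(self, diamond):
        assert metabolite_neighborhood(diamond, "A") == {"g1", "g2"}
        assert metabolite_neighborhood(diamond, "D") == {"g3", "g4"}

    def test_spontaneous_only_metabolite_has_empty_neighborhood(self):
        model = Model()
        add_reactions(model, [Reaction("EX_X", {"X": 1.0}), Reaction("R", {"X": -1.0, "Y": 1.0})])
        assert metabolite_neighborhood(model, "X") == set()

    def test_equals_union_over_reactions(self):
        model = fx.random_model(9, 16, seed=8)
        for mid, met in model.metabolites.items():
            union = set()
            for rid in met.reaction_ids:
                union |= model.reactions[rid].gene_ids
            assert metabolite_neighborhood(model, mid) == union

    def test_unknown_metabolite_rejected(self, diamond):
        with pytest.raises(UnknownIdError):
            metabolite_neighborhood(diamond, "nope")


class TestReporterScores:
    def test_null_uniform_scores_near_zero(self, diamond):
        scores = {g: 0.5 for g in diamond.genes}
        with pytest.warns(UserWarning, match="degenerate"):
            result = reporter_scores(diamond, scores, n_background=1000, seed=0)
        for entry in result:
            assert entry.z_raw == pytest.approx(0.0, abs=1e-9)
            assert abs(entry.z_corrected) < 0.5

    def test_unscored_metabolites_reported_separately(self, diamond):
        result = reporter_scores(diamond, {"g1": 0.1}, n_background=100, seed=0)
        scored = {e.metabolite_id for e in result}
        # only metabolites touching a g1-reaction (R1: A->B) are scorable
        assert scored == {"A", "B"}
        assert set(result.unscored) == {"C", "D"}
        for entry in result:
            assert entry.k >= 1

    def test_fixed_seed_is_bit_reproducible(self):
        model = fx.random_model(15, 28, seed=2)
        scores = fx.random_scores(model, seed=3)
        a = reporter_scores(model, scores, n_background=200, seed=5)
        b = reporter_scores(model, scores, n_background=200, seed=5)
        assert [(e.metabolite_id, e.z_raw, e.z_corrected, e.p_corrected) for e in a] == [
            (e.metabolite_id, e.z_raw, e.z_corrected, e.p_corrected) for e in b
        ]

    def test_empty_table_rejected(self, diamond):
        with pytest.raises(ValueError, match="empty"):
            reporter_scores(diamond, {}, n_background=100, seed=0)
        with pytest.raises(ValueError, match="n_background"):
            reporter_scores(diamond, {"g1": 0.5}, n_background=10, seed=0)
        with pytest.raises(ValueError, match="no gene"):
            reporter_scores(diamond, {"zz": 0.5}, n_background=100, seed=0)

    def test_permutation_invariance_under_gene_relabeling(self):
        """Consistently renaming genes in model and table leaves every
        reporter statistic unchanged."""
        model = fx.random_model(10, 18, seed=12)
        scores = fx.random_scores(model, seed=1)
        result_a = reporter_scores(model, scores, n_background=300, seed=9)

        mapping = {g: f"locus_{i:03d}" for i, g in enumerate(model.genes)}
        relabeled = model.copy()
        for rxn in relabeled.reactions.values():
            text = rxn.gpr_text
            for old in sorted(mapping, key=len, reverse=True):
                text = text.replace(old, mapping[old])
            rxn.set_gpr(text)
        relabeled.genes = {
            mapping[g]: type(gene)(id=mapping[g], reaction_ids=set(gene.reaction_ids))
            for g, gene in relabeled.genes.items()
        }
        scores_b = {mapping[g]: p for g, p in scores.items()}
        result_b = reporter_scores(relabeled, scores_b, n_background=300, seed=9)
        assert [e.metabolite_id for e in result_a] == [e.metabolite_id for e in result_b]
        for ea, eb in zip(result_a, result_b):
            assert ea.k == eb.k
            # summation order over the renamed neighborhood may differ,
            # so allow last-ulp float noise
            assert ea.z_raw == pytest.approx(eb.z_raw, abs=1e-9)
            assert ea.z_corrected == pytest.approx(eb.z_corrected, abs=1e-9)

    def test_z_raw_monotone_in_single_gene_significance(self, diamond):
        """Making one neighborhood gene more significant never lowers the
        metabolite's raw aggregate."""
        base = {"g1": 0.4, "g2": 0.6, "g3": 0.5, "g4": 0.5}
        better = dict(base, g1=0.01)
        z_base = {e.metabolite_id: e.z_raw
                  for e in reporter_scores(diamond, base, n_background=100, seed=0)}
        z_better = {e.metabolite_id: e.z_raw
                    for e in reporter_scores(diamond, better, n_background=100, seed=0)}
        for mid in z_base:
            if "g1" in metabolite_neighborhood(diamond, mid):
                assert z_better[mid] >= z_base[mid]
            else:
                assert z_better[mid] == pytest.approx(z_base[mid], abs=1e-12)


class TestCalibrationAndPower:
    def test_null_calibration_on_uniform_scores(self):
        """With uniform p-values the corrected scores behave like a standard
        normal: mean within +/-0.1, sd within [0.8, 1.2] at
        n_background = 1000 over >= 50 metabolites.

        Scores on a fixed network are correlated across metabolites (shared
        genes), so the distribution is pooled over independent score
        replicates to estimate its mean and sd stably."""
        model = fx.random_model(120, 220, seed=7)
        z = []
        for rep in range(24):
            scores = fx.random_scores(model, seed=700 + rep)
            result = reporter_scores(model, scores, n_background=1000, seed=rep)
            z.extend(e.z_corrected for e in result)
        z = np.array(z)
        assert len({e for e in model.metabolites}) >= 50
        assert abs(z.mean()) <= 0.1
        assert 0.8 <= z.std() <= 1.2

    def test_planted_signal_ranks_first(self):
        """A metabolite whose whole neighborhood carries p = 0.001 tops the
        ranking in at least 19 of 20 seeded replicates."""
        hits = 0
        for seed in range(20):
            model = fx.random_model(25, 48, seed=100 + seed)
            planted = "M10"
            scores = fx.random_scores(model, planted_metabolite=planted, seed=seed)
            result = reporter_scores(model, scores, n_background=1000, seed=seed)
            if result.ranked_ids()[0] == planted:
                hits += 1
        assert hits >= 19
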