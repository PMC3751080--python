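"""FBA, media, FVA and gene-deletion screens against independent oracles."""

from __future__ import annotations

import copy

import numpy as np
import pytest

from cobracore import fixtures as fx
from cobracore.core import UnknownIdError, copy_model
from cobracore.flux_analysis import (
    apply_medium,
    double_gene_deletion,
    essentiality,
    flux_variability,
    optimize,
    parallel_map,
    single_gene_deletion,
    synthetic_lethal_pairs,
)
from cobracore.solvers import build_lp, get_config, solve

from conftest import deletion_oracle, fva_oracle

TOL = get_config()["tolerance"]


def snapshot_bounds(model):
    return {rid: (r.lower_bound, r.upper_bound) for rid, r in model.reactions.items()}


def _chain_with_gprs(gprs: list[str]):
    """Linear source->...->sink model with one internal step per GPR."""
    from cobracore.core import Model, Reaction, add_reactions

    n = len(gprs)
    model = Model(id="custom_chain")
    mets = [f"M{i}" for i in range(n + 1)]
    reactions = [Reaction("EX_src", {mets[0]: 1.0}, upper_bound=10.0)]
    for i, gpr in enumerate(gprs):
        reactions.append(Reaction(f"R{i + 1}", {mets[i]: -1.0, mets[i + 1]: 1.0}, gpr_text=gpr))
    reactions.append(Reaction("EX_sink", {mets[-1]: -1.0}, objective_coefficient=1.0))
    add_reactions(model, reactions)
    return model


def _flaky_square(x):
    if x == 2:
        raise RuntimeError("boom")
    return x * x


class TestOptimize:
    def test_diamond_optimum(self, diamond):
        sol = optimize(diamond)
        assert sol.status == "optimal"
        assert sol.objective_value == pytest.approx(10.0, abs=TOL)

    def test_closed_source_zero(self):
        chain = fx.make_chain(2)
        chain.reactions["EX_src"].upper_bound = 0.0
        assert optimize(chain).objective_value == pytest.approx(0.0, abs=TOL)

    def test_equals_lp_interface_path(self, diamond):
        direct = solve(build_lp(diamond))
        wrapped = optimize(diamond)
        assert wrapped.status == direct.status
        assert wrapped.objective_value == direct.objective_value

    def test_all_zero_objective_advises(self, diamond):
        for rxn in diamond.reactions.values():
            rxn.objective_coefficient = 0.0
        with pytest.raises(ValueError, match="objective"):
            optimize(diamond)


class TestApplyMedium:
    def test_uptake_medium_supports_growth(self, diamond_exchange):
        fed = apply_medium(diamond_exchange, {"EX_A": (-10.0, 1000.0)})
        assert optimize(fed).objective_value == pytest.approx(10.0, abs=TOL)

    def test_stored_model_medium(self, diamond_exchange):
        fed = apply_medium(diamond_exchange, diamond_exchange.media["minimal"])
        assert optimize(fed).objective_value == pytest.approx(10.0, abs=TOL)

    def test_empty_medium_closes_all_uptakes(self, diamond_exchange):
        starved = apply_medium(diamond_exchange, {})
        assert optimize(starved).objective_value == pytest.approx(0.0, abs=TOL)

    def test_internal_reaction_in_medium_rejected(self, diamond_exchange):
        with pytest.raises(ValueError, match="R1"):
            apply_medium(diamond_exchange, {"R1": (-5.0, 5.0)})
        with pytest.raises(UnknownIdError, match="EX_missing"):
            apply_medium(diamond_exchange, {"EX_missing": (-5.0, 5.0)})

    def test_input_model_not_modified(self, diamond_exchange):
        before = snapshot_bounds(diamond_exchange)
        apply_medium(diamond_exchange, {})
        assert snapshot_bounds(diamond_exchange) == before


class TestFva:
    def test_diamond_branches_trade_off(self, diamond):
        result = flux_variability(diamond, fraction_of_optimum=1.0)
        assert result["R1"] == pytest.approx((0.0, 10.0), abs=TOL)
        assert result["R2"] == pytest.approx((0.0, 10.0), abs=TOL)

    def test_objective_reaction_pinned_at_fraction_one(self, diamond):
        result = flux_variability(diamond, fraction_of_optimum=1.0)
        assert result["EX_D"] == pytest.approx((10.0, 10.0), abs=TOL)

    def test_single_path_chain_fully_pinned(self, chain5):
        result = flux_variability(chain5, fraction_of_optimum=1.0)
        for rid in chain5.reactions:
            assert result[rid] == pytest.approx((10.0, 10.0), abs=TOL)

    def test_fraction_validation(self, diamond):
        for bad in (0.0, -0.5, 1.5):
            with pytest.raises(ValueError, match="fraction"):
                flux_variability(diamond, fraction_of_optimum=bad)

    def test_min_le_max_everywhere(self):
        model = fx.random_model(8, 15, seed=9)
        result = flux_variability(model, fraction_of_optimum=0.9)
        for lo, hi in result.ranges.values():
            assert lo <= hi + TOL

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle(self, seed):
        model = fx.random_model(7, 12, seed=seed)
        for fraction in (1.0, 0.9):
            mine = flux_variability(model, fraction_of_optimum=fraction)
            oracle = fva_oracle(model, fraction)
            for rid in model.reactions:
                assert mine[rid] == pytest.approx(oracle[rid], abs=TOL)

    def test_envelope_widens_as_fraction_drops(self, diamond):
        tight = flux_variability(diamond, fraction_of_optimum=1.0)
        loose = flux_variability(diamond, fraction_of_optimum=0.5)
        for rid in diamond.reactions:
            assert loose[rid][0] <= tight[rid][0] + TOL
            assert loose[rid][1] >= tight[rid][1] - TOL

    def test_fba_optimum_lies_inside_intervals(self, diamond):
        sol = optimize(diamond)
        result = flux_variability(diamond, fraction_of_optimum=1.0)
        for rid, flux in sol.fluxes.items():
            lo, hi = result[rid]
            assert lo - TOL <= flux <= hi + TOL

    def test_reaction_subset_and_unknown_id(self, diamond):
        result = flux_variability(diamond, reactions=["R1", "EX_D"])
        assert set(result.ranges) == {"R1", "EX_D"}
        with pytest.raises(UnknownIdError):
            flux_variability(diamond, reactions=["nope"])

    def test_model_bounds_restored(self, diamond):
        before = snapshot_bounds(diamond)
        flux_variability(diamond, fraction_of_optimum=0.9)
        assert snapshot_bounds(diamond) == before


class TestSingleDeletion:
    def test_chain_gene_is_essential(self):
        chain = fx.make_chain(1)
        result = single_gene_deletion(chain)
        assert result.baseline == pytest.approx(10.0, abs=TOL)
        assert result.objective("g1") == pytest.approx(0.0, abs=TOL)

    def test_parallel_path_reroutes(self, diamond):
        result = single_gene_deletion(diamond)
        for gene in ("g1", "g2", "g3", "g4"):
            assert result.objective(gene) == pytest.approx(10.0, abs=TOL)

    def test_isozyme_deletion_harmless(self):
        chain = _chain_with_gprs(["g1 or g2"])
        result = single_gene_deletion(chain)
        assert result.objective("g1") == pytest.approx(10.0, abs=TOL)

    def test_unknown_gene_rejected(self, diamond):
        with pytest.raises(UnknownIdError, match="ghost"):
            single_gene_deletion(diamond, genes=["ghost"])

    def test_no_deletion_exceeds_baseline(self):
        model = fx.random_model(8, 16, seed=21)
        result = single_gene_deletion(model)
        for status, value in result.results.values():
            if status == "optimal":
                assert value <= result.baseline + TOL

    def test_model_bounds_restored(self, diamond):
        before = snapshot_bounds(diamond)
        single_gene_deletion(diamond)
        assert snapshot_bounds(diamond) == before


class TestDoubleDeletion:
    def test_branch_pairs_are_synthetic_lethal(self, diamond):
        single = single_gene_deletion(diamond)
        double = double_gene_deletion(diamond)
        assert double.objective(("g1", "g2")) == pytest.approx(0.0, abs=TOL)
        assert double.objective(("g3", "g4")) == pytest.approx(0.0, abs=TOL)
        lethal = synthetic_lethal_pairs(double, single)
        assert {("g1", "g2"), ("g3", "g4")}.issubset(lethal)

    def test_diagonal_equals_single(self, diamond):
        single = single_gene_deletion(diamond)
        double = double_gene_deletion(diamond)
        for g in diamond.genes:
            assert double.results[(g, g)] == single.results[g]

    def test_pair_bounded_by_member_singles(self):
        model = fx.random_model(8, 16, seed=13)
        single = single_gene_deletion(model)
        double = double_gene_deletion(model)
        for (g, h), (status, value) in double.results.items():
            if g == h or status != "optimal":
                continue
            for member in (g, h):
                m_status, m_value = single.results[member]
                if m_status == "optimal":
                    assert value <= m_value + TOL

    @pytest.mark.parametrize("seed", [0, 5])
    def test_grid_matches_exhaustive_oracle(self, seed):
        model = fx.random_model(6, 12, seed=seed)
        double = double_gene_deletion(model)
        for (g, h), (status, value) in double.results.items():
            o_status, o_value = deletion_oracle(model, {g, h})
            assert status == o_status
            if status == "optimal":
                assert value == pytest.approx(o_value, abs=TOL)


def test_deletion_monotonicity_on_random_models():
    """For D1 subset of D2, the optimum under D2 never exceeds D1's."""
    rng = np.random.default_rng(2)
    for seed in range(5):
        model = fx.random_model(7, 14, seed=seed)
        genes = list(model.genes)
        for _ in range(6):
            size2 = int(rng.integers(1, min(4, len(genes)) + 1))
            d2 = set(rng.choice(genes, size=size2, replace=False))
            d1 = set(list(d2)[: int(rng.integers(0, size2))])
            s1, v1 = deletion_oracle(model, d1)
            s2, v2 = deletion_oracle(model, d2)
            if s1 == "optimal" and s2 == "optimal":
                assert v2 <= v1 + TOL


class TestEssentiality:
    def test_chain_gene_essential_isozyme_not(self):
        chain = _chain_with_gprs(["g1", "ga or gb"])
        result = single_gene_deletion(chain)
        classes = essentiality(result)
        assert classes["g1"] is True
        assert classes["ga"] is False and classes["gb"] is False

    def test_zero_baseline_rejected(self, diamond):
        result = single_gene_deletion(diamond)
        with pytest.raises(ValueError, match="baseline"):
            essentiality(result, baseline=0.0)


class TestParallelMap:
    def test_identical_across_worker_counts(self, diamond):
        grids = [double_gene_deletion(diamond, n_workers=n).results for n in (1, 2, 4)]
        assert grids[0] == grids[1] == grids[2]

    def test_fva_split_equals_sequential(self):
        model = fx.random_model(10, 20, seed=6)
        seq = flux_variability(model, n_workers=1)
        par = flux_variability(model, n_workers=3)
        assert seq.ranges == par.ranges

    def test_worker_failure_recorded_without_poisoning(self):
        outcomes = parallel_map(_flaky_square, [0, 1, 2, 3], n_workers=2)
        assert [o.value for o in outcomes if o.ok] == [0, 1, 9]
        assert "boom" in outcomes[2].error

    def test_invalid_worker_count(self):
        with pytest.raises(ValueError):
            parallel_map(len, [[1]], n_workers=0)
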