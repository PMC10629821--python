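"""Unit and property tests for the centrosome-inheritance lineage simulator."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import binom

import centrotrace as ct
from centrotrace.errors import ParameterError, StateError
from centrotrace.lineage import simulate_cohort_arrays


def make_founder(recombined=True, L0=1.0, unit=0, lineage=0):
    return ct.CellRecord(
        unit_id=unit,
        lineage_id=lineage,
        compartment=ct.Compartment.VZ,
        pool=ct.CentriolinPool(L0, 0.0),
        centrosome_birth_div=0,
        recombined=recombined,
        fate_marker=ct.Fate.SOX2,
    )


class TestTurnover:
    @pytest.mark.parametrize(
        "tau,recombined,pool,expected",
        [
            (0.0, True, (1.0, 0.0), (1.0, 0.0)),
            (1.0, True, (1.0, 0.0), (0.0, 1.0)),
            (0.05, True, (1.0, 0.0), (0.95, 0.05)),
            (0.5, False, (1.0, 0.0), (1.0, 0.0)),  # replacement is same colour
        ],
    )
    def test_examples(self, tau, recombined, pool, expected):
        out = ct.turnover_step(ct.CentriolinPool(*pool), tau, recombined, 1.0)
        assert out.T == pytest.approx(expected[0], abs=1e-12)
        assert out.N == pytest.approx(expected[1], abs=1e-12)

    def test_invalid_tau(self):
        with pytest.raises(ParameterError):
            ct.turnover_step(ct.CentriolinPool(1, 0), 1.5, True, 1.0)

    @given(
        tau=st.floats(0, 1),
        recombined=st.booleans(),
        steps=st.integers(0, 20),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_load_conservation_and_colour(self, tau, recombined, steps):
        """Total load stays at L0; unrecombined pools never gain NeonGreen;
        the green ratio is non-decreasing under recombined turnover."""
        pool = ct.CentriolinPool(1.0, 0.0)
        prev_ratio = 0.0
        for _ in range(steps):
            pool = ct.turnover_step(pool, tau, recombined, 1.0)
            assert pool.total == pytest.approx(1.0, abs=1e-9)
            if recombined:
                ratio = pool.N / pool.total
                assert ratio >= prev_ratio - 1e-12
                prev_ratio = ratio
            else:
                assert pool.N == 0.0

    def test_pure_green_stays_pure(self):
        """A centrosome born after recombination keeps ratio exactly 1."""
        pool = ct.CentriolinPool(0.0, 1.0)
        for _ in range(10):
            pool = ct.turnover_step(pool, 0.05, True, 1.0)
            assert pool.T == 0.0
            assert pool.N / pool.total == 1.0


class TestDuplicate:
    def test_recombined_definition(self):
        old, new = ct.duplicate_centrosome(ct.CentriolinPool(0.9, 0.1), True, 1.0, 3, 1)
        assert (old[0].T, old[0].N, old[1]) == (0.9, 0.1, 1)
        assert (new[0].T, new[0].N, new[1]) == (0.0, 1.0, 3)

    def test_unrecombined_indistinguishable(self):
        old, new = ct.duplicate_centrosome(ct.CentriolinPool(1, 0), False, 1.0, 2, 0)
        assert (new[0].T, new[0].N) == (1.0, 0.0)
        assert (old[0].T, old[0].N) == (new[0].T, new[0].N)

    def test_old_branch_conserved_without_turnover(self):
        pool, birth = ct.CentriolinPool(1, 0), 0
        for d in range(1, 6):
            (pool, birth), _ = ct.duplicate_centrosome(pool, True, 1.0, d, birth)
        assert (pool.T, pool.N, birth) == (1.0, 0.0, 0)


class TestDivide:
    @pytest.mark.parametrize("p_asym,vz_keeps_old", [(1.0, True), (0.0, False)])
    def test_deterministic_branches(self, p_asym, vz_keeps_old):
        cfg = ct.SimConfig(p_asym=p_asym, tau=0.0)
        rng = np.random.default_rng(0)
        for _ in range(20):
            vz, prog = ct.divide(make_founder(), cfg, rng, 1)
            if vz_keeps_old:
                assert vz.centrosome_birth_div < prog.centrosome_birth_div
            else:
                assert vz.centrosome_birth_div > prog.centrosome_birth_div

    def test_progeny_cell_refused(self):
        cfg = ct.SimConfig()
        prog = ct.divide(make_founder(), cfg, np.random.default_rng(0), 1)[1]
        with pytest.raises(StateError):
            ct.divide(prog, cfg, np.random.default_rng(0), 2)

    def test_random_inheritance_monte_carlo(self):
        """At p_asym = 0.5 the old-to-VZ fraction falls in the central 99%
        binomial interval."""
        cfg = ct.SimConfig(p_asym=0.5)
        rng = np.random.default_rng(42)
        n = 10_000
        old_to_vz = sum(
            ct.divide(make_founder(), cfg, rng, 1)[0].centrosome_birth_div == 0
            for _ in range(n)
        )
        lo, hi = binom.ppf([0.005, 0.995], n, 0.5)
        assert lo <= old_to_vz <= hi


class TestInitCohort:
    def test_empty(self):
        assert ct.init_cohort(ct.SimConfig(n_lineages_per_unit=0)) == []

    @pytest.mark.parametrize("f_rec,expected", [(1.0, True), (0.0, False)])
    def test_degenerate_probability(self, f_rec, expected):
        founders = ct.init_cohort(ct.SimConfig(f_rec=f_rec, n_units=2, n_lineages_per_unit=5))
        assert all(f.recombined is expected for f in founders)

    def test_recombined_count_within_binomial_interval(self):
        founders = ct.init_cohort(
            ct.SimConfig(f_rec=0.5, n_units=100, n_lineages_per_unit=10, seed=11)
        )
        k = sum(f.recombined for f in founders)
        lo, hi = binom.ppf([0.005, 0.995], 1000, 0.5)
        assert (lo, hi) == (459, 541)  # central 99% interval of Binom(1000, 0.5)
        assert lo <= k <= hi

    def test_invalid_config(self):
        with pytest.raises(ParameterError):
            ct.SimConfig(p_asym=1.2)
        with pytest.raises(ParameterError):
            ct.SimConfig(n_div=-1)


class TestSimulateLineage:
    def test_no_divisions(self):
        f = make_founder()
        out = ct.simulate_lineage(f, ct.SimConfig(n_div=0), np.random.default_rng(0))
        assert out == [f]

    def test_strict_asymmetry_pools(self):
        cfg = ct.SimConfig(p_asym=1.0, tau=0.0, n_div=3)
        out = ct.simulate_lineage(make_founder(), cfg, np.random.default_rng(0))
        vz, progeny = out[0], out[1:]
        assert (vz.pool.T, vz.pool.N) == (1.0, 0.0)
        assert all((p.pool.T, p.pool.N) == (0.0, 1.0) for p in progeny)

    def test_original_centrosome_exported_first(self):
        cfg = ct.SimConfig(p_asym=0.0, tau=0.0, n_div=2)
        out = ct.simulate_lineage(make_founder(), cfg, np.random.default_rng(0))
        first_prog = [c for c in out if c.division_of_exit == 1][0]
        assert (first_prog.pool.T, first_prog.pool.N) == (1.0, 0.0)
        assert (out[0].pool.T, out[0].pool.N) == (0.0, 1.0)

    @pytest.mark.parametrize("p_asym", [0.0, 1.0])
    def test_hand_enumerated_snapshot(self, p_asym):
        """Full snapshot equals the hand-enumerated table for n_div = 3.

        With tau = 0.1 and L0 = 1, turnover multiplies the founder's T by 0.9
        before each duplication.  p_asym = 1: the founder centrosome stays in
        the VZ (T = 0.9^3) and each exported centrosome is newborn (0, 1).
        p_asym = 0: the resident is exported right after turnover, so the
        first progeny carries (0.9, 0.1) with birth 0, later progeny carry
        the previous division's newborn after one further turnover (0, 1).
        """
        cfg = ct.SimConfig(p_asym=p_asym, tau=0.1, n_div=3)
        out = ct.simulate_lineage(make_founder(), cfg, np.random.default_rng(0))
        by_exit = {c.division_of_exit: c for c in out[1:]}
        vz = out[0]
        if p_asym == 1.0:
            assert vz.pool.T == pytest.approx(0.9**3)
            assert vz.centrosome_birth_div == 0
            for d in (1, 2, 3):
                assert by_exit[d].pool.T == 0.0
                assert by_exit[d].pool.N == pytest.approx(1.0)
                assert by_exit[d].centrosome_birth_div == d
        else:
            assert by_exit[1].pool.T == pytest.approx(0.9)
            assert by_exit[1].pool.N == pytest.approx(0.1)
            assert by_exit[1].centrosome_birth_div == 0
            for d in (2, 3):
                assert by_exit[d].pool.T == 0.0
                assert by_exit[d].centrosome_birth_div == d - 1
            assert vz.centrosome_birth_div == 3

    def test_compartment_structure(self):
        cfg = ct.SimConfig(n_div=5, seed=2)
        out = ct.simulate_lineage(make_founder(), cfg, np.random.default_rng(2))
        assert sum(c.compartment is ct.Compartment.VZ for c in out) == 1
        assert sum(c.compartment is ct.Compartment.PROGENY for c in out) == 5
        assert out[0].fate_marker is ct.Fate.SOX2
        assert all(c.fate_marker is ct.Fate.CTIP2 for c in out[1:])


class TestSimulateCohort:
    def test_row_count(self):
        cfg = ct.SimConfig(n_units=2, n_lineages_per_unit=3, n_div=4)
        assert len(ct.simulate_cohort(cfg)) == 30

    def test_determinism(self):
        cfg = ct.SimConfig(n_units=2, n_lineages_per_unit=4, n_div=3, seed=9)
        a = ct.simulate_cohort(cfg).to_csv(index=False)
        b = ct.simulate_cohort(cfg).to_csv(index=False)
        assert a == b

    def test_vz_pools_greener_than_founder_retention_rate(self):
        """Fraction of lineages whose VZ cell keeps the founder centrosome
        matches p_asym^n_div in expectation."""
        p, n_div = 0.8, 4
        cfg = ct.SimConfig(
            p_asym=p, n_div=n_div, f_rec=1.0, n_units=1, n_lineages_per_unit=2000, seed=5
        )
        coh = ct.simulate_cohort(cfg)
        vz = coh[coh["compartment"] == "VZ"]
        kept = int((vz["centrosome_birth_div"] == 0).sum())
        lo, hi = binom.ppf([0.005, 0.995], len(vz), p**n_div)
        assert lo <= kept <= hi

    def test_vz_less_green_than_progeny(self):
        """Asymmetric inheritance leaves VZ pools redder than progeny pools."""
        cfg = ct.SimConfig(
            p_asym=0.9, tau=0.05, n_div=6, f_rec=1.0, n_units=1,
            n_lineages_per_unit=200, seed=3,
        )
        coh = ct.simulate_cohort(cfg)
        ratio = coh["N"] / (coh["T"] + coh["N"])
        vz = coh["compartment"] == "VZ"
        assert ratio[vz].mean() < ratio[~vz].mean()

    @pytest.mark.parametrize("p_asym", [0.0, 1.0])
    def test_vectorised_path_matches_records(self, p_asym):
        """The array-based snapshot equals the record-level path wherever the
        model is deterministic (pool contents and compartment multisets)."""
        cfg = ct.SimConfig(
            p_asym=p_asym, tau=0.1, n_div=3, f_rec=1.0, n_units=2, n_lineages_per_unit=3
        )
        rec_path = ct.simulate_cohort(cfg)
        arr = simulate_cohort_arrays(cfg, np.random.default_rng(0))
        a = sorted(zip(rec_path["T"].round(12), rec_path["N"].round(12),
                       rec_path["compartment"] == "VZ"))
        b = sorted(zip(np.round(arr["T"], 12), np.round(arr["N"], 12), arr["is_vz"]))
        assert a == b

    def test_fate_coupling_reduces_vz_rows(self):
        base = ct.SimConfig(p_asym=0.5, n_div=6, f_rec=1.0, n_units=1,
                            n_lineages_per_unit=300, seed=8)
        coupled = ct.SimConfig(p_asym=0.5, n_div=6, f_rec=1.0, n_units=1,
                               n_lineages_per_unit=300, q_diff=0.5, seed=8)
        n_vz_base = (ct.simulate_cohort(base)["compartment"] == "VZ").sum()
        n_vz_coupled = (ct.simulate_cohort(coupled)["compartment"] == "VZ").sum()
        assert n_vz_coupled < n_vz_base
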