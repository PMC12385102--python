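import numpy as np
import pytest

from mrpath.errors import CollinearityError, InsufficientInstrumentsError
from mrpath.estimators import ivw
from mrpath.instruments import ld_clump
from mrpath.mvmr import MvDataset, assemble_mv_dataset, mvmr_egger, mvmr_ivw
from mrpath.simulate import simulate_ld_blocks, simulate_mv_exposures
from mrpath.summary_stats import GwasTable

from conftest import make_dataset, make_gwas_table


def make_mv(G, by, se_y, ids=None, se_x=0.01):
    k, m = G.shape
    return MvDataset(
        ids or [f"e{i + 1}" for i in range(m)],
        "out",
        [f"rs{j + 1}" for j in range(k)],
        np.asarray(G, float),
        np.full((k, m), se_x),
        np.asarray(by, float),
        np.asarray(se_y, float),
    )


class TestAssemble:
    def _tables(self, ld, specs):
        """specs: list of (trait, ids, pvals); betas chosen to match pvals."""
        tables = []
        for trait, ids, pv in specs:
            pos = [ld.positions[ld.index_of(v)] for v in ids]
            tables.append(
                make_gwas_table(trait, ids, [0.2] * len(ids), [0.01] * len(ids),
                                pvalue=pv, positions=pos)
            )
        return tables

    def test_disjoint_instruments_union(self):
        ld = simulate_ld_blocks(7, 1, 0.0, positions_spacing_kb=20_000)
        ids = ld.variant_ids
        exp1, exp2 = self._tables(
            ld,
            [("e1", ids, [1e-10] * 3 + [0.5] * 4), ("e2", ids, [0.5] * 3 + [1e-10] * 4)],
        )
        out = make_gwas_table("out", ids, [0.02] * 7, [0.01] * 7,
                              positions=ld.positions)
        data = assemble_mv_dataset([exp1, exp2], out, ld)
        assert data.k == 7
        assert sorted(data.variant_ids) == sorted(ids)

    def test_shared_instruments_clumped_once(self):
        ld = simulate_ld_blocks(4, 2, 0.9, positions_spacing_kb=100)
        ids = ld.variant_ids
        pv = [1e-10, 1e-9, 1e-11, 1e-9, 1e-12, 1e-9, 1e-13, 1e-9]
        exp1, exp2 = self._tables(ld, [("e1", ids, pv), ("e2", ids, pv)])
        out = make_gwas_table("out", ids, [0.02] * 8, [0.01] * 8, positions=ld.positions)
        data = assemble_mv_dataset([exp1, exp2], out, ld)
        assert data.k == 4  # one per block

    def test_matches_union_then_clump_oracle(self, rng):
        ld = simulate_ld_blocks(5, 4, 0.8, positions_spacing_kb=500)
        ids = ld.variant_ids
        pv1 = rng.uniform(1e-12, 1e-6, 20)
        pv2 = rng.uniform(1e-12, 1e-6, 20)
        exp1, exp2 = self._tables(ld, [("e1", ids, pv1), ("e2", ids, pv2)])
        out = make_gwas_table("out", ids, [0.02] * 20, [0.01] * 20, positions=ld.positions)
        data = assemble_mv_dataset([exp1, exp2], out, ld, p_threshold=1e-6)

        # oracle: explicit union of significant sets, min-p key, greedy clump
        union = sorted(
            {v for v, p in zip(ids, pv1) if p < 1e-6}
            | {v for v, p in zip(ids, pv2) if p < 1e-6}
        )
        minp = {v: min(pv1[ld.index_of(v)], pv2[ld.index_of(v)]) for v in union}
        pool = make_gwas_table(
            "pool", union, [0.2] * len(union), [0.01] * len(union),
            pvalue=[minp[v] for v in union],
            positions=[ld.positions[ld.index_of(v)] for v in union],
        )
        expected = ld_clump(pool, ld)
        assert sorted(data.variant_ids) == sorted(expected)

    def test_too_few_joint_instruments(self):
        ld = simulate_ld_blocks(3, 1, 0.0, positions_spacing_kb=20_000)
        ids = ld.variant_ids
        exp1, exp2 = self._tables(
            ld, [("e1", ids, [1e-10, 0.5, 0.5]), ("e2", ids, [0.5, 1e-10, 0.5])]
        )
        out = make_gwas_table("out", ids, [0.02] * 3, [0.01] * 3, positions=ld.positions)
        with pytest.raises(InsufficientInstrumentsError):
            assemble_mv_dataset([exp1, exp2], out, ld)


class TestMvmrIvw:
    def test_noiseless_recovery_to_machine_precision(self, rng):
        G = rng.normal(0.2, 0.1, (12, 2))
        by = 0.18 * G[:, 1]  # exposure 1 has no direct effect
        res = mvmr_ivw(make_mv(G, by, np.full(12, 0.01)))
        assert res.estimates["e1"].beta == pytest.approx(0.0, abs=1e-12)
        assert res.estimates["e2"].beta == pytest.approx(0.18, abs=1e-12)

    def test_single_exposure_reduces_to_univariable_ivw(self, rng):
        bx = rng.normal(0.2, 0.1, 10)
        by = rng.normal(0.04, 0.02, 10)
        se_y = rng.uniform(0.01, 0.05, 10)
        res = mvmr_ivw(make_mv(bx[:, None], by, se_y, ids=["e1"]))
        uni = ivw(make_dataset(bx, by, se_y), model="fixed")
        assert res.estimates["e1"].beta == pytest.approx(uni.beta, rel=1e-12)

    def test_exposure_order_invariance(self, rng):
        G = rng.normal(0.2, 0.1, (15, 3))
        by = G @ np.array([0.1, -0.2, 0.05]) + rng.normal(0, 0.01, 15)
        se_y = np.full(15, 0.02)
        a = mvmr_ivw(make_mv(G, by, se_y, ids=["e1", "e2", "e3"]))
        b = mvmr_ivw(make_mv(G[:, ::-1], by, se_y, ids=["e3", "e2", "e1"]))
        for eid in ("e1", "e2", "e3"):
            assert a.estimates[eid].beta == pytest.approx(b.estimates[eid].beta, rel=1e-10)

    def test_collinear_exposures_named(self, rng):
        g = rng.normal(0.2, 0.1, 10)
        G = np.column_stack([g, 2 * g])
        with pytest.raises(CollinearityError):
            mvmr_ivw(make_mv(G, 0.1 * g, np.full(10, 0.01)))

    def test_recovery_with_correlated_exposures(self):
        ests = []
        truth = np.array([0.12, 0.17, -0.2])
        for s in range(500):
            ex, out, ld, _ = simulate_mv_exposures(seed=1_000 + s, direct_effects=tuple(truth))
            data = assemble_mv_dataset(ex, out, ld)
            r = mvmr_ivw(data)
            ests.append([r.estimates[e.trait_id].beta for e in ex])
        ests = np.asarray(ests)
        mcse = ests.std(0, ddof=1) / np.sqrt(len(ests))
        assert np.all(np.abs(ests.mean(0) - truth) < 2 * mcse + 1e-9)


class TestMvmrEgger:
    def test_noiseless_zero_intercept_matches_ivw(self, rng):
        G = np.abs(rng.normal(0.2, 0.1, (12, 2)))
        by = 0.1 * G[:, 0] + 0.2 * G[:, 1]
        data = make_mv(G, by, np.full(12, 0.01))
        eg = mvmr_egger(data)
        iv = mvmr_ivw(data)
        assert eg.intercept == pytest.approx(0.0, abs=1e-10)
        for eid in ("e1", "e2"):
            assert eg.estimates[eid].beta == pytest.approx(iv.estimates[eid].beta, abs=1e-10)

    def test_planted_constant_pleiotropy_recovered(self):
        ints = []
        for s in range(200):
            ex, out, ld, _ = simulate_mv_exposures(
                seed=3_000 + s, direct_effects=(0.0, 0.17, 0.0), pleiotropy_mean=0.05
            )
            data = assemble_mv_dataset(ex, out, ld)
            ints.append(mvmr_egger(data).intercept)
        ints = np.asarray(ints)
        # orientation uses the observed (noisy) sign of the first exposure's
        # beta, so a few misoriented rows attenuate the intercept slightly;
        # recovery is checked to 10% of the planted value
        assert ints.mean() == pytest.approx(0.05, abs=0.005)

    def test_orientation_flip_leaves_slopes_unchanged(self, rng):
        G = rng.normal(0.0, 0.15, (15, 2))
        by = G @ np.array([0.1, 0.2]) + rng.normal(0, 0.02, 15)
        data = make_mv(G, by, np.full(15, 0.02))
        flipped = make_mv(-G, -by, np.full(15, 0.02))
        a, b = mvmr_egger(data), mvmr_egger(flipped)
        for eid in ("e1", "e2"):
            assert a.estimates[eid].beta == pytest.approx(b.estimates[eid].beta, rel=1e-10)

    def test_needs_m_plus_two_rows(self, rng):
        G = rng.normal(0.2, 0.1, (3, 2))
        with pytest.raises(InsufficientInstrumentsError):
            mvmr_egger(make_mv(G, G[:, 0], np.full(3, 0.01)))


def test_independent_exposures_match_univariable(rng):
    """With mutually independent exposure effects the conditional estimates
    coincide with the univariable ones up to sampling noise."""
    k = 200
    G = rng.normal(0.0, 0.2, (k, 2))
    by = G @ np.array([0.15, -0.1]) + rng.normal(0, 0.02, k)
    se_y = np.full(k, 0.02)
    mv = mvmr_ivw(make_mv(G, by, se_y))
    uni1 = ivw(make_dataset(G[:, 0], by, se_y), model="fixed")
    uni2 = ivw(make_dataset(G[:, 1], by, se_y), model="fixed")
    assert mv.estimates["e1"].beta == pytest.approx(uni1.beta, abs=0.02)
    assert mv.estimates["e2"].beta == pytest.approx(uni2.beta, abs=0.02)
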