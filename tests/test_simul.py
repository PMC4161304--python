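"""Generator audits: structured genotypes, QTN layout, phenotype schemes."""

import numpy as np
import pytest
from scipy import stats

from adgwas import simul
from adgwas.model import MISSING, compute_maf


class TestStructuredGenotypes:
    def test_seed_determinism(self):
        g1, s1 = simul.simulate_structured_genotypes(50, 200, 3, seed=5)
        g2, s2 = simul.simulate_structured_genotypes(50, 200, 3, seed=5)
        np.testing.assert_array_equal(g1.calls, g2.calls)
        assert s1.mapping == s2.mapping

    def test_vanishing_fst_limit(self):
        g, sub = simul.simulate_structured_genotypes(600, 300, 3,
                                                     fst=1e-4, seed=6)
        groups = sub.group_vector(g.line_ids)
        freqs = []
        for lab in np.unique(groups):
            idx = np.flatnonzero(groups == lab)
            sel = g.calls[idx].astype(float)
            sel[sel == MISSING] = np.nan
            freqs.append(np.nanmean(sel, axis=0) / 2.0)
        diffs = [np.abs(freqs[i] - freqs[j]).mean()
                 for i in range(3) for j in range(i + 1, 3)]
        assert max(diffs) < 0.05   # sampling noise only at fst -> 0

    def test_moderate_fst_separates_subpopulations(self, structured_panel):
        from sklearn.decomposition import PCA
        from sklearn.metrics import silhouette_score

        g, sub = structured_panel
        X = g.calls.astype(float)
        X[X == MISSING] = np.nan
        X = np.nan_to_num(X - np.nanmean(X, axis=0))
        pcs = PCA(n_components=2).fit_transform(X)
        labels = sub.group_vector(g.line_ids)
        assert silhouette_score(pcs, labels) > 0

    def test_coding_is_major_allele_anchored(self, structured_panel):
        g, _ = structured_panel
        maf = compute_maf(g)
        assert np.nanmax(maf) <= 0.5 + 1e-12

    def test_residual_heterozygosity_low(self, structured_panel):
        g, _ = structured_panel
        assert g.heterozygosity().mean() < 0.02


@pytest.fixture(scope="module")
def panel():
    return simul.simulate_structured_genotypes(300, 4000, 3, fst=0.1, seed=7)


@pytest.fixture(scope="module")
def panel_with_qtns(panel):
    g, sub = panel
    qtns = simul.assign_qtn_effects(g, simul.scheme(1), seed=1)
    return g, sub, qtns


class TestQTNAssignment:

    def test_scheme1_layout(self, panel):
        g, _ = panel
        qtns = simul.assign_qtn_effects(g, simul.scheme(1), seed=1)
        assert len(qtns) == 20
        cls = [q.qtn_class for q in qtns]
        assert cls.count("major") == 4 and cls.count("moderate") == 16
        for want in ("rare", "common"):
            assert sum(1 for q in qtns
                       if q.qtn_class == "major" and q.maf_class == want) == 2

    def test_maf_windows_respected(self, panel):
        g, _ = panel
        maf = compute_maf(g)
        qtns = simul.assign_qtn_effects(g, simul.scheme(1), seed=2)
        for q in qtns:
            lo, hi = (simul.RARE_WINDOW if q.maf_class == "rare"
                      else simul.COMMON_WINDOW)
            assert lo <= maf[q.snp_index] <= hi

    def test_within_class_effect_ratio_is_equal_variance_rule(self, panel):
        """Within a class, |effect| ratios follow sqrt(m2(1-m2)/(m1(1-m1)))
        -- the rule that gives rare and common QTNs equal variance (about
        1.81 between the window anchors 0.075 and 0.35)."""
        g, _ = panel
        maf = compute_maf(g)
        qtns = simul.assign_qtn_effects(g, simul.scheme(1), seed=3)
        mods = [q for q in qtns if q.qtn_class == "moderate"]
        q0 = mods[0]
        for q in mods[1:]:
            m0, m1 = maf[q0.snp_index], maf[q.snp_index]
            expect = np.sqrt(m1 * (1 - m1) / (m0 * (1 - m0)))
            assert abs(q0.effect / q.effect) == pytest.approx(expect,
                                                              rel=1e-9)

    def test_major_class_variance_share(self, panel):
        g, _ = panel
        qtns = simul.assign_qtn_effects(g, simul.scheme(1), seed=4)
        X = g.calls[:, [q.snp_index for q in qtns]].astype(float)
        Xc = X - X.mean(axis=0)
        eff = np.array([q.effect for q in qtns])
        is_major = np.array([q.qtn_class == "major" for q in qtns])
        v_major = (Xc[:, is_major] @ eff[is_major]).var()
        v_mod = (Xc[:, ~is_major] @ eff[~is_major]).var()
        assert v_major / (v_major + v_mod) == pytest.approx(0.30, abs=0.02)

    def test_scheme3_layout_and_renormalized_shares(self, panel):
        g, _ = panel
        qtns = simul.assign_qtn_effects(g, simul.scheme(3), seed=5)
        cls = [q.qtn_class for q in qtns]
        assert cls.count("background") == 1
        assert cls.count("major") == 3 and cls.count("moderate") == 16
        total = sum(q.share for q in qtns)
        assert total == pytest.approx(1.0, abs=1e-9)
        bg = [q for q in qtns if q.qtn_class == "background"][0]
        assert bg.share == pytest.approx(0.25 / 1.05, abs=1e-9)
        assert bg.maf_class == "rare"

    def test_insufficient_pool_errors(self):
        g, _ = simul.simulate_structured_genotypes(40, 30, 2, seed=8)
        with pytest.raises(ValueError, match="MAF window"):
            simul.assign_qtn_effects(g, simul.scheme(1), seed=1)


class TestPhenotypeSchemes:
    @pytest.fixture
    def setup(self, panel_with_qtns):
        return panel_with_qtns

    def test_determinism(self, setup):
        g, sub, qtns = setup
        y1, _ = simul.simulate_phenotype(g, sub, qtns, simul.scheme(1), seed=9)
        y2, _ = simul.simulate_phenotype(g, sub, qtns, simul.scheme(1), seed=9)
        np.testing.assert_array_equal(y1, y2)

    def test_realized_pve_near_targets(self, setup):
        g, sub, qtns = setup
        pves = {"structure": [], "additive": [], "epistasis": []}
        for rep in range(30):
            _, truth = simul.simulate_phenotype(g, sub, qtns,
                                                simul.scheme(1), seed=rep)
            for k in pves:
                pves[k].append(truth["realized_pve"][k])
        assert np.mean(pves["structure"]) == pytest.approx(0.10, abs=0.03)
        assert np.mean(pves["epistasis"]) == pytest.approx(0.10, abs=0.03)
        assert np.mean(pves["additive"]) == pytest.approx(0.50, abs=0.03)

    def test_scheme2_contamination_increases_kurtosis(self, setup):
        g, sub, qtns = setup
        k1, k2 = [], []
        for rep in range(30):
            y1, _ = simul.simulate_phenotype(g, sub, qtns, simul.scheme(1),
                                             seed=rep)
            y2, t2 = simul.simulate_phenotype(g, sub, qtns, simul.scheme(2),
                                              seed=rep)
            k1.append(stats.kurtosis(y1))
            k2.append(stats.kurtosis(y2))
            assert t2["outliers"].sum() == round(0.10 * g.n_lines)
        assert np.mean(k2) > np.mean(k1)

    def test_null_generator_is_pure_noise(self, setup):
        g, sub, qtns = setup
        null_scheme = simul.scheme(1, h2=0.0, structure_pve=0.0,
                                   epistasis_pve=0.0)
        zero_qtns = [simul.QTNSpec(q.snp_index, q.qtn_class, q.maf_class,
                                   0.0, q.share) for q in qtns]
        y, truth = simul.simulate_phenotype(g, sub, zero_qtns, null_scheme,
                                            seed=3)
        assert truth["realized_pve"]["residual"] == pytest.approx(1.0)
        assert y.var() == pytest.approx(1.0, rel=1e-6)
        assert stats.shapiro(y).pvalue > 1e-4   # no gross non-normality

    def test_excess_pve_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            simul.scheme(1, h2=0.9)


class TestPowerStudyMechanics:
    def test_determinism_and_report_shape(self):
        g, sub = simul.simulate_structured_genotypes(80, 300, 2, fst=0.1,
                                                     seed=10)
        kw = dict(methods=("kw", "lm"), n_replicates=5, n_perm=20, seed=3)
        r1 = simul.run_power_study(g, sub, simul.scheme(1), **kw)
        r2 = simul.run_power_study(g, sub, simul.scheme(1), **kw)
        assert r1.thresholds == r2.thresholds
        assert r1.detection.equals(r2.detection)
        assert r1.n_replicates == 5
        assert set(r1.detection.columns) == {"kw", "lm"}
        assert len(r1.qtns) == 20
        assert ((r1.detection.to_numpy() >= 0)
                & (r1.detection.to_numpy() <= 1)).all()
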