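"""Simulator: design fixture, generative model calibration, MTX round-trips."""

import math

import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.stats

from cropmap import assign, screen_sim
from cropmap.screen_sim import SimParams, simulate_screen


class TestDefaultDesign:
    def test_library_composition(self, default_design):
        d = default_design
        assert len(d.guides) == 67
        assert d.n_candidates == 57
        assert d.n_controls == 10
        sizes = {k: len(v.candidate_guide_ids) for k, v in d.loci.items()}
        assert sizes == {"CISD1": 20, "PARK7": 19, "DAP": 18}

    def test_control_breakdown(self, default_design):
        classes = pd.Series([g.control_class for g in default_design.guides])
        assert classes.value_counts().to_dict() == {
            "candidate": 57, "positive": 5, "negative": 3, "non_snp": 2
        }

    def test_deterministic_in_seed(self):
        a = screen_sim.default_screen_design(3)
        b = screen_sim.default_screen_design(3)
        assert [g.protospacer for g in a.guides] == [g.protospacer for g in b.guides]

    def test_every_candidate_maps_to_one_target_gene(self, default_design):
        target = default_design.target_gene_of()
        cands = [g.guide_id for g in default_design.guides if g.control_class == "candidate"]
        assert sorted(target) == sorted(cands)


class TestEditingModel:
    def test_p_edit_zero_gives_no_edits(self, default_design):
        sim = simulate_screen(default_design, SimParams(n_cells=500, p_edit=0.0, seed=1))
        assert not sim.cell_truth["edited"].any()
        assert not sim.cell_truth["disrupted"].any()

    def test_edited_fraction_near_default(self, default_design):
        sim = simulate_screen(default_design, SimParams(n_cells=4000, seed=2))
        guided = sim.cell_truth[sim.cell_truth["targeting"]]
        frac = guided["edited"].mean()
        se = math.sqrt(0.92 * 0.08 / len(guided))
        assert abs(frac - 0.92) < 4 * se

    def test_single_allele_fraction_among_edited(self, default_design):
        sim = simulate_screen(default_design, SimParams(n_cells=4000, seed=3))
        edited = sim.cell_truth[sim.cell_truth["edited"]]
        frac = (edited["n_alleles_edited"] == 1).mean()
        se = math.sqrt(0.29 * 0.71 / len(edited))
        assert abs(frac - 0.29) < 4 * se

    def test_negative_controls_never_edit(self, default_design):
        sim = simulate_screen(default_design, SimParams(n_cells=2000, seed=4))
        neg = sim.cell_truth[sim.cell_truth["primary_guide"] == ""]
        assert not neg["edited"].any()


class TestUptakeModel:
    def test_guide_multiplicity_matches_truncated_poisson_with_dropout(self, default_design):
        """Detected guides per cell ~ ZTP(moi) thinned by binomial dropout."""
        moi, drop = 0.5, 0.05
        params = SimParams(
            n_cells=50_000, moi=moi, detect_dropout=drop, seed=5,
            n_background_genes=5,
        )
        sim = simulate_screen(default_design, params)
        obs = sim.cell_truth["n_detected"].value_counts().sort_index()
        kmax = 12
        pk = scipy.stats.poisson.pmf(np.arange(1, kmax), moi) / (1 - math.exp(-moi))
        pmf = np.zeros(kmax)
        for k, p_k in zip(range(1, kmax), pk):
            pmf[: k + 1] += p_k * scipy.stats.binom.pmf(np.arange(k + 1), k, 1 - drop)
        bins = [0, 1, 2, 3]
        exp = np.array([pmf[b] for b in bins] + [pmf[4:].sum()]) * params.n_cells
        got = np.array([obs.get(b, 0) for b in bins] + [obs[obs.index >= 4].sum()])
        keep = exp >= 5
        chi2 = ((got[keep] - exp[keep]) ** 2 / exp[keep]).sum()
        p = scipy.stats.chi2.sf(chi2, keep.sum() - 1)
        assert p > 0.01

    def test_moi_recovery_from_preselection_zeros(self, default_design):
        params = SimParams(n_cells=50_000, moi=0.5, detect_dropout=0.0, seed=6,
                           n_background_genes=5)
        sim = simulate_screen(default_design, params)
        f0 = sim.n_zero_preselection / (sim.n_zero_preselection + params.n_cells)
        assert abs(assign.estimate_moi(f0) - 0.5) / 0.5 < 0.05

    def test_essential_survival_depletes_positive_controls(self, default_design):
        full = simulate_screen(default_design, SimParams(n_cells=4000, seed=7,
                                                         n_background_genes=5))
        dep = simulate_screen(default_design, SimParams(n_cells=4000, seed=7,
                                                        essential_survival=0.2,
                                                        n_background_genes=5))
        def pos_frac(sim):
            t = sim.cell_truth
            return t["guides"].str.contains("pos_").mean()
        assert pos_frac(dep) < 0.5 * pos_frac(full)


class TestEffectInjection:
    def test_infeasible_calibration_raises(self):
        with pytest.raises(ValueError, match="infeasible"):
            screen_sim.calibrate_effect_factor(
                mean_umi=5.0, dispersion=10.0, libsize=3742.0,
                scale_factor=10_000.0, effect_sd=20.0,
            )

    def test_calibrated_factor_produces_requested_shift(self):
        """Monte-Carlo check of the analytic calibration at one gene."""
        rng = np.random.default_rng(8)
        mu, r, T, sf, delta = 12.0, 10.0, 3742.0, 10_000.0, 0.5
        f = screen_sim.calibrate_effect_factor(mu, r, T, sf, delta)
        assert 0 < f < 1

        def draw(mean, n):
            lam = rng.gamma(r, mean / r, size=n)
            x = rng.poisson(lam)
            return np.log2(1 + sf * x / T)

        base = draw(mu, 200_000)
        shifted = draw(f * mu, 200_000)
        shift_sd = (base.mean() - shifted.mean()) / base.std()
        assert abs(shift_sd - delta) < 0.03

    def test_effect_lowers_target_gene_in_disrupted_cells(self, small_sim):
        truth = small_sim.cell_truth.set_index("barcode")
        adata = small_sim.adata
        cisd1 = np.asarray(
            adata[:, adata.var_names == "CISD1"].X.todense()
        ).ravel()
        causal = truth["primary_guide"].eq("CISD1_snp07") & truth["disrupted"]
        rest = truth["primary_guide"].str.startswith("CISD1") & ~causal
        assert cisd1[causal.to_numpy()].mean() < cisd1[rest.to_numpy()].mean()


class TestMtxIO:
    def test_roundtrip_equals_in_memory(self, tmp_path, default_design):
        sim = simulate_screen(default_design, SimParams(n_cells=50, seed=9,
                                                        n_background_genes=5))
        screen_sim.write_10x_like(sim, tmp_path)
        back = screen_sim.read_10x_like(tmp_path)
        assert (back.X != sim.adata.X).nnz == 0
        assert list(back.obs_names) == list(sim.adata.obs_names)
        assert list(back.var_names) == list(sim.adata.var_names)
        assert (back.var["feature_type"] == sim.adata.var["feature_type"]).all()

    def test_header_nnz_matches_triplets(self, tmp_path, default_design):
        sim = simulate_screen(default_design, SimParams(n_cells=30, seed=10,
                                                        n_background_genes=5))
        paths = screen_sim.write_10x_like(sim, tmp_path)
        lines = [l for l in open(paths["matrix"]) if not l.startswith("%")]
        n_feat, n_cells, nnz = map(int, lines[0].split())
        assert (n_feat, n_cells) == (sim.adata.n_vars, sim.adata.n_obs)
        assert nnz == len(lines) - 1 == sim.adata.X.nnz

    def test_empty_screen_valid_mtx(self, tmp_path):
        import scipy.sparse as sp

        empty = ad.AnnData(
            X=sp.csr_matrix((0, 3), dtype=np.int64),
            var=pd.DataFrame(
                {"name": ["a", "b", "g"],
                 "feature_type": [screen_sim.GENE_TYPE] * 2 + [screen_sim.GUIDE_TYPE]},
                index=["a", "b", "g"],
            ),
        )
        screen_sim.write_10x_like(empty, tmp_path)
        back = screen_sim.read_10x_like(tmp_path)
        assert back.shape == (0, 3)

    def test_same_seed_byte_identical(self, tmp_path, default_design):
        params = SimParams(n_cells=100, seed=42, n_background_genes=5)
        a = simulate_screen(default_design, params)
        b = simulate_screen(default_design, params)
        screen_sim.write_10x_like(a, tmp_path / "a")
        screen_sim.write_10x_like(b, tmp_path / "b")
        assert (tmp_path / "a/matrix.mtx").read_bytes() == (tmp_path / "b/matrix.mtx").read_bytes()
        assert (tmp_path / "a/cell_truth.tsv").read_bytes() == (tmp_path / "b/cell_truth.tsv").read_bytes()


def test_design_tsv_roundtrip(tmp_path, default_design):
    path = tmp_path / "design.tsv"
    screen_sim.write_design(default_design, path)
    back = screen_sim.read_design(path)
    assert back.guide_ids == default_design.guide_ids
    assert back.causal_effects == default_design.causal_effects
    assert {k: v.target_gene for k, v in back.loci.items()} == {
        k: v.target_gene for k, v in default_design.loci.items()
    }
    assert back.loci["CISD1"].adjacent_genes == ("IPMK", "UBE2D1")
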