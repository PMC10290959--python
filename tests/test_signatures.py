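import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gmconcord.concordance import run_meta_screen
from gmconcord.datamodel import AnalysisConfig, GeneSetCollection, GmcError
from gmconcord.signatures import (
    drop_gene_variant,
    pathway_vs_rest_concordance,
    score_signatures,
    signature_metabolite_screen,
    ssgsea_score,
)

from conftest import make_matrix


def running_sum_oracle(values: pd.Series, gene_set, exponent):
    """Independent step-by-step walk down the ranked gene list."""
    genes = list(values.index)
    rho = stats.rankdata(values.to_numpy())
    order = sorted(range(len(genes)), key=lambda i: (-values.iloc[i], i))
    in_set = [genes[i] in gene_set for i in range(len(genes))]
    total_in = sum(rho[i] ** exponent for i in range(len(genes)) if in_set[i])
    n_out = sum(1 for f in in_set if not f)
    es, p_in, p_out = 0.0, 0.0, 0.0
    for i in order:
        if in_set[i]:
            p_in += rho[i] ** exponent / total_in
        else:
            p_out += 1.0 / n_out
        es += p_in - p_out
    return es


class TestSsgseaScore:
    @pytest.fixture
    def four_genes(self):
        return pd.Series([4.0, 3.0, 2.0, 1.0], index=["A", "B", "C", "D"])

    def test_top_gene_set_frozen_value(self, four_genes):
        # hand walk: in-set ECDF jumps to 1 at the top position, out-set
        # ECDF climbs 1/3 per step -> differences 1, 2/3, 1/3, 0
        assert ssgsea_score(four_genes, {"A"}, 0.0) == pytest.approx(2.0)
        # single-member sets are weight-normalization-free
        assert ssgsea_score(four_genes, {"A"}, 0.25) == pytest.approx(2.0)

    def test_second_gene_set_frozen_value(self, four_genes):
        assert ssgsea_score(four_genes, {"B"}, 0.0) == pytest.approx(2 / 3)

    def test_matches_running_sum_oracle(self, rng):
        for _ in range(25):
            n = int(rng.integers(4, 11))
            genes = [f"g{i}" for i in range(n)]
            vals = pd.Series(rng.uniform(0, 100, size=n), index=genes)
            k = int(rng.integers(1, n))
            gene_set = set(rng.choice(genes, size=k, replace=False))
            for exponent in (0.0, 0.25, 1.0):
                assert ssgsea_score(vals, gene_set, exponent) == pytest.approx(
                    running_sum_oracle(vals, gene_set, exponent)
                )

    def test_rank_invariance(self, rng):
        genes = [f"g{i}" for i in range(9)]
        vals = pd.Series(rng.uniform(1, 5, size=9), index=genes)
        gene_set = set(genes[:3])
        base = ssgsea_score(vals, gene_set, 0.25)
        for f in (np.exp, lambda v: v**3, lambda v: 10 * v + 2):
            assert ssgsea_score(
                pd.Series(f(vals.to_numpy()), index=genes), gene_set, 0.25
            ) == pytest.approx(base)

    def test_complement_flips_sign_at_exponent_zero(self, rng):
        genes = [f"g{i}" for i in range(8)]
        vals = pd.Series(rng.uniform(size=8), index=genes)
        s = set(genes[:3])
        comp = set(genes[3:])
        assert ssgsea_score(vals, s, 0.0) == pytest.approx(
            -ssgsea_score(vals, comp, 0.0)
        )

    def test_degenerate_sets_rejected(self, four_genes):
        with pytest.raises(GmcError, match="no genes"):
            ssgsea_score(four_genes, {"ZZ"}, 0.25)
        with pytest.raises(GmcError, match="complement"):
            ssgsea_score(four_genes, {"A", "B", "C", "D"}, 0.25)


class TestScoreSignatures:
    def _collection(self, n_sets, genes, size=5):
        rng = np.random.default_rng(0)
        return GeneSetCollection(sets={
            f"SIG{i:02d}": frozenset(
                rng.choice(genes, size=size, replace=False)
            )
            for i in range(n_sets)
        })

    def test_identical_samples_identical_scores(self, rng):
        genes = [f"g{i}" for i in range(30)]
        col = rng.uniform(1, 50, size=30)
        m = make_matrix(
            np.column_stack([col, col]), features=genes,
            omics_kind="transcript", scale_state="log2",
        )
        res = score_signatures(m, self._collection(3, genes))
        pd.testing.assert_series_equal(
            res.scores.iloc[:, 0], res.scores.iloc[:, 1], check_names=False
        )

    def test_shape_one_row_per_signature(self, rng):
        genes = [f"g{i}" for i in range(100)]
        m = make_matrix(rng.uniform(1, 9, size=(100, 4)), features=genes,
                        omics_kind="transcript", scale_state="log2")
        res = score_signatures(m, self._collection(24, genes))
        assert res.scores.shape == (24, 4)

    def test_unmeasured_signature_flagged_nan(self, rng):
        genes = [f"g{i}" for i in range(10)]
        m = make_matrix(rng.uniform(1, 9, size=(10, 3)), features=genes,
                        omics_kind="transcript", scale_state="log2")
        sigs = GeneSetCollection(sets={
            "present": frozenset(genes[:4]),
            "absent": frozenset({"zz1", "zz2"}),
        })
        res = score_signatures(m, sigs)
        assert res.scores.loc["absent"].isna().all()
        assert res.scores.loc["present"].notna().all()
        assert res.genes_missing["absent"] == ["zz1", "zz2"]

    def test_score_tracks_latent_mixture_fraction(self, rng):
        # signature genes shift up with the latent fraction f; the
        # signature score must increase monotonically with f
        n, n_genes = 50, 60
        genes = [f"g{i}" for i in range(n_genes)]
        sig = set(genes[:12])
        f = rng.beta(2, 5, size=n)
        vals = rng.normal(5, 1, size=(n_genes, n))
        for i, g in enumerate(genes):
            if g in sig:
                vals[i] += 8.0 * f
        m = make_matrix(vals, features=genes, omics_kind="transcript",
                        scale_state="log2")
        res = score_signatures(
            m, GeneSetCollection(sets={"sig": frozenset(sig)})
        )
        rho = stats.spearmanr(res.scores.loc["sig"].to_numpy(), f).statistic
        assert rho > 0.9


class TestDropGeneVariant:
    def test_removes_exactly_one(self):
        sigs = GeneSetCollection(sets={"mast": frozenset({"HDC", "X", "Y"})})
        out = drop_gene_variant(sigs, "mast", "HDC")
        variant = out.sets["mast_minus_HDC"]
        assert variant == {"X", "Y"}
        assert len(variant) == len(sigs.sets["mast"]) - 1

    def test_non_member_rejected(self):
        sigs = GeneSetCollection(sets={"mast": frozenset({"X", "Y"})})
        with pytest.raises(GmcError, match="not a member"):
            drop_gene_variant(sigs, "mast", "HDC")


class TestSignatureScreen:
    def test_composition_gives_perfect_concordance(self, rng):
        # a metabolite that is a strictly increasing function of the
        # signature score must reach c_scaled = 1
        genes = [f"g{i}" for i in range(20)]
        sig = frozenset(genes[:5])
        vals = rng.normal(size=(20, 15))
        m = make_matrix(vals, features=genes, omics_kind="transcript",
                        scale_state="log2")
        scores = score_signatures(
            m, GeneSetCollection(sets={"sig": sig})
        ).scores
        met = pd.DataFrame(
            [np.exp(scores.loc["sig"].to_numpy())],
            index=["M1"], columns=scores.columns,
        )
        out = signature_metabolite_screen(
            {"D0": scores}, {"D0": met}, min_datasets=1
        )
        assert out.iloc[0].c_scaled == pytest.approx(1.0)

    def test_grid_size(self, rng):
        cols = [f"S{i}" for i in range(10)]
        scores = {"D0": pd.DataFrame(rng.normal(size=(3, 10)),
                                     index=["A", "B", "C"], columns=cols)}
        mets = {"D0": pd.DataFrame(rng.normal(size=(4, 10)),
                                   index=list("wxyz"), columns=cols)}
        out = signature_metabolite_screen(scores, mets, min_datasets=1)
        assert len(out) == 12

    def test_planted_hub_recovered_with_leave_one_out_stability(self, rng):
        """The immune hub metabolite reaches significant positive
        concordance with the planted signature, and dropping one
        non-driver gene preserves the sign."""
        genes = [f"g{i}" for i in range(40)]
        sig_genes = genes[:10]
        hits = loo_sign = 0
        n_rep = 20
        for rep in range(n_rep):
            rng_r = np.random.default_rng(500 + rep)
            score_mats, met_mats = {}, {}
            for d in range(3):
                n = 30
                cols = [f"D{d}_S{i}" for i in range(n)]
                f = rng_r.beta(2, 5, size=n)
                vals = rng_r.normal(5, 1, size=(40, n))
                for i, g in enumerate(genes):
                    if g in sig_genes:
                        vals[i] += 8.0 * f
                m = make_matrix(vals, features=genes, samples=cols,
                                omics_kind="transcript", scale_state="log2",
                                dataset_id=f"D{d}")
                sigs = GeneSetCollection(sets={
                    "immune": frozenset(sig_genes)
                })
                sigs = drop_gene_variant(sigs, "immune", sig_genes[-1])
                score_mats[f"D{d}"] = score_signatures(m, sigs).scores
                met = 6.0 * f + rng_r.normal(0, 1, size=n)
                met_mats[f"D{d}"] = pd.DataFrame(
                    [met], index=["hub"], columns=cols
                )
            out = signature_metabolite_screen(
                score_mats, met_mats, AnalysisConfig()
            ).set_index("x_id")
            full = out.loc["immune"]
            loo = out.loc[f"immune_minus_{sig_genes[-1]}"]
            if full.significant and full.c_scaled > 0:
                hits += 1
            if np.sign(loo.c_scaled) == np.sign(full.c_scaled):
                loo_sign += 1
        assert hits / n_rep >= 0.95
        assert loo_sign / n_rep >= 0.95


class TestPathwayVsRest:
    def _records(self, values):
        return pd.DataFrame({
            "x_id": [f"M{i}" for i in range(len(values))],
            "c_scaled": values,
        })

    def test_top_block_attains_small_p(self, rng):
        vals = np.r_[np.linspace(0.8, 0.95, 4), rng.uniform(0, 0.2, 16)]
        rec = self._records(vals)
        membership = {"top": {f"M{i}" for i in range(4)}}
        out = pathway_vs_rest_concordance(rec, membership)
        assert out.loc[0, "p"] < 0.01

    def test_single_member_defined(self, rng):
        rec = self._records(rng.uniform(-1, 1, size=10))
        out = pathway_vs_rest_concordance(rec, {"solo": {"M0"}})
        assert np.isfinite(out.loc[0, "p"])

    def test_null_assignment_centers_near_half(self, rng):
        vals = rng.uniform(-1, 1, size=30)
        ps = []
        for _ in range(200):
            members = set(
                f"M{i}" for i in rng.choice(30, size=8, replace=False)
            )
            rec = self._records(vals)
            ps.append(
                pathway_vs_rest_concordance(rec, {"p": members}).loc[0, "p"]
            )
        assert 0.4 < np.mean(ps) < 0.6
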