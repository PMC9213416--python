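"""Association scan, inflation diagnostics, LD clumping and meta-analysis.

The published 12-lead-SNP association table for the grouped phenotype is
used as an input fixture to check the STAT -> P internal-consistency
contract against independently printed values.
"""

import io

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from snpher.gwas import (
    CHI2_MEDIAN_1DF,
    association_scan,
    clump_loci,
    genomic_inflation,
    lambda_1000,
    meta_analyse_gwas,
    to_sumstats,
)
from snpher.simulate import SimulationConfig, simulate_panel

# published lead-SNP rows: CHR BP SNP A1 P BETA STAT NMISS
LEAD_SNP_TABLE = pd.read_csv(
    io.StringIO(
        """CHR\tBP\tSNP\tA1\tP\tBETA\tSTAT\tNMISS
2\t217905832\trs13387042\tG\t1.550E-08\t-0.003852\t-5.656\t237570
8\t128011937\trs10086908\tC\t1.671E-10\t-0.00476\t-6.389\t236744
8\t128093297\trs1016343\tT\t2.511E-08\t0.004711\t5.573\t237567
8\t128107153\trs16901949\tC\t1.875E-08\t0.01064\t5.623\t237553
8\t128407443\trs10505477\tG\t3.035E-08\t-0.003777\t-5.540\t237573
8\t128517573\trs4242382\tA\t1.292E-08\t0.006406\t5.687\t237573
10\t51549496\trs10993994\tT\t2.434E-09\t0.004161\t5.966\t237568
10\t123334457\trs10736303\tG\t7.971E-12\t0.004688\t6.839\t236037
11\t68973970\trs4255548\tA\t3.927E-09\t-0.004171\t-5.887\t231722
16\t52538040\trs17271951\tC\t4.424E-11\t0.005219\t6.589\t234844
17\t36098040\trs4430796\tG\t2.362E-08\t-0.003817\t-5.583\t237530
19\t51361757\trs17632542\tC\t2.668E-10\t-0.008252\t-6.317\t237572"""
    ),
    sep="\t",
)


def two_sig_figs(x):
    from math import floor, log10

    return round(x, -int(floor(log10(abs(x)))) + 1)


def test_printed_p_recomputed_from_stat():
    """Two-sided normal tail of each printed STAT reproduces the printed P
    to two significant figures."""
    for _, row in LEAD_SNP_TABLE.iterrows():
        p = 2.0 * stats.norm.sf(abs(row["STAT"]))
        assert two_sig_figs(p) == pytest.approx(two_sig_figs(row["P"]), rel=0.05)


def test_lead_snp_rs17632542():
    row = LEAD_SNP_TABLE.set_index("SNP").loc["rs17632542"]
    p = 2.0 * stats.norm.sf(6.317)
    assert p == pytest.approx(2.67e-10, rel=0.01)
    assert p == pytest.approx(row["P"], rel=0.05)


# ---------------------------------------------------------------------------
# association scan


@pytest.fixture(scope="module")
def scan_panel():
    cfg = SimulationConfig(
        n_samples=900, n_variants=600, master_seed=21, ld_block_length=10,
        ld_rho=0.9, subtype_specs=(), trait_specs=(),
    )
    return simulate_panel(cfg)


def test_perfect_predictor_beta(scan_panel):
    g = scan_panel.dosages[:, 0].astype(float)
    y = g / 2.0
    assoc = association_scan(
        scan_panel.subset(variant_idx=[0]), y, model="linear"
    )
    assert assoc.table.loc[0, "BETA"] == pytest.approx(0.5, abs=1e-12)
    assert assoc.table.loc[0, "P"] < 1e-100


def test_stat_p_consistency_and_validate(scan_panel):
    rng = np.random.default_rng(0)
    y = rng.standard_normal(scan_panel.n_samples)
    assoc = association_scan(scan_panel, y, model="linear")
    assoc.validate()
    t = assoc.table
    assert (t["NMISS"] == scan_panel.n_samples).all()


def test_null_p_uniform():
    cfg = SimulationConfig(
        n_samples=2000, n_variants=5000, master_seed=23, ld_block_length=1,
        subtype_specs=(), trait_specs=(),
    )
    panel = simulate_panel(cfg)
    y = np.random.default_rng(1).standard_normal(2000)
    assoc = association_scan(panel, y, model="linear")
    ks = stats.kstest(assoc.table["P"], "uniform")
    assert ks.pvalue > 0.01


def test_logistic_matches_statsmodels_oracle(scan_panel):
    import statsmodels.api as sm

    rng = np.random.default_rng(2)
    g = scan_panel.dosages[:, 5].astype(float)
    eta = -1.5 + 0.4 * g
    y = (rng.random(len(g)) < 1 / (1 + np.exp(-eta))).astype(float)
    assoc = association_scan(
        scan_panel.subset(variant_idx=[5]), y, model="logistic"
    )
    X = sm.add_constant(g)
    ref = sm.Logit(y, X).fit(disp=0)
    assert assoc.table.loc[0, "BETA"] == pytest.approx(ref.params[1], rel=1e-5)
    assert assoc.table.loc[0, "SE"] == pytest.approx(ref.bse[1], rel=1e-4)


def test_logistic_separation_flagged(scan_panel):
    g = scan_panel.dosages[:, 3].astype(float)
    y = (g > 0).astype(float)  # perfectly separated
    assoc = association_scan(
        scan_panel.subset(variant_idx=[3]), y, model="logistic"
    )
    assert assoc.table.loc[0, "FLAG_SEPARATION"]
    assert np.isnan(assoc.table.loc[0, "BETA"])


def test_covariate_adjustment_removes_confounding(scan_panel):
    rng = np.random.default_rng(3)
    g = scan_panel.dosages[:, 10].astype(float)
    conf = g + rng.standard_normal(len(g))
    y = conf + rng.standard_normal(len(g))  # y depends on g only via conf
    raw = association_scan(scan_panel.subset(variant_idx=[10]), y, model="linear")
    adj = association_scan(
        scan_panel.subset(variant_idx=[10]), y, covariates=conf, model="linear"
    )
    assert raw.table.loc[0, "P"] < 1e-6
    assert adj.table.loc[0, "P"] > 1e-3


def test_missing_genotypes_reduce_nmiss():
    cfg = SimulationConfig(
        n_samples=400, n_variants=50, master_seed=24, missing_rate=0.1,
        subtype_specs=(), trait_specs=(),
    )
    panel = simulate_panel(cfg)
    y = np.random.default_rng(4).standard_normal(400)
    assoc = association_scan(panel, y, model="linear")
    assert (assoc.table["NMISS"] < 400).any()
    assoc.validate()


# ---------------------------------------------------------------------------
# genomic inflation


def test_lambda_fixed_point():
    assert lambda_1000(1.0, 123, 45678) == 1.0


def test_lambda_1000_worked_example():
    assert lambda_1000(1.1, 50_000, 50_000) == pytest.approx(1.002, abs=1e-9)


def test_lambda_requires_positive_counts():
    with pytest.raises(ValueError):
        lambda_1000(1.1, 0, 100)


def test_chi2_median_constant():
    assert stats.chi2.ppf(0.5, 1) == pytest.approx(CHI2_MEDIAN_1DF, abs=5e-8)


def test_null_scan_lambda_near_one():
    cfg = SimulationConfig(
        n_samples=1000, n_variants=8000, master_seed=25, ld_block_length=1,
        subtype_specs=(), trait_specs=(),
    )
    panel = simulate_panel(cfg)
    rng = np.random.default_rng(6)
    y = (rng.random(1000) < 0.3).astype(float)
    assoc = association_scan(panel, y, model="linear")
    infl = genomic_inflation(assoc, int(y.sum()), int((1 - y).sum()))
    assert 0.95 <= infl.lambda_observed <= 1.05
    assert infl.qq.shape[0] == 8000


# ---------------------------------------------------------------------------
# clumping


def fake_assoc(panel, pvals):
    rng = np.random.default_rng(0)
    t = panel.variants.rename(
        columns={"chrom": "CHR", "pos": "BP", "snp": "SNP", "a1": "A1", "a2": "A2"}
    )[["CHR", "BP", "SNP", "A1", "A2"]].copy()
    t["P"] = pvals
    t["BETA"] = rng.standard_normal(len(t))
    t["SE"] = 1.0
    t["STAT"] = stats.norm.isf(t["P"] / 2)
    t["NMISS"] = panel.n_samples
    from snpher.gwas import AssociationTable

    return AssociationTable(t, "linear", None, None)


def test_clump_no_significant(scan_panel):
    pvals = np.full(scan_panel.n_variants, 0.5)
    loci = clump_loci(fake_assoc(scan_panel, pvals), scan_panel)
    assert len(loci.table) == 0


def test_clump_linked_vs_unlinked(scan_panel):
    """Three significant SNPs: two in tight LD collapse to one locus, an
    unlinked SNP on another chromosome stays independent."""
    d = scan_panel.dosages
    r2 = np.corrcoef(d[:, 1].astype(float), d[:, 2].astype(float))[0, 1] ** 2
    assert r2 > 0.1  # same AR(1) block, adjacent, both common
    pvals = np.full(scan_panel.n_variants, 0.5)
    far = scan_panel.n_variants - 1
    pvals[[1, 2, far]] = [1e-10, 1e-9, 1e-12]
    loci = clump_loci(fake_assoc(scan_panel, pvals), scan_panel)
    assert len(loci.table) == 2
    leads = set(loci.table["SNP"])
    assert scan_panel.variants["snp"].iloc[far] in leads
    # brute force: enumerate valid clusterings of the 3 significant SNPs
    sig = [1, 2, far]
    links = {
        (i, j)
        for i in sig
        for j in sig
        if i < j
        and scan_panel.variants["chrom"].iloc[i] == scan_panel.variants["chrom"].iloc[j]
        and np.corrcoef(d[:, i].astype(float), d[:, j].astype(float))[0, 1] ** 2 >= 0.1
    }
    assert links == {(1, 2)}  # so exactly 2 loci is the unique valid answer


def test_clump_row_order_invariance(scan_panel):
    pvals = np.random.default_rng(7).uniform(1e-12, 1e-8, scan_panel.n_variants)
    assoc = fake_assoc(scan_panel, pvals)
    loci1 = clump_loci(assoc, scan_panel)
    shuffled = assoc
    shuffled.table = assoc.table.sample(frac=1.0, random_state=1).reset_index(drop=True)
    loci2 = clump_loci(shuffled, scan_panel)
    assert list(loci1.table["SNP"]) == list(loci2.table["SNP"])


# ---------------------------------------------------------------------------
# meta-analysis


def test_meta_single_table_identity(scan_panel):
    y = np.random.default_rng(8).standard_normal(scan_panel.n_samples)
    assoc = association_scan(scan_panel, y, model="linear")
    out = meta_analyse_gwas([assoc])
    assert out is assoc


def test_meta_equal_tables_halve_variance(scan_panel):
    y = np.random.default_rng(9).standard_normal(scan_panel.n_samples)
    assoc = association_scan(scan_panel, y, model="linear")
    out = meta_analyse_gwas([assoc, assoc])
    merged = out.table.set_index("SNP")
    orig = assoc.table.set_index("SNP")
    common = merged.index[:50]
    assert np.allclose(merged.loc[common, "BETA"], orig.loc[common, "BETA"])
    assert np.allclose(
        merged.loc[common, "SE"], orig.loc[common, "SE"] / np.sqrt(2)
    )


def test_meta_k_copies_shrink_se_sqrt_k(scan_panel):
    y = np.random.default_rng(10).standard_normal(scan_panel.n_samples)
    assoc = association_scan(scan_panel, y, model="linear")
    out = meta_analyse_gwas([assoc] * 4)
    merged = out.table.set_index("SNP")
    orig = assoc.table.set_index("SNP")
    assert np.allclose(
        merged["SE"], orig.loc[merged.index, "SE"] / 2.0, rtol=1e-12
    )


def test_meta_allele_flip_harmonized(scan_panel):
    y = np.random.default_rng(11).standard_normal(scan_panel.n_samples)
    assoc = association_scan(scan_panel, y, model="linear")
    flipped = association_scan(scan_panel, y, model="linear")
    t = flipped.table
    t["A1"], t["A2"] = t["A2"].copy(), t["A1"].copy()
    t["BETA"] = -t["BETA"]
    t["STAT"] = -t["STAT"]
    out = meta_analyse_gwas([assoc, flipped])
    merged = out.table.set_index("SNP")
    orig = assoc.table.set_index("SNP")
    assert np.allclose(merged["BETA"], orig.loc[merged.index, "BETA"], rtol=1e-12)


def test_grouped_scan_outpowers_subtype_meta():
    """At loci shared across subtypes, scanning the grouped phenotype finds
    at least as many genome-wide-significant hits as meta-analysing the
    per-subtype scans, in >= 8/10 replicates (the power rationale for
    grouping related diseases)."""
    from scipy import stats as ss

    wins = 0
    for rep in range(10):
        n, m = 4000, 600
        cfg = SimulationConfig(
            n_samples=n, n_variants=m, master_seed=12_000 + rep,
            ld_block_length=1, subtype_specs=(), trait_specs=(),
        )
        panel = simulate_panel(cfg)
        xs = panel.standardized()
        rng = np.random.default_rng(12_500 + rep)
        shared = [50, 250, 450]
        subs = []
        for k in range(3):
            own = rng.choice(m, 20, replace=False)  # subtype-specific part
            liab = (
                xs[:, shared] @ np.full(3, 3 * np.sqrt(0.01))
                + xs[:, own] @ (rng.standard_normal(20) * 0.05)
                + rng.standard_normal(n)
            )
            liab = (liab - liab.mean()) / liab.std()
            subs.append((liab > ss.norm.isf(0.05)).astype(float))
        grouped = (np.vstack(subs).sum(0) > 0).astype(float)
        scans = [association_scan(panel, y, model="linear") for y in subs]
        meta = meta_analyse_gwas(scans)
        gscan = association_scan(panel, grouped, model="linear")
        hits_meta = int((meta.table["P"].to_numpy()[shared] < 5e-8).sum())
        hits_grp = int((gscan.table["P"].to_numpy()[shared] < 5e-8).sum())
        wins += hits_grp >= hits_meta
    assert wins >= 8


def test_to_sumstats_layout(scan_panel):
    y = np.random.default_rng(12).standard_normal(scan_panel.n_samples)
    assoc = association_scan(scan_panel, y, model="linear")
    ss = to_sumstats(assoc)
    assert list(ss.columns) == ["SNP", "A1", "A2", "N", "Z"]
    assert np.allclose(ss["Z"], assoc.table["STAT"])
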