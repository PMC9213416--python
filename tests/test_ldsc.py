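"""LD scores, summary-statistic heritability/rg regression, interaction
scan and GxEsum inversion."""

import numpy as np
import pandas as pd
import pytest

from snpher.gwas import association_scan, to_sumstats
from snpher.ldsc import (
    GxEsumRegression,
    LdscRegression,
    compute_ld_scores,
    gxesum_fit,
    interaction_scan,
    ldsc_h2,
    ldsc_rg,
)
from snpher.simulate import GenotypePanel, SimulationConfig, simulate_panel


def panel_from_dosages(dosages, pos=None, chrom=None):
    dosages = np.asarray(dosages, dtype=np.int8)
    n, m = dosages.shape
    freq = dosages.mean(0) / 2
    variants = pd.DataFrame(
        {
            "chrom": chrom if chrom is not None else np.ones(m, int),
            "pos": pos if pos is not None else np.arange(1, m + 1) * 1000,
            "snp": [f"v{i}" for i in range(m)],
            "a1": ["A"] * m,
            "a2": ["G"] * m,
            "maf": np.minimum(freq, 1 - freq),
            "info": np.ones(m),
        }
    )
    return GenotypePanel(
        sample_ids=np.array([f"S{i}" for i in range(n)]),
        sex=np.array(["female"] * n),
        variants=variants,
        dosages=dosages,
    )


# ---------------------------------------------------------------------------
# LD scores


def test_unlinked_mean_ld_score_near_one(unlinked_panel):
    ld = compute_ld_scores(unlinked_panel, window_bp=100_000)
    assert ld.table["l2"].mean() == pytest.approx(1.0, abs=0.05)


def test_duplicated_isolated_pair_scores_two():
    rng = np.random.default_rng(0)
    g = rng.binomial(2, 0.4, size=(500, 1)).astype(np.int8)
    other = rng.binomial(2, 0.4, size=(500, 2)).astype(np.int8)
    d = np.hstack([g, g, other])
    # twins adjacent; the other SNPs far outside the window
    panel = panel_from_dosages(d, pos=[1000, 2000, 10_000_000, 20_000_000])
    ld = compute_ld_scores(panel, window_bp=5000)
    assert ld.table["l2"].iloc[0] == pytest.approx(2.0, abs=1e-9)
    assert ld.table["l2"].iloc[1] == pytest.approx(2.0, abs=1e-9)


def test_ar1_block_interior_exceeds_edges():
    for seed in range(3):
        cfg = SimulationConfig(
            n_samples=800, n_variants=40, master_seed=seed, ld_block_length=40,
            ld_rho=0.9, maf_range=(0.2, 0.5), subtype_specs=(), trait_specs=(),
        )
        panel = simulate_panel(cfg)
        ld = compute_ld_scores(panel, window_bp=10_000_000)
        l2 = ld.table["l2"].to_numpy()
        interior = l2[15:25].mean()
        edges = (l2[0] + l2[-1]) / 2
        assert interior > edges


def test_ld_scores_invariant_to_order_and_strand(unlinked_panel):
    ld0 = compute_ld_scores(unlinked_panel, window_bp=50_000)
    # strand relabel: count the other allele at half the SNPs
    flipped = unlinked_panel.subset()
    flipped.dosages = flipped.dosages.copy()
    flipped.dosages[:, ::2] = 2 - flipped.dosages[:, ::2]
    ld1 = compute_ld_scores(flipped, window_bp=50_000)
    assert np.allclose(ld0.table["l2"], ld1.table["l2"], atol=1e-9)
    # SNP order within a chromosome permuted (positions travel with SNPs)
    perm = np.random.default_rng(1).permutation(unlinked_panel.n_variants)
    shuffled = unlinked_panel.subset(variant_idx=perm)
    ld2 = compute_ld_scores(shuffled, window_bp=50_000)
    back = ld2.table.set_index("snp").loc[ld0.table["snp"], "l2"].to_numpy()
    assert np.allclose(ld0.table["l2"], back, atol=1e-9)


def test_bad_window_rejected(unlinked_panel):
    with pytest.raises(ValueError):
        compute_ld_scores(unlinked_panel, window_bp=0)


# ---------------------------------------------------------------------------
# univariate LDSC


def synth_ldscores(m, seed=0):
    rng = np.random.default_rng(seed)
    l2 = 1.0 + rng.gamma(2.0, 2.0, m)
    return pd.DataFrame(
        {"snp": [f"v{i}" for i in range(m)], "chrom": 1, "pos": np.arange(m), "l2": l2}
    )


def synth_sumstats(l2, n, h2, m, seed=0, intercept=1.0):
    """Summary stats drawn from the LDSC generative model itself."""
    rng = np.random.default_rng(seed)
    lam = intercept + n * h2 * l2 / m
    z2 = lam * rng.chisquare(1, len(l2))
    z = np.sqrt(z2) * rng.choice([-1, 1], len(l2))
    return pd.DataFrame(
        {
            "SNP": [f"v{i}" for i in range(len(l2))],
            "A1": "A",
            "A2": "G",
            "N": n,
            "Z": z,
        }
    )


def test_ldsc_recovers_h2_from_generative_model():
    from snpher.ldsc import LdScoreTable

    m = 20_000
    ld = synth_ldscores(m, seed=3)
    ss = synth_sumstats(ld["l2"].to_numpy(), n=20_000, h2=0.3, m=m, seed=4)
    fit = ldsc_h2(ss, LdScoreTable(ld), M=m)
    assert fit.h2_observed == pytest.approx(0.3, abs=2 * fit.h2_se)
    assert fit.h2_se < 0.05
    assert fit.intercept == pytest.approx(1.0, abs=2 * fit.intercept_se)


def test_ldsc_null_h2_zero():
    from snpher.ldsc import LdScoreTable

    m = 10_000
    ld = synth_ldscores(m, seed=5)
    ss = synth_sumstats(ld["l2"].to_numpy(), n=10_000, h2=0.0, m=m, seed=6)
    fit = ldsc_h2(ss, LdScoreTable(ld), M=m)
    assert abs(fit.h2_observed) <= 2 * fit.h2_se
    assert fit.intercept == pytest.approx(1.0, abs=2 * fit.intercept_se)


def test_ldsc_flat_chi2_gives_zero():
    from snpher.ldsc import LdScoreTable

    m = 1000
    ld = synth_ldscores(m, seed=7)
    ss = pd.DataFrame(
        {"SNP": [f"v{i}" for i in range(m)], "A1": "A", "A2": "G", "N": 5000,
         "Z": np.ones(m)}
    )
    fit = ldsc_h2(ss, LdScoreTable(ld), M=m)
    assert fit.h2_observed == pytest.approx(0.0, abs=1e-12)
    assert fit.intercept == pytest.approx(1.0, abs=1e-12)


def test_ldsc_constrained_intercept():
    from snpher.ldsc import LdScoreTable

    m = 10_000
    ld = synth_ldscores(m, seed=8)
    ss = synth_sumstats(ld["l2"].to_numpy(), n=10_000, h2=0.25, m=m, seed=9)
    reg = LdscRegression(constrain_intercept=True).fit(ss, LdScoreTable(ld), M=m)
    assert reg.intercept_ == 1.0
    assert reg.h2_ == pytest.approx(0.25, abs=2 * reg.h2_se_)


def test_ldsc_liability_conversion():
    from snpher.ldsc import LdScoreTable

    m = 5000
    ld = synth_ldscores(m, seed=10)
    ss = synth_sumstats(ld["l2"].to_numpy(), n=5000, h2=0.1, m=m, seed=11)
    fit = ldsc_h2(ss, LdScoreTable(ld), M=m, K=0.06)
    from snpher.greml import liability_multiplier

    assert fit.h2_liability == pytest.approx(
        fit.h2_observed * liability_multiplier(0.06, 0.06), rel=1e-9
    )


def test_ldsc_too_few_snps():
    from snpher.ldsc import LdScoreTable

    ld = synth_ldscores(100)
    ss = synth_sumstats(ld["l2"].to_numpy(), 1000, 0.2, 100)
    with pytest.raises(ValueError):
        ldsc_h2(ss, LdScoreTable(ld), M=100)


# ---------------------------------------------------------------------------
# cross-trait rg


def synth_pair(l2, n, h2a, h2b, rg, m, seed=0, overlap_intercept=0.0):
    rng = np.random.default_rng(seed)
    k = len(l2)
    sa = np.sqrt(np.maximum(n * h2a * l2 / m, 0))
    sb = np.sqrt(np.maximum(n * h2b * l2 / m, 0))
    ga = rng.standard_normal(k)
    gb = rg * ga + np.sqrt(max(0.0, 1 - rg**2)) * rng.standard_normal(k)
    ea = rng.standard_normal(k)
    eb = overlap_intercept * ea + np.sqrt(max(0.0, 1 - overlap_intercept**2)) * rng.standard_normal(k)
    za = sa * ga + ea
    zb = sb * gb + eb
    mk = lambda z: pd.DataFrame(
        {"SNP": [f"v{i}" for i in range(k)], "A1": "A", "A2": "G", "N": n, "Z": z}
    )
    return mk(za), mk(zb)


def test_rg_self_is_one():
    from snpher.ldsc import LdScoreTable

    m = 10_000
    ld = synth_ldscores(m, seed=12)
    sa, _ = synth_pair(ld["l2"].to_numpy(), 10_000, 0.4, 0.4, 1.0, m, seed=13)
    est = ldsc_rg(sa, sa.copy(), LdScoreTable(ld), M=m)
    assert est.rg_raw == pytest.approx(1.0, abs=3 * est.se)


def test_rg_recovery_with_shared_controls():
    """rg = 0.5 recovered; the cross-trait intercept absorbs the shared-
    control correlation instead of biasing rg."""
    from snpher.ldsc import LdScoreTable

    m = 20_000
    ld = synth_ldscores(m, seed=14)
    sa, sb = synth_pair(
        ld["l2"].to_numpy(), 20_000, 0.4, 0.4, 0.5, m, seed=15,
        overlap_intercept=0.3,
    )
    est = ldsc_rg(sa, sb, LdScoreTable(ld), M=m)
    assert est.rg_raw == pytest.approx(0.5, abs=2 * est.se)
    assert est.se < 0.15


def test_rg_independent_traits_null():
    from snpher.ldsc import LdScoreTable

    m = 20_000
    ld = synth_ldscores(m, seed=16)
    sa, sb = synth_pair(ld["l2"].to_numpy(), 20_000, 0.4, 0.4, 0.0, m, seed=17)
    est = ldsc_rg(sa, sb, LdScoreTable(ld), M=m)
    assert abs(est.rg_raw) <= 2 * est.se


def test_rg_not_estimable_with_null_trait():
    from snpher.ldsc import LdScoreTable

    m = 5000
    ld = synth_ldscores(m, seed=18)
    sa, _ = synth_pair(ld["l2"].to_numpy(), 5000, 0.4, 0.4, 1.0, m, seed=19)
    # trait B has no polygenic signal at all: h2 estimate ~ 0/negative
    rng = np.random.default_rng(20)
    sb = sa.copy()
    sb["Z"] = -0.0 * sb["Z"] + rng.standard_normal(m) * 0.6  # deflated chi2
    est = ldsc_rg(sa, sb, LdScoreTable(ld), M=m)
    assert est.rg is None
    assert "not estimable" in est.reason


def test_rg_allele_flip_harmonization():
    from snpher.ldsc import LdScoreTable

    m = 10_000
    ld = synth_ldscores(m, seed=21)
    sa, sb = synth_pair(ld["l2"].to_numpy(), 10_000, 0.4, 0.4, 0.5, m, seed=22)
    flipped = sb.copy()
    flipped["A1"], flipped["A2"] = flipped["A2"].copy(), flipped["A1"].copy()
    flipped["Z"] = -flipped["Z"]
    est0 = ldsc_rg(sa, sb, LdScoreTable(ld), M=m)
    est1 = ldsc_rg(sa, flipped, LdScoreTable(ld), M=m)
    assert est0.rg_raw == pytest.approx(est1.rg_raw, rel=1e-9)


# ---------------------------------------------------------------------------
# interaction scan + GxEsum


def test_interaction_null_chi2_mean_one(unlinked_panel):
    rng = np.random.default_rng(23)
    n = unlinked_panel.n_samples
    y = rng.standard_normal(n)
    E = rng.standard_normal(n)
    ss = interaction_scan(unlinked_panel, y, E)
    chi2 = ss["Z"].to_numpy() ** 2
    assert chi2.mean() == pytest.approx(1.0, abs=0.08)


def test_interaction_constant_env_rejected(unlinked_panel):
    y = np.zeros(unlinked_panel.n_samples)
    with pytest.raises(ValueError, match="constant"):
        interaction_scan(unlinked_panel, y, np.ones(len(y)))


def test_interaction_planted_signal_found(unlinked_panel):
    rng = np.random.default_rng(24)
    n = unlinked_panel.n_samples
    xs = unlinked_panel.standardized()
    E = rng.standard_normal(n)
    y = 0.5 * xs[:, 7] * E + rng.standard_normal(n)
    ss = interaction_scan(unlinked_panel, y, E)
    assert int(np.argmax(ss["Z"] ** 2)) == 7


def test_gxesum_null_point():
    """b1 = 0, b0 = 1 inverts to (sigma2_g1, sigma2_tau1) = (0, 0)."""
    from snpher.ldsc import LdScoreTable

    m = 2000
    ld = synth_ldscores(m, seed=25)
    ss = pd.DataFrame(
        {"SNP": [f"v{i}" for i in range(m)], "A1": "A", "A2": "G", "N": 5000,
         "Z": np.ones(m)}
    )
    fit = gxesum_fit(ss, LdScoreTable(ld), N=5000, M=m)
    assert fit.sigma2_g1 == pytest.approx(0.0, abs=1e-12)
    assert fit.sigma2_tau1 == pytest.approx(0.0, abs=1e-12)


def test_gxesum_inversion_identity():
    """Plugging the fitted (b0, b1) back into the expectation reproduces the
    fitted line exactly (weighted residual mean zero)."""
    from snpher.ldsc import LdScoreTable

    m = 5000
    rng = np.random.default_rng(26)
    ld = synth_ldscores(m, seed=27)
    l2 = ld["l2"].to_numpy()
    N, M = 8000.0, m
    chi2 = 1.1 + 0.002 * l2 * N / M + 0.1 * rng.standard_normal(m)
    ss = pd.DataFrame(
        {"SNP": [f"v{i}" for i in range(m)], "A1": "A", "A2": "G", "N": N,
         "Z": np.sqrt(np.maximum(chi2, 0))}
    )
    reg = GxEsumRegression(chi2_max=None).fit(ss, LdScoreTable(ld), N=N, M=M)
    fit = reg.fit_
    pred = fit.intercept + fit.slope * l2
    w = 1.0 / np.maximum(l2, 1.0)
    resid = np.maximum(chi2, 0) - pred
    assert np.average(resid, weights=w) == pytest.approx(0.0, abs=1e-9)
    # and the inversion is the exact algebra of the expectation
    assert fit.sigma2_g1 == pytest.approx(fit.slope * M / N, rel=1e-12)
    assert fit.sigma2_tau1 == pytest.approx(
        (fit.intercept - 1) / 2 - fit.sigma2_g1, rel=1e-9, abs=1e-12
    )


def test_gxesum_boundary_flag():
    from snpher.ldsc import LdScoreTable

    m = 2000
    ld = synth_ldscores(m, seed=28)
    ss = pd.DataFrame(
        {"SNP": [f"v{i}" for i in range(m)], "A1": "A", "A2": "G", "N": 5000,
         "Z": np.full(m, 0.5)}
    )
    fit = gxesum_fit(ss, LdScoreTable(ld), N=5000, M=m)
    assert fit.boundary
    assert fit.sigma2_tau1 < 0


def test_end_to_end_scan_feeds_ldsc(unlinked_panel):
    """The gwas module's sumstats merge cleanly into the regression."""
    rng = np.random.default_rng(29)
    y = rng.standard_normal(unlinked_panel.n_samples)
    assoc = association_scan(unlinked_panel, y, model="linear")
    ld = compute_ld_scores(unlinked_panel, window_bp=50_000)
    fit = ldsc_h2(to_sumstats(assoc), ld, M=unlinked_panel.n_variants)
    assert abs(fit.h2_observed) <= 3 * fit.h2_se
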