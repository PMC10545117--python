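import numpy as np
import pytest
from scipy import integrate, special

from surfload.core_io import CodingAlignment
from surfload.dfe_alpha import (
    DFEParams,
    UnfoldedSFSPair,
    build_sfs,
    expected_pin_pis,
    expected_sfs,
    fit_gamma_expo,
    fixation_rate,
    omega_na,
    read_sfs,
    selection_summary,
    sojourn_density,
    write_sfs,
    _sojourn_basis,
    _log_s_grid,
    _S_CUTOFF_HI,
)
from surfload.simulate import sample_prf_sfs


def _params(**kw):
    base = dict(shape=0.3, mean_sd=-1000.0, theta_syn=1.0, theta_nonsyn=1.0)
    base.update(kw)
    return DFEParams(**base)


# --- analytic limits ------------------------------------------------------


def test_neutral_synonymous_sfs_is_theta_over_i():
    p = _params(theta_syn=7.0)
    e_syn, _ = expected_sfs(p, 12)
    np.testing.assert_allclose(e_syn, 7.0 / np.arange(1, 12), atol=1e-10)


def test_distortion_multiplies_classwise():
    r = np.array([1.0, 2.0, 0.5])
    p = _params(theta_syn=1.0, r=r)
    e_syn, _ = expected_sfs(p, 4)
    np.testing.assert_allclose(e_syn, r / np.arange(1, 4), atol=1e-12)


def test_sojourn_density_neutral_limit_on_grid():
    x = np.linspace(0.005, 0.995, 199)
    np.testing.assert_allclose(sojourn_density(x, 1e-9) * x, 1.0, atol=1e-8)


def test_sojourn_density_against_quadrature_oracle():
    """b_i(S) from the cached basis matches direct adaptive quadrature."""
    n = 8
    s_vals, _ = _log_s_grid(_S_CUTOFF_HI)
    basis = _sojourn_basis(n, -1, _S_CUTOFF_HI)
    for k in (40, 80, 110):  # |S| across the grid
        S = -s_vals[k]
        for i in (1, 3, 7):
            want, _ = integrate.quad(
                lambda x: sojourn_density(x, S)
                * special.comb(n, i)
                * x**i
                * (1 - x) ** (n - i),
                0,
                1,
                limit=200,
            )
            assert basis[i - 1, k] == pytest.approx(want, rel=1e-6)


def test_strong_selection_inflates_singleton_fraction():
    p = _params(mean_sd=-1000.0, shape=20.0)  # concentrated near |S|=1000
    _, e_n = expected_sfs(p, 10)
    neutral = 1.0 / np.arange(1, 10)
    assert e_n[0] / e_n.sum() > neutral[0] / neutral.sum()


def test_misorientation_half_symmetrizes():
    p = _params(eps_anc=0.4999)
    e_syn, e_n = expected_sfs(p, 10)
    np.testing.assert_allclose(e_syn, e_syn[::-1], rtol=1e-3)
    np.testing.assert_allclose(e_n, e_n[::-1], rtol=1e-3)


def test_dfe_normalization():
    for p in (
        _params(),
        _params(shape=0.1, mean_sd=-10.0),
        _params(p_b=0.1, mean_sb=5.0),
    ):
        assert p.dfe_mass() == pytest.approx(1.0, abs=1e-8)


def test_stronger_purifying_selection_lowers_ratio_and_omega_na():
    weak = _params(mean_sd=-5.0)
    strong = _params(mean_sd=-5000.0)
    assert expected_pin_pis(strong) < expected_pin_pis(weak)
    assert omega_na(strong) < omega_na(weak)


# --- fixation rate and alpha identities ----------------------------------


def test_u_closed_form_at_minus_two():
    assert fixation_rate(-2.0)[0] == pytest.approx(2.0 / (np.e**2 - 1), abs=1e-12)


def test_u_neutral_limit_by_numeric_continuity():
    assert fixation_rate(0.0)[0] == 1.0
    assert fixation_rate(1e-9)[0] == pytest.approx(1.0, abs=1e-6)
    assert fixation_rate(-1e-9)[0] == pytest.approx(1.0, abs=1e-6)


def test_selection_summary_printed_identities():
    sfs = UnfoldedSFSPair(
        8, np.ones(7), np.ones(7), L_syn=100.0, L_nonsyn=100.0, D_syn=20.0, D_nonsyn=3.0
    )
    # dN/dS = (3/100)/(20/100) = 0.15; force omega_na = 0.10 via a DFE probe
    p = _params()
    w_na = omega_na(p)
    s = selection_summary(p, sfs)
    assert s.dnds_obs == pytest.approx(0.15)
    assert s.omega_a == pytest.approx(0.15 - w_na)
    assert s.alpha == pytest.approx((0.15 - w_na) / 0.15)
    assert s.omega_a + s.omega_na == pytest.approx(s.dnds_obs, abs=1e-15)
    assert s.alpha <= 1.0


def test_fully_neutral_dfe_has_omega_na_one():
    p = _params(mean_sd=-1e-12)
    assert omega_na(p) == pytest.approx(1.0, abs=1e-6)


# --- fitting --------------------------------------------------------------


def test_prf_recovery_short():
    true = DFEParams(
        shape=0.3, mean_sd=-1000.0, p_b=0.02, mean_sb=4.0,
        theta_syn=5000.0, theta_nonsyn=5000.0,
    )
    ok = 0
    for rep in range(3):
        sfs = sample_prf_sfs(true, 20, seed=500 + rep, L_syn=1e6, L_nonsyn=1e6)
        fit = fit_gamma_expo(
            sfs, n_starts=5, seed=rep, fit_distortion=False, fit_misorientation=False
        )
        ok += (
            abs(fit.params.shape - 0.3) <= 0.1
            and abs(np.log10(abs(fit.params.mean_sd)) - 3.0) <= 0.5
        )
    assert ok >= 2


def test_neutral_nonsyn_fit_gives_unit_ratio():
    rng = np.random.default_rng(3)
    n = 20
    theta = 4000.0
    e = theta / np.arange(1, n)
    sfs = UnfoldedSFSPair(
        n, rng.poisson(e).astype(float), rng.poisson(e).astype(float),
        L_syn=1e6, L_nonsyn=1e6,
    )
    fit = fit_gamma_expo(
        sfs, model="GammaZero", n_starts=5, seed=0,
        fit_distortion=False, fit_misorientation=False,
    )
    assert expected_pin_pis(fit.params) == pytest.approx(1.0, abs=0.05)


def test_undistorted_data_does_not_reject_plain_model():
    """Fitting the r/eps nuisance on undistorted data must not improve the
    likelihood beyond chance (likelihood-ratio bound)."""
    from scipy.stats import chi2

    true = DFEParams(shape=0.4, mean_sd=-300.0, theta_syn=3000.0, theta_nonsyn=3000.0)
    sfs = sample_prf_sfs(true, 10, seed=11, L_syn=1e6, L_nonsyn=1e6)
    plain = fit_gamma_expo(sfs, model="GammaZero", n_starts=4, seed=1,
                           fit_distortion=False, fit_misorientation=False)
    rich = fit_gamma_expo(sfs, model="GammaZero", n_starts=4, seed=2,
                          fit_distortion=True, fit_misorientation=True)
    extra_df = rich.n_free - plain.n_free
    lr = 2.0 * (rich.loglik - plain.loglik)
    assert lr < chi2.ppf(0.999, extra_df)


def test_model_comparison_reports_both():
    from surfload.dfe_alpha import compare_models

    true = DFEParams(shape=0.3, mean_sd=-500.0, theta_syn=2000.0, theta_nonsyn=2000.0)
    sfs = sample_prf_sfs(true, 8, seed=4, L_syn=1e6, L_nonsyn=1e6)
    fits = compare_models(sfs, seed=0, n_starts=3, fit_distortion=False,
                          fit_misorientation=False)
    assert set(fits) == {"GammaZero", "GammaExpo"}
    assert all(np.isfinite(f.aic) for f in fits.values())


# --- SFS construction -----------------------------------------------------


def _alignment_from_haplotypes(haps, gene_id="g"):
    pairs = [(haps[i], haps[i + 1]) for i in range(0, len(haps), 2)]
    return CodingAlignment(gene_id, [f"s{i}" for i in range(len(pairs))], pairs)


def test_build_sfs_site_coverage_threshold():
    # 16 haplotypes, one codon column has 9 called -> below gapN_site 10
    base = "ATGGCTGCTGCTGCTGCT"  # 6 codons
    haps = [base] * 16
    masked = ["NNN" + base[3:]] * 7 + [base] * 9
    anc = {"g": base}
    full = build_sfs([_alignment_from_haplotypes(haps)], anc, sample_size=8)
    part = build_sfs([_alignment_from_haplotypes(masked)], anc, sample_size=8)
    assert part.L_syn < full.L_syn  # masked codon dropped from site totals


def test_build_sfs_min_codon_filter():
    base = "ATGGCTGCTGCTGCT"  # 5 codons < min 6
    sfs = build_sfs(
        [_alignment_from_haplotypes([base] * 16)], {"g": base}, sample_size=8
    )
    assert sfs.filter_log["genes_dropped_codons"] == 1
    assert sfs.L_syn == 0


def test_build_sfs_internal_stop_disqualifies():
    good = "ATGGCT" * 25  # 50 codons
    with_stop = good[:75] + "TAA" + good[78:]  # stop at codon 25 (inside zone)
    sfs = build_sfs(
        [_alignment_from_haplotypes([with_stop] * 16)], {"g": good},
        sample_size=8, tolerance_zone=20,
    )
    assert sfs.filter_log["genes_dropped_stop"] == 1


def test_hypergeometric_projection_preserves_expected_count():
    # derived count 4 of 16 projected to 8: expected derived count = 2
    base = "ATGGCTGCTGCTGCTGCTGCT"  # 7 codons >= 6
    derived = "ATGGCTGCTGCTGCTGCTGCG"  # syn change at last codon third position
    haps = [derived] * 4 + [base] * 12
    sfs = build_sfs([_alignment_from_haplotypes(haps)], {"g": base}, sample_size=8)
    i = np.arange(1, 8)
    # total fractional mass = 1 - P(0 derived in the subsample); expected
    # derived count over classes 1..7 = n*k/m = 2 (class 8 is impossible)
    p0 = special.comb(12, 8) / special.comb(16, 8)
    assert sfs.syn_sfs.sum() == pytest.approx(1.0 - p0, abs=1e-9)
    assert float((i * sfs.syn_sfs).sum()) == pytest.approx(2.0, abs=1e-9)


def test_divergence_counted_against_outgroup():
    base = "ATGGCTGCTGCTGCTGCTGCT"
    outg = "ATGGCGGCTGCTGCTGCTGCT"  # one synonymous substitution (codon 2, 3rd pos)
    sfs = build_sfs(
        [_alignment_from_haplotypes([base] * 16)], {"g": base},
        sample_size=8, outgroup_cds={"g": outg},
    )
    assert sfs.D_syn == 1 and sfs.D_nonsyn == 0


def test_sfs_file_round_trip(tmp_path):
    sfs = UnfoldedSFSPair(
        8, np.arange(1.0, 8.0), np.arange(2.0, 9.0),
        L_syn=1234.5, L_nonsyn=4321.0, D_syn=10.0, D_nonsyn=7.0,
    )
    p = tmp_path / "pop.dofe"
    write_sfs(sfs, p)
    back = read_sfs(p)
    np.testing.assert_allclose(back.syn_sfs, sfs.syn_sfs)
    np.testing.assert_allclose(back.nonsyn_sfs, sfs.nonsyn_sfs)
    assert back.dnds_obs == pytest.approx(sfs.dnds_obs)
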