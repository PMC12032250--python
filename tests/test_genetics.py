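"""Unit and property tests of the two-locus inheritance engine."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from drivesuite.genetics import (
    Diplotype,
    DriveAllele,
    DriveParams,
    EffectorAllele,
    FitnessClass,
    Sex,
    all_drive_genotypes,
    all_effector_genotypes,
    cross_distribution,
    deterministic_step,
    drive_fitness_class,
    drive_locus_gamete_distribution,
    expected_inheritance,
    gamete_distribution,
)

from conftest import C, CR, D, E, R1, R2, W, make_dip


# ------------------------------------------------------------- fitness class


@pytest.mark.parametrize(
    "a1,a2,expected",
    [
        (D, D, FitnessClass.HOMOZYGOUS_LOF),
        (D, R2, FitnessClass.HOMOZYGOUS_LOF),
        (R2, R2, FitnessClass.HOMOZYGOUS_LOF),
        (W, R1, FitnessClass.FUNCTIONAL),
        (W, W, FitnessClass.FUNCTIONAL),
        (R1, R1, FitnessClass.FUNCTIONAL),
        (D, R1, FitnessClass.HETEROZYGOUS_LOF),
        (D, W, FitnessClass.HETEROZYGOUS_LOF),
        (R2, W, FitnessClass.HETEROZYGOUS_LOF),
    ],
)
def test_fitness_class_partitions_by_broken_copies(a1, a2, expected):
    assert drive_fitness_class(make_dip(a1, a2)) is expected


def test_diplotype_is_unordered():
    a = Diplotype((D, C), (W, E), Sex.FEMALE)
    b = Diplotype((W, E), (D, C), Sex.FEMALE)
    assert a == b and hash(a) == hash(b)


# -------------------------------------------------------------- gamete rules


def test_wild_type_homozygote_transmits_only_wild_type():
    g = gamete_distribution(make_dip(W, W), DriveParams())
    assert g == {(W, C): 1.0}


def test_measured_female_heterozygote_marginals(measured_params):
    g = drive_locus_gamete_distribution((D, W), Sex.FEMALE, measured_params)
    assert g[D] == pytest.approx(0.996, abs=1e-12)
    assert g[R1] == pytest.approx(0.0004, abs=1e-12)
    assert g[R2] == pytest.approx(0.0036, abs=1e-12)


def test_rare_functional_resistance_per_gamete():
    # 99% inheritance, full conversion, 1:999 functional split -> 1e-5 R1
    p = DriveParams(
        homing_female=0.99, homing_male=0.99,
        uncut_fraction=0.0, functional_fraction=0.001,
    )
    g = drive_locus_gamete_distribution((D, W), Sex.FEMALE, p)
    assert g[R1] == pytest.approx(1e-5, rel=1e-9)


def test_no_wild_type_target_is_mendelian(measured_params):
    g = drive_locus_gamete_distribution((D, R2), Sex.FEMALE, measured_params)
    assert g == pytest.approx({D: 0.5, R2: 0.5})


def test_mendelian_limit(mendelian_params):
    g = drive_locus_gamete_distribution((D, W), Sex.MALE, mendelian_params)
    assert g[D] == pytest.approx(0.5) and g[W] == pytest.approx(0.5)


def test_gamete_distributions_sum_to_one_exhaustively(measured_params):
    for dg, eg, sex in itertools.product(
        all_drive_genotypes(), all_effector_genotypes(), Sex
    ):
        dip = Diplotype.from_alleles(dg, eg, sex)
        total = sum(gamete_distribution(dip, measured_params).values())
        assert abs(total - 1.0) < 1e-12


def test_invalid_parameters_rejected():
    with pytest.raises(ValueError):
        DriveParams(homing_female=1.2)
    with pytest.raises(ValueError):
        DriveParams(recombination_fraction=0.7)


# ------------------------------------------------- effector (trans) locus


def _random_diplotype(rng, sex=Sex.FEMALE):
    dg = rng.choice(len(all_drive_genotypes()))
    eg = rng.choice(len(all_effector_genotypes()))
    return Diplotype.from_alleles(
        all_drive_genotypes()[dg], all_effector_genotypes()[eg], sex
    )


def test_effector_mendelian_without_drive_allele(measured_params):
    """E homes only in the presence of Cas9 (a D allele) in trans."""
    rng = np.random.default_rng(42)
    for _ in range(200):
        dip = _random_diplotype(rng)
        if D in dip.drive_alleles:
            continue
        marg = {}
        for (da, ea), p in gamete_distribution(dip, measured_params).items():
            marg[ea] = marg.get(ea, 0.0) + p
        expected = {}
        for ea in dip.effector_alleles:
            expected[ea] = expected.get(ea, 0.0) + 0.5
        for ea, p in expected.items():
            assert marg[ea] == pytest.approx(p, abs=1e-12)


def test_effector_homing_active_with_drive_present(measured_params):
    dip = make_dip(D, W, E, C)
    marg = {}
    for (da, ea), p in gamete_distribution(dip, measured_params).items():
        marg[ea] = marg.get(ea, 0.0) + p
    assert marg[E] == pytest.approx(measured_params.effector_homing, abs=1e-12)


def test_linked_loci_bias_cotransmission():
    # D and E in cis, no homing at all: tighter linkage raises parental
    # haplotype transmission
    p_loose = DriveParams.mendelian()
    p_tight = DriveParams(
        homing_female=0.5, homing_male=0.5, uncut_fraction=1.0,
        effector_homing=0.5, effector_uncut_fraction=1.0,
        recombination_fraction=0.1,
    )
    dip = make_dip(W, R1, E, C)  # no D: both loci Mendelian, linkage only
    g_loose = gamete_distribution(dip, p_loose)
    g_tight = gamete_distribution(dip, p_tight)
    parental = (W, E)
    assert g_loose[parental] == pytest.approx(0.25, abs=1e-12)
    assert g_tight[parental] == pytest.approx(0.45, abs=1e-12)  # (1-r)/2


# ------------------------------------------------------------------ crosses


def test_cross_requires_correct_sexes(measured_params):
    mom = make_dip(W, W, sex=Sex.FEMALE)
    dad = make_dip(W, W, sex=Sex.MALE)
    with pytest.raises(ValueError):
        cross_distribution(dad, mom, measured_params)


def test_drive_homozygote_cross_gives_all_heterozygotes(measured_params):
    mom = make_dip(D, D, sex=Sex.FEMALE)
    dad = make_dip(W, W, sex=Sex.MALE)
    dist = cross_distribution(mom, dad, measured_params)
    for dip, p in dist.items():
        assert set(dip.drive_alleles) == {D, W}
    assert sum(dist.values()) == pytest.approx(1.0, abs=1e-12)


def test_measured_carrier_rates_from_hemizygous_crosses(measured_params):
    wt_dad = make_dip(W, W, sex=Sex.MALE)
    het_mom = make_dip(D, W, sex=Sex.FEMALE)
    dist = cross_distribution(het_mom, wt_dad, measured_params)
    p_carrier = sum(p for dip, p in dist.items() if D in dip.drive_alleles)
    assert p_carrier == pytest.approx(0.996, abs=1e-12)

    het_dad = make_dip(D, W, sex=Sex.MALE)
    wt_mom = make_dip(W, W, sex=Sex.FEMALE)
    dist = cross_distribution(wt_mom, het_dad, measured_params)
    p_carrier = sum(p for dip, p in dist.items() if D in dip.drive_alleles)
    assert p_carrier == pytest.approx(0.971, abs=1e-12)


def test_certain_transmission_when_both_parents_always_pass_drive():
    p = DriveParams(homing_female=1.0, homing_male=1.0, uncut_fraction=0.0)
    mom = make_dip(D, W, sex=Sex.FEMALE)
    dad = make_dip(D, W, sex=Sex.MALE)
    dist = cross_distribution(mom, dad, p)
    p_no_drive = sum(p_ for dip, p_ in dist.items() if D not in dip.drive_alleles)
    assert p_no_drive == 0.0


def test_cross_equals_brute_force_gamete_enumeration():
    """Oracle equivalence over random parameter draws: the offspring
    distribution must equal the explicit outer product of the two parental
    gamete distributions with a 1:1 sex split."""
    rng = np.random.default_rng(7)
    for _ in range(300):
        params = DriveParams(
            homing_female=rng.uniform(),
            homing_male=rng.uniform(),
            uncut_fraction=rng.uniform(),
            functional_fraction=rng.uniform(),
            effector_homing=rng.uniform(),
            effector_uncut_fraction=rng.uniform(),
            recombination_fraction=rng.uniform(0, 0.5),
        )
        mom = _random_diplotype(rng, Sex.FEMALE)
        dad = _random_diplotype(rng, Sex.MALE)
        dist = cross_distribution(mom, dad, params)
        # independent enumeration
        oracle = {}
        for hm, pm in gamete_distribution(mom, params).items():
            for hf, pf in gamete_distribution(dad, params).items():
                for sex in Sex:
                    child = Diplotype(hm, hf, sex)
                    oracle[child] = oracle.get(child, 0.0) + 0.5 * pm * pf
        assert set(dist) == set(oracle)
        for dip in oracle:
            assert abs(dist[dip] - oracle[dip]) < 1e-12


def test_gamete_marginals_match_locus_product_oracle():
    """At free recombination the two-locus gamete distribution must equal
    the product of independently derived per-locus marginals written
    straight from the inheritance rules."""
    rng = np.random.default_rng(11)
    for _ in range(300):
        params = DriveParams(
            homing_female=rng.uniform(),
            homing_male=rng.uniform(),
            uncut_fraction=rng.uniform(),
            functional_fraction=rng.uniform(),
            effector_homing=rng.uniform(),
            effector_uncut_fraction=rng.uniform(),
            recombination_fraction=0.5,
        )
        sex = Sex.FEMALE if rng.uniform() < 0.5 else Sex.MALE
        dip = _random_diplotype(rng, sex)
        d = dip.drive_alleles
        e = dip.effector_alleles
        h = params.homing(sex)
        u, f = params.uncut_fraction, params.functional_fraction
        # drive-locus marginal straight from the stated rule
        if set(d) == {D, W}:
            dm = {
                D: h,
                W: (1 - h) * u,
                R1: (1 - h) * (1 - u) * f,
                R2: (1 - h) * (1 - u) * (1 - f),
            }
        else:
            dm = {}
            for a in d:
                dm[a] = dm.get(a, 0.0) + 0.5
        hE, uE = params.effector_homing, params.effector_uncut_fraction
        if D in d and set(e) == {E, C}:
            em = {E: hE, C: (1 - hE) * uE, CR: (1 - hE) * (1 - uE)}
        else:
            em = {}
            for a in e:
                em[a] = em.get(a, 0.0) + 0.5
        g = gamete_distribution(dip, params)
        for (da, ea), p in g.items():
            assert abs(p - dm.get(da, 0.0) * em.get(ea, 0.0)) < 1e-12


# --------------------------------------------------- deterministic recursion


def test_deterministic_step_frozen_example():
    # brute-force-derived value for q_D' from q_D = 0.2, h = 0.984, u = 0
    p = DriveParams(
        homing_female=0.984, homing_male=0.984,
        uncut_fraction=0.0, functional_fraction=0.0,
    )
    q1 = deterministic_step([0.8, 0.2, 0.0, 0.0], p)
    assert q1[1] == pytest.approx(0.35488, abs=1e-12)


def test_fixation_is_absorbing(measured_params):
    q1 = deterministic_step([0.0, 1.0, 0.0, 0.0], measured_params)
    assert q1[1] == pytest.approx(1.0, abs=1e-12)


def test_neutral_mendelian_locus_is_stationary(mendelian_params):
    q = [0.5, 0.2, 0.2, 0.1]
    q1 = deterministic_step(q, mendelian_params)
    np.testing.assert_allclose(q1, q, atol=1e-12)


@pytest.mark.parametrize("u", [0.0, 1.0])
@pytest.mark.parametrize("q0", [0.01, 0.2, 0.7])
def test_monotone_spread_above_mendelian(u, q0):
    p = DriveParams(
        homing_female=0.9, homing_male=0.9,
        uncut_fraction=u, functional_fraction=0.0,
    )
    q = np.array([1.0 - q0, q0, 0.0, 0.0])
    for _ in range(30):
        q_next = deterministic_step(q, p)
        if q[0] > 1e-12:
            assert q_next[1] > q[1]
        q = q_next


def test_degenerate_weights_raise(measured_params):
    with pytest.raises(ValueError):
        deterministic_step(
            [0.8, 0.2, 0.0, 0.0],
            measured_params,
            {c: 0.0 for c in FitnessClass},
        )


def test_expected_inheritance_reports_sex_specific_rate(measured_params):
    assert expected_inheritance(measured_params, Sex.FEMALE) == 0.996
    assert expected_inheritance(measured_params, Sex.MALE) == 0.971
    assert expected_inheritance(DriveParams.mendelian(), Sex.FEMALE) == 0.5


@settings(deadline=None, max_examples=50)
@given(
    h=st.floats(0.5, 1.0),
    u=st.floats(0.0, 1.0),
    f=st.floats(0.0, 1.0),
    q0=st.floats(0.01, 0.99),
)
def test_deterministic_step_conserves_total_frequency(h, u, f, q0):
    p = DriveParams(
        homing_female=h, homing_male=h, uncut_fraction=u, functional_fraction=f
    )
    q1 = deterministic_step([1.0 - q0, q0, 0.0, 0.0], p)
    assert q1.sum() == pytest.approx(1.0, abs=1e-9)
    assert (q1 >= -1e-15).all()
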