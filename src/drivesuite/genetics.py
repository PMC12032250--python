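"""Exact two-locus inheritance engine for a homing gene drive with a
trans-acting effector.

The model tracks two unlinked-or-linked loci on the same chromosome:

* the **drive locus**, carrying one of four alleles — wild type ``W``, the
  drive construct ``D`` (a Cas9 + gRNA insertion that destroys the target
  gene), functional resistance ``R1`` (cleavage-resistant, target gene still
  works) and non-functional resistance ``R2`` (cleavage-resistant, target
  gene broken);
* the **effector locus**, carrying wild type ``C``, the anti-parasite
  effector insertion ``E`` (gRNA only — it homes exclusively when Cas9 is
  supplied in trans by a ``D`` allele elsewhere in the genome) or a
  cleavage-resistant variant ``CR``.

Homing is modelled as germline conversion in a ``D/W`` heterozygote: the
drive is transmitted with probability ``h`` (the measured inheritance rate),
and the residual ``1 - h`` of gametes carry the originally wild-type
chromosome whose allele either stayed uncut (share ``u``) or was repaired
into resistance — functional ``R1`` with share ``(1 - u) * f`` and
non-functional ``R2`` with share ``(1 - u) * (1 - f)``.  The effector locus
follows the same rule with its own ``h_E``/``u_E`` whenever the individual
carries at least one ``D``.

Fitness attaches to the drive locus only, through three classes: both
alleles functional (``W``/``R1``), one broken copy, or both copies broken
(``D``/``R2``).  ``D`` and ``R2`` are phenotypically identical, as are ``W``
and ``R1``.
"""

from __future__ import annotations

import enum
import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Tuple

import numpy as np

__all__ = [
    "DriveAllele",
    "EffectorAllele",
    "Sex",
    "FitnessClass",
    "Haplotype",
    "Diplotype",
    "DriveParams",
    "FitnessParams",
    "DRIVE_ALLELE_ORDER",
    "EFFECTOR_ALLELE_ORDER",
    "drive_fitness_class",
    "gamete_distribution",
    "drive_locus_gamete_distribution",
    "cross_distribution",
    "expected_inheritance",
    "deterministic_step",
    "all_drive_genotypes",
    "all_effector_genotypes",
]


class DriveAllele(enum.Enum):
    """Allele at the drive (target-gene) locus."""

    W = "W"
    D = "D"
    R1 = "R1"
    R2 = "R2"

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class EffectorAllele(enum.Enum):
    """Allele at the effector (payload) locus."""

    C = "C"
    E = "E"
    CR = "CR"

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Sex(enum.Enum):
    FEMALE = "female"
    MALE = "male"


class FitnessClass(enum.Enum):
    """Drive-locus fitness class: how many target-gene copies still work."""

    FUNCTIONAL = "functional"
    HETEROZYGOUS_LOF = "heterozygous_LOF"
    HOMOZYGOUS_LOF = "homozygous_LOF"


DRIVE_ALLELE_ORDER: Tuple[DriveAllele, ...] = (
    DriveAllele.W,
    DriveAllele.D,
    DriveAllele.R1,
    DriveAllele.R2,
)
EFFECTOR_ALLELE_ORDER: Tuple[EffectorAllele, ...] = (
    EffectorAllele.C,
    EffectorAllele.E,
    EffectorAllele.CR,
)

#: alleles at the drive locus that retain target-gene function
FUNCTIONAL_DRIVE = frozenset({DriveAllele.W, DriveAllele.R1})
#: loss-of-function alleles (drive insertion or broken-repair resistance)
LOF_DRIVE = frozenset({DriveAllele.D, DriveAllele.R2})

Haplotype = Tuple[DriveAllele, EffectorAllele]

_DRIVE_RANK = {a: i for i, a in enumerate(DRIVE_ALLELE_ORDER)}
_EFFECTOR_RANK = {a: i for i, a in enumerate(EFFECTOR_ALLELE_ORDER)}


def _hap_key(h: Haplotype) -> Tuple[int, int]:
    return (_DRIVE_RANK[h[0]], _EFFECTOR_RANK[h[1]])


@dataclass(frozen=True)
class Diplotype:
    """Phased two-locus genotype of one individual.

    Haplotypes are canonicalised (sorted) on construction so that a
    ``h1``/``h2`` swap yields an equal, equally-hashable object.
    """

    haplotype1: Haplotype
    haplotype2: Haplotype
    sex: Sex

    def __post_init__(self) -> None:
        h1, h2 = self.haplotype1, self.haplotype2
        if _hap_key(h1) > _hap_key(h2):
            object.__setattr__(self, "haplotype1", h2)
            object.__setattr__(self, "haplotype2", h1)

    @classmethod
    def from_alleles(
        cls,
        drive: Tuple[DriveAllele, DriveAllele],
        effector: Tuple[EffectorAllele, EffectorAllele] = (
            EffectorAllele.C,
            EffectorAllele.C,
        ),
        sex: Sex = Sex.FEMALE,
    ) -> "Diplotype":
        """Build a diplotype from per-locus allele pairs (cis phasing)."""
        return cls((drive[0], effector[0]), (drive[1], effector[1]), sex)

    @property
    def drive_alleles(self) -> Tuple[DriveAllele, DriveAllele]:
        return (self.haplotype1[0], self.haplotype2[0])

    @property
    def effector_alleles(self) -> Tuple[EffectorAllele, EffectorAllele]:
        return (self.haplotype1[1], self.haplotype2[1])

    def carries(self, allele) -> bool:
        """True if either haplotype carries ``allele`` (at either locus)."""
        return allele in (*self.drive_alleles, *self.effector_alleles)

    def label(self) -> str:
        """Compact human-readable genotype string, e.g. ``D-C/W-E``."""
        return "/".join(
            f"{h[0].value}-{h[1].value}" for h in (self.haplotype1, self.haplotype2)
        )


def _check_prob(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0) or math.isnan(value):
        raise ValueError(f"{name} must lie in [0, 1], got {value!r}")


@dataclass(frozen=True)
class DriveParams:
    """Inheritance parameters of the drive and effector constructs.

    Parameters
    ----------
    homing_female, homing_male:
        Probability that a drive/wild-type heterozygote of the given sex
        transmits the drive allele (the measured inheritance rate).  0.5 is
        Mendelian.
    uncut_fraction:
        Of the non-drive-transmitting gametes from a D/W parent, the share
        whose allele remained wild type (escaped cleavage without repair
        scarring).  0 means every residual allele becomes resistance.
    functional_fraction:
        Of newly generated resistance alleles, the share that retain target
        gene function (R1 rather than R2).  The default is the low 1:999
        split: the drive targets an ultra-conserved microRNA, so nearly
        every repair-scarred allele is expected to break it.
    effector_homing, effector_uncut_fraction:
        Same quantities for the effector locus; only active in individuals
        that carry at least one drive allele (Cas9 in trans).
    recombination_fraction:
        Recombination fraction between the two loci; 0.5 = free assortment.
    """

    homing_female: float = 0.996
    homing_male: float = 0.971
    uncut_fraction: float = 0.0
    functional_fraction: float = 0.001
    effector_homing: float = 0.95
    effector_uncut_fraction: float = 0.0
    recombination_fraction: float = 0.5

    def __post_init__(self) -> None:
        _check_prob("homing_female", self.homing_female)
        _check_prob("homing_male", self.homing_male)
        _check_prob("uncut_fraction", self.uncut_fraction)
        _check_prob("functional_fraction", self.functional_fraction)
        _check_prob("effector_homing", self.effector_homing)
        _check_prob("effector_uncut_fraction", self.effector_uncut_fraction)
        if not (0.0 <= self.recombination_fraction <= 0.5):
            raise ValueError(
                "recombination_fraction must lie in [0, 0.5], got "
                f"{self.recombination_fraction!r}"
            )

    def homing(self, sex: Sex) -> float:
        return self.homing_female if sex is Sex.FEMALE else self.homing_male

    @classmethod
    def mendelian(cls) -> "DriveParams":
        """Parameters under which both loci segregate 1:1 with no repair."""
        return cls(
            homing_female=0.5,
            homing_male=0.5,
            uncut_fraction=1.0,
            effector_homing=0.5,
            effector_uncut_fraction=1.0,
        )


def _default_class_map() -> Dict[FitnessClass, float]:
    return {c: 1.0 for c in FitnessClass}


@dataclass(frozen=True)
class FitnessParams:
    """Fitness phenotype of the drive-locus loss-of-function classes.

    ``daily_mort_mult_hom`` scales the baseline adult daily death hazard in
    LOF homozygotes; heterozygotes get half the impact by default
    (``1 + (m_hom - 1)/2``).  ``bloodmeal_mort_hom`` is the probability that
    a LOF-homozygous female dies as a consequence of each blood meal.
    ``fecundity_mult`` and ``mating_weight`` are per-fitness-class relative
    multipliers (default 1 everywhere: no fertility cost was measured for
    the modelled drive; mating weight is where reduced flight ability can be
    expressed).
    """

    daily_mort_mult_hom: float = 1.0
    daily_mort_mult_het: float | None = None
    bloodmeal_mort_hom: float = 0.0
    fecundity_mult: Mapping[FitnessClass, float] = field(
        default_factory=_default_class_map
    )
    mating_weight: Mapping[FitnessClass, float] = field(
        default_factory=_default_class_map
    )

    def __post_init__(self) -> None:
        if self.daily_mort_mult_hom < 1.0:
            raise ValueError("daily_mort_mult_hom must be >= 1 (a cost)")
        if self.daily_mort_mult_het is None:
            object.__setattr__(
                self,
                "daily_mort_mult_het",
                1.0 + (self.daily_mort_mult_hom - 1.0) / 2.0,
            )
        if self.daily_mort_mult_het < 1.0:
            raise ValueError("daily_mort_mult_het must be >= 1")
        _check_prob("bloodmeal_mort_hom", self.bloodmeal_mort_hom)
        for m in (self.fecundity_mult, self.mating_weight):
            for c in FitnessClass:
                if m.get(c, 1.0) < 0:
                    raise ValueError("class multipliers must be non-negative")

    def mortality_multiplier(self, cls: FitnessClass) -> float:
        if cls is FitnessClass.HOMOZYGOUS_LOF:
            return self.daily_mort_mult_hom
        if cls is FitnessClass.HETEROZYGOUS_LOF:
            return float(self.daily_mort_mult_het)  # type: ignore[arg-type]
        return 1.0

    def bloodmeal_mortality(self, cls: FitnessClass) -> float:
        return self.bloodmeal_mort_hom if cls is FitnessClass.HOMOZYGOUS_LOF else 0.0


def drive_fitness_class(diplotype: Diplotype) -> FitnessClass:
    """Map a genotype to its drive-locus fitness class.

    Both drive-locus alleles broken (D or R2) -> homozygous LOF; both intact
    (W or R1) -> functional; mixed -> heterozygous LOF.  The effector locus
    never enters.
    """
    n_lof = sum(a in LOF_DRIVE for a in diplotype.drive_alleles)
    if n_lof == 2:
        return FitnessClass.HOMOZYGOUS_LOF
    if n_lof == 0:
        return FitnessClass.FUNCTIONAL
    return FitnessClass.HETEROZYGOUS_LOF


def _residual_drive_split(params: DriveParams) -> Dict[DriveAllele, float]:
    u, f = params.uncut_fraction, params.functional_fraction
    return {
        DriveAllele.W: u,
        DriveAllele.R1: (1.0 - u) * f,
        DriveAllele.R2: (1.0 - u) * (1.0 - f),
    }


def _residual_effector_split(params: DriveParams) -> Dict[EffectorAllele, float]:
    u = params.effector_uncut_fraction
    return {EffectorAllele.C: u, EffectorAllele.CR: 1.0 - u}


def gamete_distribution(
    diplotype: Diplotype, params: DriveParams
) -> Dict[Haplotype, float]:
    """Exact gamete (haplotype) distribution of one parent.

    Drive locus: in a D/W heterozygote the drive chromosome is transmitted
    with probability ``h_sex``; with probability ``1 - h_sex`` the gamete
    descends from the originally wild-type chromosome whose allele is W with
    share ``u``, R1 with ``(1-u) f`` and R2 with ``(1-u)(1-f)``.  Any other
    drive genotype segregates 1:1.

    Effector locus: identical rule with ``h_E``/``u_E``, active only if the
    individual carries at least one D and is exactly E/C at the effector
    locus; otherwise 1:1.

    The two loci are coupled through the recombination fraction ``r``: the
    chromosome the gamete descends from at each locus is drawn from the
    biased per-locus transmission weights, tilted towards the parental
    (non-recombinant) configurations with weight ``1 - r`` against ``r``.
    At ``r = 0.5`` (the default) the loci assort independently and the
    per-locus marginals above hold exactly.
    """
    h1, h2 = diplotype.haplotype1, diplotype.haplotype2
    d = (h1[0], h2[0])
    e = (h1[1], h2[1])

    # per-chromosome transmission weight and residual replacement at the
    # drive locus
    drive_w = [0.5, 0.5]
    drive_residual = [None, None]  # replacement split if that chromosome is chosen
    if set(d) == {DriveAllele.D, DriveAllele.W}:
        h = params.homing(diplotype.sex)
        i_d = 0 if d[0] is DriveAllele.D else 1
        drive_w[i_d] = h
        drive_w[1 - i_d] = 1.0 - h
        drive_residual[1 - i_d] = _residual_drive_split(params)

    eff_w = [0.5, 0.5]
    eff_residual = [None, None]
    if DriveAllele.D in d and set(e) == {EffectorAllele.E, EffectorAllele.C}:
        hE = params.effector_homing
        i_e = 0 if e[0] is EffectorAllele.E else 1
        eff_w[i_e] = hE
        eff_w[1 - i_e] = 1.0 - hE
        eff_residual[1 - i_e] = _residual_effector_split(params)

    r = params.recombination_fraction
    # joint ancestry weights: parental configurations (i == j) tilted by 1-r
    joint = np.empty((2, 2))
    for i in range(2):
        for j in range(2):
            base = (1.0 - r) if i == j else r
            joint[i, j] = 2.0 * base * drive_w[i] * eff_w[j]
    joint /= joint.sum()

    out: Dict[Haplotype, float] = {}
    for i in range(2):
        for j in range(2):
            p_ij = joint[i, j]
            if p_ij == 0.0:
                continue
            d_split = (
                drive_residual[i] if drive_residual[i] is not None else {d[i]: 1.0}
            )
            e_split = eff_residual[j] if eff_residual[j] is not None else {e[j]: 1.0}
            for da, pd in d_split.items():
                if pd == 0.0:
                    continue
                for ea, pe in e_split.items():
                    if pe == 0.0:
                        continue
                    hap = (da, ea)
                    out[hap] = out.get(hap, 0.0) + p_ij * pd * pe
    return out


def drive_locus_gamete_distribution(
    drive_genotype: Tuple[DriveAllele, DriveAllele],
    sex: Sex,
    params: DriveParams,
) -> Dict[DriveAllele, float]:
    """Drive-locus marginal of :func:`gamete_distribution` (effector C/C)."""
    dip = Diplotype.from_alleles(drive_genotype, sex=sex)
    marg: Dict[DriveAllele, float] = {}
    for (da, _ea), p in gamete_distribution(dip, params).items():
        marg[da] = marg.get(da, 0.0) + p
    return marg


def cross_distribution(
    mother: Diplotype, father: Diplotype, params: DriveParams
) -> Dict[Diplotype, float]:
    """Offspring diplotype distribution of one mating pair.

    The outer product of the maternal and paternal gamete distributions;
    offspring sex is assigned 1:1 (autosomal model).
    """
    if mother.sex is not Sex.FEMALE:
        raise ValueError("mother must be female")
    if father.sex is not Sex.MALE:
        raise ValueError("father must be male")
    gm = gamete_distribution(mother, params)
    gf = gamete_distribution(father, params)
    out: Dict[Diplotype, float] = {}
    for (hm, pm), (hf, pf) in itertools.product(gm.items(), gf.items()):
        for sex in (Sex.FEMALE, Sex.MALE):
            child = Diplotype(hm, hf, sex)
            out[child] = out.get(child, 0.0) + 0.5 * pm * pf
    return out


def expected_inheritance(params: DriveParams, sex: Sex) -> float:
    """Probability that a D/W parent of the given sex transmits D."""
    return params.homing(sex)


def all_drive_genotypes() -> Tuple[Tuple[DriveAllele, DriveAllele], ...]:
    """The 10 unordered drive-locus genotypes."""
    return tuple(
        itertools.combinations_with_replacement(DRIVE_ALLELE_ORDER, 2)
    )


def all_effector_genotypes() -> Tuple[Tuple[EffectorAllele, EffectorAllele], ...]:
    """The 6 unordered effector-locus genotypes."""
    return tuple(
        itertools.combinations_with_replacement(EFFECTOR_ALLELE_ORDER, 2)
    )


def deterministic_step(
    allele_freqs: Iterable[float],
    params: DriveParams,
    genotype_weights: Mapping[FitnessClass, float] | None = None,
) -> np.ndarray:
    """One generation of the infinite-population drive-locus recursion.

    ``allele_freqs`` is the frequency vector over (W, D, R1, R2).  Genotypes
    form at Hardy-Weinberg proportions, are weighted by the relative weight
    of their fitness class (viability/mating success lumped together), and
    contribute gametes through the homing rule; mothers use the female
    homing rate and fathers the male rate, and the next generation's allele
    frequencies are the average of the two gamete pools.
    """
    q = np.asarray(list(allele_freqs), dtype=float)
    if q.shape != (4,):
        raise ValueError("allele_freqs must have 4 entries (W, D, R1, R2)")
    if np.any(q < -1e-12):
        raise ValueError("allele frequencies must be non-negative")
    if abs(q.sum() - 1.0) > 1e-9:
        raise ValueError("allele frequencies must sum to 1")
    if genotype_weights is None:
        genotype_weights = {c: 1.0 for c in FitnessClass}

    pools = []
    for sex in (Sex.FEMALE, Sex.MALE):
        pool = np.zeros(4)
        total = 0.0
        for i, j in itertools.combinations_with_replacement(range(4), 2):
            geno = (DRIVE_ALLELE_ORDER[i], DRIVE_ALLELE_ORDER[j])
            freq = q[i] * q[j] * (2.0 if i != j else 1.0)
            if freq == 0.0:
                continue
            cls = drive_fitness_class(Diplotype.from_alleles(geno, sex=sex))
            w = genotype_weights.get(cls, 1.0) * freq
            if w == 0.0:
                continue
            total += w
            for allele, p in drive_locus_gamete_distribution(
                geno, sex, params
            ).items():
                pool[DRIVE_ALLELE_ORDER.index(allele)] += w * p
        if total <= 0.0:
            raise ValueError(
                "degenerate population: all genotype weights are zero"
            )
        pools.append(pool / total)
    out = 0.5 * (pools[0] + pools[1])
    return out / out.sum()
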