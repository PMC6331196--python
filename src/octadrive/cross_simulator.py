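"""Generative model of a *Zymoseptoria tritici* cross and its octads.

One sexual cycle is modelled end to end: the two parents are assigned female
and male roles (the female donates the mitochondria), the diploid zygote
receives paired homologs for chromosomes present in both parents and single
unpaired copies for chromosomes unique to one parent, and a single meiosis
followed by a post-meiotic mitosis yields an ascus of eight ascospores -- an
*octad* of four genetically identical twin pairs.

Five transmission mechanisms can act on the supernumerary chromosomes:

``mendelian``
    No amplification.  Paired homologs disjoin at meiosis I; an unpaired
    chromosome migrates to a uniformly random pole, so exactly four of the
    eight spores inherit it (the 4:0 expectation).
``female_drive``
    Each unpaired chromosome inherited from the *female* parent is duplicated
    once meiosis starts (with per-chromosome penetrance), so its two copies
    behave as a pair and every meiotic product -- hence all eight spores --
    receives one copy (8:0).
``premeiotic_amplification``
    Every female supernumerary chromosome is duplicated before karyogamy.
    By default each extra copy of a *paired* chromosome is subsequently lost
    before meiosis I, which makes the outcome indistinguishable from
    ``female_drive``; with ``premeiotic_copy_loss=False`` the zygote stays
    trisomic for paired chromosomes and disomic ascospores appear.
``preferential_segregation``
    Unpaired chromosomes are sent to a designated pole with probability
    ``preferential_bias``.  This biases *which* spores carry the chromosome
    but can never produce more than four carriers.
``spore_killing``
    Segregation is Mendelian, but every ascospore lacking the designated
    killer chromosome is destroyed, leaving an incomplete ascus.

Two nuisance processes apply to supernumerary chromosomes only: *loss*
(per parental chromosome instance, one chromatid is dropped at meiosis I,
removing the chromosome from one meiotic product and its twin spores) and
*non-disjunction* (for a paired chromosome, a single chromatid migrates to
the wrong pole, producing two disomic spores with one copy from each parent
and two nullisomic spores; for an unpaired chromosome, both sister chromatids
enter one meiosis-II product, producing a same-parent two-copy spore pair).

Core markers always segregate 4:4 and the mitochondrial haplotype of the
female parent is transmitted to every spore.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigError, IncompatibleCrossError, NotInCrossError
from .strains import CORE_MARKERS, SUPERNUMERARY_CHROMOSOMES, ParentalStrain

MECHANISMS: tuple[str, ...] = (
    "mendelian",
    "female_drive",
    "premeiotic_amplification",
    "preferential_segregation",
    "spore_killing",
)


# ---------------------------------------------------------------------------
# configuration and cross layout
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PairingMap:
    """Partition of the zygote's supernumerary chromosomes by pairing state."""

    paired: frozenset[str]
    unpaired_from_p1: frozenset[str]
    unpaired_from_p2: frozenset[str]

    def chromosomes(self) -> frozenset[str]:
        return self.paired | self.unpaired_from_p1 | self.unpaired_from_p2

    def status(self, chromosome: str) -> str:
        """``"paired"``, ``"unpaired_p1"`` or ``"unpaired_p2"``."""
        if chromosome in self.paired:
            return "paired"
        if chromosome in self.unpaired_from_p1:
            return "unpaired_p1"
        if chromosome in self.unpaired_from_p2:
            return "unpaired_p2"
        raise NotInCrossError(f"{chromosome} is not in this cross")

    def owner_index(self, chromosome: str) -> int | None:
        """Index (0/1) of the only parent carrying an unpaired chromosome."""
        status = self.status(chromosome)
        if status == "paired":
            return None
        return 0 if status == "unpaired_p1" else 1

    def unpaired_of(self, parent_index: int) -> frozenset[str]:
        return self.unpaired_from_p1 if parent_index == 0 else self.unpaired_from_p2


def build_cross(parent1: ParentalStrain, parent2: ParentalStrain) -> PairingMap:
    """Partition the parents' supernumerary complements for the zygote.

    Raises :class:`IncompatibleCrossError` if the parents share a mating type
    (the fungus is heterothallic) and :class:`ConfigError` for unknown
    chromosome identifiers.  Chromosomes absent from both parents never
    appear in the returned map.
    """
    if parent1.mating_type == parent2.mating_type:
        raise IncompatibleCrossError(
            f"incompatible cross: {parent1.name} and {parent2.name} are both "
            f"{parent1.mating_type}"
        )
    c1, c2 = parent1.supernumerary_complement, parent2.supernumerary_complement
    return PairingMap(
        paired=frozenset(c1 & c2),
        unpaired_from_p1=frozenset(c1 - c2),
        unpaired_from_p2=frozenset(c2 - c1),
    )


@dataclass(frozen=True)
class CrossConfig:
    """Full specification of a simulated crossing experiment.

    ``drive_penetrance`` may be a single probability or a per-chromosome
    mapping (unlisted chromosomes default to 1.0); this is how the chr14
    exception -- the one supernumerary chromosome without observable drive --
    is expressed, e.g. ``{"chr14": 0.0}``.
    """

    parent1: ParentalStrain
    parent2: ParentalStrain
    mechanism: str = "mendelian"
    loss_rate: float = 0.0
    nondisjunction_rate: float = 0.0
    preferential_bias: float = 1.0
    drive_penetrance: "float | Mapping[str, float]" = 1.0
    density_exponent: float = 1.0
    n_asci: int = 0
    seed: int = 0
    killer_chromosome: str | None = None
    premeiotic_copy_loss: bool = True

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise ConfigError(f"unknown mechanism {self.mechanism!r}")
        for name in ("loss_rate", "nondisjunction_rate"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {value}")
        if not 0.5 <= self.preferential_bias <= 1.0:
            raise ConfigError(
                f"preferential_bias must lie in [0.5, 1], got {self.preferential_bias}"
            )
        if not self.density_exponent > 0:
            raise ConfigError("density_exponent must be positive")
        if self.n_asci < 0:
            raise ConfigError("n_asci must be non-negative")
        if isinstance(self.drive_penetrance, Mapping):
            for chrom, value in self.drive_penetrance.items():
                if not 0.0 <= value <= 1.0:
                    raise ConfigError(
                        f"drive_penetrance[{chrom!r}] must lie in [0, 1]"
                    )
        elif not 0.0 <= self.drive_penetrance <= 1.0:
            raise ConfigError("drive_penetrance must lie in [0, 1]")
        if self.mechanism == "spore_killing" and self.killer_chromosome is None:
            raise ConfigError(
                "mechanism 'spore_killing' needs a killer_chromosome"
            )
        # mating-type compatibility is validated here as well so that an
        # invalid cross fails as early as possible
        build_cross(self.parent1, self.parent2)

    def penetrance(self, chromosome: str) -> float:
        if isinstance(self.drive_penetrance, Mapping):
            return float(self.drive_penetrance.get(chromosome, 1.0))
        return float(self.drive_penetrance)

    @property
    def parents(self) -> tuple[ParentalStrain, ParentalStrain]:
        return (self.parent1, self.parent2)


# ---------------------------------------------------------------------------
# sexual roles
# ---------------------------------------------------------------------------


def female_probability(density1: float, density2: float, exponent: float = 1.0) -> float:
    """Probability that parent 1 takes the female role.

    The model is ``P(parent1 female) = d2**a / (d1**a + d2**a)``: the partner
    inoculated at the lower density tends to develop the ascogonium and act
    as the female, with equality giving 1/2.
    """
    if not (density1 > 0 and density2 > 0):
        raise ConfigError("densities must be positive")
    if not exponent > 0:
        raise ConfigError("exponent must be positive")
    w1, w2 = density1**exponent, density2**exponent
    return w2 / (w1 + w2)


def assign_sexual_roles(
    density1: float,
    density2: float,
    exponent: float,
    rng: np.random.Generator,
) -> tuple[int, int]:
    """Draw the female/male roles; returns ``(female_index, male_index)``.

    Indices are 0 for parent 1 and 1 for parent 2.
    """
    p1_female = female_probability(density1, density2, exponent)
    if rng.random() < p1_female:
        return 0, 1
    return 1, 0


# ---------------------------------------------------------------------------
# octad data model
# ---------------------------------------------------------------------------


@dataclass
class Ascospore:
    """One ascospore: marker genotype plus per-parent chromosome copy numbers."""

    spore_id: str
    twin_id: str
    core_alleles: dict[str, str]
    mito: str
    copies: dict[str, tuple[int, int]]

    def total_copies(self, chromosome: str) -> int:
        c1, c2 = self.copies.get(chromosome, (0, 0))
        return c1 + c2

    def has(self, chromosome: str) -> bool:
        return self.total_copies(chromosome) > 0


@dataclass
class Octad:
    """The (up to) eight ascospores of one ascus.

    ``spores`` holds fewer than eight entries only when spore killing removed
    spores.  ``parent1``/``parent2`` record the parent order used in the
    ``copies`` tuples of every spore.
    """

    ascus_id: str
    spores: list[Ascospore]
    female_parent: str
    mechanism: str
    parent1: str
    parent2: str

    def carrier_count(self, chromosome: str, parent_index: int | None = None) -> int:
        """Number of spores with at least one copy (optionally of one parent)."""
        if parent_index is None:
            return sum(s.has(chromosome) for s in self.spores)
        return sum(
            s.copies.get(chromosome, (0, 0))[parent_index] >= 1 for s in self.spores
        )


# ---------------------------------------------------------------------------
# meiosis
# ---------------------------------------------------------------------------


def _zygote_instances(
    pairing: PairingMap,
    female: int,
    config: CrossConfig,
    rng: np.random.Generator,
) -> dict[str, list[int]]:
    """Owner indices of every chromosome instance entering meiosis.

    The mechanism-specific amplification step acts here, before meiosis I.
    """
    instances: dict[str, list[int]] = {}
    for chrom in sorted(pairing.paired):
        instances[chrom] = [0, 1]
    for chrom in sorted(pairing.unpaired_from_p1):
        instances[chrom] = [0]
    for chrom in sorted(pairing.unpaired_from_p2):
        instances[chrom] = [1]

    if config.mechanism == "female_drive":
        for chrom in sorted(pairing.unpaired_of(female)):
            if rng.random() < config.penetrance(chrom):
                instances[chrom].append(female)
    elif config.mechanism == "premeiotic_amplification":
        # every female supernumerary chromosome is duplicated in the
        # ascogonium, before karyogamy
        for chrom in sorted(instances):
            if female in instances[chrom]:
                instances[chrom].append(female)
        if config.premeiotic_copy_loss:
            # the surplus copy of each *paired* chromosome is dropped again
            # before meiosis I, restoring a normally paired zygote
            for chrom in sorted(pairing.paired):
                instances[chrom].remove(female)
    return instances


def _segregate_chromosome(
    owners: Sequence[int],
    rng: np.random.Generator,
    config: CrossConfig,
    unpaired_bias: bool,
) -> list[list[int]]:
    """Push one chromosome's instances through meiosis I, II and loss.

    Returns the owner indices of the copies received by each of the four
    meiotic products (products 0 and 1 descend from one meiosis-I pole,
    products 2 and 3 from the other).
    """
    # --- meiosis I: pole assignment -------------------------------------
    # each entry: [owner, n_chromatids, pole, mii_nondisjunction]
    inst: list[list] = []
    if len(owners) == 2:
        orientation = int(rng.integers(2))
        inst.append([owners[0], 2, orientation, False])
        inst.append([owners[1], 2, 1 - orientation, False])
    elif len(owners) == 1:
        if unpaired_bias:
            pole = 0 if rng.random() < config.preferential_bias else 1
        else:
            pole = int(rng.integers(2))
        inst.append([owners[0], 2, pole, False])
    elif len(owners) == 3:
        # trisomic zygote: the two same-parent copies pair, the odd copy
        # behaves as unpaired
        dup_owner = owners[0] if owners.count(owners[0]) == 2 else owners[-1]
        odd_owner = [o for o in owners if o != dup_owner] or [dup_owner]
        orientation = int(rng.integers(2))
        inst.append([dup_owner, 2, orientation, False])
        inst.append([dup_owner, 2, 1 - orientation, False])
        remaining = list(owners)
        remaining.remove(dup_owner)
        remaining.remove(dup_owner)
        for owner in remaining:
            inst.append([owner, 2, int(rng.integers(2)), False])
    else:  # pragma: no cover - zygotes never carry >3 copies in this model
        raise ConfigError(f"unsupported instance count {len(owners)}")

    # --- chromosome loss (one chromatid per affected instance) ----------
    if config.loss_rate > 0:
        for entry in inst:
            if rng.random() < config.loss_rate:
                entry[1] -= 1

    # --- non-disjunction -------------------------------------------------
    strays: list[tuple[int, int]] = []  # (owner, pole)
    if config.nondisjunction_rate > 0 and rng.random() < config.nondisjunction_rate:
        if len(inst) >= 2:
            # paired configuration: one chromatid of a random homolog
            # migrates with the other homolog at meiosis I
            candidates = [e for e in inst if e[1] == 2]
            if candidates:
                entry = candidates[int(rng.integers(len(candidates)))]
                entry[1] -= 1
                strays.append((entry[0], 1 - entry[2]))
        else:
            # unpaired chromosome: both sister chromatids enter the same
            # meiosis-II product
            inst[0][3] = True

    # --- meiosis II: chromatid disjunction -------------------------------
    products: list[list[int]] = [[], [], [], []]
    for owner, n_chromatids, pole, mii_nd in inst:
        base = 2 * pole
        if n_chromatids == 2 and mii_nd:
            target = base + int(rng.integers(2))
            products[target].extend([owner, owner])
        elif n_chromatids == 2:
            products[base].append(owner)
            products[base + 1].append(owner)
        elif n_chromatids == 1:
            products[base + int(rng.integers(2))].append(owner)
    for owner, pole in strays:
        products[2 * pole + int(rng.integers(2))].append(owner)
    return products


def _core_marker_products(rng: np.random.Generator) -> list[dict[str, int]]:
    """Assign each core marker's parental alleles to the four meiotic products.

    Every marker splits the products 2:2 (Mendelian 4:4 at the spore level);
    the chromatid arrangement is drawn uniformly from the six 2-of-4 patterns,
    which mixes first- and second-division segregation.  The draw is
    conditioned on the four products being pairwise distinct over the full
    six-marker panel so that twin pairs are unambiguous, mirroring the
    resolving power the marker panel was chosen for.
    """
    while True:
        assignment: dict[str, tuple[int, ...]] = {}
        for marker in CORE_MARKERS:
            assignment[marker] = tuple(rng.choice(4, size=2, replace=False))
        profiles = [
            tuple(0 if prod in assignment[m] else 1 for m in CORE_MARKERS)
            for prod in range(4)
        ]
        if len(set(profiles)) == 4:
            return [
                {m: (0 if prod in assignment[m] else 1) for m in CORE_MARKERS}
                for prod in range(4)
            ]


def simulate_octad(
    pairing: PairingMap,
    female: int,
    config: CrossConfig,
    rng: np.random.Generator,
    ascus_id: str = "A0001",
) -> Octad:
    """Simulate one meiosis and its post-meiotic mitosis.

    ``female`` is the index (0/1) of the parent acting as the female; all
    spores receive that parent's mitochondrial haplotype.  The four meiotic
    products are each duplicated into a pair of identical twin spores; spore
    ``2j``/``2j+1`` descend from product ``j``.
    """
    parents = config.parents
    if config.mechanism == "spore_killing":
        if config.killer_chromosome not in pairing.chromosomes():
            raise ConfigError(
                f"killer chromosome {config.killer_chromosome!r} is not in the cross"
            )

    instances = _zygote_instances(pairing, female, config, rng)
    product_copies: dict[str, list[list[int]]] = {}
    for chrom in sorted(instances):
        unpaired_bias = (
            config.mechanism == "preferential_segregation"
            and len(instances[chrom]) == 1
        )
        product_copies[chrom] = _segregate_chromosome(
            instances[chrom], rng, config, unpaired_bias
        )

    marker_products = _core_marker_products(rng)
    mito = parents[female].mito_haplotype

    spores: list[Ascospore] = []
    for product in range(4):
        twin_id = f"{ascus_id}.t{product + 1}"
        core = {
            marker: parents[idx].core_marker_alleles[marker]
            for marker, idx in marker_products[product].items()
        }
        # every supernumerary chromosome is scored in every spore; those
        # absent from both parents are simply (0, 0) -- this keeps on-disk
        # tables rectangular and round-trips lossless
        copies = {
            chrom: (
                (
                    product_copies[chrom][product].count(0),
                    product_copies[chrom][product].count(1),
                )
                if chrom in product_copies
                else (0, 0)
            )
            for chrom in SUPERNUMERARY_CHROMOSOMES
        }
        for half in range(2):
            spores.append(
                Ascospore(
                    spore_id=f"{ascus_id}.s{2 * product + half + 1}",
                    twin_id=twin_id,
                    core_alleles=dict(core),
                    mito=mito,
                    copies=dict(copies),
                )
            )

    if config.mechanism == "spore_killing":
        killer = config.killer_chromosome
        spores = [s for s in spores if s.has(killer)]

    return Octad(
        ascus_id=ascus_id,
        spores=spores,
        female_parent=parents[female].name,
        mechanism=config.mechanism,
        parent1=parents[0].name,
        parent2=parents[1].name,
    )


def simulate_experiment(config: CrossConfig) -> list[Octad]:
    """Simulate ``config.n_asci`` octads with independently drawn sexual roles.

    Each ascus runs on its own random substream derived from the master seed
    by a counter (``SeedSequence(seed, spawn_key=(i,))``), so changing
    ``n_asci`` never perturbs earlier asci and reruns are fully reproducible.
    """
    pairing = build_cross(config.parent1, config.parent2)
    octads: list[Octad] = []
    for i in range(config.n_asci):
        rng = np.random.default_rng(
            np.random.SeedSequence(config.seed, spawn_key=(i,))
        )
        female, _male = assign_sexual_roles(
            config.parent1.density,
            config.parent2.density,
            config.density_exponent,
            rng,
        )
        octads.append(
            simulate_octad(pairing, female, config, rng, ascus_id=f"A{i + 1:05d}")
        )
    return octads


def with_fixed_female(
    config: CrossConfig, female: int, ascus_ids: Sequence[str] | None = None
) -> list[Octad]:
    """Like :func:`simulate_experiment` but with the female role pinned.

    Useful for conditioning analyses on the mitochondrial genotype (e.g. the
    drive signature is defined given which parent donated the mitochondria).
    """
    pairing = build_cross(config.parent1, config.parent2)
    octads = []
    for i in range(config.n_asci):
        rng = np.random.default_rng(
            np.random.SeedSequence(config.seed, spawn_key=(i,))
        )
        ascus_id = ascus_ids[i] if ascus_ids is not None else f"A{i + 1:05d}"
        octads.append(simulate_octad(pairing, female, config, rng, ascus_id=ascus_id))
    return octads
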