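"""Parental strains of the *Zymoseptoria tritici* crossing panel.

*Z. tritici* is a heterothallic, haploid ascomycete: a cross requires one
*mat1-1* and one *mat1-2* partner.  The reference isolate IPO323 carries the
full set of eight supernumerary (accessory) chromosomes, chr14..chr21; the
field isolate IPO94269 carries homologs of chr14, chr15, chr16, chr17, chr19
and chr21 but lacks chr18 and chr20.  Whole-chromosome deletion derivatives of
IPO323 (here ``IPO323dchrNN``) remove one supernumerary chromosome each, so
that a chosen chromosome can be placed in the zygote in an unpaired state.

Six segregating PCR markers on the essential (core) chromosomes distinguish
the two parental genomes in every ascospore; their allele labels below are the
diagnostic product sizes (bp) of the marker assays, and the mating-type locus
doubles as the sixth marker.  A mitochondrial marker identifies which parent
acted as the female (mitochondria are inherited uniparentally from the female
partner).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .errors import ConfigError

#: The six core-chromosome markers, in canonical column order.
CORE_MARKERS: tuple[str, ...] = (
    "mat",
    "m11O21",
    "m04L20",
    "caa0002",
    "ggc001",
    "ac0001",
)

#: The eight supernumerary chromosomes of the IPO323 reference karyotype.
SUPERNUMERARY_CHROMOSOMES: tuple[str, ...] = tuple(
    f"chr{n}" for n in range(14, 22)
)

_IPO323_ALLELES: dict[str, str] = {
    "mat": "mat1-1",
    "m11O21": "205",
    "m04L20": "192",
    "caa0002": "412",
    "ggc001": "254",
    "ac0001": "187",
}

_IPO94269_ALLELES: dict[str, str] = {
    "mat": "mat1-2",
    "m11O21": "199",
    "m04L20": "199",
    "caa0002": "396",
    "ggc001": "234",
    "ac0001": "173",
}

#: Default co-inoculation density (cells/mL) used in the crossing experiments.
DEFAULT_DENSITY = 1e7


@dataclass(frozen=True)
class ParentalStrain:
    """One haploid parent of a cross.

    Parameters
    ----------
    name
        Strain identifier, e.g. ``"IPO323"``.
    mating_type
        Either ``"mat1-1"`` or ``"mat1-2"``; the two parents of a cross must
        differ.
    supernumerary_complement
        Subset of :data:`SUPERNUMERARY_CHROMOSOMES` carried by the strain.
    core_marker_alleles
        Mapping of every marker in :data:`CORE_MARKERS` to this strain's
        allele label.
    mito_haplotype
        Label of the strain's mitochondrial marker allele.
    density
        Inoculation density in cells/mL (must be positive); lower-density
        partners tend to take the female role.
    """

    name: str
    mating_type: str
    supernumerary_complement: frozenset[str]
    core_marker_alleles: Mapping[str, str]
    mito_haplotype: str
    density: float = DEFAULT_DENSITY

    def __post_init__(self) -> None:
        if self.mating_type not in ("mat1-1", "mat1-2"):
            raise ConfigError(
                f"unknown mating type {self.mating_type!r} for {self.name}"
            )
        unknown = set(self.supernumerary_complement) - set(
            SUPERNUMERARY_CHROMOSOMES
        )
        if unknown:
            raise ConfigError(
                f"unknown chromosome identifier(s) {sorted(unknown)} in the "
                f"complement of {self.name}; expected a subset of "
                f"{SUPERNUMERARY_CHROMOSOMES[0]}..{SUPERNUMERARY_CHROMOSOMES[-1]}"
            )
        missing = set(CORE_MARKERS) - set(self.core_marker_alleles)
        if missing:
            raise ConfigError(
                f"strain {self.name} lacks core-marker alleles for {sorted(missing)}"
            )
        if not self.density > 0:
            raise ConfigError(f"density of {self.name} must be positive")
        # Freeze the mutable containers handed in by the caller.
        object.__setattr__(
            self, "supernumerary_complement", frozenset(self.supernumerary_complement)
        )
        object.__setattr__(
            self, "core_marker_alleles", dict(self.core_marker_alleles)
        )


def ipo323(density: float = DEFAULT_DENSITY) -> ParentalStrain:
    """The *mat1-1* reference isolate with all eight supernumerary chromosomes."""
    return ParentalStrain(
        name="IPO323",
        mating_type="mat1-1",
        supernumerary_complement=frozenset(SUPERNUMERARY_CHROMOSOMES),
        core_marker_alleles=_IPO323_ALLELES,
        mito_haplotype="mtIPO323",
        density=density,
    )


def ipo94269(density: float = DEFAULT_DENSITY) -> ParentalStrain:
    """The *mat1-2* isolate lacking homologs of chr18 and chr20."""
    return ParentalStrain(
        name="IPO94269",
        mating_type="mat1-2",
        supernumerary_complement=frozenset(
            {"chr14", "chr15", "chr16", "chr17", "chr19", "chr21"}
        ),
        core_marker_alleles=_IPO94269_ALLELES,
        mito_haplotype="mtIPO94269",
        density=density,
    )


def ipo323_deletion(chromosome: str, density: float = DEFAULT_DENSITY) -> ParentalStrain:
    """An isogenic IPO323 derivative lacking one supernumerary chromosome.

    ``chromosome`` must be one of chr14..chr21.  The strain is named
    ``IPO323dchrNN`` (``d`` for deletion).
    """
    if chromosome not in SUPERNUMERARY_CHROMOSOMES:
        raise ConfigError(
            f"cannot delete {chromosome!r}: not a supernumerary chromosome"
        )
    base = ipo323(density=density)
    return ParentalStrain(
        name=f"IPO323d{chromosome}",
        mating_type=base.mating_type,
        supernumerary_complement=base.supernumerary_complement - {chromosome},
        core_marker_alleles=base.core_marker_alleles,
        mito_haplotype=base.mito_haplotype,
        density=density,
    )


def resolve_strain(spec: "str | Mapping | ParentalStrain") -> ParentalStrain:
    """Resolve a strain reference from configuration.

    Accepts a :class:`ParentalStrain`, a built-in strain name (``IPO323``,
    ``IPO94269`` or ``IPO323dchrNN``; the deletion may also be written with a
    delta character), or a mapping with the full set of strain fields.
    Mappings may also use ``{"name": "IPO323dchr19", "density": 1e5}`` to
    tweak a built-in strain's density.
    """
    if isinstance(spec, ParentalStrain):
        return spec
    if isinstance(spec, str):
        return _builtin(spec, DEFAULT_DENSITY)
    if isinstance(spec, Mapping):
        fields = dict(spec)
        name = fields.get("name")
        if name is None:
            raise ConfigError("strain mapping needs at least a 'name' field")
        density = float(fields.pop("density", DEFAULT_DENSITY))
        if set(fields) <= {"name"}:
            return _builtin(str(name), density)
        return ParentalStrain(
            name=str(name),
            mating_type=str(fields["mating_type"]),
            supernumerary_complement=frozenset(fields["supernumerary_complement"]),
            core_marker_alleles=dict(fields["core_marker_alleles"]),
            mito_haplotype=str(fields["mito_haplotype"]),
            density=density,
        )
    raise ConfigError(f"cannot interpret strain reference {spec!r}")


def _builtin(name: str, density: float) -> ParentalStrain:
    canonical = name.replace("Δ", "d").replace("∆", "d").replace("Delta", "d")
    canonical = canonical.replace(" ", "")
    if canonical == "IPO323":
        return ipo323(density=density)
    if canonical == "IPO94269":
        return ipo94269(density=density)
    if canonical.startswith("IPO323d"):
        return ipo323_deletion(canonical[len("IPO323d"):], density=density)
    raise ConfigError(f"unknown built-in strain name {name!r}")
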