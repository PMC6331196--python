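"""Verification that eight isolated ascospores form one true octad.

Because the post-meiotic mitosis duplicates each meiotic product, a correctly
isolated ascus consists of four pairs of genetically identical twin spores,
and each of the six core-chromosome markers must segregate exactly 4:4.
An eight-spore group is accepted only if *both* conditions hold: a group is
rejected when any spore has no twin or more than one twin even if every
marker shows a clean 4:4 ratio.  Supernumerary chromosomes and the
mitochondrial marker are never used for the ratio test (supernumerary
chromosomes are lost too often to be diagnostic, and the mitochondria are
uniparental, hence constant within an ascus).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .cross_simulator import Octad
from .errors import FormatError
from .strains import CORE_MARKERS

#: Failure codes emitted by :func:`verify_ascus`.
FAILURE_CODES = ("wrong_spore_count", "marker_ratio", "twin_missing", "twin_multiple")


@dataclass
class VerificationResult:
    """Outcome of octad verification for one candidate ascus."""

    ascus_id: str
    valid: bool
    marker_ratios: dict[str, tuple[int, ...]]
    twin_assignment: dict[str, str]
    failure_reasons: list[str] = field(default_factory=list)


def _profile(spore, markers: tuple[str, ...]):
    try:
        profile = tuple(
            spore.core_alleles[m] for m in markers if m != "mito"
        )
    except KeyError as exc:  # pragma: no cover - re-raised with context below
        raise FormatError(f"spore {spore.spore_id} lacks marker {exc}") from exc
    if "mito" in markers:
        profile += (spore.mito,)
    return profile


def find_twins(octad: Octad, marker_set: str = "core_plus_mito") -> dict[str, str]:
    """Pair spores with identical profiles over the chosen marker set.

    ``marker_set`` is ``"core_only"`` (the six core markers) or
    ``"core_plus_mito"`` (default; the mitochondrial marker is constant
    within a genuine ascus so it never splits true twins, but it separates
    spores accidentally mixed in from another cross direction).

    Returns a mapping ``spore_id -> twin spore_id``, with the sentinel values
    ``"none"`` (no identical partner) and ``"multiple"`` (more than one).
    """
    if not octad.spores:
        raise FormatError("cannot search for twins in an empty ascus")
    if marker_set == "core_only":
        markers: tuple[str, ...] = CORE_MARKERS
    elif marker_set == "core_plus_mito":
        markers = CORE_MARKERS + ("mito",)
    else:
        raise FormatError(f"unknown marker_set {marker_set!r}")

    for spore in octad.spores:
        missing = [m for m in CORE_MARKERS if m not in spore.core_alleles]
        if missing:
            raise FormatError(
                f"spore {spore.spore_id} lacks core marker(s) {missing}"
            )

    groups: dict[tuple, list[str]] = {}
    for spore in octad.spores:
        groups.setdefault(_profile(spore, markers), []).append(spore.spore_id)

    assignment: dict[str, str] = {}
    for members in groups.values():
        if len(members) == 1:
            assignment[members[0]] = "none"
        elif len(members) == 2:
            assignment[members[0]] = members[1]
            assignment[members[1]] = members[0]
        else:
            for spore_id in members:
                assignment[spore_id] = "multiple"
    return assignment


def verify_ascus(octad: Octad) -> VerificationResult:
    """Apply the full octad acceptance rule to one candidate ascus.

    Valid iff the ascus holds exactly eight spores, every core marker splits
    4:4, and the spores form exactly four twin pairs.  All violated rules are
    reported, not just the first.
    """
    reasons: list[str] = []
    if len(octad.spores) != 8:
        reasons.append("wrong_spore_count")

    marker_ratios: dict[str, tuple[int, ...]] = {}
    if octad.spores:
        for marker in CORE_MARKERS:
            counts: dict[str, int] = {}
            for spore in octad.spores:
                if marker not in spore.core_alleles:
                    raise FormatError(
                        f"spore {spore.spore_id} lacks core marker {marker!r}"
                    )
                allele = spore.core_alleles[marker]
                counts[allele] = counts.get(allele, 0) + 1
            ratio = tuple(counts[a] for a in sorted(counts))
            marker_ratios[marker] = ratio
            if sorted(ratio) != [4, 4]:
                if "marker_ratio" not in reasons:
                    reasons.append("marker_ratio")
        twins = find_twins(octad)
        if any(t == "none" for t in twins.values()):
            reasons.append("twin_missing")
        if any(t == "multiple" for t in twins.values()):
            reasons.append("twin_multiple")
    else:
        twins = {}

    return VerificationResult(
        ascus_id=octad.ascus_id,
        valid=not reasons,
        marker_ratios=marker_ratios,
        twin_assignment=twins,
        failure_reasons=reasons,
    )
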