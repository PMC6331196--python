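"""Per-ascus, per-chromosome segregation patterns and transmission tables.

For every supernumerary chromosome of a verified octad the classifier counts
carrier spores by parental origin and assigns exactly one pattern label:

================  ==========================================================
``disomy``         at least one spore carries two or more copies (from both
                   parents, or a same-parent double)
``total_absence``  no spore carries the chromosome
``drive_8_0``      an unpaired chromosome present in all eight spores
``partial_drive``  an unpaired chromosome present in five to seven spores
``mendelian_4_4``  a paired chromosome with each parental homolog in exactly
                   four spores
``mendelian_4_0``  an unpaired chromosome in exactly four spores
``loss_deviation`` fewer carriers than expected (chromosome loss)
================  ==========================================================

Labels are assigned with priority disomy > total_absence > drive/partial >
mendelian > loss_deviation.  "Presence" is marker-level -- at least one copy,
matching PCR detection -- and copy number beyond presence is only consulted
for disomy.

The transmission table aggregates spore-level presence/absence of one
chromosome conditional on the spores' mitochondrial genotype, the readout in
which female-restricted drive becomes visible (the mitochondria identify the
female parent).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .cross_simulator import Ascospore, Octad, PairingMap
from .errors import NoDataError, NotInCrossError

LABELS: tuple[str, ...] = (
    "mendelian_4_4",
    "mendelian_4_0",
    "drive_8_0",
    "partial_drive",
    "loss_deviation",
    "disomy",
    "total_absence",
)


@dataclass
class SegregationRecord:
    """Segregation outcome for one chromosome in one ascus."""

    ascus_id: str
    chromosome: str
    pairing_status: str  # paired / unpaired_female / unpaired_male
    carriers_p1: int
    carriers_p2: int
    disomic_spores: int
    absent_spores: int
    label: str
    expected_carriers: int
    n_spores: int = 8

    @property
    def carriers(self) -> int:
        """Spores with at least one copy from either parent."""
        return self.n_spores - self.absent_spores


@dataclass
class TransmissionSummary:
    """Presence/absence of one chromosome among spores of one mito class."""

    chromosome: str
    mito_genotype: str
    present: int
    absent: int
    expected_mendelian_fraction: float = 0.5

    @property
    def total(self) -> int:
        return self.present + self.absent

    @property
    def fraction_present(self) -> float:
        return self.present / self.total


def detect_disomy(spore: Ascospore, chromosome: str) -> bool:
    """True iff the spore carries two or more copies of the chromosome.

    Covers both the biparental case (one copy from each parent, e.g. the
    chr21 disomies) and same-parent doubles arising from meiosis-II
    non-disjunction of an unpaired chromosome.
    """
    if chromosome not in spore.copies:
        raise NotInCrossError(
            f"{chromosome} was not scored in spore {spore.spore_id}"
        )
    return spore.total_copies(chromosome) >= 2


def _pairing_status(octad: Octad, chromosome: str, pairing: PairingMap) -> str:
    status = pairing.status(chromosome)
    if status == "paired":
        return "paired"
    owner_name = octad.parent1 if status == "unpaired_p1" else octad.parent2
    return "unpaired_female" if owner_name == octad.female_parent else "unpaired_male"


def classify_chromosome(
    octad: Octad,
    chromosome: str,
    pairing: PairingMap,
    *,
    drive_hypothesis: bool = False,
) -> SegregationRecord:
    """Classify the segregation of one chromosome in one ascus.

    ``drive_hypothesis`` sets the carrier expectation for a female-inherited
    unpaired chromosome to eight (the drive prediction) instead of the
    Mendelian four; it affects the ``expected_carriers`` bookkeeping only --
    the hypothesis context is an explicit argument, never inferred from the
    data.
    """
    if chromosome not in pairing.chromosomes():
        raise NotInCrossError(f"{chromosome} is not in this cross")
    status = _pairing_status(octad, chromosome, pairing)
    spores = octad.spores
    n = len(spores)

    carriers_p1 = sum(s.copies.get(chromosome, (0, 0))[0] >= 1 for s in spores)
    carriers_p2 = sum(s.copies.get(chromosome, (0, 0))[1] >= 1 for s in spores)
    disomic = sum(s.total_copies(chromosome) >= 2 for s in spores)
    absent = sum(s.total_copies(chromosome) == 0 for s in spores)
    carriers_any = n - absent

    if status == "paired":
        expected = 4  # per parental homolog
    elif status == "unpaired_female" and drive_hypothesis:
        expected = 8
    else:
        expected = 4

    if disomic > 0:
        label = "disomy"
    elif carriers_any == 0:
        label = "total_absence"
    elif status == "paired":
        label = (
            "mendelian_4_4"
            if carriers_p1 == 4 and carriers_p2 == 4
            else "loss_deviation"
        )
    else:
        owner = pairing.owner_index(chromosome)
        k = carriers_p1 if owner == 0 else carriers_p2
        if k == 8:
            label = "drive_8_0"
        elif 5 <= k <= 7:
            label = "partial_drive"
        elif k == 4:
            label = "mendelian_4_0"
        else:
            label = "loss_deviation"

    return SegregationRecord(
        ascus_id=octad.ascus_id,
        chromosome=chromosome,
        pairing_status=status,
        carriers_p1=carriers_p1,
        carriers_p2=carriers_p2,
        disomic_spores=disomic,
        absent_spores=absent,
        label=label,
        expected_carriers=expected,
        n_spores=n,
    )


def classify_octad(
    octad: Octad,
    pairing: PairingMap,
    *,
    drive_hypothesis: bool = False,
) -> list[SegregationRecord]:
    """Classify every chromosome of the cross in one octad."""
    return [
        classify_chromosome(
            octad, chrom, pairing, drive_hypothesis=drive_hypothesis
        )
        for chrom in sorted(pairing.chromosomes())
    ]


def records_to_frame(records: list[SegregationRecord]) -> pd.DataFrame:
    """Tabulate segregation records (one row per ascus x chromosome)."""
    return pd.DataFrame(
        [
            {
                "ascus_id": r.ascus_id,
                "chromosome": r.chromosome,
                "pairing_status": r.pairing_status,
                "carriers_p1": r.carriers_p1,
                "carriers_p2": r.carriers_p2,
                "disomic_spores": r.disomic_spores,
                "absent_spores": r.absent_spores,
                "label": r.label,
                "expected_carriers": r.expected_carriers,
                "n_spores": r.n_spores,
            }
            for r in records
        ]
    )


def transmission_table(
    spores: pd.DataFrame, chromosome: str
) -> dict[str, TransmissionSummary]:
    """Presence/absence counts of one chromosome, split by mito genotype.

    ``spores`` is a spore-level table with a ``mito`` column and the two
    per-parent copy-count columns ``<chromosome>_p1`` / ``<chromosome>_p2``.
    A spore counts as a carrier when it holds at least one copy from either
    parent.  Raises :class:`NoDataError` on an empty table.
    """
    if len(spores) == 0:
        raise NoDataError("no spores scored: transmission table is undefined")
    col1, col2 = f"{chromosome}_p1", f"{chromosome}_p2"
    for col in ("mito", col1, col2):
        if col not in spores.columns:
            raise NotInCrossError(f"column {col!r} missing from the spore table")
    present = (spores[col1] + spores[col2]) >= 1
    out: dict[str, TransmissionSummary] = {}
    for mito, group in spores.groupby("mito", sort=True):
        n_present = int(present.loc[group.index].sum())
        out[str(mito)] = TransmissionSummary(
            chromosome=chromosome,
            mito_genotype=str(mito),
            present=n_present,
            absent=int(len(group) - n_present),
        )
    return out
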