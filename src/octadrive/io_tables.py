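"""Readers and writers for the pipeline's tab-separated tables.

All stages exchange plain TSV so every intermediate is greppable and
diffable.  The octad table has one row per ascospore:

``ascus_id  spore_id  twin_id  mat  m11O21  m04L20  caa0002  ggc001  ac0001
mito  chr14_p1  chr14_p2 ... chr21_p1  chr21_p2``

where ``chrNN_p1``/``chrNN_p2`` are the copy counts inherited from parent 1
and parent 2.  Pipeline configuration is YAML mirroring the cross-config
fields; built-in strain names (``IPO323``, ``IPO94269``, ``IPO323dchrNN``)
are resolved automatically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import pandas as pd
import yaml

from .cross_simulator import Ascospore, CrossConfig, Octad, PairingMap, build_cross
from .errors import ConfigError, FormatError
from .segregation_classifier import SegregationRecord, records_to_frame
from .strains import CORE_MARKERS, SUPERNUMERARY_CHROMOSOMES, resolve_strain
from .tetrad_qc import VerificationResult

COPY_COLUMNS = tuple(
    f"{chrom}_p{i}" for chrom in SUPERNUMERARY_CHROMOSOMES for i in (1, 2)
)
OCTAD_COLUMNS = ("ascus_id", "spore_id", "twin_id") + CORE_MARKERS + (
    "mito",
) + COPY_COLUMNS


def default_mito_to_parent(mito: str) -> str:
    """Map a mitochondrial allele label to a parent name (strip ``mt``)."""
    return mito[2:] if mito.startswith("mt") else mito


# ---------------------------------------------------------------------------
# octad tables
# ---------------------------------------------------------------------------


def octads_to_frame(octads: Sequence[Octad]) -> pd.DataFrame:
    """Flatten octads into the canonical one-row-per-spore table."""
    rows = []
    for octad in octads:
        for spore in octad.spores:
            row: dict[str, object] = {
                "ascus_id": octad.ascus_id,
                "spore_id": spore.spore_id,
                "twin_id": spore.twin_id,
            }
            for marker in CORE_MARKERS:
                row[marker] = spore.core_alleles[marker]
            row["mito"] = spore.mito
            for chrom in SUPERNUMERARY_CHROMOSOMES:
                c1, c2 = spore.copies.get(chrom, (0, 0))
                row[f"{chrom}_p1"] = c1
                row[f"{chrom}_p2"] = c2
            rows.append(row)
    return pd.DataFrame(rows, columns=list(OCTAD_COLUMNS))


def frame_to_octads(
    frame: pd.DataFrame,
    *,
    parent1: str = "parent1",
    parent2: str = "parent2",
    mechanism: str = "unknown",
    mito_to_parent: Callable[[str], str] | None = None,
) -> list[Octad]:
    """Group a spore table into octads, validating schema and copy counts.

    Raises :class:`FormatError` for a missing column (named) or a copy count
    outside {0, 1, 2} (with the offending row number).  An ascus with other
    than eight rows is kept but triggers a warning; downstream verification
    flags it as ``wrong_spore_count``.
    """
    missing = [c for c in OCTAD_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"octad table lacks column(s) {missing}")
    mapper = mito_to_parent or default_mito_to_parent

    for col in COPY_COLUMNS:
        bad = frame.index[~frame[col].isin((0, 1, 2))]
        if len(bad):
            raise FormatError(
                f"copy count outside {{0,1,2}} in column {col!r}, "
                f"row {int(bad[0]) + 2} of the file"
            )

    octads: list[Octad] = []
    for ascus_id, group in frame.groupby("ascus_id", sort=True):
        if len(group) != 8:
            warnings.warn(
                f"ascus {ascus_id} has {len(group)} spores (expected 8); "
                "kept for downstream QC",
                stacklevel=2,
            )
        spores = []
        for _, row in group.iterrows():
            spores.append(
                Ascospore(
                    spore_id=str(row["spore_id"]),
                    twin_id=str(row["twin_id"]),
                    core_alleles={m: str(row[m]) for m in CORE_MARKERS},
                    mito=str(row["mito"]),
                    copies={
                        chrom: (
                            int(row[f"{chrom}_p1"]),
                            int(row[f"{chrom}_p2"]),
                        )
                        for chrom in SUPERNUMERARY_CHROMOSOMES
                    },
                )
            )
        mito = spores[0].mito if spores else ""
        octads.append(
            Octad(
                ascus_id=str(ascus_id),
                spores=spores,
                female_parent=mapper(mito),
                mechanism=mechanism,
                parent1=parent1,
                parent2=parent2,
            )
        )
    return octads


def write_octad_table(octads: Sequence[Octad], path: "str | Path") -> None:
    octads_to_frame(octads).to_csv(path, sep="\t", index=False)


def read_octad_table(path: "str | Path", **kwargs) -> list[Octad]:
    """Read an octad TSV back into :class:`Octad` objects.

    Keyword arguments are forwarded to :func:`frame_to_octads` (parent names,
    mechanism, mito-to-parent mapping).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"octad table {path} does not exist")
    frame = pd.read_csv(path, sep="\t", dtype={m: str for m in CORE_MARKERS})
    return frame_to_octads(frame, **kwargs)


# ---------------------------------------------------------------------------
# pairing, verification and record tables
# ---------------------------------------------------------------------------


def write_pairing_table(pairing: PairingMap, path: "str | Path") -> None:
    rows = [
        {"chromosome": c, "status": pairing.status(c)}
        for c in sorted(pairing.chromosomes())
    ]
    pd.DataFrame(rows, columns=["chromosome", "status"]).to_csv(
        path, sep="\t", index=False
    )


def read_pairing_table(path: "str | Path") -> PairingMap:
    frame = pd.read_csv(path, sep="\t")
    for col in ("chromosome", "status"):
        if col not in frame.columns:
            raise FormatError(f"pairing table lacks column {col!r}")
    sets: dict[str, set[str]] = {"paired": set(), "unpaired_p1": set(), "unpaired_p2": set()}
    for _, row in frame.iterrows():
        status = str(row["status"])
        if status not in sets:
            raise FormatError(f"unknown pairing status {status!r}")
        sets[status].add(str(row["chromosome"]))
    return PairingMap(
        paired=frozenset(sets["paired"]),
        unpaired_from_p1=frozenset(sets["unpaired_p1"]),
        unpaired_from_p2=frozenset(sets["unpaired_p2"]),
    )


def verification_to_frame(results: Sequence[VerificationResult]) -> pd.DataFrame:
    rows = []
    for res in results:
        row: dict[str, object] = {
            "ascus_id": res.ascus_id,
            "valid": int(res.valid),
            "failure_reasons": ";".join(res.failure_reasons) or "-",
        }
        for marker, ratio in res.marker_ratios.items():
            row[f"ratio_{marker}"] = ":".join(str(x) for x in ratio)
        rows.append(row)
    return pd.DataFrame(rows)


def write_verification_report(
    results: Sequence[VerificationResult], path: "str | Path"
) -> None:
    verification_to_frame(results).to_csv(path, sep="\t", index=False)


def write_records_table(
    records: Sequence[SegregationRecord], path: "str | Path"
) -> None:
    records_to_frame(list(records)).to_csv(path, sep="\t", index=False)


def read_records_table(path: "str | Path") -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    required = {"ascus_id", "chromosome", "pairing_status", "label"}
    missing = required - set(frame.columns)
    if missing:
        raise FormatError(f"records table lacks column(s) {sorted(missing)}")
    return frame


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Everything :func:`octadrive.pipeline.run_pipeline` needs."""

    cross: CrossConfig
    outdir: Path
    stages: dict[str, bool] = field(
        default_factory=lambda: {
            "verify": True,
            "classify": True,
            "stats": True,
            "snpspectrum": False,
        }
    )
    drive_hypothesis: bool = False
    snp: dict = field(default_factory=dict)

    @property
    def pairing(self) -> PairingMap:
        return build_cross(self.cross.parent1, self.cross.parent2)


def config_from_mapping(raw: Mapping) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from parsed YAML."""
    data = dict(raw)
    try:
        parent1 = resolve_strain(data.pop("parent1"))
        parent2 = resolve_strain(data.pop("parent2"))
    except KeyError as exc:
        raise ConfigError(f"config lacks required key {exc}") from exc
    outdir = Path(data.pop("outdir", "results/run"))
    stages = {
        "verify": True,
        "classify": True,
        "stats": True,
        "snpspectrum": False,
    }
    stages.update(data.pop("stages", {}) or {})
    drive_hypothesis = bool(data.pop("drive_hypothesis", False))
    snp = dict(data.pop("snp", {}) or {})

    cross_kwargs: dict = {"parent1": parent1, "parent2": parent2}
    for key in (
        "mechanism",
        "loss_rate",
        "nondisjunction_rate",
        "preferential_bias",
        "drive_penetrance",
        "density_exponent",
        "n_asci",
        "seed",
        "killer_chromosome",
        "premeiotic_copy_loss",
    ):
        if key in data:
            cross_kwargs[key] = data.pop(key)
    if data:
        raise ConfigError(f"unknown config key(s): {sorted(data)}")
    if any(stages.values()) and "seed" not in cross_kwargs:
        raise ConfigError("a seed is required when stochastic stages are enabled")
    return PipelineConfig(
        cross=CrossConfig(**cross_kwargs),
        outdir=outdir,
        stages=stages,
        drive_hypothesis=drive_hypothesis,
        snp=snp,
    )


def load_config(path: "str | Path") -> PipelineConfig:
    """Load and validate a YAML pipeline configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file {path} does not exist")
    with open(path) as handle:
        raw = yaml.safe_load(handle)
    if not isinstance(raw, Mapping):
        raise ConfigError("config file must hold a key: value mapping")
    return config_from_mapping(raw)
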