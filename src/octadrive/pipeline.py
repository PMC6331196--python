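"""End-to-end pipeline: simulate -> verify -> classify -> stats (-> SNPs).

Every stage writes one TSV under the configured output directory and a final
``summary.json`` captures per-stage record counts, the seed and the package
version, so a run is fully reproducible and auditable.  All randomness flows
from the single configured seed; identical config + seed give byte-identical
outputs.  If any stage fails, files written so far are removed and the error
is re-raised with the stage name attached.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cross_simulator import simulate_experiment
from .drive_stats import (
    binomial_drive_test,
    discriminate_mechanisms,
    estimate_loss_rate,
    label_counts_from_records,
    randomize_one_per_ascus,
)
from .errors import NoDataError, OctadriveError
from .io_tables import (
    PipelineConfig,
    octads_to_frame,
    write_octad_table,
    write_pairing_table,
    write_records_table,
    write_verification_report,
)
from .segregation_classifier import classify_octad, records_to_frame, transmission_table
from .snp_spectrum import sharing_spectrum, simulate_snp_matrix, spectrum_to_frame
from .tetrad_qc import verify_ascus

logger = logging.getLogger("octadrive")


class StageError(OctadriveError):
    """A pipeline stage failed; the stage name is in the message."""


def run_pipeline(config: PipelineConfig, seed: int | None = None) -> dict:
    """Run the configured stages; returns the summary dictionary.

    ``seed`` overrides the seed of the cross configuration (the CLI's
    ``--seed`` flag).
    """
    from dataclasses import replace

    cross = config.cross if seed is None else replace(config.cross, seed=seed)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    summary: dict = {
        "version": __version__,
        "seed": cross.seed,
        "mechanism": cross.mechanism,
        "stages": {},
    }

    def emit(frame: pd.DataFrame, name: str) -> Path:
        path = outdir / name
        frame.to_csv(path, sep="\t", index=False)
        written.append(path)
        return path

    stage = "simulate"
    try:
        logger.info("[simulate] %d asci, mechanism=%s, seed=%d",
                    cross.n_asci, cross.mechanism, cross.seed)
        octads = simulate_experiment(cross)
        pairing = config.pairing
        write_octad_table(octads, outdir / "octads.tsv")
        written.append(outdir / "octads.tsv")
        write_pairing_table(pairing, outdir / "pairing.tsv")
        written.append(outdir / "pairing.tsv")
        spores = octads_to_frame(octads)
        summary["stages"]["simulate"] = {"asci": len(octads), "spores": len(spores)}

        verified_ids: set[str] = {o.ascus_id for o in octads}
        if config.stages.get("verify", True):
            stage = "verify"
            results = [verify_ascus(o) for o in octads]
            write_verification_report(results, outdir / "verification.tsv")
            written.append(outdir / "verification.tsv")
            verified_ids = {r.ascus_id for r in results if r.valid}
            logger.info("[verify] %d/%d asci verified", len(verified_ids), len(octads))
            summary["stages"]["verify"] = {
                "asci": len(octads),
                "verified": len(verified_ids),
            }

        records = []
        if config.stages.get("classify", True):
            stage = "classify"
            for octad in octads:
                if octad.ascus_id in verified_ids:
                    records.extend(
                        classify_octad(
                            octad, pairing, drive_hypothesis=config.drive_hypothesis
                        )
                    )
            write_records_table(records, outdir / "records.tsv")
            written.append(outdir / "records.tsv")
            logger.info("[classify] %d records from %d verified asci",
                        len(records), len(verified_ids))
            summary["stages"]["classify"] = {"records": len(records)}

        if config.stages.get("stats", True):
            stage = "stats"
            unpaired = sorted(pairing.unpaired_from_p1 | pairing.unpaired_from_p2)
            report = _stats_report(
                spores, records, unpaired, cross.seed, len(verified_ids), len(octads)
            )
            emit(report, "stats_report.tsv")
            logger.info("[stats] %d report rows", len(report))
            summary["stages"]["stats"] = {"rows": len(report)}

        if config.stages.get("snpspectrum", False):
            stage = "snpspectrum"
            snp_cfg = dict(config.snp)
            n_snps = int(snp_cfg.pop("n_snps", 5000))
            threshold = int(snp_cfg.pop("threshold", 8))
            rng = np.random.default_rng(
                np.random.SeedSequence(cross.seed, spawn_key=(10_000,))
            )
            matrix = simulate_snp_matrix(n_snps, rng, **snp_cfg)
            emit(matrix, "snp_matrix.tsv")
            spectra = [
                sharing_spectrum(matrix, filter_mode=mode, threshold=threshold)
                for mode in ("none", "min_cov_any", "min_cov_all")
            ]
            emit(spectrum_to_frame(spectra), "snp_spectrum.tsv")
            logger.info("[snpspectrum] %d SNPs simulated", n_snps)
            summary["stages"]["snpspectrum"] = {"snps": n_snps}

        summary_path = outdir / "summary.json"
        with open(summary_path, "w") as handle:
            json.dump(summary, handle, indent=2, sort_keys=True)
            handle.write("\n")
        written.append(summary_path)
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        if isinstance(exc, OctadriveError):
            raise StageError(f"stage {stage!r} failed: {exc}") from exc
        raise StageError(f"stage {stage!r} failed: {exc!r}") from exc
    return summary


def _stats_report(
    spores: pd.DataFrame,
    records,
    unpaired: list[str],
    seed: int,
    n_verified: int,
    n_asci: int,
) -> pd.DataFrame:
    """Long-format statistics table (one metric per row)."""
    rows: list[dict] = []

    def add(section, metric, value, chromosome="-", mito="-", stars="-"):
        rows.append(
            {
                "section": section,
                "chromosome": chromosome,
                "mito": mito,
                "metric": metric,
                "value": value,
                "stars": stars,
            }
        )

    add("overview", "asci", n_asci)
    add("overview", "verified_asci", n_verified)

    if len(spores):
        randomized = randomize_one_per_ascus(spores, seed)
        for chrom in unpaired:
            for mito, summary in transmission_table(spores, chrom).items():
                add(
                    "transmission",
                    "present",
                    summary.present,
                    chromosome=chrom,
                    mito=mito,
                )
                add(
                    "transmission",
                    "absent",
                    summary.absent,
                    chromosome=chrom,
                    mito=mito,
                )
            for mito, summary in transmission_table(randomized, chrom).items():
                if summary.total >= 1:
                    test = binomial_drive_test(summary.present, summary.total)
                    add(
                        "binomial_vs_mendelian",
                        "p_value",
                        test.p_value,
                        chromosome=chrom,
                        mito=mito,
                        stars=test.stars,
                    )

    if isinstance(records, pd.DataFrame):
        frame = records
    else:
        frame = records_to_frame(list(records))
    if len(frame):
        for label, n in frame["label"].value_counts().sort_index().items():
            add("labels", str(label), int(n))
        try:
            loss = estimate_loss_rate(frame)
            add("loss", "rate", loss.rate)
            add("loss", "events", loss.loss_events)
            add("loss", "instances", loss.instances)
            if loss.heterogeneity is not None:
                add(
                    "loss",
                    "heterogeneity_p",
                    loss.heterogeneity.p_value,
                    stars=loss.heterogeneity.stars,
                )
        except NoDataError:
            pass
        completeness = n_verified / n_asci if n_asci else 0.0
        try:
            verdict = discriminate_mechanisms(
                label_counts_from_records(frame), completeness
            )
            add("mechanisms", "consistent", ";".join(sorted(verdict.consistent)))
            for mech, why in sorted(verdict.excluded.items()):
                add("mechanisms", f"excluded_{mech}", why)
        except NoDataError:
            pass

    return pd.DataFrame(
        rows, columns=["section", "chromosome", "mito", "metric", "value", "stars"]
    )
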