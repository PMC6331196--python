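"""Drive statistics over the panel: transmission, tests, losses, verdict.

Writes results/04_transmission.tsv (presence by mitochondrial genotype with
exact binomial tests on one randomly selected spore per ascus),
results/04_loss.tsv (per-chromosome loss with the heterogeneity test) and
prints the mechanism-discrimination verdict.

Finding: pooled over the panel, unpaired chromosomes are strongly
overrepresented among spores sharing the mitochondrial genotype of the
parent that donated them (the female) and Mendelian among the reciprocal
mito class; the binomial test rejects p=0.5 only in the female classes.
Paired-chromosome losses run near the configured 3.7% per instance, and the
falsification rules leave female-restricted meiotic drive as the only
mechanism consistent with complete octads, 8:0 female transmission and
clean 4:4 paired segregation.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from panel import simulate_panel

from octadrive.drive_stats import (
    binomial_drive_test,
    discriminate_mechanisms,
    estimate_loss_rate,
    label_counts_from_records,
    randomize_one_per_ascus,
)
from octadrive.io_tables import octads_to_frame
from octadrive.segregation_classifier import classify_octad, records_to_frame
from octadrive.tetrad_qc import verify_ascus

RESULTS = Path("results")


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    records = []
    # spores pooled per unpaired chromosome, only from crosses where that
    # chromosome really is unpaired (it is paired in the other crosses)
    spores_by_unpaired: dict[str, list[pd.DataFrame]] = {}
    unpaired_owner: dict[str, str] = {}
    n_asci = n_verified = 0
    for name, config, pairing, octads in simulate_panel():
        frame = octads_to_frame(octads)
        # keep ascus ids unique across crosses for the one-per-ascus draw
        frame["ascus_id"] = name + ":" + frame["ascus_id"]
        for chrom in pairing.unpaired_from_p1 | pairing.unpaired_from_p2:
            owner = (
                "IPO323" if chrom in pairing.unpaired_from_p1 else "IPO94269"
            )
            unpaired_owner[chrom] = owner
            spores_by_unpaired.setdefault(chrom, []).append(frame)
        for octad in octads:
            n_asci += 1
            n_verified += verify_ascus(octad).valid
            records.extend(classify_octad(octad, pairing))
    rec_frame = records_to_frame(records)

    # transmission conditioned on the mitochondrial genotype, one spore/ascus
    rows = []
    for chrom, owner in sorted(unpaired_owner.items()):
        pooled = pd.concat(spores_by_unpaired[chrom], ignore_index=True)
        randomized = randomize_one_per_ascus(pooled, seed=11)
        present = (randomized[f"{chrom}_p1"] + randomized[f"{chrom}_p2"]) >= 1
        for mito, group in randomized.groupby("mito"):
            k = int(present.loc[group.index].sum())
            n = len(group)
            test = binomial_drive_test(k, n)
            rows.append(
                {
                    "chromosome": chrom,
                    "inherited_from": owner,
                    "mito": mito,
                    "present": k,
                    "absent": n - k,
                    "fraction": round(k / n, 3),
                    "binomial_p": test.p_value,
                    "stars": test.stars,
                }
            )
    trans = pd.DataFrame(rows)
    trans.to_csv(RESULTS / "04_transmission.tsv", sep="\t", index=False)
    print(trans.to_string(index=False))

    loss = estimate_loss_rate(rec_frame)
    loss.per_chromosome.to_csv(RESULTS / "04_loss.tsv", sep="\t", index=False)
    print(
        f"\nloss: {loss.loss_events}/{loss.instances} instances "
        f"({100 * loss.rate:.1f}%); heterogeneity p = "
        + (f"{loss.heterogeneity.p_value:.3g}" if loss.heterogeneity else "n/a")
    )

    verdict = discriminate_mechanisms(
        label_counts_from_records(rec_frame), n_verified / n_asci
    )
    print(f"\nconsistent mechanisms: {sorted(verdict.consistent)}")
    for mech, why in sorted(verdict.excluded.items()):
        print(f"  excluded {mech}: {why}")


if __name__ == "__main__":
    main()
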