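"""SNP sharing across the eight spores of an octad, under coverage filters.

When whole-genome reads of all eight ascospores are mapped to one parent's
reference, the SNPs private to the other parent should appear in exactly the
four spores that inherited that parent's haplotype block -- Mendelian 2:2
segregation at the chromatid level, read out as 4-of-8 at the spore level,
with crossovers switching *which* four spores carry a block along the
chromosome.  Deviations arise from gene conversion (heteroduplex tracts that
resolve only at the post-meiotic mitosis, giving 3- or 5-spore sharing) and,
far more often, from uneven read coverage: poorly covered sites miss the
allele in some carriers.  Progressively stricter coverage filters therefore
concentrate the sharing spectrum at k = 4.

The synthetic generator emulates exactly these ingredients; the filter and
spectrum operations reproduce the coverage-threshold analysis on either
synthetic or imported matrices.

A SNP matrix is a :class:`pandas.DataFrame` with the columns ``snp_id``,
``chromosome``, ``position`` (1-based), ``presence_s1`` .. ``presence_s8``
(0/1: alternate allele detected in that spore) and ``cov_s1`` .. ``cov_s8``
(read depth at the site).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, FormatError

FILTER_MODES = ("none", "min_cov_any", "min_cov_all")

PRESENCE_COLS = tuple(f"presence_s{i}" for i in range(1, 9))
COVERAGE_COLS = tuple(f"cov_s{i}" for i in range(1, 9))
SNP_COLUMNS = ("snp_id", "chromosome", "position") + PRESENCE_COLS + COVERAGE_COLS

#: Default read-depth threshold; the filters read "more than 8 reads".
DEFAULT_THRESHOLD = 8


@dataclass
class SpectrumResult:
    """Sharing spectrum: number of SNPs detected in exactly k of 8 spores."""

    filter_mode: str
    threshold: int
    counts: dict[int, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def fraction_at(self, k: int) -> float:
        if self.total == 0:
            return float("nan")
        return self.counts.get(k, 0) / self.total


def _validate_matrix(matrix: pd.DataFrame) -> None:
    missing = [c for c in SNP_COLUMNS if c not in matrix.columns]
    if missing:
        raise FormatError(f"SNP matrix lacks column(s) {missing}")


def simulate_snp_matrix(
    n_snps: int,
    rng: np.random.Generator,
    *,
    context: str = "paired",
    chromosome: str = "chr1",
    chrom_length: int = 1_000_000,
    crossover_rate: float = 2.0,
    conversion_rate: float = 0.0,
    conversion_tract_length: int = 2_000,
    coverage_mean: float = 20.0,
    coverage_dispersion: float = 5.0,
    dropout_rate: float = 0.0,
) -> pd.DataFrame:
    """Simulate the alternate-parent SNP matrix of one octad.

    ``context`` selects the transmission of the chromosome carrying the SNPs:
    ``"paired"`` (default) puts the alternate haplotype in 2 of 4 chromatids,
    so each SNP starts in exactly four spores; ``"unpaired_drive"`` models an
    amplified unpaired chromosome present in all eight spores; and
    ``"unpaired_mendelian"`` an unpaired chromosome in four spores, with zero
    coverage (the chromosome is physically absent) in the other four.

    Crossover breakpoints are drawn per meiosis (Poisson count with mean
    ``crossover_rate``, uniform positions) and exchange the distal segments
    of one chromatid from each homolog, so every SNP remains on exactly two
    chromatids while haplotype blocks alternate along the chromosome.  Gene
    conversion tracts (Poisson count with mean ``conversion_rate``) convert a
    single DNA strand of one chromatid; the post-meiotic mitosis resolves the
    heteroduplex, flipping the allele in exactly one twin of the affected
    spore pair -- the 5:3 / 3:5 aberrant-segregation signature.  Read depth
    is drawn per site and spore from an overdispersed negative-binomial
    distribution with mean ``coverage_mean``; presence is masked at zero
    coverage and by a per-cell Bernoulli ``dropout_rate``.
    """
    if n_snps < 0:
        raise ConfigError("n_snps must be non-negative")
    for name, value in (
        ("conversion_rate", conversion_rate),
        ("dropout_rate", dropout_rate),
    ):
        if value < 0:
            raise ConfigError(f"{name} must be non-negative")
    if context not in ("paired", "unpaired_drive", "unpaired_mendelian"):
        raise ConfigError(f"unknown octad context {context!r}")

    if n_snps <= chrom_length:
        positions = (
            np.sort(rng.choice(chrom_length, size=n_snps, replace=False)) + 1
        ).astype(int)
    else:
        positions = np.sort(rng.integers(1, chrom_length + 1, size=n_snps)).astype(int)

    # chromatid c goes to meiotic product c; product j -> spores 2j, 2j+1
    if context == "unpaired_drive":
        alt = np.ones((n_snps, 4), dtype=bool)
    else:
        alt = np.zeros((n_snps, 4), dtype=bool)
        alt[:, 2:] = True  # chromatids 2,3 descend from the alternate parent
        n_crossovers = rng.poisson(crossover_rate)
        for _ in range(n_crossovers):
            breakpoint = rng.integers(1, chrom_length + 1)
            a = int(rng.integers(2))  # chromatid of homolog 1
            b = 2 + int(rng.integers(2))  # chromatid of homolog 2
            distal = positions > breakpoint
            alt[distal, a], alt[distal, b] = (
                alt[distal, b].copy(),
                alt[distal, a].copy(),
            )

    presence = np.repeat(alt, 2, axis=1)  # spore s = 2*product + twin half

    n_tracts = rng.poisson(conversion_rate)
    for _ in range(n_tracts):
        chromatid = int(rng.integers(4))
        twin_half = int(rng.integers(2))
        start = int(rng.integers(1, chrom_length + 1))
        in_tract = (positions >= start) & (positions < start + conversion_tract_length)
        spore = 2 * chromatid + twin_half
        # heteroduplex resolution: the converted strand ends up in one twin
        presence[in_tract, spore] = ~presence[in_tract, spore]

    # overdispersed read depth (negative binomial parameterised by mean/size)
    size = coverage_dispersion
    p = size / (size + coverage_mean)
    coverage = rng.negative_binomial(size, p, size=(n_snps, 8))
    if context == "unpaired_mendelian":
        # spores lacking the chromosome yield no reads at its sites
        coverage = np.where(presence, coverage, 0)

    detected = presence & (coverage > 0)
    if dropout_rate > 0:
        detected &= rng.random((n_snps, 8)) >= dropout_rate

    data: dict[str, object] = {
        "snp_id": [f"snp{i + 1:06d}" for i in range(n_snps)],
        "chromosome": chromosome,
        "position": positions,
    }
    for j, col in enumerate(PRESENCE_COLS):
        data[col] = detected[:, j].astype(int)
    for j, col in enumerate(COVERAGE_COLS):
        data[col] = coverage[:, j].astype(int)
    return pd.DataFrame(data, columns=list(SNP_COLUMNS))


def filter_by_coverage(
    matrix: pd.DataFrame,
    mode: str,
    threshold: int = DEFAULT_THRESHOLD,
    *,
    inclusive: bool = False,
    all_scope: str = "spores",
) -> pd.DataFrame:
    """Apply a read-coverage filter to a SNP matrix.

    ``min_cov_any`` keeps SNPs whose coverage exceeds ``threshold`` in at
    least one spore; ``min_cov_all`` keeps SNPs whose coverage exceeds it in
    every spore (``all_scope="spores"``, the default, which makes the filters
    strictly nested) or, with ``all_scope="carriers"``, in every spore where
    the allele was detected; ``none`` is the identity.  The comparison is
    strict (``> threshold``) unless ``inclusive`` is set -- "more than 8
    reads" means at least 9.
    """
    _validate_matrix(matrix)
    if mode not in FILTER_MODES:
        raise ConfigError(f"unknown filter mode {mode!r}")
    if all_scope not in ("spores", "carriers"):
        raise ConfigError(f"unknown all_scope {all_scope!r}")
    if mode == "none":
        return matrix.copy()

    cov = matrix[list(COVERAGE_COLS)].to_numpy()
    ok = cov >= threshold if inclusive else cov > threshold
    if mode == "min_cov_any":
        keep = ok.any(axis=1)
    elif all_scope == "spores":
        keep = ok.all(axis=1)
    else:
        pres = matrix[list(PRESENCE_COLS)].to_numpy().astype(bool)
        keep = (ok | ~pres).all(axis=1) & (cov > 0).all(axis=1)
    return matrix.loc[keep].reset_index(drop=True)


def sharing_spectrum(
    matrix: pd.DataFrame,
    *,
    filter_mode: str = "none",
    threshold: int = DEFAULT_THRESHOLD,
    inclusive: bool = False,
    all_scope: str = "spores",
) -> SpectrumResult:
    """Count SNPs by the number of spores in which they were detected.

    The optional coverage filter is applied first; the returned counts cover
    k = 0..8 and sum to the number of SNPs surviving the filter.
    """
    filtered = filter_by_coverage(
        matrix, filter_mode, threshold, inclusive=inclusive, all_scope=all_scope
    )
    k = filtered[list(PRESENCE_COLS)].to_numpy().sum(axis=1)
    counts = {i: int((k == i).sum()) for i in range(9)}
    return SpectrumResult(filter_mode=filter_mode, threshold=threshold, counts=counts)


def spectrum_to_frame(results: "list[SpectrumResult]") -> pd.DataFrame:
    """Long-format table of one or more sharing spectra."""
    rows = []
    for res in results:
        for k in range(9):
            rows.append(
                {
                    "filter_mode": res.filter_mode,
                    "threshold": res.threshold,
                    "k_spores": k,
                    "n_snps": res.counts.get(k, 0),
                }
            )
    return pd.DataFrame(rows)
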