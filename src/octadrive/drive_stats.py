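"""Statistical layer: drive tests, loss rates and mechanism discrimination.

The central test is the exact two-sided binomial test of a carrier count
against the Mendelian null of p = 0.5 (an unpaired chromosome is expected in
half of the progeny).  Contingency comparisons use Fisher's exact test for
small tables and switch to Pearson's chi-squared (no continuity correction)
for large ones.  Because all spores of an ascus share one mitochondrial
genotype, mitochondrial-transmission statistics are computed on one randomly
selected spore per ascus.

Beyond hypothesis tests, the module estimates the per-meiosis chromosome-loss
rate (with a chi-squared heterogeneity test across chromosomes), derives the
carrier-count distribution each transmission mechanism predicts, and applies
the falsification logic that discriminates between mechanisms:

* complete, verified eight-spore octads rule out spore killing;
* an unpaired chromosome in all eight spores exceeds what Mendelian
  segregation or preferential segregation (support capped at four carriers)
  can produce;
* clean 4:4 segregation of paired chromosomes without disomic spores rules
  out a pre-meiotic amplification, which would leave trisomic zygotes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import cross_simulator as cs
from .errors import ConfigError, DegenerateTableError, NoDataError

#: Size above which (or expected-count condition failing which) the Fisher
#: branch yields to Pearson's chi-squared.
LARGE_SAMPLE_THRESHOLD = 200

CONTEXTS = ("female_unpaired", "male_unpaired", "paired")


@dataclass
class TestResult:
    """Outcome of one hypothesis test."""

    statistic_name: str
    p_value: float
    counts: tuple
    alternative: str = "two-sided"
    null_probability: float | None = None
    statistic: float | None = None
    note: str | None = None

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)


def significance_stars(p: float) -> str:
    """Star notation: ``*`` p<0.05, ``**`` p<0.005, ``***`` p<0.0005."""
    if p < 0.0005:
        return "***"
    if p < 0.005:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


# ---------------------------------------------------------------------------
# exact tests
# ---------------------------------------------------------------------------


def binomial_drive_test(k: int, n: int) -> TestResult:
    """Exact two-sided binomial test of ``k`` carriers in ``n`` spores vs p=0.5.

    Two-sided by the minimum-likelihood rule: the p-value sums the
    probabilities of all outcomes no more likely than the observed one.
    """
    if n < 1:
        raise ValueError("binomial test needs at least one scored spore")
    if not 0 <= k <= n:
        raise ValueError(f"carrier count k={k} outside [0, n={n}]")
    p_value = float(sps.binomtest(k, n, 0.5).pvalue)
    return TestResult(
        statistic_name="binomial_exact",
        p_value=min(p_value, 1.0),
        counts=(k, n),
        null_probability=0.5,
    )


def _log_table_probability(table: np.ndarray, log_const: float) -> float:
    return log_const - sum(math.lgamma(x + 1) for x in table.flat)


def _exact_rxc_pvalue(table: np.ndarray) -> float:
    """Exact conditional (Fisher-type) p-value for an r x c table.

    Enumerates every table with the observed margins and sums the
    probabilities of tables no more probable than the observed one under the
    multivariate hypergeometric null.  Feasible for small N only.
    """
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    n = int(table.sum())
    log_const = (
        sum(math.lgamma(r + 1) for r in rows)
        + sum(math.lgamma(c + 1) for c in cols)
        - math.lgamma(n + 1)
    )
    log_p_obs = _log_table_probability(table, log_const)
    threshold = log_p_obs + 1e-9

    total = 0.0
    r, c = table.shape

    def fill(row: int, remaining_cols: np.ndarray) -> Iterable[np.ndarray]:
        if row == r - 1:
            yield remaining_cols.copy().reshape(1, c)
            return
        target = rows[row]
        # enumerate row `row` cell by cell under the margin constraints
        def cells(j: int, left: int, acc: list[int]):
            if j == c - 1:
                if left <= remaining_cols[j]:
                    yield acc + [left]
                return
            for v in range(min(left, remaining_cols[j]) + 1):
                yield from cells(j + 1, left - v, acc + [v])

        for row_values in cells(0, int(target), []):
            rest = remaining_cols - np.array(row_values)
            for tail in fill(row + 1, rest):
                yield np.vstack([np.array(row_values).reshape(1, c), tail])

    for candidate in fill(0, cols.astype(int)):
        if _log_table_probability(candidate, log_const) <= threshold:
            total += math.exp(_log_table_probability(candidate, log_const))
    return min(total, 1.0)


def contingency_test(
    table: "Sequence[Sequence[int]] | np.ndarray",
    large_sample_threshold: int = LARGE_SAMPLE_THRESHOLD,
) -> TestResult:
    """Fisher's exact test or Pearson's chi-squared, by sample size.

    Fisher's exact two-sided test runs when the grand total is below
    ``large_sample_threshold`` or any expected cell count is below five;
    otherwise Pearson's chi-squared without continuity correction is used.
    ``statistic_name`` records which branch ran.  A zero row or column margin
    raises :class:`DegenerateTableError`.
    """
    arr = np.asarray(table, dtype=int)
    if arr.ndim != 2 or (arr < 0).any():
        raise ConfigError("contingency table must be 2-D with non-negative counts")
    rows, cols, n = arr.sum(axis=1), arr.sum(axis=0), int(arr.sum())
    if (rows == 0).any() or (cols == 0).any():
        raise DegenerateTableError("degenerate table: a margin is zero")
    expected = np.outer(rows, cols) / n
    use_fisher = n < large_sample_threshold or (expected < 5).any()

    if use_fisher:
        if arr.shape == (2, 2):
            p = float(sps.fisher_exact(arr, alternative="two-sided")[1])
            return TestResult("fisher_exact", min(p, 1.0), tuple(arr.flatten()))
        if n <= 120:
            p = _exact_rxc_pvalue(arr)
            return TestResult("fisher_exact", p, tuple(arr.flatten()))
        note = "table too large for exact enumeration; chi-squared used"
    else:
        note = None
    chi2, p, _dof, _exp = sps.chi2_contingency(arr, correction=False)
    return TestResult(
        "chi_squared",
        float(min(p, 1.0)),
        tuple(arr.flatten()),
        statistic=float(chi2),
        note=note,
    )


def randomize_one_per_ascus(spores: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Select one uniformly random spore per ascus, reproducibly.

    Counters the pseudo-replication of mitochondrial (and drive) genotypes:
    all spores of an ascus share a female parent, so only one observation per
    ascus is statistically independent.
    """
    if "ascus_id" not in spores.columns:
        raise ConfigError("spore table needs an 'ascus_id' column")
    rng = np.random.default_rng(seed)
    chosen = []
    for _ascus, group in spores.groupby("ascus_id", sort=True):
        chosen.append(group.index[int(rng.integers(len(group)))])
    return spores.loc[chosen]


# ---------------------------------------------------------------------------
# loss-rate estimation
# ---------------------------------------------------------------------------


@dataclass
class LossRateEstimate:
    """Chromosome-loss rate over paired supernumerary instances."""

    rate: float
    loss_events: int
    instances: int
    per_chromosome: pd.DataFrame
    heterogeneity: TestResult | None
    spore_absence_fraction: float


def loss_percentage(loss_cases: int, scored_instances: int) -> float:
    """Loss percentage from raw totals, rounded to one decimal place."""
    if scored_instances < 1:
        raise NoDataError("no scored instances")
    return round(100.0 * loss_cases / scored_instances, 1)


def _as_record_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    from .segregation_classifier import records_to_frame

    return records_to_frame(list(records))


def estimate_loss_rate(records) -> LossRateEstimate:
    """Estimate the per-instance loss rate from paired-chromosome records.

    A loss event is a parental homolog of a paired chromosome seen in fewer
    than four spores of an ascus (disomy-labelled records are excluded from
    the event count: their deficits stem from non-disjunction, not loss).
    The rate is events per parental chromosome instance per meiosis -- two
    instances per paired record.  A chi-squared heterogeneity test compares
    loss proportions across chromosomes; the per-spore absence fraction is
    reported alongside as an alternative aggregation.
    """
    frame = _as_record_frame(records)
    if len(frame) == 0 or "pairing_status" not in frame.columns:
        raise NoDataError("no segregation records supplied")
    paired = frame[frame["pairing_status"] == "paired"]
    if len(paired) == 0:
        raise NoDataError("no paired-chromosome records: loss rate undefined")

    non_disomy = paired[paired["label"] != "disomy"]
    events = (non_disomy["carriers_p1"] < 4).astype(int) + (
        non_disomy["carriers_p2"] < 4
    ).astype(int)
    per_chrom = (
        pd.DataFrame(
            {
                "chromosome": non_disomy["chromosome"],
                "loss_events": events,
            }
        )
        .groupby("chromosome", sort=True)
        .agg(loss_events=("loss_events", "sum"), records=("loss_events", "size"))
        .reset_index()
    )
    per_chrom["instances"] = 2 * per_chrom["records"]
    per_chrom["rate"] = per_chrom["loss_events"] / per_chrom["instances"]

    total_events = int(per_chrom["loss_events"].sum())
    total_instances = int(per_chrom["instances"].sum())
    heterogeneity: TestResult | None = None
    if len(per_chrom) > 1 and 0 < total_events < total_instances:
        table = np.column_stack(
            [
                per_chrom["loss_events"],
                per_chrom["instances"] - per_chrom["loss_events"],
            ]
        )
        chi2, p, _dof, _exp = sps.chi2_contingency(table, correction=False)
        heterogeneity = TestResult(
            "chi_squared",
            float(min(p, 1.0)),
            tuple(table.flatten()),
            statistic=float(chi2),
        )

    return LossRateEstimate(
        rate=total_events / total_instances,
        loss_events=total_events,
        instances=total_instances,
        per_chromosome=per_chrom,
        heterogeneity=heterogeneity,
        spore_absence_fraction=float(
            paired["absent_spores"].sum() / paired["n_spores"].sum()
        ),
    )


# ---------------------------------------------------------------------------
# mechanism predictions and discrimination
# ---------------------------------------------------------------------------


@dataclass
class MechanismPrediction:
    """Carrier-count distribution one mechanism predicts in one context."""

    mechanism: str
    context: str
    carrier_count_distribution: dict[int, float]
    octad_complete: bool
    mc_stderr: float | None = None


def predict_patterns(
    mechanism: str,
    context: str,
    *,
    drive_penetrance: float = 1.0,
    preferential_bias: float = 1.0,
    loss_rate: float = 0.0,
    nondisjunction_rate: float = 0.0,
    premeiotic_copy_loss: bool = True,
    n_sim: int = 2000,
    seed: int = 0,
) -> MechanismPrediction:
    """Predicted distribution of carrier spores (0..8) per octad.

    Closed forms are returned where available (all zero-nuisance cases);
    otherwise the distribution is estimated by Monte-Carlo simulation of a
    canonical cross and the largest binomial standard error over the count
    classes is reported.  For the ``paired`` context the distribution refers
    to carriers of the parent-1 (female-side, in the canonical cross)
    homolog.
    """
    if mechanism not in cs.MECHANISMS:
        raise ConfigError(f"unknown mechanism {mechanism!r}")
    if context not in CONTEXTS:
        raise ConfigError(f"unknown context {context!r}")

    complete = not (mechanism == "spore_killing" and context != "paired")
    closed_form = loss_rate == 0.0 and nondisjunction_rate == 0.0

    if closed_form:
        if mechanism == "female_drive" and context == "female_unpaired":
            dist = {8: drive_penetrance, 4: 1.0 - drive_penetrance}
            dist = {k: v for k, v in dist.items() if v > 0}
        elif (
            mechanism == "premeiotic_amplification"
            and context == "female_unpaired"
        ):
            dist = {8: 1.0}
        elif (
            mechanism == "premeiotic_amplification"
            and context == "paired"
            and not premeiotic_copy_loss
        ):
            dist = {8: 1.0}  # the female homolog pairs with its extra copy
        else:
            dist = {4: 1.0}
        return MechanismPrediction(mechanism, context, dist, complete)

    # Monte-Carlo over the canonical IPO323 x IPO94269 cross: chr18 is
    # unpaired (from IPO323), chr21 is paired.
    from .strains import ipo323, ipo94269

    focal = "chr21" if context == "paired" else "chr18"
    female = 1 if context == "male_unpaired" else 0
    config = cs.CrossConfig(
        parent1=ipo323(),
        parent2=ipo94269(),
        mechanism=mechanism,
        loss_rate=loss_rate,
        nondisjunction_rate=nondisjunction_rate,
        preferential_bias=preferential_bias,
        drive_penetrance=drive_penetrance,
        n_asci=n_sim,
        seed=seed,
        killer_chromosome=focal if mechanism == "spore_killing" else None,
        premeiotic_copy_loss=premeiotic_copy_loss,
    )
    octads = cs.with_fixed_female(config, female)
    counts = np.zeros(9, dtype=float)
    for octad in octads:
        if context == "paired":
            k = octad.carrier_count(focal, parent_index=0)
        else:
            k = octad.carrier_count(focal)
        counts[k] += 1
    probs = counts / counts.sum()
    stderr = float(np.sqrt(probs * (1 - probs) / n_sim).max())
    dist = {k: float(p) for k, p in enumerate(probs) if p > 0}
    return MechanismPrediction(mechanism, context, dist, complete, mc_stderr=stderr)


@dataclass
class DiscriminationResult:
    """Mechanisms consistent with observed segregation, plus exclusions."""

    consistent: set[str]
    excluded: dict[str, str]
    notes: list[str] = field(default_factory=list)


def label_counts_from_records(
    records,
) -> dict[str, dict[str, int]]:
    """Tally segregation labels by pairing context for the discriminator."""
    frame = _as_record_frame(records)
    out: dict[str, dict[str, int]] = {}
    for (context, label), n in (
        frame.groupby(["pairing_status", "label"]).size().items()
    ):
        out.setdefault(str(context), {})[str(label)] = int(n)
    return out


def discriminate_mechanisms(
    label_counts: Mapping[str, Mapping[str, int]],
    octads_complete: "bool | float",
    *,
    disomy_excess_threshold: float = 0.05,
) -> DiscriminationResult:
    """Apply the falsification rules to observed label counts.

    ``octads_complete`` is True/False or the fraction of asci that passed
    verification with all eight spores (treated as complete at >= 0.9 and as
    systematically incomplete at <= 0.1).  Each excluded mechanism carries a
    one-line reason; mechanisms never positively excluded remain in the
    consistent set, with a note when drive mechanisms at zero penetrance are
    indistinguishable from Mendelian segregation.
    """
    # accept both the classifier's pairing_status vocabulary
    # ("unpaired_female") and the prediction contexts ("female_unpaired")
    aliases = {"unpaired_female": "female_unpaired", "unpaired_male": "male_unpaired"}
    label_counts = {
        aliases.get(context, context): dict(labels)
        for context, labels in label_counts.items()
    }
    total = sum(
        n for context in label_counts.values() for n in context.values()
    )
    if total == 0:
        raise NoDataError("no segregation labels to discriminate on")

    if isinstance(octads_complete, bool):
        frac_complete = 1.0 if octads_complete else 0.0
    else:
        frac_complete = float(octads_complete)

    excluded: dict[str, str] = {}
    notes: list[str] = []

    if frac_complete >= 0.9:
        excluded["spore_killing"] = (
            "complete eight-spore octads were recovered; spore killing would "
            "make complete tetrads impossible to isolate"
        )
    elif frac_complete <= 0.1:
        for mech in (
            "mendelian",
            "female_drive",
            "preferential_segregation",
            "premeiotic_amplification",
        ):
            excluded[mech] = (
                "octads are systematically incomplete; this mechanism leaves "
                "all eight ascospores intact"
            )

    fu = label_counts.get("female_unpaired", {})
    fu_total = sum(fu.values())
    if fu_total > 0 and fu.get("drive_8_0", 0) > fu_total / 2:
        excluded.setdefault(
            "mendelian",
            "female-inherited unpaired chromosomes are mostly present in all "
            "eight spores, above the Mendelian 4:0 ceiling",
        )
        excluded.setdefault(
            "preferential_segregation",
            "preferential segregation cannot place an unpaired chromosome in "
            "more than four of the eight spores",
        )

    paired = label_counts.get("paired", {})
    p_total = sum(paired.values())
    if p_total > 0:
        disomy_frac = paired.get("disomy", 0) / p_total
        mendelian_frac = paired.get("mendelian_4_4", 0) / p_total
        if disomy_frac <= disomy_excess_threshold and mendelian_frac >= 0.5:
            excluded.setdefault(
                "premeiotic_amplification",
                "paired chromosomes segregate 4:4 without disomy excess; "
                "pre-meiotic amplification would leave trisomic zygotes and "
                "disomic spores",
            )
        elif disomy_frac > disomy_excess_threshold:
            for mech, why in (
                (
                    "female_drive",
                    "widespread disomy of paired chromosomes is not produced "
                    "by a meiosis-restricted amplification of unpaired "
                    "chromosomes",
                ),
                (
                    "mendelian",
                    "disomy excess on paired chromosomes exceeds Mendelian "
                    "expectation",
                ),
                (
                    "preferential_segregation",
                    "disomy excess on paired chromosomes exceeds what biased "
                    "pole choice of single copies can produce",
                ),
            ):
                excluded.setdefault(mech, why)

    consistent = set(cs.MECHANISMS) - set(excluded)
    if fu_total > 0 and fu.get("drive_8_0", 0) == 0 and "mendelian" in consistent:
        drive_like = consistent & {"female_drive", "premeiotic_amplification"}
        if drive_like:
            notes.append(
                "no drive signature observed: "
                + ", ".join(sorted(drive_like))
                + " remain consistent only at zero penetrance and are "
                "indistinguishable from Mendelian segregation"
            )
    return DiscriminationResult(consistent=consistent, excluded=excluded, notes=notes)
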