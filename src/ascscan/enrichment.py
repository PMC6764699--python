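"""Positional ASC frequencies, sign-test batteries, and enrichment calls.

Observed ASC frequencies (overall or stratified by primary stop and
expression class) are compared with a null (dinucleotide chain or
geometric first-stop model) in three ways: Z-score sign/deviation binomial
batteries across genomes, per-position 1-df chi-square goodness-of-fit
calls per genome, and genome-set comparisons against the analytic
1 - 0.99^5 genome-level null.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .null_models import (
    POSITIONS,
    WHOLE,
    FirstStopNull,
    NullDistribution,
    first_stop_probability,
)
from .sequence_io import GenomeUTRSet

logger = logging.getLogger(__name__)

#: per-position alpha for positional chi-square calls (0.05 over 5 positions)
POSITIONAL_ALPHA = 0.05 / 5
#: genome-level null probability of >=1 enriched position among +2..+6
GENOME_NULL_P = 1 - 0.99**5
#: positions entering genome-level calls; +1 is excluded by default because
#: of its +4T confound
CALL_POSITIONS = (2, 3, 4, 5, 6)
#: one-tailed Bonferroni Z threshold for the Z-score genome-level rule
Z_CALL_THRESHOLD = 2.33


@dataclass
class TestResult:
    name: str
    statistic: float
    pvalue: float
    tails: int = 2
    df: int | None = None
    extra: dict = field(default_factory=dict)


@dataclass
class PositionalFrequencies:
    genome_id: str
    primary_stop: str  # TAA | TGA | TAG | any
    expression: str  # HEG | LEG | all
    freq: dict  # position -> fraction, plus "whole"
    n_genes: int


@dataclass
class EnrichmentCall:
    genome_id: str
    scheme: str  # zscore | chi2_dinuc | chi2_firststop
    per_position: dict  # position -> (statistic, pvalue, direction)
    enriched: bool


def downstream_codon(record, position: int) -> str:
    return record.downstream_seq[3 * (position - 1) : 3 * position]


def select_stratum(utr_set: GenomeUTRSet, primary_stop="any", expression="all"):
    recs = utr_set.records
    if primary_stop != "any":
        recs = [r for r in recs if r.primary_stop == primary_stop]
    if expression != "all":
        recs = [r for r in recs if r.expression_class == expression]
    return recs


def positional_asc_frequencies(
    utr_set: GenomeUTRSet,
    primary_stop: str = "any",
    expression: str = "all",
    positions=POSITIONS,
) -> PositionalFrequencies | None:
    """Fraction of stratum genes with a stop codon at each position +k,
    plus the whole-UTR frequency (>=1 stop anywhere at +1..+6). Stop
    membership honours the genome's translation table."""
    recs = select_stratum(utr_set, primary_stop, expression)
    if not recs:
        logger.info(
            "empty stratum (%s, %s) in %s", primary_stop, expression, utr_set.genome_id
        )
        return None
    stop_set = utr_set.stop_set
    freq: dict = {}
    hit_any = np.zeros(len(recs), dtype=bool)
    for k in positions:
        hits = np.array([downstream_codon(r, k) in stop_set for r in recs])
        freq[k] = float(hits.mean())
        hit_any |= hits
    freq[WHOLE] = float(hit_any.mean())
    return PositionalFrequencies(
        utr_set.genome_id, primary_stop, expression, freq, len(recs)
    )


def observed_stop_counts(utr_set: GenomeUTRSet, positions=POSITIONS) -> dict:
    """Per-position counts of genes whose codon +k is a stop."""
    stop_set = utr_set.stop_set
    return {
        k: sum(1 for r in utr_set.records if downstream_codon(r, k) in stop_set)
        for k in positions
    }


def first_stop_counts(utr_set: GenomeUTRSet, positions=POSITIONS) -> dict:
    """Per-position counts of genes whose FIRST downstream stop is at +k."""
    stop_set = utr_set.stop_set
    counts = {k: 0 for k in positions}
    for r in utr_set.records:
        for k in positions:
            if downstream_codon(r, k) in stop_set:
                counts[k] += 1
                break
    return counts


# ---------------------------------------------------------------------------
# Z-score binomial battery


def sign_test_battery(
    zscores: dict,
    z_two_tailed: float = 1.96,
    z_one_tailed: float = 1.64,
    deviation_rate: float = 0.05,
    n_tests: int = 6,
) -> list[TestResult]:
    """The four binomial tests per position and for the whole UTR.

    ``zscores`` maps genome_id -> {position or "whole" -> Z}. Tests:
    (a) #(Z>0) against 0.5, two-tailed; (b) #(|Z|>1.96) against 5%,
    two-tailed; (c) #(Z>1.64) against 5%, one-tailed (fewer than expected
    indicates a dearth of significant enrichment); (d) #(Z<-1.64) against
    5%, one-tailed (more than expected indicates excess depletion). Each
    result notes whether it survives Bonferroni at 0.05/n_tests.
    """
    results: list[TestResult] = []
    keys = list(POSITIONS) + [WHOLE]
    for key in keys:
        zs = np.array([z[key] for z in zscores.values() if key in z])
        n = len(zs)
        if n == 0:
            continue
        specs = [
            ("positive_z", int((zs > 0).sum()), 0.5, "two-sided"),
            ("deviated", int((np.abs(zs) > z_two_tailed).sum()), deviation_rate, "two-sided"),
            ("enriched_one_tailed", int((zs > z_one_tailed).sum()), deviation_rate, "less"),
            ("depleted_one_tailed", int((zs < -z_one_tailed).sum()), deviation_rate, "greater"),
        ]
        for name, count, p0, alt in specs:
            res = stats.binomtest(count, n, p0, alternative=alt)
            results.append(
                TestResult(
                    f"{name}@{key}",
                    float(count),
                    float(res.pvalue),
                    tails=2 if alt == "two-sided" else 1,
                    extra={
                        "n": n,
                        "null_p": p0,
                        "bonferroni_significant": res.pvalue < 0.05 / n_tests,
                    },
                )
            )
    return results


# ---------------------------------------------------------------------------
# Chi-square positional calls


def _chi2_gof(observed: float, expected: float, n: int) -> tuple[float, float]:
    """1-df Pearson goodness of fit on (stop, non-stop) counts, no
    continuity correction."""
    e_other = n - expected
    stat = (observed - expected) ** 2 * (1 / expected + 1 / e_other)
    return stat, float(stats.chi2.sf(stat, 1))


def chi2_positional_calls(
    observed_counts: dict,
    n_genes: int,
    null,
    positions=CALL_POSITIONS,
    alpha: float = POSITIONAL_ALPHA,
    genome_id: str = "",
    scheme: str | None = None,
) -> EnrichmentCall:
    """Per-position chi-square enrichment call for one genome.

    With a :class:`NullDistribution`, ``observed_counts`` are per-position
    stop counts and the expected count is n * null mean. With a
    :class:`FirstStopNull`, they are first-stop counts and the expected is
    n * p(1-p)^(n-1). A genome is enriched when at least one position shows
    observed > expected with p < alpha.
    """
    if isinstance(null, FirstStopNull):
        scheme = scheme or "chi2_firststop"
        expected = {k: n_genes * first_stop_probability(null.p, k) for k in positions}
    elif isinstance(null, NullDistribution):
        scheme = scheme or "chi2_dinuc"
        expected = {k: n_genes * null.mean[k] for k in positions}
    else:
        raise TypeError("null must be a NullDistribution or FirstStopNull")
    per_position: dict = {}
    enriched = False
    for k in positions:
        e = expected[k]
        if e <= 0 or e >= n_genes:
            logger.warning("degenerate expected count at +%d; position skipped", k)
            continue
        o = observed_counts[k]
        stat, p = _chi2_gof(o, e, n_genes)
        direction = "+" if o > e else "-"
        per_position[k] = (stat, p, direction)
        if direction == "+" and p < alpha:
            enriched = True
    return EnrichmentCall(genome_id, scheme, per_position, enriched)


def zscore_call(
    zscores: dict,
    positions=CALL_POSITIONS,
    threshold: float = Z_CALL_THRESHOLD,
    genome_id: str = "",
) -> EnrichmentCall:
    """Z-score genome-level rule: enriched iff any position has
    Z > threshold (one-tailed, Bonferroni-corrected)."""
    per_position = {
        k: (zscores[k], float(stats.norm.sf(zscores[k])), "+" if zscores[k] > 0 else "-")
        for k in positions
        if k in zscores and math.isfinite(zscores[k])
    }
    enriched = any(zscores[k] > threshold for k in positions if k in zscores)
    return EnrichmentCall(genome_id, "zscore", per_position, enriched)


# ---------------------------------------------------------------------------
# Genome-set comparisons


def chi2_2x2_corrected(a: tuple[int, int], b: tuple[int, int]) -> tuple[float, float]:
    """2x2 Pearson chi-square with continuity correction subtracting
    min(0.5, |O-E|) from each |O-E|."""
    table = np.array([a, b], dtype=float)
    if table.sum() == 0:
        raise ValueError("empty 2x2 table")
    rows = table.sum(axis=1, keepdims=True)
    cols = table.sum(axis=0, keepdims=True)
    expected = rows @ cols / table.sum()
    dev = np.abs(table - expected)
    dev = dev - np.minimum(0.5, dev)
    stat = float((dev**2 / expected).sum())
    return stat, float(stats.chi2.sf(stat, 1))


def compare_genome_sets(
    set_a: tuple[int, int],
    set_b: tuple[int, int],
    p0: float = GENOME_NULL_P,
) -> list[TestResult]:
    """Within-set binomial tests against the genome-level null and the
    between-set continuity-corrected 2x2 chi-square.

    ``set_a``/``set_b`` are (enriched, not-enriched) genome counts. The
    one-tailed direction of each binomial test follows the observed count
    relative to its expectation; expected counts are reported rounded.
    """
    if sum(set_a) == 0 or sum(set_b) == 0:
        raise ValueError("genome sets must be non-empty")
    results = []
    for label, (enriched, not_enriched) in (("set_a", set_a), ("set_b", set_b)):
        n = enriched + not_enriched
        expected = n * p0
        alt = "greater" if enriched > expected else "less"
        res = stats.binomtest(enriched, n, p0, alternative=alt)
        results.append(
            TestResult(
                f"binomial_{label}",
                float(enriched),
                float(res.pvalue),
                tails=1,
                extra={"n": n, "expected": round(expected), "direction": alt},
            )
        )
    stat, p = chi2_2x2_corrected(set_a, set_b)
    results.append(
        TestResult("between_sets_chi2", stat, p, tails=2, df=1,
                   extra={"set_a": set_a, "set_b": set_b})
    )
    return results


# ---------------------------------------------------------------------------
# Stratified rank tests and correlation utilities


def paired_rank_test(x, y, alternative: str = "two-sided") -> TestResult:
    """Wilcoxon signed-rank on paired per-genome values; zero differences
    dropped; exact distribution for n <= 25, normal approximation above."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    d = x - y
    d = d[d != 0]
    if len(d) == 0:
        return TestResult("paired_rank", 0.0, 1.0, tails=2 if alternative == "two-sided" else 1)
    method = "exact" if len(d) <= 25 and len(np.unique(np.abs(d))) == len(d) else "approx"
    res = stats.wilcoxon(d, alternative=alternative, method=method)
    return TestResult(
        "paired_rank",
        float(res.statistic),
        float(res.pvalue),
        tails=2 if alternative == "two-sided" else 1,
        extra={"n_nonzero": len(d)},
    )


def rank_correlation(x, y) -> TestResult:
    rho, p = stats.spearmanr(x, y)
    return TestResult("spearman", float(rho), float(p))


def regression_slope(x, y) -> TestResult:
    res = stats.linregress(x, y)
    return TestResult(
        "ls_slope", float(res.slope), float(res.pvalue),
        extra={"intercept": float(res.intercept), "r": float(res.rvalue)},
    )


def stratified_tests(
    frequencies: list[PositionalFrequencies],
    gc3: dict | None = None,
) -> list[TestResult]:
    """Cross-genome stratified battery on a list of per-genome,
    per-stratum positional frequencies.

    Emits: paired HEG-vs-LEG tests per position and whole-UTR; the
    TGA-HEG vs TAA-LEG contrast; Kruskal-Wallis heterogeneity across
    primary stops within each expression class (with post-hoc paired rank
    tests when significant); and, when ``gc3`` maps genome_id -> GC3,
    Spearman correlations plus least-squares slopes of the all-genes
    frequency on GC3.
    """
    by_key: dict = {}
    for f in frequencies:
        by_key.setdefault((f.primary_stop, f.expression), {})[f.genome_id] = f
    results: list[TestResult] = []
    keys = list(POSITIONS) + [WHOLE]

    def paired(stratum_a, stratum_b, label):
        a, b = by_key.get(stratum_a, {}), by_key.get(stratum_b, {})
        genomes = sorted(set(a) & set(b))
        if len(genomes) < 6:
            logger.warning("fewer than 6 paired genomes for %s; skipped", label)
            return
        for key in keys:
            t = paired_rank_test(
                [a[g].freq[key] for g in genomes], [b[g].freq[key] for g in genomes]
            )
            t.name = f"{label}@{key}"
            results.append(t)

    paired(("any", "HEG"), ("any", "LEG"), "heg_vs_leg")
    paired(("TGA", "HEG"), ("TAA", "LEG"), "tga_heg_vs_taa_leg")

    for expr in ("all", "HEG", "LEG"):
        strata = [by_key.get((s, expr), {}) for s in ("TAA", "TGA", "TAG")]
        genomes = sorted(set(strata[0]) & set(strata[1]) & set(strata[2]))
        if len(genomes) < 6:
            continue
        for key in keys:
            groups = [[s[g].freq[key] for g in genomes] for s in strata]
            stat, p = stats.kruskal(*groups)
            results.append(
                TestResult(f"kruskal_{expr}@{key}", float(stat), float(p), df=2,
                           extra={"n": len(genomes)})
            )
            if p < 0.05:
                for (i, si), (j, sj) in (((0, "TAA"), (1, "TGA")), ((1, "TGA"), (2, "TAG")), ((0, "TAA"), (2, "TAG"))):
                    t = paired_rank_test(groups[i], groups[j])
                    t.name = f"posthoc_{si}_vs_{sj}_{expr}@{key}"
                    results.append(t)

    if gc3 is not None:
        allg = by_key.get(("any", "all"), {})
        genomes = sorted(set(allg) & set(gc3))
        if len(genomes) >= 10:
            xs = [gc3[g] for g in genomes]
            for key in keys:
                ys = [allg[g].freq[key] for g in genomes]
                t = rank_correlation(xs, ys)
                t.name = f"freq_vs_gc3_spearman@{key}"
                results.append(t)
                s = regression_slope(xs, ys)
                s.name = f"freq_vs_gc3_slope@{key}"
                results.append(s)
    return results
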