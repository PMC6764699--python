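"""Stop-codon context analyses: +4 base, T-starting codons, and frames.

The fourth site (the first nucleotide after the primary stop, i.e. the
first base of codon +1) modulates termination efficiency: a +4T improves
release-factor cross-linking. These analyses ask whether apparent
stop-codon enrichment immediately after the stop is better explained by
nucleotide-level motif preferences (+4T, TT/TC-starting codons) than by
selection for stops per se, whether an ASC predicts further downstream
ASCs, whether ASCs carry the +4T signature of functional stops, and
whether relative TAA:TGA:TAG usage downstream tracks primary-stop usage
across reading frames and GC3.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np

from .enrichment import (
    TestResult,
    downstream_codon,
    paired_rank_test,
    rank_correlation,
    select_stratum,
)
from .null_models import NUCS, POSITIONS
from .sequence_io import GenomeUTRSet

logger = logging.getLogger(__name__)

ALL_CODONS = ["".join(c) for c in itertools.product(NUCS, repeat=3)]
CANONICAL_STOPS = ("TAA", "TGA", "TAG")


@dataclass
class ContextProfile:
    genome_id: str
    primary_stop: str
    expression: str
    fourth_base_freq: dict  # base -> fraction
    t_start_freq: dict  # position -> fraction of codons starting with T
    n_genes: int


def fourth_site_profile(
    utr_set: GenomeUTRSet, primary_stop: str = "any", expression: str = "all"
) -> ContextProfile | None:
    """Per-stratum +4 base frequencies and T-starting codon frequency at
    each downstream position."""
    recs = select_stratum(utr_set, primary_stop, expression)
    if not recs:
        return None
    fourth = {b: 0 for b in NUCS}
    for r in recs:
        fourth[r.downstream_seq[0]] += 1
    n = len(recs)
    t_start = {
        k: sum(1 for r in recs if downstream_codon(r, k)[0] == "T") / n
        for k in POSITIONS
    }
    return ContextProfile(
        utr_set.genome_id,
        primary_stop,
        expression,
        {b: c / n for b, c in fourth.items()},
        t_start,
        n,
    )


def t_vs_next_highest_test(profiles: list[ContextProfile]) -> TestResult:
    """Across genomes: is +4T more frequent than the next most frequent
    +4 base? Paired rank test of T frequency against the max of A/C/G."""
    t = [p.fourth_base_freq["T"] for p in profiles]
    other = [max(p.fourth_base_freq[b] for b in "ACG") for p in profiles]
    res = paired_rank_test(t, other, alternative="greater")
    res.name = "fourth_site_T_vs_next"
    return res


def t_start_position1_test(
    utr_sets: list[GenomeUTRSet],
    variant: str = "all",
    primary_stop: str = "any",
    expression: str = "all",
) -> TestResult:
    """Across genomes: T-starting codon frequency at +1 versus the mean
    T-starting frequency over +1..+6 (paired rank, one-tailed for excess).

    Variants: "all" counts every gene; "no_plus1_asc" restricts to genes
    lacking a +1 stop; "nonstop_t" counts only non-stop T-starting codons.
    """
    at1, mean_all = [], []
    for uset in utr_sets:
        recs = select_stratum(uset, primary_stop, expression)
        if variant == "no_plus1_asc":
            recs = [r for r in recs if downstream_codon(r, 1) not in uset.stop_set]
        if not recs:
            continue

        def t_freq(position: int) -> float:
            hits = 0
            for r in recs:
                c = downstream_codon(r, position)
                if c[0] != "T":
                    continue
                if variant == "nonstop_t" and c in uset.stop_set:
                    continue
                hits += 1
            return hits / len(recs)

        freqs = {k: t_freq(k) for k in POSITIONS}
        at1.append(freqs[1])
        mean_all.append(np.mean(list(freqs.values())))
    res = paired_rank_test(at1, mean_all, alternative="greater")
    res.name = f"t_start_plus1_vs_utr_mean[{variant}]"
    res.extra["n_genomes"] = len(at1)
    return res


def tt_tc_start_test(utr_sets: list[GenomeUTRSet], prefix: str = "TT") -> TestResult:
    """Fifth-site analysis: frequency of prefix-starting (TT or TC) codons
    at +1 versus the +1..+6 mean, paired across genomes."""
    at1, mean_all = [], []
    for uset in utr_sets:
        recs = uset.records
        if not recs:
            continue
        freqs = {
            k: sum(1 for r in recs if downstream_codon(r, k).startswith(prefix)) / len(recs)
            for k in POSITIONS
        }
        at1.append(freqs[1])
        mean_all.append(np.mean(list(freqs.values())))
    res = paired_rank_test(at1, mean_all, alternative="greater")
    res.name = f"{prefix.lower()}_start_plus1_vs_utr_mean"
    return res


def codon_positional_frequency(
    utr_set: GenomeUTRSet, codon: str, position: int,
    primary_stop: str = "any", expression: str = "all",
) -> float:
    recs = select_stratum(utr_set, primary_stop, expression)
    if not recs:
        return float("nan")
    return sum(1 for r in recs if downstream_codon(r, position) == codon) / len(recs)


def codon_enrichment_score(F1: float, F3: float, F4: float, F5: float, F6: float) -> float:
    """Position +1 enrichment of a codon relative to its own downstream
    baseline: F1 / mean(F3, F4, F5, F6) - 1. Position +2 is excluded from
    the baseline."""
    denom = (F3 + F4 + F5 + F6) / 4
    if denom == 0:
        raise ZeroDivisionError("zero baseline frequency")
    return F1 / denom - 1


def codon_enrichment_table(
    utr_set: GenomeUTRSet, codons=None, primary_stop="any", expression="all"
) -> dict:
    """Enrichment score per codon (skipping codons with a zero baseline)."""
    scores = {}
    for codon in codons or ALL_CODONS:
        fs = [
            codon_positional_frequency(utr_set, codon, k, primary_stop, expression)
            for k in (1, 3, 4, 5, 6)
        ]
        try:
            scores[codon] = codon_enrichment_score(*fs)
        except ZeroDivisionError:
            logger.info("codon %s has zero baseline in %s; skipped", codon, utr_set.genome_id)
    return scores


# ---------------------------------------------------------------------------
# Conditional downstream ASC analyses


def conditional_downstream_asc(
    utr_sets: list[GenomeUTRSet], focal: int, mode: str = "any-downstream"
) -> TestResult:
    """Does an ASC at or before position +N predict downstream ASC content?

    Per genome, genes are split by presence of >=1 stop at positions <= N;
    the downstream ASC frequency (over N+1..+6, or exactly N+1 in
    "next-position" mode) is compared between groups, then a one-tailed
    paired rank test runs across genomes (fail-safe direction: containing
    group lower).
    """
    if not 1 <= focal <= 5:
        raise ValueError("focal position must be +1..+5 (no downstream left after +6)")
    down = (focal + 1,) if mode == "next-position" else tuple(range(focal + 1, 7))
    with_asc, without_asc = [], []
    for uset in utr_sets:
        stop_set = uset.stop_set
        grp = {True: [], False: []}
        for r in uset.records:
            has = any(downstream_codon(r, k) in stop_set for k in range(1, focal + 1))
            f = np.mean([downstream_codon(r, k) in stop_set for k in down])
            grp[has].append(f)
        if grp[True] and grp[False]:
            with_asc.append(float(np.mean(grp[True])))
            without_asc.append(float(np.mean(grp[False])))
    res = paired_rank_test(with_asc, without_asc, alternative="less")
    res.name = f"conditional_asc[N=+{focal},{mode}]"
    res.extra["n_genomes"] = len(with_asc)
    return res


# ---------------------------------------------------------------------------
# ASC-followed-by-T analyses


def following_base_probabilities(
    utr_set: GenomeUTRSet, stop_variant: str = "any"
) -> dict | None:
    """P(next base is T) after primary stops, after ASCs, and after
    non-ASC downstream codons (plus the non-stop-ending-in-A control).

    The following base of a codon at +k is the first base of codon +k+1
    within the stored window; codons with no stored following base are
    excluded.
    """
    stop_set = utr_set.stop_set
    prim_t = prim_n = asc_t = asc_n = non_t = non_n = ctrl_t = ctrl_n = 0
    for r in utr_set.records:
        if stop_variant in ("any", r.primary_stop):
            prim_t += r.downstream_seq[0] == "T"
            prim_n += 1
        max_pos = len(r.downstream_seq) // 3
        for k in range(1, min(6, max_pos - 1) + 1):
            codon = downstream_codon(r, k)
            nxt = r.downstream_seq[3 * k]
            if codon in stop_set:
                if stop_variant in ("any", codon):
                    asc_t += nxt == "T"
                    asc_n += 1
            else:
                non_t += nxt == "T"
                non_n += 1
                if codon.endswith("A"):
                    ctrl_t += nxt == "T"
                    ctrl_n += 1
    if asc_n == 0:
        return None
    return {
        "primary": prim_t / prim_n if prim_n else float("nan"),
        "asc": asc_t / asc_n,
        "non_asc": non_t / non_n if non_n else float("nan"),
        "non_asc_end_A": ctrl_t / ctrl_n if ctrl_n else float("nan"),
    }


def asc_followed_by_T(
    utr_sets: list[GenomeUTRSet], stop_variant: str = "any"
) -> list[TestResult]:
    """Paired rank tests across genomes of P(T | after ASC) against
    P(T | after primary stop) and against P(T | after non-ASC codon),
    plus the dinucleotide control restricted to non-stop codons ending
    in A. Genomes with no ASCs of the requested variant are excluded."""
    probs = [following_base_probabilities(u, stop_variant) for u in utr_sets]
    probs = [p for p in probs if p is not None]
    results = []
    for other, label in (("primary", "vs_primary"), ("non_asc", "vs_non_asc"),
                         ("non_asc_end_A", "vs_non_asc_end_A")):
        pairs = [(p["asc"], p[other]) for p in probs if np.isfinite(p[other])]
        if not pairs:
            continue
        res = paired_rank_test([a for a, _ in pairs], [b for _, b in pairs])
        res.name = f"asc_plus4T[{stop_variant}]_{label}"
        res.extra["n_genomes"] = len(pairs)
        results.append(res)
    return results


# ---------------------------------------------------------------------------
# Relative stop usage by position and reading frame versus GC3


def relative_stop_usage(
    utr_set: GenomeUTRSet, frame: int = 0, positions=POSITIONS
) -> dict | None:
    """Relative TAA:TGA:TAG proportions among occurrences of the three
    canonical stop triplets in downstream windows read at frame offset 0,
    1, or 2; frame=-1 tallies primary-stop usage instead. Proportions are
    of canonical-triplet occurrences regardless of translation table."""
    counts = {s: 0 for s in CANONICAL_STOPS}
    if frame == -1:
        for r in utr_set.records:
            if r.primary_stop in counts:
                counts[r.primary_stop] += 1
    else:
        for r in utr_set.records:
            for k in positions:
                lo = frame + 3 * (k - 1)
                c = r.downstream_seq[lo : lo + 3]
                if c in counts:
                    counts[c] += 1
    total = sum(counts.values())
    if total == 0:
        return None
    return {s: c / total for s, c in counts.items()}


def stop_usage_by_frame(
    utr_sets: list[GenomeUTRSet], gc3: dict | None = None
) -> tuple[dict, list[TestResult]]:
    """Per-genome relative stop usage at the primary site and in the three
    downstream frames, with Spearman correlations of each proportion
    against GC3 across genomes (>=10 genomes per frame required)."""
    usage: dict = {}
    for frame, label in ((-1, "primary"), (0, "in-frame"), (1, "+1 shift"), (2, "+2 shift")):
        for uset in utr_sets:
            props = relative_stop_usage(uset, frame)
            if props is None:
                logger.info("no stop occurrences in %s frame %s", uset.genome_id, label)
                continue
            usage.setdefault(label, {})[uset.genome_id] = props
    results: list[TestResult] = []
    if gc3 is not None:
        for label, per_genome in usage.items():
            genomes = sorted(set(per_genome) & set(gc3))
            if len(genomes) < 10:
                continue
            xs = [gc3[g] for g in genomes]
            for s in CANONICAL_STOPS:
                t = rank_correlation(xs, [per_genome[g][s] for g in genomes])
                t.name = f"usage_vs_gc3[{label},{s}]"
                results.append(t)
    return usage, results
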