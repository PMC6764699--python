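"""TT4 versus TT11 downstream codon usage: LOESS and GC-matched tests.

Translation-table-4 mollicutes read TGA as tryptophan, so TGA carries no
termination role there. If TGA is maintained downstream of stops in TT11
genomes because it acts as a fail-safe stop, TT4 genomes should under-use
TGA at downstream positions relative to GC3-matched TT11 expectation.
Expectation is formed two ways: a LOESS fit of per-position codon
frequency against GC3 across TT11 genomes, and direct GC3-window matching
(|dGC3| <= 0.035). The same machinery ranks all 64 codons by their
one-tailed deficit p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .enrichment import TestResult, paired_rank_test
from .stop_context import ALL_CODONS

logger = logging.getLogger(__name__)

DEFAULT_SPAN = 2 / 3
POSITIONS = (1, 2, 3, 4, 5, 6)


@dataclass
class LoessModel:
    """Local linear regression with tricube weights over the span-fraction
    nearest neighbours; no robustness iterations; predictions clipped to
    [0, 1]; no extrapolation beyond the training GC3 range."""

    x: np.ndarray
    y: np.ndarray
    span: float = DEFAULT_SPAN

    def __post_init__(self):
        order = np.argsort(self.x, kind="stable")
        self.x = np.asarray(self.x, dtype=float)[order]
        self.y = np.asarray(self.y, dtype=float)[order]
        if not 0 < self.span <= 1:
            raise ValueError("span must lie in (0, 1]")
        if len(self.x) < 10:
            raise ValueError("need at least 10 training points")

    def predict(self, x_query) -> np.ndarray:
        xq = np.atleast_1d(np.asarray(x_query, dtype=float))
        if xq.min() < self.x.min() or xq.max() > self.x.max():
            raise ValueError(
                f"query outside training range [{self.x.min():.4f}, {self.x.max():.4f}]"
            )
        k = max(2, int(np.ceil(self.span * len(self.x))))
        out = np.empty(len(xq))
        for i, x0 in enumerate(xq):
            d = np.abs(self.x - x0)
            h = np.sort(d)[k - 1]
            if h == 0:
                out[i] = self.y[d == 0].mean()
                continue
            w = np.clip(1 - (d / h) ** 3, 0, None) ** 3
            sw = w.sum()
            xb = (w * self.x).sum() / sw
            yb = (w * self.y).sum() / sw
            sxx = (w * (self.x - xb) ** 2).sum()
            if sxx == 0:
                out[i] = yb
            else:
                slope = (w * (self.x - xb) * (self.y - yb)).sum() / sxx
                out[i] = yb + slope * (x0 - xb)
        return np.clip(out, 0.0, 1.0)


def loess_fit_predict(training, query_gc3, span: float = DEFAULT_SPAN) -> np.ndarray:
    """Fit on (GC3, frequency) pairs and predict at the query GC3 values."""
    xs, ys = zip(*training)
    return LoessModel(np.array(xs), np.array(ys), span).predict(query_gc3)


def tt4_deficit_test(
    tt4_freqs: dict,
    tt4_gc3: dict,
    tt11_freqs: dict,
    tt11_gc3: dict,
    codon: str = "TGA",
    positions=POSITIONS,
    span: float = DEFAULT_SPAN,
) -> list[TestResult]:
    """One-tailed paired rank tests of observed - LOESS-predicted codon
    frequency across TT4 genomes, per position plus a whole-UTR variant
    (the +1..+6 mean frequency). ``*_freqs`` map genome_id ->
    {position -> frequency of the codon}; ``*_gc3`` map genome_id -> GC3.
    Run with TT11 mollicute inputs as the negative control.
    """
    tt4_ids = sorted(set(tt4_freqs) & set(tt4_gc3))
    tt11_ids = sorted(set(tt11_freqs) & set(tt11_gc3))
    if len(tt4_ids) < 6:
        logger.warning("fewer than 6 focal genomes; descriptive only")
    results: list[TestResult] = []
    obs_by_pos, pred_by_pos = {}, {}
    for k in positions:
        training = [(tt11_gc3[g], tt11_freqs[g][k]) for g in tt11_ids]
        model = LoessModel(*map(np.array, zip(*training)), span=span)
        obs = np.array([tt4_freqs[g][k] for g in tt4_ids])
        pred = model.predict([tt4_gc3[g] for g in tt4_ids])
        obs_by_pos[k], pred_by_pos[k] = obs, pred
        res = paired_rank_test(obs, pred, alternative="less")
        res.name = f"loess_deficit[{codon}]@{k}"
        res.extra.update(
            n_genomes=len(tt4_ids),
            mean_difference=float((obs - pred).mean()),
            bonferroni_significant=res.pvalue < 0.05 / 6,
        )
        results.append(res)
    whole_obs = np.mean([obs_by_pos[k] for k in positions], axis=0)
    whole_pred = np.mean([pred_by_pos[k] for k in positions], axis=0)
    res = paired_rank_test(whole_obs, whole_pred, alternative="less")
    res.name = f"loess_deficit[{codon}]@whole"
    res.extra["n_genomes"] = len(tt4_ids)
    results.append(res)
    return results


def gc_matched_comparison(
    focal_gc3: float,
    focal_freqs: dict,
    tt11_freqs: dict,
    tt11_gc3: dict,
    tolerance: float = 0.035,
    positions=POSITIONS,
) -> dict | None:
    """Per-position difference between a focal TT4 genome's codon
    frequency and the mean over TT11 genomes whose GC3 lies within
    ``tolerance`` (absolute). Returns None when no TT11 genome matches."""
    matched = [g for g in tt11_freqs if abs(tt11_gc3[g] - focal_gc3) <= tolerance]
    if not matched:
        logger.warning("no TT11 genome within %.3f GC3 of %.3f", tolerance, focal_gc3)
        return None
    return {
        k: focal_freqs[k] - float(np.mean([tt11_freqs[g][k] for g in matched]))
        for k in positions
    }


def gc_matched_test(
    tt4_freqs: dict,
    tt4_gc3: dict,
    tt11_freqs: dict,
    tt11_gc3: dict,
    tolerance: float = 0.035,
    positions=POSITIONS,
) -> list[TestResult]:
    """Aggregate GC-matched differences across TT4 genomes with one-tailed
    paired rank tests (deficit direction) per position."""
    diffs = {k: [] for k in positions}
    for g in sorted(tt4_freqs):
        d = gc_matched_comparison(
            tt4_gc3[g], tt4_freqs[g], tt11_freqs, tt11_gc3, tolerance, positions
        )
        if d is None:
            continue
        for k in positions:
            diffs[k].append(d[k])
    results = []
    for k in positions:
        res = paired_rank_test(diffs[k], [0.0] * len(diffs[k]), alternative="less")
        res.name = f"gc_matched_deficit@{k}"
        res.extra["n_genomes"] = len(diffs[k])
        results.append(res)
    return results


def rank_codon_deficits(
    tt4_codon_freqs: dict,
    tt4_gc3: dict,
    tt11_codon_freqs: dict,
    tt11_gc3: dict,
    positions=POSITIONS,
    span: float = DEFAULT_SPAN,
) -> dict:
    """Rank all 64 codons by one-tailed LOESS-deficit p-value per position.

    ``*_codon_freqs`` map genome_id -> {codon -> {position -> frequency}}.
    Returns {position -> list of (codon, pvalue, rank)} sorted ascending
    by p; tied p-values share the minimum rank, display order is
    codon-alphabetical within ties.
    """
    out = {}
    for k in positions:
        pvals = []
        for codon in ALL_CODONS:
            t4 = {g: {k: tt4_codon_freqs[g][codon][k]} for g in tt4_codon_freqs}
            t11 = {g: {k: tt11_codon_freqs[g][codon][k]} for g in tt11_codon_freqs}
            res = tt4_deficit_test(
                t4, tt4_gc3, t11, tt11_gc3, codon=codon, positions=(k,), span=span
            )[0]
            pvals.append((codon, res.pvalue))
        pvals.sort(key=lambda t: (t[1], t[0]))
        ranked, rank = [], 0
        for i, (codon, p) in enumerate(pvals):
            if i == 0 or p > pvals[i - 1][1]:
                rank = i + 1
            ranked.append((codon, p, rank))
        out[k] = ranked
    return out


def codon_rank(ranked: dict, codon: str, position: int) -> int:
    for c, _, r in ranked[position]:
        if c == codon:
            return r
    raise KeyError(codon)
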