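"""Dinucleotide Markov null models for 3' UTR stop-codon content.

The central null asks: given only the dinucleotide composition of a
genome's pooled downstream windows, how often would in-frame stop codons
appear at positions +1..+6 by chance? A first-order Markov chain is fitted
to the pooled windows; null 21-mers (a pseudo primary stop plus six
downstream codons) are then simulated from the chain, or the per-position
stop probability is computed exactly from the chain's marginals. Observed
frequencies are standardised to Z-scores against the null.

Also provided: the geometric first-stop null, in which the first downstream
stop appears at codon n with probability p(1-p)^(n-1), p being the
background per-codon stop rate of the 3' pool.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

NUCS = "ACGT"
_IDX = {b: i for i, b in enumerate(NUCS)}

#: simulated sequence length: pseudo-stop codon + 6 downstream codons
SIM_LENGTH = 21
POSITIONS = (1, 2, 3, 4, 5, 6)
WHOLE = "whole"


@dataclass
class DinucleotideModel:
    """First-order chain over {A,C,G,T}.

    ``initial`` holds the pooled mononucleotide frequencies (used for the
    first simulated base); ``transition[i, j]`` is P(next=j | prev=i) from
    overlapping dinucleotide counts.
    """

    initial: np.ndarray
    transition: np.ndarray

    def __post_init__(self):
        self.initial = np.asarray(self.initial, dtype=float)
        self.transition = np.asarray(self.transition, dtype=float)
        if self.initial.shape != (4,) or self.transition.shape != (4, 4):
            raise ValueError("model requires a 4-vector and a 4x4 matrix")
        if np.any(self.initial < 0) or np.any(self.transition < 0):
            raise ValueError("probabilities must be non-negative")
        if abs(self.initial.sum() - 1) > 1e-9:
            raise ValueError("initial vector must sum to 1")
        rows = self.transition.sum(axis=1)
        if np.any(np.abs(rows - 1) > 1e-9):
            raise ValueError("transition rows must sum to 1")


@dataclass
class NullDistribution:
    """Per-position null mean/sd of ASC frequency from simulated pseudo-sets.

    Keys of ``mean``/``sd`` are codon positions 1..6 plus ``"whole"`` (the
    fraction of sequences with at least one stop at +1..+6).
    """

    mean: dict
    sd: dict
    replicates: int
    set_size: int
    conditioned_first_base: str | None = None
    analytic: bool = False


@dataclass
class FirstStopNull:
    """Geometric null: first stop at codon n with probability p(1-p)^(n-1)."""

    p: float

    def __post_init__(self):
        if not 0 <= self.p <= 1:
            raise ValueError("p must lie in [0, 1]")


def _stop_lookup(stop_set) -> np.ndarray:
    """Boolean table over 64 codon indices (16*a + 4*b + c)."""
    table = np.zeros(64, dtype=bool)
    for codon in stop_set:
        a, b, c = (_IDX[x] for x in codon)
        table[16 * a + 4 * b + c] = True
    return table


def fit_dinucleotide_model(windows) -> DinucleotideModel:
    """Fit the chain to a pool of downstream windows.

    Mononucleotide frequencies come from the concatenated pool; overlapping
    dinucleotides are counted within each window only, never across gene
    boundaries. A nucleotide never observed as a dinucleotide prefix gets a
    uniform transition row (with a warning).
    """
    windows = list(windows)
    if not windows or all(len(w) == 0 for w in windows):
        raise ValueError("cannot fit a model to an empty pool")
    mono = np.zeros(4)
    di = np.zeros((4, 4))
    for w in windows:
        idx = np.fromiter((_IDX[b] for b in w), dtype=np.intp, count=len(w))
        np.add.at(mono, idx, 1)
        if len(idx) > 1:
            np.add.at(di, (idx[:-1], idx[1:]), 1)
    initial = mono / mono.sum()
    rowsums = di.sum(axis=1)
    transition = np.empty((4, 4))
    for i in range(4):
        if rowsums[i] == 0:
            warnings.warn(
                f"no dinucleotide counts with previous base {NUCS[i]}; using uniform row"
            )
            transition[i] = 0.25
        else:
            transition[i] = di[i] / rowsums[i]
    return DinucleotideModel(initial, transition)


def _first_base_distribution(
    model: DinucleotideModel, condition_first_base: str | None
) -> np.ndarray:
    if condition_first_base is None:
        return model.initial
    d = np.zeros(4)
    d[_IDX[condition_first_base]] = 1.0
    return d


def simulate_sequences(
    model: DinucleotideModel,
    n_sequences: int,
    rng: np.random.Generator,
    length: int = SIM_LENGTH,
    condition_first_base: str | None = None,
) -> np.ndarray:
    """Draw ``n_sequences`` chain realisations as an (n, length) int array."""
    if condition_first_base is not None:
        i = _IDX[condition_first_base]
        if model.transition[i].sum() == 0:
            raise ValueError(f"zero-probability dead-end at conditioned base {NUCS[i]}")
    d0 = _first_base_distribution(model, condition_first_base)
    seqs = np.empty((n_sequences, length), dtype=np.int8)
    cum0 = np.cumsum(d0)
    seqs[:, 0] = np.searchsorted(cum0, rng.random(n_sequences) * cum0[-1], side="right")
    cumT = np.cumsum(model.transition, axis=1)
    for j in range(1, length):
        prev = seqs[:, j - 1]
        rows = cumT[prev]
        u = rng.random(n_sequences) * rows[:, -1]
        seqs[:, j] = (u[:, None] >= rows).sum(axis=1)
    return seqs


def _codon_stop_matrix(seqs: np.ndarray, stop_set) -> np.ndarray:
    """(n, 6) booleans: is the codon at position +k (k=1..6) a stop?
    Codon +k occupies bases 3k..3k+2 of the 21-mer (codon 0 is the
    pseudo primary stop and is ignored)."""
    table = _stop_lookup(stop_set)
    out = np.empty((seqs.shape[0], 6), dtype=bool)
    for k in range(1, 7):
        c = 16 * seqs[:, 3 * k] + 4 * seqs[:, 3 * k + 1] + seqs[:, 3 * k + 2]
        out[:, k - 1] = table[c]
    return out


def simulate_null(
    model: DinucleotideModel,
    N: int,
    R: int,
    stop_set,
    rng_seed: int | np.random.Generator = 0,
    condition_first_base: str | None = None,
) -> NullDistribution:
    """Monte-Carlo null: R replicate pseudo-sets of N 21-mers each.

    Per replicate, the ASC frequency at each position (and the whole-UTR
    frequency, i.e. any stop at +1..+6) is computed over the N sequences;
    the null mean/sd are taken across the R replicates.
    """
    if N < 1 or R < 2:
        raise ValueError("need N >= 1 and R >= 2")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    seqs = simulate_sequences(model, R * N, rng, condition_first_base=condition_first_base)
    stops = _codon_stop_matrix(seqs, stop_set).reshape(R, N, 6)
    per_rep = stops.mean(axis=1)  # (R, 6)
    whole = stops.any(axis=2).mean(axis=1)  # (R,)
    mean = {k: float(per_rep[:, k - 1].mean()) for k in POSITIONS}
    sd = {k: float(per_rep[:, k - 1].std(ddof=1)) for k in POSITIONS}
    mean[WHOLE] = float(whole.mean())
    sd[WHOLE] = float(whole.std(ddof=1))
    return NullDistribution(mean, sd, R, N, condition_first_base)


def analytic_stop_probability(
    model: DinucleotideModel,
    position: int,
    stop_set,
    condition_first_base: str | None = None,
) -> float:
    """Exact P(codon at +position is a stop) under the chain.

    The codon at +position starts at base index 3*position of the 21-mer;
    its first-base marginal is the initial distribution propagated by that
    many transition steps.
    """
    if position < 1:
        raise ValueError("position must be >= 1")
    d0 = _first_base_distribution(model, condition_first_base)
    marg = d0 @ np.linalg.matrix_power(model.transition, 3 * position)
    T = model.transition
    prob = 0.0
    for codon in stop_set:
        a, b, c = (_IDX[x] for x in codon)
        prob += marg[a] * T[a, b] * T[b, c]
    return float(prob)


def analytic_whole_utr_probability(
    model: DinucleotideModel,
    stop_set,
    condition_first_base: str | None = None,
    n_codons: int = 6,
) -> float:
    """Exact P(at least one stop among codons +1..+n_codons) under the chain.

    Uses a transfer matrix over non-stop codons: M[b_prev, b_last] sums the
    chain probability of every non-stop codon given the previous base.
    """
    T = model.transition
    table = _stop_lookup(stop_set)
    # rows indexed by previous codon's last base, columns by this codon's last base
    M = np.zeros((4, 4))
    for a in range(4):
        for b in range(4):
            for c in range(4):
                if table[16 * a + 4 * b + c]:
                    continue
                M[:, c] += T[:, a] * T[a, b] * T[b, c]
    d0 = _first_base_distribution(model, condition_first_base)
    v = d0 @ np.linalg.matrix_power(T, 2)  # marginal of the pseudo-stop's last base
    p_none = float(v @ np.linalg.matrix_power(M, n_codons) @ np.ones(4))
    return 1.0 - p_none


def analytic_null(
    model: DinucleotideModel,
    N: int,
    stop_set,
    condition_first_base: str | None = None,
) -> NullDistribution:
    """Binomial fast path: exact per-position stop probability f0 with the
    pseudo-set standard deviation sqrt(f0 (1-f0) / N)."""
    mean, sd = {}, {}
    for k in POSITIONS:
        f0 = analytic_stop_probability(model, k, stop_set, condition_first_base)
        mean[k] = f0
        sd[k] = math.sqrt(f0 * (1 - f0) / N)
    f0 = analytic_whole_utr_probability(model, stop_set, condition_first_base)
    mean[WHOLE] = f0
    sd[WHOLE] = math.sqrt(f0 * (1 - f0) / N)
    return NullDistribution(mean, sd, 0, N, condition_first_base, analytic=True)


def compute_zscore(observed_freq: float, null: NullDistribution, position) -> float:
    """Z = (observed - null mean) / null sd for a position or "whole"."""
    mu, sigma = null.mean[position], null.sd[position]
    if sigma == 0:
        if observed_freq == mu:
            return 0.0
        return math.inf if observed_freq > mu else -math.inf
    return (observed_freq - mu) / sigma


def estimate_background_stop_rate(
    windows, stop_set, span_nt: int | None = None
) -> float:
    """Background per-codon stop probability p of a 3' pool.

    Each gene's frame is anchored at its own stop; codons never run across
    gene boundaries. With ``span_nt`` set, only the first span_nt
    nucleotides of each window are scanned and shorter windows are skipped.
    """
    total_stops = 0
    total_codons = 0
    for w in windows:
        if span_nt is not None:
            if len(w) < span_nt:
                continue
            w = w[:span_nt]
        n = len(w) // 3
        for i in range(n):
            if w[3 * i : 3 * i + 3] in stop_set:
                total_stops += 1
        total_codons += n
    if total_codons == 0:
        raise ValueError("no codon positions available to estimate p")
    return total_stops / total_codons


def first_stop_probability(p: float, n: int) -> float:
    """Geometric first-stop probability p(1-p)^(n-1) at codon position n."""
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    return p * (1 - p) ** (n - 1)
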