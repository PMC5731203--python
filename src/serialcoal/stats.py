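"""Summary statistics on alignments and genealogies.

Gene diversity H, nucleotide diversity pi (mean pairwise differences per
sequence), distance-based Fst (two-level AMOVA Phi-st on the pairwise
difference matrix, the estimator Arlequin applies to sequence data), the
coalescent-time form (t1 - t0)/t1, and the per-replicate pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .coalescent import mean_coal_times, simulate_genealogy
from .demography import ForwardDemography, run_forward
from .mutation import MutationModel, SequenceAlignment, drop_mutations
from .world import ScenarioConfig

__all__ = [
    "SummaryStats",
    "gene_diversity",
    "nucleotide_diversity",
    "pairwise_distance_matrix",
    "pairwise_fst",
    "fst_from_times",
    "summarize_replicate",
    "run_replicates",
]


def _as_codes(sample) -> np.ndarray:
    """Coerce a sample (2D int array or list of equal-length strings) to codes."""
    if isinstance(sample, np.ndarray) and sample.ndim == 2:
        return sample
    rows = []
    length = None
    lut = {"A": 0, "C": 1, "G": 2, "T": 3}
    for s in sample:
        if length is None:
            length = len(s)
        elif len(s) != length:
            raise ValueError("sequences must all have the same length")
        rows.append([lut[b] for b in s.upper()])
    return np.asarray(rows, dtype=np.int8)


def gene_diversity(sample) -> float:
    """Unbiased gene (haplotype) diversity, H = n/(n-1) * (1 - sum p_i^2)."""
    codes = _as_codes(sample)
    n = codes.shape[0]
    if n < 2:
        raise ValueError("gene diversity needs at least two sequences")
    _, counts = np.unique(codes, axis=0, return_counts=True)
    p = counts / n
    return n / (n - 1) * (1.0 - float((p**2).sum()))


def nucleotide_diversity(sample) -> float:
    """Mean pairwise differences per sequence over all unordered pairs."""
    codes = _as_codes(sample)
    n = codes.shape[0]
    if n < 2:
        raise ValueError("nucleotide diversity needs at least two sequences")
    d = pairwise_distance_matrix(codes)
    return float(d[np.triu_indices(n, k=1)].mean())


def pairwise_distance_matrix(codes: np.ndarray) -> np.ndarray:
    """Number of differing sites per sequence pair, shape (n, n)."""
    return (codes[:, None, :] != codes[None, :, :]).sum(axis=2)


def pairwise_fst(sample_a, sample_b, method: str = "phi_st") -> float:
    """Genetic differentiation between two samples.

    ``phi_st`` (default): two-level AMOVA on the pairwise-difference distance
    matrix, Phi-st = sigma2_among / (sigma2_among + sigma2_within).
    ``haplotype``: the same decomposition on the 0/1 haplotype-identity
    distance (Arlequin's "conventional" F-statistics).  Negative estimates
    are returned as computed.  Returns 0.0 when the data carry no variation.
    """
    a = _as_codes(sample_a)
    b = _as_codes(sample_b)
    na, nb = a.shape[0], b.shape[0]
    if na < 2 or nb < 2:
        raise ValueError("both samples need at least two sequences")
    if a.shape[1] != b.shape[1]:
        raise ValueError("samples must share the sequence length")
    codes = np.concatenate([a, b], axis=0)
    d = pairwise_distance_matrix(codes).astype(np.float64)
    if method == "haplotype":
        d = (d > 0).astype(np.float64)
    elif method != "phi_st":
        raise ValueError(f"unknown Fst method: {method!r}")
    n = na + nb
    iu = np.triu_indices(n, k=1)
    ssd_total = d[iu].sum() / n
    ssd_within = (
        d[:na, :na][np.triu_indices(na, k=1)].sum() / na
        + d[na:, na:][np.triu_indices(nb, k=1)].sum() / nb
    )
    ssd_among = ssd_total - ssd_within
    df_within = n - 2
    sigma_w = ssd_within / df_within
    n_bar = (n - (na * na + nb * nb) / n) / 1.0  # (N - sum n_g^2 / N)/(G - 1)
    sigma_a = (ssd_among / 1.0 - sigma_w) / n_bar
    denom = sigma_a + sigma_w
    if denom == 0.0:
        return 0.0
    return float(sigma_a / denom)


def fst_from_times(t0: float, t1: float) -> float:
    """Coalescent-time form of Fst: (t1 - t0) / t1 (requires t1 > 0)."""
    if t1 <= 0:
        raise ValueError("t1 must be positive")
    return (t1 - t0) / t1


@dataclass(frozen=True)
class SummaryStats:
    """One replicate's summary statistics."""

    fst: float
    H_mod: float
    H_anc: float
    pi_mod: float
    pi_anc: float
    t0_mod: float
    t0_anc: float
    t0: float
    t1: float

    def __post_init__(self):
        for name in ("H_mod", "H_anc"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} = {v} outside [0, 1]")


def summarize_replicate(alignment: SequenceAlignment, genealogy) -> SummaryStats:
    """All summary statistics for one simulated replicate."""
    mod = alignment.by_label("modern")
    anc = alignment.by_label("ancient")
    times = mean_coal_times(genealogy)
    return SummaryStats(
        fst=pairwise_fst(mod, anc),
        H_mod=gene_diversity(mod),
        H_anc=gene_diversity(anc),
        pi_mod=nucleotide_diversity(mod),
        pi_anc=nucleotide_diversity(anc),
        t0_mod=times.t0_mod,
        t0_anc=times.t0_anc,
        t0=times.t0,
        t1=times.t1,
    )


def replicate_seeds(master_seed: int, n: int) -> list[tuple[int, np.random.SeedSequence]]:
    """Per-replicate (kernel seed, mutation seed-sequence) pairs.

    Each replicate gets an independent stream derived from the master seed by
    replicate index, so any replicate is reproducible in isolation.
    """
    out = []
    for i in range(n):
        child = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(i,))
        kchild, mchild = child.spawn(2)
        kseed = int(kchild.generate_state(1)[0] & 0x7FFFFFFF)
        out.append((kseed, mchild))
    return out


def run_replicates(
    scenario: ScenarioConfig,
    n_reps: int,
    master_seed: int,
    demography: ForwardDemography | None = None,
) -> pd.DataFrame:
    """Simulate ``n_reps`` independent replicates of a scenario.

    The forward demography is deterministic and computed once (or supplied by
    the caller when shared across calls); coalescent and mutation are
    stochastic per replicate.  Returns one row of summary statistics per
    replicate.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if demography is None:
        demography = run_forward(scenario)
    model = MutationModel(scenario.mu, scenario.L, per_site=scenario.mu_per_site)
    rows = []
    for i, (kseed, mseq) in enumerate(replicate_seeds(master_seed, n_reps)):
        genealogy = simulate_genealogy(demography, scenario, kseed)
        alignment = drop_mutations(genealogy, model, np.random.default_rng(mseq))
        stats = summarize_replicate(alignment, genealogy)
        rows.append(
            {"replicate": i, "seed": kseed}
            | {f.name: getattr(stats, f.name) for f in fields(SummaryStats)}
        )
    return pd.DataFrame(rows)
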