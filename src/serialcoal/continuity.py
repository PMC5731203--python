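"""Model-based test of population continuity and its type-I-error experiment.

The null hypothesis is that the serial samples derive from one population
evolving under the scenario's demography (drift plus, in spatial scenarios,
local gene flow).  The observed Fst is compared with the Fst distribution of
simulated replicates; the one-sided p-value is the proportion of simulated
values strictly greater than the observed one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .demography import ForwardDemography, run_forward
from .stats import run_replicates
from .world import ScenarioConfig

__all__ = [
    "NullDistribution",
    "TestResult",
    "PodsResult",
    "simulate_null",
    "p_value",
    "continuity_test",
    "type1_error",
    "bonferroni_adjust",
]


@dataclass
class NullDistribution:
    """Simulated Fst distribution under a continuity scenario."""

    scenario_label: str
    fst_values: np.ndarray = field(repr=False)
    master_seed: int = 0

    @property
    def n_sims(self) -> int:
        return int(self.fst_values.size)


@dataclass(frozen=True)
class TestResult:
    """Outcome of one continuity test."""

    observed_fst: float
    p_value: float
    alpha: float
    reject: bool
    n_sims: int


@dataclass(frozen=True)
class PodsResult:
    """Type-I-error estimate from pseudo-observed datasets (pods)."""

    generating_scenario: str
    testing_scenario: str
    n_pods: int
    n_sims: int
    rejection_rate: float


def simulate_null(
    scenario: ScenarioConfig,
    n_sims: int,
    master_seed: int,
    demography: ForwardDemography | None = None,
) -> NullDistribution:
    """Fst distribution under continuity: one value per simulated replicate."""
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    frame = run_replicates(scenario, n_sims, master_seed, demography=demography)
    return NullDistribution(
        scenario_label=scenario.label,
        fst_values=frame["fst"].to_numpy(),
        master_seed=int(master_seed),
    )


def p_value(observed: float, null: NullDistribution) -> float:
    """Proportion of null Fst values strictly greater than the observed one."""
    if null.n_sims < 1:
        raise ValueError("null distribution is empty")
    return float(np.mean(null.fst_values > observed))


def continuity_test(
    observed_fst: float,
    scenario: ScenarioConfig,
    n_sims: int,
    seed: int,
    alpha: float = 0.05,
    demography: ForwardDemography | None = None,
) -> TestResult:
    """Test continuity: reject when P(simulated Fst > observed) < alpha."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    null = simulate_null(scenario, n_sims, seed, demography=demography)
    p = p_value(observed_fst, null)
    return TestResult(
        observed_fst=float(observed_fst),
        p_value=p,
        alpha=alpha,
        reject=bool(p < alpha),
        n_sims=null.n_sims,
    )


def type1_error(
    generating: ScenarioConfig,
    testing: ScenarioConfig,
    n_pods: int,
    n_sims: int,
    seed: int,
    alpha: float = 0.05,
    generating_demography: ForwardDemography | None = None,
    testing_demography: ForwardDemography | None = None,
) -> PodsResult:
    """Rejection rate of the continuity test over pseudo-observed datasets.

    ``n_pods`` replicates are simulated under ``generating``; each pod's Fst is
    tested against one shared null of ``n_sims`` replicates simulated under
    ``testing`` (pods and null use independent seed streams derived from
    ``seed``).
    """
    if n_pods < 1:
        raise ValueError("n_pods must be >= 1")
    ss = np.random.SeedSequence(int(seed))
    null_seed, pods_seed = (
        int(s.generate_state(1)[0] & 0x7FFFFFFF) for s in ss.spawn(2)
    )
    if generating_demography is None:
        generating_demography = run_forward(generating)
    if testing_demography is None:
        testing_demography = run_forward(testing)
    null = simulate_null(testing, n_sims, null_seed, demography=testing_demography)
    pods = run_replicates(
        generating, n_pods, pods_seed, demography=generating_demography
    )["fst"].to_numpy()
    rejected = int(sum(p_value(f, null) < alpha for f in pods))
    return PodsResult(
        generating_scenario=generating.label,
        testing_scenario=testing.label,
        n_pods=n_pods,
        n_sims=n_sims,
        rejection_rate=rejected / n_pods,
    )


def bonferroni_adjust(p_values) -> list[float]:
    """Bonferroni-adjusted p-values: p * n, capped at 1."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    _, adjusted, _, _ = multipletests(p, method="bonferroni")
    return [float(x) for x in adjusted]
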