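"""Synthetic loci and cohorts with the model's exact generative structure.

A simulated locus draws Q distinct binary epiallele patterns of length d
uniformly at random, assigns each read a generator pattern according to
the mixing weights, flips every CpG independently with probability
epsilon, and masks entries independently with a missingness probability.
A simulated cohort adds the contamination structure: the normal sample's
reads are drawn from the normal epiallele distribution n, and each
tumour sample's reads from the mixture rho * t + (1 - rho) * n, so the
purity machinery can be exercised against known ground truth.

Inference quality is scored as the proportion of reads attributed to
their correct underlying epiallele, which requires both that the correct
pattern was inferred (bit-identical) and that the read was attributed to
it.

Reproducibility: a single global seed streams per-locus seeds through a
counter-based scheme, so any locus can be regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .inference import EpialleleModel, FitConfig, select_model
from .io import Locus, ReadVector
from .purity import XiDistribution


@dataclass(frozen=True)
class SimulationScenario:
    """Study conditions for a synthetic locus or cohort.

    Defaults mirror the simulation design used to validate the method:
    three distinct random epialleles over six CpGs, 100 reads with equal
    expected generator weights, and a 5% per-CpG flip probability.
    """

    q_true: int = 3
    d: int = 6
    n_reads: int = 100
    epsilon: float = 0.05
    weights: tuple[float, ...] | None = None  # None = equal
    missing_fraction: float = 0.0
    rho_by_sample: Mapping[str, float] | None = None
    n_loci: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.epsilon <= 0.5:
            raise ValueError("epsilon must lie in [0, 1/2]")
        if self.weights is not None:
            if len(self.weights) != self.q_true:
                raise ValueError("weights length must equal q_true")
            if abs(sum(self.weights) - 1.0) > 1e-9:
                raise ValueError("weights must sum to 1")
        if not 0.0 <= self.missing_fraction < 1.0:
            raise ValueError("missing_fraction must lie in [0, 1)")

    @property
    def effective_weights(self) -> np.ndarray:
        if self.weights is None:
            return np.full(self.q_true, 1.0 / self.q_true)
        return np.asarray(self.weights, dtype=np.float64)


@dataclass
class SimulationTruth:
    """Ground truth for a simulated locus."""

    true_patterns: np.ndarray  # (Q, d) binary
    true_assignment: np.ndarray  # per-read generator index, 0-based
    true_t: np.ndarray | None = None
    true_n: np.ndarray | None = None
    true_rho: Mapping[str, float] | None = None


def _rng_for(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(index)]))


def _draw_patterns(rng: np.random.Generator, q: int, d: int) -> np.ndarray:
    """Draw q distinct binary patterns uniformly over {0,1}^d."""
    if q > 2 ** d:
        raise ValueError(f"cannot draw {q} distinct patterns of length {d}")
    seen: set[tuple[int, ...]] = set()
    patterns = []
    while len(patterns) < q:
        p = rng.integers(0, 2, size=d, dtype=np.uint8)
        key = tuple(int(b) for b in p)
        if key not in seen:
            seen.add(key)
            patterns.append(p)
    return np.stack(patterns)


def _emit_reads(rng: np.random.Generator, patterns: np.ndarray,
                assignment: np.ndarray, epsilon: float,
                missing_fraction: float, sample_ids: Sequence[str]) -> list[ReadVector]:
    n, d = assignment.size, patterns.shape[1]
    values = patterns[assignment].astype(np.uint8)
    flips = rng.random((n, d)) < epsilon
    values = np.where(flips, 1 - values, values).astype(np.uint8)
    mask = rng.random((n, d)) >= missing_fraction
    return [
        ReadVector(values[i] * mask[i], mask[i], sample_ids[i]) for i in range(n)
    ]


def simulate_locus(
    scenario: SimulationScenario,
    locus_index: int = 0,
    sample_id: str = "s1",
    chrom: str = "chr1",
) -> tuple[Locus, SimulationTruth]:
    """Simulate one locus for a single sample.

    Fully reproducible from (scenario.seed, locus_index). CpG positions
    are laid out 10 bp apart in disjoint 100 kb windows per locus so
    assembled loci never overlap.
    """
    rng = _rng_for(scenario.seed, locus_index)
    patterns = _draw_patterns(rng, scenario.q_true, scenario.d)
    assignment = rng.choice(scenario.q_true, size=scenario.n_reads,
                            p=scenario.effective_weights)
    reads = _emit_reads(rng, patterns, assignment, scenario.epsilon,
                        scenario.missing_fraction,
                        [sample_id] * scenario.n_reads)
    start = 1 + locus_index * 100_000
    positions = start + 10 * np.arange(scenario.d)
    locus = Locus(chrom, int(positions[0]), int(positions[-1]), positions, reads,
                  locus_id=f"sim{locus_index}")
    return locus, SimulationTruth(patterns, assignment)


def simulate_cohort(
    scenario: SimulationScenario,
    normal_sample: str = "N",
    altered_fraction: float = 0.5,
    concentration: float = 1.0,
) -> tuple[list[Locus], list[SimulationTruth]]:
    """Simulate a multi-region cohort of pooled loci with contamination.

    Per locus, the normal tissue is epigenetically homogeneous (its
    distribution n is concentrated on one pattern) while, at an
    ``altered_fraction`` of loci, the tumour distribution t is a
    Dirichlet draw over the remaining patterns (at least two, requiring
    q_true >= 3) — so altered loci have disjoint tumour/normal support
    and their xi approaches rho. At unaltered loci t = n. Each tumour
    sample s draws its reads from rho_s * t + (1 - rho_s) * n; the
    normal sample draws from n. Reads from all samples are pooled into
    one Locus per site, as the fitting protocol expects.
    """
    rho_by_sample = dict(scenario.rho_by_sample or {"R1": 0.8})
    if normal_sample in rho_by_sample:
        raise ValueError("normal sample cannot carry a purity value")
    loci: list[Locus] = []
    truths: list[SimulationTruth] = []
    for j in range(scenario.n_loci):
        rng = _rng_for(scenario.seed, j)
        patterns = _draw_patterns(rng, scenario.q_true, scenario.d)
        n_dist = np.zeros(scenario.q_true)
        n_dist[0] = 1.0
        if rng.random() < altered_fraction:
            t_dist = np.zeros(scenario.q_true)
            t_dist[1:] = rng.dirichlet(np.full(scenario.q_true - 1, concentration))
        else:
            t_dist = n_dist.copy()
        reads: list[ReadVector] = []
        assignment_parts: list[np.ndarray] = []
        for sample in [normal_sample] + sorted(rho_by_sample):
            if sample == normal_sample:
                mix = n_dist
            else:
                rho = rho_by_sample[sample]
                if not 0.0 <= rho <= 1.0:
                    raise ValueError(f"purity for {sample} must lie in [0, 1]")
                mix = rho * t_dist + (1.0 - rho) * n_dist
            assignment = rng.choice(scenario.q_true, size=scenario.n_reads, p=mix)
            reads.extend(
                _emit_reads(rng, patterns, assignment, scenario.epsilon,
                            scenario.missing_fraction,
                            [sample] * scenario.n_reads)
            )
            assignment_parts.append(assignment)
        start = 1 + j * 100_000
        positions = start + 10 * np.arange(scenario.d)
        loci.append(
            Locus("chr1", int(positions[0]), int(positions[-1]), positions, reads,
                  locus_id=f"sim{j}")
        )
        truths.append(
            SimulationTruth(patterns, np.concatenate(assignment_parts),
                            true_t=t_dist, true_n=n_dist,
                            true_rho=dict(rho_by_sample))
        )
    return loci, truths


def simulate_cell_line_mixture(
    d: int = 6,
    n_reads: int = 100,
    methylated_fraction: float = 0.9,
    epsilon: float = 0.0,
    seed: int = 0,
    sample_id: str = "mix",
) -> tuple[Locus, SimulationTruth]:
    """Two single-pattern populations (all-1s and all-0s) mixed 9:1.

    Emulates mixing a fully methylated and a fully unmethylated cell
    line before sequencing to test low-frequency epiallele detection.
    """
    rng = _rng_for(seed, 0)
    patterns = np.stack([np.ones(d, dtype=np.uint8), np.zeros(d, dtype=np.uint8)])
    assignment = (rng.random(n_reads) >= methylated_fraction).astype(np.intp)
    reads = _emit_reads(rng, patterns, assignment, epsilon, 0.0,
                        [sample_id] * n_reads)
    positions = 1 + 10 * np.arange(d)
    locus = Locus("chr1", 1, int(positions[-1]), positions, reads,
                  locus_id="cellline")
    return locus, SimulationTruth(patterns, assignment)


def simulate_xi_distribution(
    rho: float,
    n_loci: int = 2000,
    n_reads: int = 100,
    q_true: int = 3,
    altered_fraction: float = 0.5,
    seed: int = 0,
    sample_id: str = "R1",
) -> XiDistribution:
    """xi values from finite read sampling at loci with known t, n, rho.

    At each locus the normal distribution is one-hot and, at altered
    loci, the tumour distribution is a Dirichlet draw over the remaining
    patterns; the tumour sample observes multinomial counts from
    rho * t + (1 - rho) * n and the normal sample from n, both with
    ``n_reads`` reads, and xi is computed between the empirical
    frequencies. The resulting density has its rightmost mode at rho.
    """
    if not 0.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 9_999]))
    xi = np.empty(n_loci)
    for j in range(n_loci):
        n_dist = np.zeros(q_true)
        n_dist[0] = 1.0
        if rng.random() < altered_fraction:
            t_dist = np.zeros(q_true)
            t_dist[1:] = rng.dirichlet(np.ones(q_true - 1))
        else:
            t_dist = n_dist
        phi = rho * t_dist + (1.0 - rho) * n_dist
        phi_hat = rng.multinomial(n_reads, phi) / n_reads
        n_hat = rng.multinomial(n_reads, n_dist) / n_reads
        xi[j] = 0.5 * np.abs(phi_hat - n_hat).sum()
    return XiDistribution(sample_id, xi)


# ---------------------------------------------------------------------------
# Scoring


def evaluate_attribution(model: EpialleleModel, truth: SimulationTruth) -> float:
    """Proportion of reads attributed to their correct underlying epiallele.

    A read counts as correct iff the pattern of its MAP-assigned
    inferred epiallele is bit-identical to the pattern that generated
    it — correct inference and correct attribution are both required.
    """
    inferred = model.X[model.w]
    generating = truth.true_patterns[truth.true_assignment]
    return float(np.all(inferred == generating, axis=1).mean())


def benchmark_point(
    scenario: SimulationScenario,
    replicates: int = 100,
    fit_config: FitConfig | None = None,
) -> tuple[float, float]:
    """Mean and standard error of attribution success over replicates."""
    fit_config = fit_config or FitConfig()
    rates = np.empty(replicates)
    for r in range(replicates):
        locus, truth = simulate_locus(scenario, locus_index=r)
        model = select_model(locus, fit_config)
        rates[r] = evaluate_attribution(model, truth)
    se = float(rates.std(ddof=1) / np.sqrt(replicates)) if replicates > 1 else 0.0
    return float(rates.mean()), se


def benchmark_grid(
    n_reads: Sequence[int] = (100,),
    d: Sequence[int] = (6,),
    epsilon: Sequence[float] = (0.05,),
    replicates: int = 100,
    seed: int = 0,
    q_true: int = 3,
    fit_config: FitConfig | None = None,
) -> pd.DataFrame:
    """Mean attribution success over a grid of (N, d, epsilon) settings."""
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rows = []
    cell = 0
    for n_r in n_reads:
        for d_ in d:
            for eps in epsilon:
                scenario = SimulationScenario(
                    q_true=q_true, d=d_, n_reads=n_r, epsilon=eps,
                    seed=seed + cell,
                )
                mean, se = benchmark_point(scenario, replicates, fit_config)
                rows.append({"N": n_r, "d": d_, "epsilon": eps,
                             "replicates": replicates,
                             "mean_success": mean, "se": se})
                cell += 1
    return pd.DataFrame(rows)
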