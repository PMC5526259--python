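"""Tumour purity estimation and decontamination of normal tissue.

A tumour sample contaminated with normal tissue observes, at each locus,
a convex mixture of the tumour and normal epiallele distributions:

    phi = rho * t + (1 - rho) * n

where rho is the sample purity. t and rho cannot be solved for jointly
from one locus, but the statistic

    xi = (1/2) * sum_q |phi_q - n_q|

(half the L1 distance, i.e. the total variation distance between the
observed and normal distributions) is bounded by rho, with equality at
loci where tumour and normal share no epialleles. Across many loci the
empirical density of xi therefore has support on [0, rho]: the purity is
read off as the rightmost maximum of a kernel density estimate of xi.
Given rho, the mixture is inverted componentwise to recover the
decontaminated tumour profile t_hat, clipping to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks
from scipy.stats import gaussian_kde

from .profiles import EpialleleProfile


@dataclass
class XiDistribution:
    """xi values for one tumour sample across its eligible loci."""

    sample_id: str
    xi_values: np.ndarray

    def __post_init__(self) -> None:
        self.xi_values = np.asarray(self.xi_values, dtype=np.float64)
        if self.xi_values.size and (
            self.xi_values.min() < -1e-9 or self.xi_values.max() > 1 + 1e-9
        ):
            raise ValueError("xi values must lie in [0, 1]")

    @property
    def n_loci(self) -> int:
        return int(self.xi_values.size)


@dataclass
class PurityEstimate:
    """Estimated purity for one tumour sample.

    ``below_detection`` is set when the rightmost qualifying density
    maximum falls under the detection floor; ``rho`` is then the floor
    itself and should be reported as "<floor".
    """

    sample_id: str
    rho: float
    peak_location: float
    bandwidth: float
    n_loci: int
    below_detection: bool = False

    def __str__(self) -> str:
        if self.below_detection:
            return f"<{self.rho:.0%}"
        return f"{self.rho:.1%}"


def xi_statistic(phi: np.ndarray, n: np.ndarray) -> float:
    """Half the L1 distance between two epiallele distributions."""
    phi = np.asarray(phi, dtype=np.float64)
    n = np.asarray(n, dtype=np.float64)
    if phi.shape != n.shape:
        raise ValueError(
            f"distributions have different lengths ({phi.size} vs {n.size})"
        )
    return float(0.5 * np.abs(phi - n).sum())


def mix_profiles(t: np.ndarray, n: np.ndarray, rho: float) -> np.ndarray:
    """Convex mixture rho * t + (1 - rho) * n of tumour and normal."""
    if not 0.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [0, 1]")
    t = np.asarray(t, dtype=np.float64)
    n = np.asarray(n, dtype=np.float64)
    if t.shape != n.shape:
        raise ValueError("t and n have different lengths")
    return rho * t + (1.0 - rho) * n


def estimate_purity(
    xi: XiDistribution,
    min_loci: int = 200,
    grid_size: int = 512,
    prominence_fraction: float = 0.05,
    detection_floor: float = 0.20,
    bw_method: str | float = "silverman",
) -> PurityEstimate:
    """Estimate purity as the rightmost maximum of the xi density.

    A Gaussian kernel density estimate (Silverman bandwidth by default)
    is evaluated on a uniform grid over [0, 1]; local maxima with
    prominence at least ``prominence_fraction`` of the global density
    maximum qualify, and the rightmost qualifying peak location is the
    purity. Peaks below ``detection_floor`` yield a below-detection call.
    """
    if xi.n_loci < min_loci:
        raise ValueError(
            f"sample {xi.sample_id}: {xi.n_loci} loci available but at least "
            f"{min_loci} are required for purity estimation"
        )
    values = xi.xi_values
    grid = np.linspace(0.0, 1.0, grid_size)
    if np.ptp(values) < 1e-12:
        # degenerate: all xi identical, density is an atom
        peak = float(values[0])
        return PurityEstimate(
            xi.sample_id, rho=peak if peak >= detection_floor else detection_floor,
            peak_location=peak, bandwidth=0.0, n_loci=xi.n_loci,
            below_detection=peak < detection_floor,
        )
    kde = gaussian_kde(values, bw_method=bw_method)
    density = kde(grid)
    bandwidth = float(kde.factor * values.std(ddof=1))
    # pad with zeros so maxima at the grid boundaries are detectable
    padded = np.concatenate([[0.0], density, [0.0]])
    peaks, _ = find_peaks(padded, prominence=prominence_fraction * density.max())
    peaks -= 1
    if peaks.size == 0:
        peak = float(grid[int(np.argmax(density))])
    else:
        peak = float(grid[peaks.max()])
    below = peak < detection_floor
    return PurityEstimate(
        xi.sample_id,
        rho=detection_floor if below else peak,
        peak_location=peak,
        bandwidth=bandwidth,
        n_loci=xi.n_loci,
        below_detection=below,
    )


def decontaminate(phi: np.ndarray, n: np.ndarray, rho: float) -> np.ndarray:
    """Invert the mixture to estimate the tumour distribution t_hat.

    t_hat_q = (phi_q - (1 - rho) * n_q) / rho, clipped to [0, 1]. When
    clipping fires the result no longer sums to one and is renormalised
    so downstream distances and entropies operate on distributions.
    """
    if not 0.0 < rho <= 1.0:
        raise ValueError("rho must lie in (0, 1]; rho=0 leaves t undefined")
    phi = np.asarray(phi, dtype=np.float64)
    n = np.asarray(n, dtype=np.float64)
    if phi.shape != n.shape:
        raise ValueError("phi and n have different lengths")
    t_hat = (phi - (1.0 - rho) * n) / rho
    clipped = np.clip(t_hat, 0.0, 1.0)
    if not np.allclose(clipped, t_hat):
        total = clipped.sum()
        if total > 0:
            clipped = clipped / total
    return clipped


def call_methylation_levels(t_hat: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Per-CpG methylation levels of the (decontaminated) profile.

    Level at site mu is sum_q t_hat_q * x_qmu, the probability that a
    read drawn from t_hat is methylated there.
    """
    t_hat = np.asarray(t_hat, dtype=np.float64)
    X = np.asarray(X, dtype=np.float64)
    if t_hat.shape[0] != X.shape[0]:
        raise ValueError("t_hat length must equal the number of patterns")
    return t_hat @ X


# ---------------------------------------------------------------------------
# Cohort-level drivers


def xi_by_sample(
    profiles_by_locus: dict[str, dict[str, EpialleleProfile]],
    normal_sample: str,
) -> dict[str, XiDistribution]:
    """xi per tumour sample over loci where it and the normal co-occur."""
    values: dict[str, list[float]] = {}
    for locus_id in sorted(profiles_by_locus):
        per_sample = profiles_by_locus[locus_id]
        normal = per_sample.get(normal_sample)
        if normal is None:
            continue
        for sample_id in sorted(per_sample):
            if sample_id == normal_sample:
                continue
            values.setdefault(sample_id, []).append(
                xi_statistic(per_sample[sample_id].phi, normal.phi)
            )
    return {
        s: XiDistribution(s, np.asarray(v, dtype=np.float64))
        for s, v in values.items()
    }


def decontaminate_cohort(
    profiles_by_locus: dict[str, dict[str, EpialleleProfile]],
    purities: dict[str, PurityEstimate],
    normal_sample: str,
) -> dict[str, dict[str, EpialleleProfile]]:
    """Decontaminate every tumour profile against the normal profile.

    Below-detection samples use their floor value for rho (a conservative
    choice that under-corrects rather than dividing by a spurious small
    purity). The normal sample's own profile is carried through unchanged.
    """
    from dataclasses import replace

    out: dict[str, dict[str, EpialleleProfile]] = {}
    for locus_id in sorted(profiles_by_locus):
        per_sample = profiles_by_locus[locus_id]
        normal = per_sample.get(normal_sample)
        if normal is None:
            continue
        out[locus_id] = {normal_sample: normal}
        for sample_id in sorted(per_sample):
            if sample_id == normal_sample or sample_id not in purities:
                continue
            rho = purities[sample_id].rho
            t_hat = decontaminate(per_sample[sample_id].phi, normal.phi, rho)
            out[locus_id][sample_id] = replace(per_sample[sample_id], phi=t_hat)
    return out
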