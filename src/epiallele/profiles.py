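"""Per-sample epiallele distributions from a pooled fit.

Reads from every tissue sample are pooled per locus before fitting, so
all samples share one inferred epiallele basis. The distribution of
epialleles within sample s is the average of the responsibility column
over that sample's reads:

    phi^s_q = (1 / N_s) * sum_{i in I_s} p(w_i = q | ...)

Epialleles accounting for less than a threshold fraction (default 5%) of
the pooled reads are discarded to focus on dominant shifts and guard
against spurious patterns; the surviving entries are renormalised so each
phi^s remains a probability distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .inference import EpialleleModel, ResponsibilityMatrix
from .io import Locus


@dataclass
class EpialleleProfile:
    """One sample's distribution over a locus's retained epialleles."""

    locus_id: str
    sample_id: str
    phi: np.ndarray
    n_reads: int
    epiallele_ids: np.ndarray  # indices into the locus's pattern matrix

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=np.float64)
        self.epiallele_ids = np.asarray(self.epiallele_ids, dtype=np.intp)
        if self.phi.shape != self.epiallele_ids.shape:
            raise ValueError("phi and epiallele_ids must have equal length")


def pooled_phi(resp: ResponsibilityMatrix) -> np.ndarray:
    """All-sample epiallele distribution: responsibility column means."""
    return resp.values.mean(axis=0)


def sample_phi(locus: Locus, model: EpialleleModel,
               resp: ResponsibilityMatrix) -> list[EpialleleProfile]:
    """Per-sample epiallele distributions phi^s at one locus.

    Samples with no reads at the locus are omitted. Ordering follows the
    sorted sample ids for determinism.
    """
    profiles = []
    ids = np.arange(model.Q, dtype=np.intp)
    for sample_id in sorted(locus.sample_index_sets):
        idx = locus.sample_index_sets[sample_id]
        if idx.size == 0:
            continue
        phi = resp.values[idx].mean(axis=0)
        profiles.append(
            EpialleleProfile(locus.locus_id, sample_id, phi, int(idx.size), ids)
        )
    return profiles


def prune_low_frequency(profiles: list[EpialleleProfile], pooled: np.ndarray,
                        threshold: float = 0.05) -> list[EpialleleProfile]:
    """Discard epialleles below the pooled-frequency threshold.

    Epialleles whose pooled (all-sample) proportion is below ``threshold``
    are removed from every sample's profile and the remaining entries are
    renormalised to sum to one. If every epiallele falls below the
    threshold the single dominant one is retained.
    """
    if not 0.0 <= threshold < 1.0:
        raise ValueError("threshold must lie in [0, 1)")
    pooled = np.asarray(pooled, dtype=np.float64)
    keep = pooled >= threshold
    if not keep.any():
        keep = pooled == pooled.max()
        first = int(np.argmax(keep))
        keep = np.zeros_like(keep)
        keep[first] = True
    out = []
    for p in profiles:
        phi = p.phi[keep]
        total = phi.sum()
        phi = phi / total if total > 0 else np.full(keep.sum(), 1.0 / keep.sum())
        out.append(replace(p, phi=phi, epiallele_ids=p.epiallele_ids[keep]))
    return out


def profile_matrix(profiles_by_locus: dict[str, list[EpialleleProfile]],
                   patterns_by_locus: dict[str, list[str] | dict[int, str]] | None = None
                   ) -> pd.DataFrame:
    """Wide profile table: rows locus x epiallele, one phi column per sample.

    ``patterns_by_locus`` optionally maps locus_id to pattern strings
    indexed by epiallele id (a list over the full pattern matrix or a
    dict over the retained ids) so each row carries its binary pattern.
    """
    samples = sorted({p.sample_id for ps in profiles_by_locus.values() for p in ps})
    rows = []
    for locus_id in sorted(profiles_by_locus):
        ps = profiles_by_locus[locus_id]
        if not ps:
            continue
        eids = ps[0].epiallele_ids
        by_sample = {p.sample_id: p for p in ps}
        for j, eid in enumerate(eids):
            row: dict[str, object] = {"locus_id": locus_id, "epiallele_id": int(eid)}
            if patterns_by_locus is not None:
                row["pattern"] = patterns_by_locus[locus_id][int(eid)]
            for s in samples:
                p = by_sample.get(s)
                row[s] = float(p.phi[j]) if p is not None else np.nan
            rows.append(row)
    return pd.DataFrame(rows)


def profiles_from_matrix(df: pd.DataFrame) -> dict[str, dict[str, EpialleleProfile]]:
    """Inverse of :func:`profile_matrix`: locus_id -> sample_id -> profile."""
    meta = {"locus_id", "epiallele_id", "pattern"}
    samples = [c for c in df.columns if c not in meta]
    out: dict[str, dict[str, EpialleleProfile]] = {}
    for locus_id, grp in df.groupby("locus_id", sort=True):
        eids = grp["epiallele_id"].to_numpy(dtype=np.intp)
        out[locus_id] = {}
        for s in samples:
            phi = grp[s].to_numpy(dtype=np.float64)
            if np.isnan(phi).any():
                continue
            out[locus_id][s] = EpialleleProfile(locus_id, s, phi, 0, eids)
    return out
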