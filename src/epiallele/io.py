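"""Core data types and per-read methylation call I/O.

Reads from reduced representation bisulfite sequencing (RRBS) arrive as
per-read CpG methylation calls: each read reports a binary methylation
state (1 = methylated, 0 = unmethylated) at an ordered set of CpG
coordinates, with missing calls where the read does not cover a site or
the call failed. Reads are grouped into *loci* — maximal sets of reads
whose CpG position sets overlap transitively — and each locus carries a
read-by-CpG matrix with an observed-entry mask.

The external format is a TSV with columns
``read_id  sample_id  chrom  positions  states`` where ``positions`` is a
comma-separated strictly increasing list of 1-based coordinates and
``states`` a comma-separated list over ``1``/``0``/``.`` (missing).
Gzip-compressed files are accepted.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING = -1  # sentinel in MethCallRecord.states

_STATE_SYMBOLS = {"1": 1, "0": 0, ".": MISSING}


class ParseError(ValueError):
    """Raised for malformed per-read call input; carries the line number."""


@dataclass(frozen=True)
class MethCallRecord:
    """One sequencing read's raw methylation calls.

    ``states`` uses 1 (methylated), 0 (unmethylated) and -1 (missing),
    aligned with ``cpg_positions`` (1-based, strictly increasing).
    """

    read_id: str
    sample_id: str
    chrom: str
    cpg_positions: tuple[int, ...]
    states: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.cpg_positions) != len(self.states):
            raise ValueError(
                f"read {self.read_id}: {len(self.cpg_positions)} positions "
                f"but {len(self.states)} states"
            )
        pos = self.cpg_positions
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError(
                f"read {self.read_id}: CpG positions must be strictly increasing"
            )


@dataclass
class ReadVector:
    """A read expanded onto its locus's CpG grid.

    ``values`` is binary of length d; entries where ``observed_mask`` is
    False are placeholders (stored as 0) and ignored by every computation.
    """

    values: np.ndarray
    observed_mask: np.ndarray
    sample_id: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.uint8)
        self.observed_mask = np.asarray(self.observed_mask, dtype=bool)
        if self.values.shape != self.observed_mask.shape:
            raise ValueError("values and observed_mask must have equal length")


@dataclass
class Locus:
    """A genomic interval with d ordered CpG sites and its pooled reads."""

    chrom: str
    start: int
    end: int
    cpg_positions: np.ndarray
    reads: list[ReadVector]
    locus_id: str = ""

    def __post_init__(self) -> None:
        self.cpg_positions = np.asarray(self.cpg_positions, dtype=np.int64)
        if self.d < 1:
            raise ValueError("locus must contain at least one CpG site")
        if self.n_reads < 1:
            raise ValueError("locus must contain at least one read")
        for r in self.reads:
            if r.values.shape[0] != self.d:
                raise ValueError("read vector length does not match locus d")
        if not self.locus_id:
            self.locus_id = f"{self.chrom}:{self.start}-{self.end}"

    @property
    def d(self) -> int:
        return int(self.cpg_positions.shape[0])

    @property
    def n_reads(self) -> int:
        return len(self.reads)

    @property
    def sample_index_sets(self) -> dict[str, np.ndarray]:
        """Mapping sample_id -> indices of that sample's reads (I_s)."""
        idx: dict[str, list[int]] = {}
        for i, r in enumerate(self.reads):
            idx.setdefault(r.sample_id, []).append(i)
        return {s: np.asarray(v, dtype=np.intp) for s, v in idx.items()}

    def matrices(self) -> tuple[np.ndarray, np.ndarray]:
        """Return the (N, d) value matrix and (N, d) observed mask."""
        values = np.stack([r.values for r in self.reads])
        mask = np.stack([r.observed_mask for r in self.reads])
        return values, mask

    @property
    def missing_fraction(self) -> float:
        _, mask = self.matrices()
        return float(1.0 - mask.mean())

    def sample_depths(self) -> dict[str, int]:
        return {s: len(v) for s, v in self.sample_index_sets.items()}


@dataclass(frozen=True)
class LocusFilterConfig:
    """Locus eligibility thresholds.

    Defaults follow the case-study filtering: at least six CpGs, median
    per-sample read depth of 100, at most 25% missing entries, and sex
    chromosomes excluded.
    """

    min_cpgs: int = 6
    min_median_depth: int = 100
    max_missing_fraction: float = 0.25
    exclude_chroms: frozenset[str] = frozenset({"chrX", "chrY", "X", "Y"})

    def __post_init__(self) -> None:
        if self.min_cpgs < 1:
            raise ValueError("min_cpgs must be >= 1")
        if not 0.0 <= self.max_missing_fraction <= 1.0:
            raise ValueError("max_missing_fraction must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Parsing

_EXPECTED_COLUMNS = ["read_id", "sample_id", "chrom", "positions", "states"]


def _open_maybe_gzip(source):
    if hasattr(source, "read"):
        return source, False
    path = Path(source)
    if path.suffix == ".gz":
        return gzip.open(path, "rt"), True
    return open(path, "rt"), True


def parse_read_calls(source) -> list[MethCallRecord]:
    """Parse a per-read methylation call TSV into records.

    ``source`` is a path (optionally gzipped) or an open text stream.
    A header line with the five expected column names is required.
    Malformed rows raise :class:`ParseError` naming the offending line.
    """
    handle, close = _open_maybe_gzip(source)
    records: list[MethCallRecord] = []
    try:
        header = handle.readline()
        if header == "":
            return records
        cols = header.rstrip("\n").split("\t")
        if cols != _EXPECTED_COLUMNS:
            raise ParseError(
                f"line 1: expected header {_EXPECTED_COLUMNS}, got {cols}"
            )
        for lineno, line in enumerate(handle, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise ParseError(f"line {lineno}: expected 5 columns, got {len(fields)}")
            read_id, sample_id, chrom, pos_s, state_s = fields
            try:
                positions = tuple(int(p) for p in pos_s.split(","))
            except ValueError as exc:
                raise ParseError(f"line {lineno}: bad position list {pos_s!r}") from exc
            states = []
            for sym in state_s.split(","):
                if sym not in _STATE_SYMBOLS:
                    raise ParseError(
                        f"line {lineno}: unknown state symbol {sym!r} "
                        "(expected '1', '0' or '.')"
                    )
                states.append(_STATE_SYMBOLS[sym])
            try:
                records.append(
                    MethCallRecord(read_id, sample_id, chrom, positions, tuple(states))
                )
            except ValueError as exc:
                raise ParseError(f"line {lineno}: {exc}") from exc
    finally:
        if close:
            handle.close()
    return records


def write_read_calls(records: Iterable[MethCallRecord], path) -> None:
    """Write records in the same TSV dialect accepted by parse_read_calls."""
    inv = {1: "1", 0: "0", MISSING: "."}
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        fh.write("\t".join(_EXPECTED_COLUMNS) + "\n")
        for r in records:
            fh.write(
                "\t".join(
                    [
                        r.read_id,
                        r.sample_id,
                        r.chrom,
                        ",".join(str(p) for p in r.cpg_positions),
                        ",".join(inv[s] for s in r.states),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Locus assembly


def assemble_loci(records: Sequence[MethCallRecord]) -> list[Locus]:
    """Group reads into non-overlapping loci by transitive CpG-set overlap.

    Reads on one chromosome that share at least one CpG coordinate
    (directly or through a chain of other reads) form one locus whose CpG
    set is the union of member positions. Each read is expanded to the
    locus length with a missing mask at positions it does not cover.
    The result is independent of input record order (up to locus order,
    which is sorted by chromosome and start coordinate).
    """
    by_chrom: dict[str, list[MethCallRecord]] = {}
    for rec in records:
        by_chrom.setdefault(rec.chrom, []).append(rec)

    loci: list[Locus] = []
    for chrom in sorted(by_chrom):
        recs = sorted(by_chrom[chrom], key=lambda r: (r.cpg_positions, r.read_id))
        # Union-find over CpG positions: each read merges its positions.
        parent: dict[int, int] = {}

        def find(x: int) -> int:
            root = x
            while parent[root] != root:
                root = parent[root]
            while parent[x] != root:
                parent[x], x = root, parent[x]
            return root

        for rec in recs:
            for p in rec.cpg_positions:
                parent.setdefault(p, p)
            first = rec.cpg_positions[0]
            for p in rec.cpg_positions[1:]:
                ra, rb = find(first), find(p)
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)

        groups: dict[int, list[MethCallRecord]] = {}
        for rec in recs:
            groups.setdefault(find(rec.cpg_positions[0]), []).append(rec)

        for root in sorted(groups):
            members = groups[root]
            union = sorted({p for rec in members for p in rec.cpg_positions})
            pos_index = {p: j for j, p in enumerate(union)}
            d = len(union)
            reads = []
            for rec in members:
                values = np.zeros(d, dtype=np.uint8)
                mask = np.zeros(d, dtype=bool)
                for p, s in zip(rec.cpg_positions, rec.states):
                    if s == MISSING:
                        continue
                    j = pos_index[p]
                    values[j] = s
                    mask[j] = True
                reads.append(ReadVector(values, mask, rec.sample_id))
            loci.append(
                Locus(
                    chrom=chrom,
                    start=union[0],
                    end=union[-1],
                    cpg_positions=np.asarray(union),
                    reads=reads,
                )
            )
    return loci


def _trim_reads_for_missingness(locus: Locus, max_missing: float) -> Locus | None:
    """Drop low-coverage reads until the locus missing-data bound holds.

    Reads observing fewer than ``(1 - max_missing) * d`` of the locus's
    CpG positions are removed one at a time (lowest coverage first, ties
    by read order); after each removal the CpG union and d are
    recomputed, since dropping a read can orphan positions. Returns None
    if the bound cannot be met.
    """
    reads = list(locus.reads)
    positions = locus.cpg_positions
    while reads:
        mask = np.stack([r.observed_mask for r in reads])
        covered = mask.any(axis=0)
        if not covered.all():  # orphaned CpG columns: shrink the grid
            positions = positions[covered]
            reads = [
                ReadVector(r.values[covered], r.observed_mask[covered], r.sample_id)
                for r in reads
            ]
            mask = mask[:, covered]
        d = mask.shape[1]
        missing_fraction = 1.0 - mask.mean()
        if missing_fraction <= max_missing:
            return Locus(locus.chrom, int(positions[0]), int(positions[-1]),
                         positions, reads)
        coverage = mask.sum(axis=1)
        low = np.flatnonzero(coverage < (1.0 - max_missing) * d)
        if low.size == 0:
            return None  # bound unreachable by trimming
        drop = low[np.argmin(coverage[low])]
        del reads[drop]
    return None


def filter_eligible_loci(
    loci: Iterable[Locus],
    config: LocusFilterConfig = LocusFilterConfig(),
    all_samples: Sequence[str] | None = None,
) -> list[Locus]:
    """Apply the locus eligibility filters.

    A locus is retained when, after trimming low-coverage reads to meet
    the missing-data bound: it has at least ``min_cpgs`` CpGs, its median
    per-sample read depth is at least ``min_median_depth`` (samples in
    ``all_samples`` absent from the locus count as depth 0), its missing
    fraction is at most ``max_missing_fraction``, and its chromosome is
    not excluded. Depth here is the locus read count per sample, N_s.
    """
    loci = list(loci)
    if all_samples is None:
        seen: set[str] = set()
        for locus in loci:
            seen.update(r.sample_id for r in locus.reads)
        all_samples = sorted(seen)

    kept: list[Locus] = []
    for locus in loci:
        if locus.chrom in config.exclude_chroms:
            continue
        trimmed = _trim_reads_for_missingness(locus, config.max_missing_fraction)
        if trimmed is None:
            continue
        if trimmed.d < config.min_cpgs:
            continue
        depths = trimmed.sample_depths()
        per_sample = [depths.get(s, 0) for s in all_samples] or [0]
        if np.median(per_sample) < config.min_median_depth:
            continue
        kept.append(trimmed)
    return kept


def locus_table(loci: Sequence[Locus]) -> pd.DataFrame:
    """Summarise loci as a table (one row per locus)."""
    samples = sorted({r.sample_id for locus in loci for r in locus.reads})
    rows = []
    for locus in loci:
        depths = locus.sample_depths()
        row = {
            "locus_id": locus.locus_id,
            "chrom": locus.chrom,
            "start": locus.start,
            "end": locus.end,
            "d": locus.d,
            "N": locus.n_reads,
            "missing_fraction": round(locus.missing_fraction, 6),
        }
        for s in samples:
            row[f"depth_{s}"] = depths.get(s, 0)
        rows.append(row)
    return pd.DataFrame(rows)


def records_from_locus(locus: Locus, read_ids: Sequence[str] | None = None) -> list[MethCallRecord]:
    """Convert a locus back to per-read records (for writing simulated data)."""
    out = []
    for i, r in enumerate(locus.reads):
        states = tuple(
            int(v) if m else MISSING for v, m in zip(r.values, r.observed_mask)
        )
        rid = read_ids[i] if read_ids is not None else f"{locus.locus_id}_r{i}"
        out.append(
            MethCallRecord(rid, r.sample_id, locus.chrom,
                           tuple(int(p) for p in locus.cpg_positions), states)
        )
    return out
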