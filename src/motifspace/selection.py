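"""Selection sequencing counts: CPM, enrichment, calibration, censuses.

CPM (counts per million) of a sequence is its read count times 1e6 divided
by the total reads in the dataset; enrichment divides the observed frequency
by the sequence's designed frequency in the starting library. Two selections
can be compared quantitatively after calibrating CPM values on sequences
observed in both (a least-squares line in log10-log10 space).

The module also implements the per-position nucleotide grouping analysis
that flags positions whose identity separates turnover-limited (kcat-like)
from affinity-limited (KM-like) behaviour between two selection conditions:
sequences shared by the two datasets are partitioned by the base at a
position and a log-log line is fitted per base; divergent group slopes mark
the position as modulating one kinetic parameter specifically.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from scipy import stats

from .design import LibraryDesign, expected_frequency
from .iupac import BASES


class SelectionError(ValueError):
    pass


@dataclass
class CountTable:
    """Unique-sequence read counts (all sequences of one length)."""

    counts: dict[str, int]

    def __post_init__(self):
        if not self.counts:
            raise SelectionError("empty count table")
        lengths = {len(s) for s in self.counts}
        if len(lengths) != 1:
            raise SelectionError(f"sequences have mixed lengths: {sorted(lengths)}")
        for s, c in self.counts.items():
            if c < 0 or int(c) != c:
                raise SelectionError(f"negative or non-integer count for {s}")
            if any(b not in BASES for b in s):
                raise SelectionError(f"non-ACGT sequence: {s!r}")

    @property
    def total_reads(self) -> int:
        return sum(self.counts.values())

    def __len__(self) -> int:
        return len(self.counts)


@dataclass
class SelectionDataset:
    """A count table plus the selection condition it came from."""

    counts: CountTable
    substrate_conc: float | None = None  # uM
    incubation_time: float | None = None  # minutes
    label: str = ""
    _cpm: dict[str, float] | None = field(default=None, repr=False)

    @property
    def cpm(self) -> dict[str, float]:
        if self._cpm is None:
            self._cpm = compute_cpm(self.counts)
        return self._cpm


def ingest_reads(
    source,
    expected_length: int,
    flank5: str = "",
    flank3: str = "",
    fmt: str | None = None,
) -> tuple[CountTable, dict[str, int]]:
    """Count identical reads from a FASTA/FASTQ stream.

    Reads are assumed pre-merged and orientation-unified. If flanking
    sequences are given they are clipped by exact match; reads whose clipped
    insert is not exactly ``expected_length`` long (or whose flanks do not
    match) are discarded. Returns the count table and a kept/discarded
    summary. Raises if no read survives.
    """
    if fmt is None:
        fmt = _sniff_format(source)
    counts: dict[str, int] = {}
    kept = discarded = 0
    for record in SeqIO.parse(source, fmt):
        seq = str(record.seq).upper()
        if flank5:
            if not seq.startswith(flank5.upper()):
                discarded += 1
                continue
            seq = seq[len(flank5):]
        if flank3:
            if not seq.endswith(flank3.upper()):
                discarded += 1
                continue
            seq = seq[: len(seq) - len(flank3)]
        if len(seq) != expected_length or any(b not in BASES for b in seq):
            discarded += 1
            continue
        counts[seq] = counts.get(seq, 0) + 1
        kept += 1
    if kept == 0:
        raise SelectionError("no reads passed ingestion filters")
    return CountTable(counts), {"kept": kept, "discarded": discarded}


def _sniff_format(source) -> str:
    path = str(source)
    if path.endswith((".fq", ".fastq")):
        return "fastq"
    return "fasta"


def compute_cpm(counts: CountTable) -> dict[str, float]:
    """CPM(s) = count(s) * 1e6 / total reads; values sum to 1e6."""
    total = counts.total_reads
    if total <= 0:
        raise SelectionError("total read count must be positive")
    return {s: c * 1e6 / total for s, c in counts.counts.items()}


def compute_enrichment(
    dataset: SelectionDataset, design: LibraryDesign
) -> tuple[dict[str, float], list[str]]:
    """Observed frequency divided by designed frequency, per sequence.

    Sequences absent from the design (designed frequency zero) are returned
    in a separate list and never divided.
    """
    total = dataset.counts.total_reads
    enrich: dict[str, float] = {}
    unexplained: list[str] = []
    for s, c in dataset.counts.counts.items():
        f0 = expected_frequency(design, s)
        if f0 == 0.0:
            unexplained.append(s)
        else:
            enrich[s] = (c / total) / f0
    return enrich, unexplained


@dataclass(frozen=True)
class Calibration:
    """Log10-log10 linear calibration between two datasets' CPM scales."""

    slope: float
    intercept: float
    n_shared: int
    fit_range: tuple[float, float]

    def apply(self, cpm_value: float) -> float:
        """Map a CPM value from dataset A onto dataset B's scale."""
        return 10 ** (self.slope * math.log10(cpm_value) + self.intercept)


def calibrate(
    dataset_a: SelectionDataset,
    dataset_b: SelectionDataset,
    shared_ids: Iterable[str] | None = None,
    fit_range: tuple[float, float] = (1.0, 1000.0),
) -> Calibration:
    """Least-squares line of log10 CPM_b against log10 CPM_a on shared sequences.

    Only sequences observed with nonzero CPM in both datasets and with
    CPM_a inside ``fit_range`` enter the fit (the paper-style reliable range
    is roughly 1-1000 CPM). Requires at least two shared sequences.
    """
    cpm_a, cpm_b = dataset_a.cpm, dataset_b.cpm
    if shared_ids is None:
        shared_ids = set(cpm_a) & set(cpm_b)
    lo, hi = fit_range
    xs, ys = [], []
    for s in shared_ids:
        a, b = cpm_a.get(s, 0.0), cpm_b.get(s, 0.0)
        if a > 0 and b > 0 and lo <= a <= hi:
            xs.append(math.log10(a))
            ys.append(math.log10(b))
    if len(xs) < 2:
        raise SelectionError(f"need >= 2 shared sequences in range, got {len(xs)}")
    if np.ptp(xs) == 0:  # vertical degenerate case
        raise SelectionError("shared sequences have identical CPM_a; cannot fit")
    res = stats.linregress(xs, ys)
    return Calibration(
        slope=float(res.slope),
        intercept=float(res.intercept),
        n_shared=len(xs),
        fit_range=fit_range,
    )


def census_above_cutoffs(
    cpm_map: Mapping[str, float], cutoffs: Sequence[float]
) -> list[int]:
    """Number of sequences with CPM >= each cutoff (cutoffs ascending)."""
    if list(cutoffs) != sorted(cutoffs):
        raise SelectionError("cutoffs must be sorted ascending")
    values = np.fromiter(cpm_map.values(), dtype=float)
    return [int((values >= c).sum()) for c in cutoffs]


def census_fold_difference(
    cpm_a: Mapping[str, float],
    cpm_b: Mapping[str, float],
    cutoffs: Sequence[float],
    calibration: Calibration | None = None,
) -> pd.DataFrame:
    """Census of both datasets per cutoff, with the fold difference A/B.

    If a calibration is given, dataset A's CPM values are mapped onto B's
    scale before the census.
    """
    if calibration is not None:
        cpm_a = {s: calibration.apply(v) for s, v in cpm_a.items() if v > 0}
    na = census_above_cutoffs(cpm_a, cutoffs)
    nb = census_above_cutoffs(cpm_b, cutoffs)
    fold = [a / b if b else math.inf for a, b in zip(na, nb)]
    return pd.DataFrame({"cutoff": list(cutoffs), "n_a": na, "n_b": nb, "fold_a_over_b": fold})


# ---------------------------------------------------------------------------
# positionwise slope analysis (kcat-vs-KM behaviour)
# ---------------------------------------------------------------------------


def _ols_slope_intercept(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    xm, ym = x.mean(), y.mean()
    slope = ((x - xm) * (y - ym)).sum() / ((x - xm) ** 2).sum()
    return float(slope), float(ym - slope * xm)


def _bootstrap_slope_se(
    x: np.ndarray, y: np.ndarray, n_boot: int, rng: np.random.Generator
) -> float:
    """Bootstrap SE of the OLS slope, vectorised over resamples."""
    n = len(x)
    idx = rng.integers(0, n, size=(n_boot, n))
    xb, yb = x[idx], y[idx]
    xm = xb.mean(axis=1, keepdims=True)
    ym = yb.mean(axis=1, keepdims=True)
    var = ((xb - xm) ** 2).sum(axis=1)
    cov = ((xb - xm) * (yb - ym)).sum(axis=1)
    ok = var > 0
    if ok.sum() < 2:
        return 0.0
    return float((cov[ok] / var[ok]).std(ddof=1))


def position_group_slopes(
    dataset_kcat: SelectionDataset,
    dataset_km: SelectionDataset,
    position: int,
    min_group: int = 2,
    n_boot: int = 1000,
    seed: int = 0,
    fit_quantiles: tuple[float, float] | None = (0.05, 0.95),
) -> pd.DataFrame:
    """Per-nucleotide slopes of log10 CPM_km vs log10 CPM_kcat at a position.

    Shared sequences are partitioned by the base at ``position`` (1-based);
    an ordinary least-squares line is fitted per group with bootstrap
    standard errors on the slope (``n_boot`` resamples, seeded). Groups with
    fewer than ``min_group`` members are skipped with a warning.

    By default each group is fitted only over a CPM window common to all
    groups (the intersection of their per-group ``fit_quantiles`` ranges on
    the kcat axis). This makes the comparison segment-matched: groups lying
    on one shared, possibly curved, CPM-CPM relation then get equal slopes,
    while groups following genuinely different relations - the signature of
    a base that modulates one kinetic parameter specifically - still
    diverge. Pass ``fit_quantiles=None`` to fit on all shared members.

    The accompanying divergence score is computed by
    :func:`slope_divergence`.
    """
    shared = sorted(set(dataset_kcat.cpm) & set(dataset_km.cpm))
    rng = np.random.default_rng(seed)
    groups: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for base in BASES:
        members = [s for s in shared if s[position - 1] == base]
        if not members:
            continue
        x = np.log10([dataset_kcat.cpm[s] for s in members])
        y = np.log10([dataset_km.cpm[s] for s in members])
        groups[base] = (x, y)
    if fit_quantiles is not None and len(groups) > 1:
        qlo, qhi = fit_quantiles
        lo = max(np.quantile(x, qlo) for x, _ in groups.values())
        hi = min(np.quantile(x, qhi) for x, _ in groups.values())
        if lo < hi:
            groups = {
                b: (x[(x >= lo) & (x <= hi)], y[(x >= lo) & (x <= hi)])
                for b, (x, y) in groups.items()
            }
    rows = []
    for base, (x, y) in groups.items():
        if len(x) < min_group or (len(x) > 0 and np.ptp(x) == 0):
            warnings.warn(
                f"group {base} at position {position} has n={len(x)} usable "
                "members or no spread; skipped"
            )
            continue
        slope, intercept = _ols_slope_intercept(x, y)
        rows.append(
            {
                "position": position,
                "base": base,
                "slope": slope,
                "intercept": intercept,
                "n": len(x),
                "slope_se": _bootstrap_slope_se(x, y, n_boot, rng),
            }
        )
    return pd.DataFrame(rows)


def slope_divergence(group_table: pd.DataFrame) -> float:
    """Max pairwise slope difference standardised by bootstrap SEs.

    Zero when fewer than two groups were fit.
    """
    if len(group_table) < 2:
        return 0.0
    best = 0.0
    recs = group_table.to_dict("records")
    for i in range(len(recs)):
        for j in range(i + 1, len(recs)):
            se = math.hypot(recs[i]["slope_se"], recs[j]["slope_se"])
            if se == 0:
                continue
            best = max(best, abs(recs[i]["slope"] - recs[j]["slope"]) / se)
    return best


def scan_position_slopes(
    dataset_kcat: SelectionDataset,
    dataset_km: SelectionDataset,
    positions: Sequence[int],
    min_group: int = 2,
    n_boot: int = 1000,
    seed: int = 0,
    fit_quantiles: tuple[float, float] | None = (0.05, 0.95),
) -> pd.DataFrame:
    """Rank positions by slope divergence between nucleotide groups.

    Returns one row per position, sorted by decreasing divergence; the
    top-ranked position is the best candidate for a base identity that
    modulates one kinetic parameter specifically.
    """
    rows = []
    for pos in positions:
        table = position_group_slopes(
            dataset_kcat,
            dataset_km,
            pos,
            min_group=min_group,
            n_boot=n_boot,
            seed=seed,
            fit_quantiles=fit_quantiles,
        )
        rows.append(
            {
                "position": pos,
                "n_groups": len(table),
                "divergence": slope_divergence(table),
            }
        )
    out = pd.DataFrame(rows).sort_values(
        ["divergence", "position"], ascending=[False, True]
    )
    return out.reset_index(drop=True)
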