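"""Pseudo-haploid genotype panels: containers, polarization, filtering, QC.

The universal substrate of the package is the :class:`CallMatrix`: an
``N x S`` matrix of pseudo-haploid calls in ``{0 = ancestral, 1 = derived,
-1 = missing}`` together with a :class:`SitePanel` describing each site
(chromosome, 1-based position, ancestral/derived allele) and a list of
sample ids.  Ancient genomes are represented by one sampled allele per
site, which sidesteps diploid genotype calling at low coverage; alleles
are oriented ancestral/derived against an outgroup consensus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

MISSING = -1

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")
_BASES = frozenset("ACGT")


def is_transversion(a: str, b: str) -> bool:
    """True when the a<->b substitution crosses the purine/pyrimidine divide."""
    return not ((a in _PURINES and b in _PURINES) or (a in _PYRIMIDINES and b in _PYRIMIDINES))


class SitePanel:
    """Per-site annotation table.

    Parameters
    ----------
    table:
        DataFrame with columns ``chrom``, ``pos`` (1-based), ``ancestral``,
        ``derived``.  Positions must be strictly increasing within each
        chromosome and ancestral must differ from derived.
    """

    REQUIRED = ("chrom", "pos", "ancestral", "derived")

    def __init__(self, table: pd.DataFrame):
        missing_cols = [c for c in self.REQUIRED if c not in table.columns]
        if missing_cols:
            raise ValueError(f"site table lacks columns {missing_cols}")
        table = table.reset_index(drop=True)
        anc = table["ancestral"].astype(str)
        der = table["derived"].astype(str)
        if not anc.isin(_BASES).all() or not der.isin(_BASES).all():
            raise ValueError("alleles must be A/C/G/T")
        if (anc == der).any():
            bad = int(np.argmax((anc == der).to_numpy()))
            raise ValueError(f"ancestral == derived at site index {bad}")
        for chrom, sub in table.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on chromosome {chrom!r}")
        self.table = table

    def __len__(self) -> int:
        return len(self.table)

    @property
    def transversion(self) -> np.ndarray:
        """Boolean flag per site; transversions are immune to deamination damage."""
        anc = self.table["ancestral"].to_numpy()
        der = self.table["derived"].to_numpy()
        return np.array([is_transversion(a, d) for a, d in zip(anc, der)], dtype=bool)

    def take(self, idx) -> "SitePanel":
        return SitePanel(self.table.iloc[np.asarray(idx)].reset_index(drop=True))

    def __eq__(self, other) -> bool:
        return isinstance(other, SitePanel) and self.table.equals(other.table)


class CallMatrix:
    """N samples x S sites of pseudo-haploid calls in {0, 1, -1(missing)}."""

    def __init__(self, data: np.ndarray, samples: Sequence[str], sites: SitePanel):
        data = np.asarray(data, dtype=np.int8)
        if data.ndim != 2:
            raise ValueError("call matrix must be 2-D")
        if data.shape[0] != len(samples):
            raise ValueError("row count does not match number of samples")
        if data.shape[1] != len(sites):
            raise ValueError("column count does not match site panel")
        if not np.isin(data, (0, 1, MISSING)).all():
            raise ValueError("calls must be 0, 1 or -1 (missing)")
        if len(set(samples)) != len(samples):
            raise ValueError("duplicated sample ids")
        self.data = data
        self.samples = list(samples)
        self.sites = sites

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_sites(self) -> int:
        return self.data.shape[1]

    def row(self, sample: str) -> np.ndarray:
        return self.data[self.samples.index(sample)]

    def observed(self) -> np.ndarray:
        """Boolean mask of non-missing entries."""
        return self.data != MISSING

    def take_sites(self, idx) -> "CallMatrix":
        idx = np.asarray(idx)
        return CallMatrix(self.data[:, idx], self.samples, self.sites.take(idx))

    def take_samples(self, ids: Sequence[str]) -> "CallMatrix":
        rows = [self.samples.index(s) for s in ids]
        return CallMatrix(self.data[rows], list(ids), self.sites)


@dataclass
class ReadCounts:
    """Per sample/site derived and total read counts (ancient low-coverage data)."""

    derived: np.ndarray  # N x S
    total: np.ndarray  # N x S
    samples: list[str]

    def __post_init__(self):
        self.derived = np.asarray(self.derived, dtype=np.int64)
        self.total = np.asarray(self.total, dtype=np.int64)
        if self.derived.shape != self.total.shape:
            raise ValueError("derived/total shape mismatch")
        if np.any(self.derived < 0) or np.any(self.derived > self.total):
            raise ValueError("need 0 <= derived <= total")

    def row(self, sample: str) -> tuple[np.ndarray, np.ndarray]:
        i = self.samples.index(sample)
        return self.derived[i], self.total[i]


@dataclass
class OutgroupConsensus:
    """Outgroup allele observations: S sites x G genomes ('' = missing).

    The consensus ancestral allele is defined by a majority rule: with all
    ``G`` genomes observed, at most ``max_alt`` of them may carry an
    alternative allele; with ``k < G`` observed the threshold scales down to
    ``floor(max_alt * k / G)``.
    """

    observations: np.ndarray  # dtype '<U1', S x G
    max_alt: int = 2

    def __post_init__(self):
        self.observations = np.asarray(self.observations, dtype="<U1")
        if self.observations.ndim != 2:
            raise ValueError("observations must be S x G")

    @property
    def n_genomes(self) -> int:
        return self.observations.shape[1]

    def consensus(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (allele per site, '' where undefined; reason per site)."""
        S, G = self.observations.shape
        allele = np.full(S, "", dtype="<U1")
        reason = np.full(S, "", dtype=object)
        for s in range(S):
            obs = [b for b in self.observations[s] if b]
            k = len(obs)
            if k == 0:
                reason[s] = "no outgroup"
                continue
            vals, counts = np.unique(obs, return_counts=True)
            order = np.argsort(-counts, kind="stable")
            vals, counts = vals[order], counts[order]
            if len(vals) > 1 and counts[0] == counts[1]:
                reason[s] = "tied outgroup majority"
                continue
            n_alt = k - counts[0]
            limit = (self.max_alt * k) // G
            if n_alt > limit:
                reason[s] = "outgroup majority rule failed"
                continue
            allele[s] = vals[0]
        return allele, reason


@dataclass
class DropReport:
    """Sites removed during polarization, with per-site reasons."""

    dropped_index: np.ndarray
    reasons: list[str]

    def __len__(self) -> int:
        return len(self.dropped_index)


def polarize_with_outgroup(
    calls: CallMatrix, outgroup: OutgroupConsensus
) -> tuple[CallMatrix, DropReport]:
    """Orient alleles ancestral/derived against the outgroup consensus.

    Sites whose consensus allele equals the panel's current derived allele
    are flipped (calls ``1 <-> 0``, alleles swapped); sites with no valid
    consensus, or whose consensus matches neither panel allele, are dropped
    and reported.  The operation is idempotent: a second application finds
    every kept site already oriented.
    """
    if outgroup.observations.shape[0] != calls.n_sites:
        raise ValueError("outgroup does not cover the panel's sites")
    allele, reason = outgroup.consensus()
    anc = calls.sites.table["ancestral"].to_numpy()
    der = calls.sites.table["derived"].to_numpy()

    keep, flip, drop_idx, drop_reason = [], [], [], []
    for s in range(calls.n_sites):
        if allele[s] == "":
            drop_idx.append(s)
            drop_reason.append(reason[s])
        elif allele[s] == anc[s]:
            keep.append(s)
            flip.append(False)
        elif allele[s] == der[s]:
            keep.append(s)
            flip.append(True)
        else:
            drop_idx.append(s)
            drop_reason.append("outgroup allele not in panel")

    keep = np.asarray(keep, dtype=int)
    flip = np.asarray(flip, dtype=bool)
    data = calls.data[:, keep].copy()
    if flip.any():
        cols = data[:, flip]
        obs = cols != MISSING
        cols[obs] = 1 - cols[obs]
        data[:, flip] = cols
    table = calls.sites.table.iloc[keep].reset_index(drop=True).copy()
    swapped_anc = np.where(flip, table["derived"], table["ancestral"])
    swapped_der = np.where(flip, table["ancestral"], table["derived"])
    table["ancestral"] = swapped_anc
    table["derived"] = swapped_der
    oriented = CallMatrix(data, calls.samples, SitePanel(table))
    return oriented, DropReport(np.asarray(drop_idx, dtype=int), drop_reason)


def filter_sites(
    calls: CallMatrix,
    transversions_only: bool = False,
    min_coverage_fraction: float = 0.0,
    min_minor_count: int = 0,
    focal_samples: Sequence[str] | None = None,
) -> tuple[CallMatrix, np.ndarray]:
    """Site filters mirroring the conditioning used for ancient panels.

    Keeps sites that (i) are transversions when ``transversions_only``,
    (ii) are non-missing in at least ``min_coverage_fraction`` of the focal
    samples, and (iii) segregate with a minor-allele count of at least
    ``min_minor_count`` among the focal samples (``min_minor_count=2``
    keeps variants segregating "at least as doubletons").

    Returns the filtered matrix and the kept-site index array.  An empty
    result is allowed.
    """
    if not (0.0 <= min_coverage_fraction <= 1.0):
        raise ValueError("min_coverage_fraction must be in [0, 1]")
    if min_minor_count < 0:
        raise ValueError("min_minor_count must be >= 0")
    if focal_samples is None:
        sub = calls.data
    else:
        rows = [calls.samples.index(s) for s in focal_samples]
        sub = calls.data[rows]
    obs = sub != MISSING
    n_obs = obs.sum(axis=0)
    n_focal = sub.shape[0]

    keep = np.ones(calls.n_sites, dtype=bool)
    if transversions_only:
        keep &= calls.sites.transversion
    keep &= n_obs >= min_coverage_fraction * n_focal
    if min_minor_count > 0:
        derived = np.where(obs, sub == 1, False).sum(axis=0)
        minor = np.minimum(derived, n_obs - derived)
        keep &= minor >= min_minor_count
    idx = np.flatnonzero(keep)
    return calls.take_sites(idx), idx


def _pairwise_r2(x: np.ndarray, y: np.ndarray, min_shared: int) -> float:
    """Squared Pearson correlation of two 0/1 call columns over shared samples.

    Returns -inf when fewer than ``min_shared`` samples observe both sites
    (such pairs are never pruned) and 0 when either site is monomorphic on
    the shared set.
    """
    shared = (x != MISSING) & (y != MISSING)
    if shared.sum() < min_shared:
        return -np.inf
    xs = x[shared].astype(float)
    ys = y[shared].astype(float)
    vx = xs.var()
    vy = ys.var()
    if vx == 0.0 or vy == 0.0:
        return 0.0
    cov = ((xs - xs.mean()) * (ys - ys.mean())).mean()
    return float(cov * cov / (vx * vy))


def ld_prune(
    calls: CallMatrix,
    window_snps: int = 50,
    step_snps: int = 10,
    r2_max: float = 0.2,
    min_shared: int = 20,
) -> np.ndarray:
    """Greedy window-based LD pruning (the plink ``--indep-pairwise`` scheme).

    Slides a window of ``window_snps`` sites advanced by ``step_snps``;
    within a window, every pair of still-kept sites with squared Pearson
    correlation above ``r2_max`` (computed on pairwise-complete samples)
    loses its later member.  Pairs sharing fewer than ``min_shared``
    non-missing samples are never pruned.  Returns the sorted kept-site
    index array; the procedure is deterministic.
    """
    S = calls.n_sites
    if window_snps < 2 or S < 2:
        return np.arange(S)
    removed = np.zeros(S, dtype=bool)
    start = 0
    while True:
        end = min(start + window_snps, S)
        live = [i for i in range(start, end) if not removed[i]]
        for a in range(len(live)):
            i = live[a]
            if removed[i]:
                continue
            for b in range(a + 1, len(live)):
                j = live[b]
                if removed[j]:
                    continue
                r2 = _pairwise_r2(calls.data[:, i], calls.data[:, j], min_shared)
                if r2 > r2_max:
                    removed[j] = True
        if end >= S:
            break
        start += step_snps
    return np.flatnonzero(~removed)


@dataclass
class ErrorRateResult:
    rate: float
    n_sites: int
    per_type: pd.DataFrame  # columns: ancestral, observed, ancient, modern, rate
    truncated: bool = False


def estimate_error_rate(
    ancient: np.ndarray,
    modern: np.ndarray,
    sites: SitePanel,
    min_sites: int = 1000,
) -> ErrorRateResult:
    """Sequencing error rate as excess derived alleles private to an ancient genome.

    Over sites where both genomes are observed (ancestral states defined by
    the outgroup-polarized panel), the rate is ``(derived_ancient -
    derived_modern) / n_comparable`` with the modern genome treated as
    error-free; negative estimates are truncated at zero and flagged.  A
    per-substitution-type table splits the same excess by ancestral ->
    derived base pair.
    """
    ancient = np.asarray(ancient)
    modern = np.asarray(modern)
    comparable = (ancient != MISSING) & (modern != MISSING)
    n = int(comparable.sum())
    if n < min_sites:
        raise ValueError(f"only {n} comparable sites; need >= {min_sites}")
    a_der = int((ancient[comparable] == 1).sum())
    m_der = int((modern[comparable] == 1).sum())
    raw = (a_der - m_der) / n
    truncated = raw < 0
    rate = max(0.0, raw)

    anc = sites.table["ancestral"].to_numpy()
    der = sites.table["derived"].to_numpy()
    rows = []
    for pair in sorted({(a, d) for a, d in zip(anc[comparable], der[comparable])}):
        mask = comparable & (anc == pair[0]) & (der == pair[1])
        nt = int(mask.sum())
        at = int((ancient[mask] == 1).sum())
        mt = int((modern[mask] == 1).sum())
        rows.append(
            {
                "ancestral": pair[0],
                "observed": pair[1],
                "n_sites": nt,
                "ancient_derived": at,
                "modern_derived": mt,
                "rate": max(0.0, (at - mt) / nt) if nt else 0.0,
            }
        )
    return ErrorRateResult(rate, n, pd.DataFrame(rows), truncated)
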