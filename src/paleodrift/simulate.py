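"""Forward drift/admixture simulator with known ground truth.

Allele frequencies evolve along a population tree under the
Balding-Nichols model: a branch with drift parameter ``F`` draws the child
frequency from a Beta distribution with mean equal to the parent frequency
``p`` and variance ``F * p * (1 - p)``.  Admixture events mix two source
frequencies linearly before any drift of their own.  Individuals are
linear mixtures of the resulting population frequencies (mixing vector
``q`` on the simplex), observed as pseudo-haploid calls with missingness,
and optionally as sequencing read counts with error.  Every draw is
deterministic given the seed.

The generator stands in for coalescent simulation at matched drift
moments; it produces the panels on which the inference modules are
validated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .panel import MISSING, CallMatrix, ReadCounts, SitePanel
from .spacetime import haversine

__all__ = [
    "Branch",
    "AdmixtureEvent",
    "DemographicModel",
    "SimulatedPanel",
    "simulate_branch_frequencies",
    "draw_admixed_individual",
    "draw_pseudohaploid",
    "draw_read_counts",
    "assign_spacetime",
    "random_site_table",
    "simulate_panel",
    "star_scenario",
    "ibd_panel",
]


@dataclass(frozen=True)
class Branch:
    parent: str
    child: str
    drift: float  # Balding-Nichols F in [0, 1]


@dataclass(frozen=True)
class AdmixtureEvent:
    target: str
    source_a: str
    source_b: str
    alpha: float  # proportion from source_a, in [0, 1]
    drift: float = 0.0  # drift of the target after mixing


def _uniform_root_law(lo: float = 0.05, hi: float = 0.95):
    def law(rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.uniform(lo, hi, size=n)

    return law


@dataclass
class DemographicModel:
    """A population tree plus admixture edges, with per-branch drift.

    ``populations`` lists every node label (internal and leaf).  Exactly one
    node is the root: it appears as neither a branch child nor an admixture
    target.  The graph must be acyclic and each node must be created exactly
    once.
    """

    populations: list[str]
    branches: list[Branch]
    admixture_events: list[AdmixtureEvent] = field(default_factory=list)
    root_frequency_law: Callable[[np.random.Generator, int], np.ndarray] = field(
        default_factory=_uniform_root_law
    )

    def __post_init__(self):
        pops = set(self.populations)
        if len(pops) != len(self.populations):
            raise ValueError("duplicated population labels")
        for b in self.branches:
            if not (0.0 <= b.drift <= 1.0):
                raise ValueError(f"branch drift F={b.drift} outside [0, 1]")
            if b.parent not in pops or b.child not in pops:
                raise ValueError(f"branch {b} references unknown population")
        for e in self.admixture_events:
            if not (0.0 <= e.alpha <= 1.0):
                raise ValueError(f"admixture alpha={e.alpha} outside [0, 1]")
            if not (0.0 <= e.drift <= 1.0):
                raise ValueError(f"admixture drift F={e.drift} outside [0, 1]")
            if {e.target, e.source_a, e.source_b} - pops:
                raise ValueError(f"admixture event {e} references unknown population")
        created = [b.child for b in self.branches] + [e.target for e in self.admixture_events]
        if len(set(created)) != len(created):
            raise ValueError("some population is created more than once")
        roots = pops - set(created)
        if len(roots) != 1:
            raise ValueError(f"model must have exactly one root, found {sorted(roots)}")
        self.root = roots.pop()
        self._order = self._toposort()

    def _toposort(self) -> list:
        """Evaluation order over creation events; raises on cycles."""
        deps: dict[str, tuple] = {}
        for b in self.branches:
            deps[b.child] = (b.parent,)
        for e in self.admixture_events:
            deps[e.target] = (e.source_a, e.source_b)
        done = {self.root}
        order: list[str] = []
        pending = set(deps)
        while pending:
            ready = [c for c in pending if all(p in done for p in deps[c])]
            if not ready:
                raise ValueError("demographic model contains a cycle")
            for c in sorted(ready):
                order.append(c)
                done.add(c)
                pending.discard(c)
        return order


def _balding_nichols(rng: np.random.Generator, p: np.ndarray, F: float) -> np.ndarray:
    """Child frequencies after one drift step of magnitude F."""
    p = np.asarray(p, dtype=float)
    if F == 0.0:
        return p.copy()
    if F == 1.0:
        return rng.random(p.shape) < p
    out = np.empty_like(p)
    interior = (p > 0.0) & (p < 1.0)
    scale = (1.0 - F) / F
    a = p[interior] * scale
    b = (1.0 - p[interior]) * scale
    out[interior] = rng.beta(a, b)
    out[~interior] = p[~interior]  # fixed alleles stay fixed
    return out


def simulate_branch_frequencies(
    model: DemographicModel, n_sites: int, seed: int
) -> pd.DataFrame:
    """Per-population derived-allele frequencies at ``n_sites`` independent sites.

    The root frequency is drawn from the model's root law; each branch
    applies a Balding-Nichols step; admixture targets mix their sources
    linearly (``alpha`` from source_a) before their own drift.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = np.random.default_rng(seed)
    freqs: dict[str, np.ndarray] = {}
    freqs[model.root] = np.asarray(model.root_frequency_law(rng, n_sites), dtype=float)
    by_branch = {b.child: b for b in model.branches}
    by_admix = {e.target: e for e in model.admixture_events}
    for node in model._order:
        if node in by_branch:
            b = by_branch[node]
            freqs[node] = _balding_nichols(rng, freqs[b.parent], b.drift)
        else:
            e = by_admix[node]
            mixed = e.alpha * freqs[e.source_a] + (1.0 - e.alpha) * freqs[e.source_b]
            freqs[node] = _balding_nichols(rng, mixed, e.drift)
    return pd.DataFrame(freqs)


def draw_admixed_individual(freq_table: pd.DataFrame, q: dict | pd.Series) -> np.ndarray:
    """Individual allele frequency p_i(s) = sum_a q_a * p_a(s)."""
    q = pd.Series(q, dtype=float)
    if np.any(q < 0) or abs(q.sum() - 1.0) > 1e-9:
        raise ValueError("q must be non-negative and sum to 1")
    unknown = set(q.index) - set(freq_table.columns)
    if unknown:
        raise ValueError(f"unknown populations in q: {sorted(unknown)}")
    p = np.zeros(len(freq_table))
    for pop, w in q.items():
        p += w * freq_table[pop].to_numpy()
    return np.clip(p, 0.0, 1.0)  # guard float roundoff at the simplex corners


def draw_pseudohaploid(
    p_individual: np.ndarray, missing_rate: float, seed: int
) -> np.ndarray:
    """One sampled allele per site: derived w.p. p, then masked missing."""
    p = np.asarray(p_individual, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("individual frequencies must lie in [0, 1]")
    if not (0.0 <= missing_rate < 1.0):
        raise ValueError("missing_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    calls = (rng.random(p.shape) < p).astype(np.int8)
    mask = rng.random(p.shape) < missing_rate
    calls[mask] = MISSING
    return calls


def draw_read_counts(
    p_individual: np.ndarray, mean_depth: float, error_rate: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Read counts: total ~ Poisson(depth); g ~ Binomial(2, p); derived reads
    are Binomial(total, g/2*(1-e) + (1-g/2)*e)."""
    p = np.asarray(p_individual, dtype=float)
    if mean_depth <= 0:
        raise ValueError("mean_depth must be > 0")
    if not (0.0 <= error_rate < 0.5):
        raise ValueError("error_rate must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    total = rng.poisson(mean_depth, size=p.shape)
    g = rng.binomial(2, p)
    pr = (g / 2.0) * (1.0 - error_rate) + (1.0 - g / 2.0) * error_rate
    derived = rng.binomial(total, pr)
    return derived, total


def random_site_table(
    n_sites: int, seed: int, transversion_fraction: float = 1.0, chrom: str = "1"
) -> SitePanel:
    """Random biallelic site annotations; ``transversion_fraction`` of sites
    get a transversion allele pair, the rest a transition."""
    rng = np.random.default_rng(seed)
    tv_pairs = [("A", "C"), ("A", "T"), ("C", "A"), ("C", "G"),
                ("G", "C"), ("G", "T"), ("T", "A"), ("T", "G")]
    ts_pairs = [("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")]
    is_tv = rng.random(n_sites) < transversion_fraction
    anc = np.empty(n_sites, dtype="<U1")
    der = np.empty(n_sites, dtype="<U1")
    for s in range(n_sites):
        pool = tv_pairs if is_tv[s] else ts_pairs
        a, d = pool[rng.integers(len(pool))]
        anc[s], der[s] = a, d
    pos = np.cumsum(rng.integers(1, 200, size=n_sites))
    table = pd.DataFrame({"chrom": chrom, "pos": pos, "ancestral": anc, "derived": der})
    return SitePanel(table)


@dataclass
class SimulatedPanel:
    """A generated panel plus its ground truth."""

    calls: CallMatrix
    q_true: pd.DataFrame  # N x K, rows sum to 1, columns = population labels
    read_counts: ReadCounts
    meta: pd.DataFrame  # id, group, age_BP, lat, lon
    freqs: pd.DataFrame  # per-population site frequencies
    seed: int

    def __post_init__(self):
        if not np.allclose(self.q_true.to_numpy().sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("q_true rows must sum to 1")
        n = self.calls.n_samples
        if len(self.q_true) != n or len(self.meta) != n:
            raise ValueError("inconsistent dimensions across panel fields")


def simulate_panel(
    model: DemographicModel,
    q_rows: pd.DataFrame,
    n_sites: int,
    seed: int,
    missing_rate: float = 0.0,
    mean_depth: float = 1.0,
    error_rate: float = 0.0,
    transversion_fraction: float = 1.0,
    groups: Sequence[str] | None = None,
) -> SimulatedPanel:
    """Generate a full panel: one individual per row of ``q_rows``.

    ``q_rows`` is an N x K DataFrame of mixing vectors over (a subset of)
    the model's populations; its index supplies sample ids.
    """
    rng = np.random.default_rng(seed)
    freqs = simulate_branch_frequencies(model, n_sites, int(rng.integers(2**31)))
    sites = random_site_table(n_sites, int(rng.integers(2**31)), transversion_fraction)
    n = len(q_rows)
    data = np.empty((n, n_sites), dtype=np.int8)
    der = np.empty((n, n_sites), dtype=np.int64)
    tot = np.empty((n, n_sites), dtype=np.int64)
    for i in range(n):
        p_i = draw_admixed_individual(freqs, q_rows.iloc[i])
        data[i] = draw_pseudohaploid(p_i, missing_rate, int(rng.integers(2**31)))
        der[i], tot[i] = draw_read_counts(p_i, mean_depth, error_rate, int(rng.integers(2**31)))
    ids = [str(s) for s in q_rows.index]
    calls = CallMatrix(data, ids, sites)
    if groups is None:
        groups = [
            q_rows.columns[int(np.argmax(q_rows.iloc[i]))]
            if q_rows.iloc[i].max() > 0.99
            else "admixed"
            for i in range(n)
        ]
    meta = pd.DataFrame(
        {"id": ids, "group": list(groups), "age_BP": 0.0, "lat": 0.0, "lon": 0.0}
    )
    return SimulatedPanel(
        calls=calls,
        q_true=q_rows.copy(),
        read_counts=ReadCounts(der, tot, ids),
        meta=meta,
        freqs=freqs,
        seed=seed,
    )


def star_scenario(
    n_per_pop: int = 50,
    n_admixed: int = 50,
    n_sites: int = 50_000,
    drifts: tuple[float, float, float] = (0.02, 0.06, 0.10),
    shared_drift: float = 0.05,
    outgroup_drift: float = 0.10,
    missing_rate: float = 0.05,
    seed: int = 0,
) -> SimulatedPanel:
    """The standard validation scenario: a three-population star.

    An outgroup and an ancestral stem diverge at the root; the stem splits
    into populations A, B, C with drifts ``drifts``; ``n_per_pop``
    unadmixed individuals per population plus ``n_admixed`` individuals
    with Dirichlet(1) mixing vectors.  One outgroup individual ("Outgroup")
    is appended for coancestry polarization.
    """
    model = DemographicModel(
        populations=["Root", "Out", "Stem", "A", "B", "C"],
        branches=[
            Branch("Root", "Out", outgroup_drift),
            Branch("Root", "Stem", shared_drift),
            Branch("Stem", "A", drifts[0]),
            Branch("Stem", "B", drifts[1]),
            Branch("Stem", "C", drifts[2]),
        ],
    )
    rng = np.random.default_rng(seed)
    pops = ["A", "B", "C"]
    rows = []
    ids = []
    for p in pops:
        for i in range(n_per_pop):
            rows.append({"A": 0.0, "B": 0.0, "C": 0.0, "Out": 0.0, p: 1.0})
            ids.append(f"{p}{i:03d}")
    for i in range(n_admixed):
        q = rng.dirichlet(np.ones(3))
        rows.append({"A": q[0], "B": q[1], "C": q[2], "Out": 0.0})
        ids.append(f"M{i:03d}")
    rows.append({"A": 0.0, "B": 0.0, "C": 0.0, "Out": 1.0})
    ids.append("Outgroup")
    q_rows = pd.DataFrame(rows, index=ids).fillna(0.0)[["A", "B", "C", "Out"]]
    return simulate_panel(
        model,
        q_rows,
        n_sites=n_sites,
        seed=int(rng.integers(2**31)),
        missing_rate=missing_rate,
    )


def assign_spacetime(
    sample_ids: Sequence[str],
    deme_of: Sequence[int],
    deme_layout: Sequence[tuple[float, float]],
    age_law: Callable[[np.random.Generator, int], np.ndarray],
    seed: int,
    jitter_km: float = 10.0,
) -> pd.DataFrame:
    """Metadata table: deme coordinates plus jitter, ages from ``age_law``."""
    for lat, lon in deme_layout:
        if not (-90.0 <= lat <= 90.0):
            raise ValueError(f"latitude {lat} outside [-90, 90]")
        if not (-180.0 <= lon < 180.0):
            raise ValueError(f"longitude {lon} outside [-180, 180)")
    rng = np.random.default_rng(seed)
    n = len(sample_ids)
    ages = np.asarray(age_law(rng, n), dtype=float)
    lat = np.empty(n)
    lon = np.empty(n)
    deg_per_km = 1.0 / 111.32  # latitude degrees per km
    for i, d in enumerate(deme_of):
        la, lo = deme_layout[d]
        lat[i] = np.clip(la + rng.normal(0, jitter_km * deg_per_km), -90.0, 90.0)
        coslat = max(np.cos(np.radians(la)), 1e-6)
        lon[i] = ((lo + rng.normal(0, jitter_km * deg_per_km / coslat)) + 180.0) % 360.0 - 180.0
    return pd.DataFrame(
        {
            "id": list(sample_ids),
            "group": [f"deme{d}" for d in deme_of],
            "age_BP": ages,
            "lat": lat,
            "lon": lon,
        }
    )


def ibd_panel(
    deme_layout: Sequence[tuple[float, float]],
    n_per_deme: int,
    n_sites: int,
    drift_per_km: float,
    seed: int,
    range_km: float = 2000.0,
    age_law: Callable[[np.random.Generator, int], np.ndarray] | None = None,
    missing_rate: float = 0.0,
    jitter_km: float = 10.0,
) -> SimulatedPanel:
    """Panel with isolation by distance: per-deme frequencies perturbed by a
    spatial random field on the logit scale.

    Deme effects follow a Gaussian field with exponential covariance
    ``drift_per_km * range_km * exp(-d / range_km)``, so the variance of the
    difference between two demes grows monotonically with their haversine
    distance (slope ~ ``2 * drift_per_km`` per km at short range), making
    expected genetic distance monotone in geographic distance.
    """
    rng = np.random.default_rng(seed)
    D = len(deme_layout)
    dist = np.zeros((D, D))
    for a in range(D):
        for b in range(a + 1, D):
            d = haversine(*deme_layout[a], *deme_layout[b])
            dist[a, b] = dist[b, a] = d
    cov = drift_per_km * range_km * np.exp(-dist / range_km)
    cov += 1e-10 * np.eye(D)
    L = np.linalg.cholesky(cov)

    p0 = rng.uniform(0.05, 0.95, size=n_sites)
    logit0 = np.log(p0 / (1.0 - p0))
    eta = L @ rng.standard_normal((D, n_sites)) if drift_per_km > 0 else np.zeros((D, n_sites))
    freqs = 1.0 / (1.0 + np.exp(-(logit0[None, :] + eta)))  # D x S

    sites = random_site_table(n_sites, int(rng.integers(2**31)))
    n = D * n_per_deme
    deme_of = np.repeat(np.arange(D), n_per_deme)
    data = np.empty((n, n_sites), dtype=np.int8)
    der = np.empty((n, n_sites), dtype=np.int64)
    tot = np.empty((n, n_sites), dtype=np.int64)
    for i in range(n):
        p_i = freqs[deme_of[i]]
        data[i] = draw_pseudohaploid(p_i, missing_rate, int(rng.integers(2**31)))
        der[i], tot[i] = draw_read_counts(p_i, 1.0, 0.0, int(rng.integers(2**31)))
    ids = [f"d{deme_of[i]}_{i:03d}" for i in range(n)]
    calls = CallMatrix(data, ids, sites)
    if age_law is None:
        age_law = lambda r, m: r.uniform(2000.0, 8000.0, size=m)
    meta = assign_spacetime(
        ids, deme_of, deme_layout, age_law, int(rng.integers(2**31)), jitter_km=jitter_km
    )
    q_true = pd.DataFrame(
        np.eye(D)[deme_of], index=ids, columns=[f"deme{d}" for d in range(D)]
    )
    return SimulatedPanel(
        calls=calls,
        q_true=q_true,
        read_counts=ReadCounts(der, tot, ids),
        meta=meta,
        freqs=pd.DataFrame(freqs.T, columns=[f"deme{d}" for d in range(D)]),
        seed=seed,
    )
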