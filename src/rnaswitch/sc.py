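"""Sampling–Clustering baseline for alternative-structure prediction.

The energy landscape is sampled at 37 °C plus a ladder of elevated
temperatures (decile steps toward the melting temperature), the samples
are split into two clusters by k-means on binary base-pair indicator
vectors — squared Euclidean distance on these vectors equals base-pair
Hamming distance on structures — and the alternative structure is the
lowest-energy sample of the cluster not containing the MFE structure. The
mean silhouette of the two clusters doubles as a riboswitch classification
score: switch-like landscapes separate into two coherent basins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans

from .energy import (
    EnsembleModel,
    estimate_melting_temperature,
    normalize_sequence,
    structure_energy,
)
from .ensemble import Constraints, sample_structures
from .structures import BasePair, Structure

__all__ = [
    "SCProtocol",
    "SampleSet",
    "Clustering",
    "DegenerateClusteringError",
    "sc_sample",
    "cluster_two",
    "sc_alternative",
    "mean_silhouette",
    "temperature_ladder",
]


class DegenerateClusteringError(ValueError):
    """The sample set cannot support a two-cluster partition."""


@dataclass(frozen=True)
class SCProtocol:
    """Sampling protocol: ``n_base`` samples at 37 °C plus ``n_step``
    samples at each of ``n_steps`` ladder temperatures (default
    300 + 150×6 = 1200 samples)."""

    n_base: int = 300
    n_step: int = 150
    n_steps: int = 6

    def __post_init__(self):
        if min(self.n_base, self.n_step) < 1 or self.n_steps < 0:
            raise ValueError("protocol counts must be ≥ 1 (steps ≥ 0)")

    @property
    def total(self) -> int:
        return self.n_base + self.n_step * self.n_steps


def temperature_ladder(t_melt: float, n_steps: int, t_base: float = 37.0) -> list[float]:
    """Ladder T_k = 37 + k·(Tm − 37)/10 for k = 1..n_steps: decile
    intervals from 37 °C toward the melting temperature."""
    return [t_base + k * (t_melt - t_base) / 10.0 for k in range(1, n_steps + 1)]


@dataclass
class SampleSet:
    """Boltzmann samples with their energies and sampling temperatures."""

    sequence: str
    samples: list[tuple[Structure, float, float]]
    protocol: SCProtocol
    rng_seed: int
    _pair_index: dict[BasePair, int] | None = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def structures(self) -> list[Structure]:
        return [s for s, _, _ in self.samples]

    @property
    def energies(self) -> np.ndarray:
        return np.array([e for _, e, _ in self.samples])

    @property
    def pair_index(self) -> dict[BasePair, int]:
        """Indicator-vector dimensions: every base pair observed in the set."""
        if self._pair_index is None:
            observed = sorted({p for s, _, _ in self.samples for p in s.pairs})
            self._pair_index = {bp: k for k, bp in enumerate(observed)}
        return self._pair_index

    def indicator_matrix(self) -> np.ndarray:
        """(n_samples × n_observed_pairs) binary matrix; L1 distance between
        rows equals base-pair Hamming distance between the structures."""
        idx = self.pair_index
        x = np.zeros((len(self.samples), max(len(idx), 1)))
        for row, (s, _, _) in enumerate(self.samples):
            for p in s.pairs:
                x[row, idx[p]] = 1.0
        return x

    def structure_vector(self, s: Structure) -> np.ndarray:
        """Indicator vector of an arbitrary structure over the observed-pair
        dimensions (pairs never observed in the set are dropped; they add
        the same amount to the distance to every sample, so nearest-
        centroid assignment is unaffected)."""
        idx = self.pair_index
        v = np.zeros(max(len(idx), 1))
        for p in s.pairs:
            if p in idx:
                v[idx[p]] = 1.0
        return v

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("structure\tenergy\ttemperature\n")
            for s, e, t in self.samples:
                fh.write(f"{s.dotbracket()}\t{e:.6g}\t{t:g}\n")


def sc_sample(
    seq: str,
    m: EnsembleModel = EnsembleModel(),
    protocol: SCProtocol = SCProtocol(),
    seed: int = 0,
    *,
    t_melt: float | None = None,
) -> SampleSet:
    """Sample the landscape per the protocol: ``n_base`` draws at 37 °C and
    ``n_step`` draws at each ladder temperature. Reproducible given seed."""
    seq = normalize_sequence(seq)
    rng = np.random.default_rng(seed)
    none = Constraints()
    if t_melt is None:
        t_melt = estimate_melting_temperature(seq, m)
    batches = [(37.0, protocol.n_base)]
    batches += [(t, protocol.n_step) for t in temperature_ladder(t_melt, protocol.n_steps)]
    samples: list[tuple[Structure, float, float]] = []
    for t, count in batches:
        for s in sample_structures(seq, count, none, m.at_temperature(t), rng):
            samples.append((s, structure_energy(seq, s, m), t))
    return SampleSet(seq, samples, protocol, seed)


@dataclass
class Clustering:
    """A 2-way partition of a sample set."""

    labels: np.ndarray
    centers: np.ndarray
    lowest_energy_idx: dict[int, int]
    degenerate: bool = False

    def members(self, label: int) -> np.ndarray:
        return np.flatnonzero(self.labels == label)


def cluster_two(ss: SampleSet, seed: int = 0) -> Clustering:
    """k = 2 k-means on indicator vectors (10 seeded k-means++ restarts,
    best inertia kept). All-identical samples yield a degenerate
    single-cluster result, flagged rather than raised."""
    if len(ss) < 2:
        raise ValueError("need at least 2 samples to cluster")
    x = ss.indicator_matrix()
    if np.all(x == x[0]):
        labels = np.zeros(len(ss), dtype=int)
        return Clustering(
            labels=labels,
            centers=x[:1].copy(),
            lowest_energy_idx={0: int(np.argmin(ss.energies))},
            degenerate=True,
        )
    km = KMeans(n_clusters=2, n_init=10, random_state=int(seed) % (2**31))
    labels = km.fit_predict(x)
    energies = ss.energies
    lowest = {}
    for lab in (0, 1):
        members = np.flatnonzero(labels == lab)
        lowest[lab] = int(members[np.argmin(energies[members])])
    return Clustering(labels=labels, centers=km.cluster_centers_, lowest_energy_idx=lowest)


def sc_alternative(ss: SampleSet, cl: Clustering, s1: Structure) -> Structure:
    """The SC alternative-structure prediction: the lowest-energy sample of
    the cluster *not* containing the MFE structure, where the MFE
    structure's cluster is decided by assigning its own indicator vector to
    the nearest centroid (S1* is not injected into the sample set)."""
    if cl.degenerate:
        raise DegenerateClusteringError("cannot pick an alternative from one cluster")
    v = ss.structure_vector(s1)
    d = np.linalg.norm(cl.centers - v, axis=1)
    mfe_cluster = int(np.argmin(d))
    alt_cluster = 1 - mfe_cluster
    return ss.samples[cl.lowest_energy_idx[alt_cluster]][0]


def mean_silhouette(ss: SampleSet, cl: Clustering) -> float:
    """Mean silhouette of the 2-way partition under base-pair Hamming
    distance; members of singleton clusters score 0."""
    if cl.degenerate:
        raise DegenerateClusteringError("silhouette undefined for one cluster")
    d = squareform(pdist(ss.indicator_matrix(), metric="cityblock"))
    labels = cl.labels
    scores = np.zeros(len(ss))
    for k in range(len(ss)):
        own = np.flatnonzero(labels == labels[k])
        other = np.flatnonzero(labels != labels[k])
        if len(own) <= 1:
            continue  # singleton convention: 0
        a = d[k, own[own != k]].mean()
        b = d[k, other].mean()
        denom = max(a, b)
        scores[k] = 0.0 if denom == 0.0 else (b - a) / denom
    return float(scores.mean())
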