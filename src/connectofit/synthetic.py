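"""Synthetic per-subject fiber-count connectivity matrices.

The real inputs this package was designed around — deterministic DTI
tractography fiber counts between 358 cortical landmark ROIs for three age
groups — are not publicly deposited, so this module generates matrices
with the statistical structure that analysis assumes: a spatially embedded
ROI set, modular community structure, distance-dependent connection
probability, heavy-tailed (lognormal) fiber counts, and multiplicative
subject-level noise around a shared group backbone.  Thresholding such a
matrix yields a sparse, clustered, short-path network, the regime in which
small-world and graphlet comparisons are meaningful.

Everything is deterministic given the profile's seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

__all__ = [
    "ConnectomeProfile",
    "ConnectivityMatrix",
    "DEFAULT_GROUP_SIZES",
    "sample_roi_positions",
    "generate_connectome",
    "generate_group",
    "write_connectivity",
    "read_connectivity",
]

#: Cohort sizes of the study population this generator emulates.
DEFAULT_GROUP_SIZES = {"adolescent": 28, "adult": 53, "elderly": 23}


@dataclass(frozen=True)
class ConnectomeProfile:
    """Parameters of the synthetic connectome generator.

    n_rois
        Number of ROIs / network nodes (default 358, the DICCCOL landmark
        count).
    n_modules
        Number of spatially coherent communities.
    intra_module_density / inter_module_density
        Baseline connection probability for ROI pairs inside the same /
        in different modules; modular structure requires inter <= intra.
    weight_scale
        Median fiber count of a present connection (lognormal scale).
    distance_decay
        Exponential decay rate of connection probability with Euclidean
        ROI distance (unit-cube coordinates).
    noise_sd
        Standard deviation of the subject-level multiplicative lognormal
        noise; 0 makes all subjects identical to the group backbone.
    """

    n_rois: int = 358
    n_modules: int = 6
    intra_module_density: float = 0.35
    inter_module_density: float = 0.06
    weight_scale: float = 30.0
    distance_decay: float = 2.0
    noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.n_rois < 2:
            raise ValueError("n_rois must be >= 2")
        if self.n_modules < 1:
            raise ValueError("n_modules must be >= 1")
        for name in ("intra_module_density", "inter_module_density"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.inter_module_density > self.intra_module_density:
            raise ValueError("inter_module_density must not exceed "
                             "intra_module_density")
        if self.weight_scale <= 0:
            raise ValueError("weight_scale must be positive")
        if self.distance_decay < 0 or self.noise_sd < 0:
            raise ValueError("distance_decay and noise_sd must be >= 0")


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric non-negative integer fiber-count matrix for one subject."""

    counts: np.ndarray
    subject_id: str = "S000"
    group: str = "adult"

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError(f"counts must be square, got {c.shape}")
        if not np.array_equal(c, c.T):
            raise ValueError("counts must be symmetric")
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")
        if np.any(np.diag(c) != 0):
            raise ValueError("diagonal must be zero (self-loops ignored)")

    @property
    def n_rois(self) -> int:
        return self.counts.shape[0]


def sample_roi_positions(profile: ConnectomeProfile):
    """ROI coordinates in the unit cube plus module assignments.

    Module centers are placed uniformly in the interior of the cube and
    each ROI is scattered around its (round-robin assigned) center, so
    modules are spatially coherent and intra-module distances are short.

    Returns (positions (n_rois, 3), modules (n_rois,)).
    """
    rng = np.random.default_rng(profile.seed)
    n, k = profile.n_rois, profile.n_modules
    centers = rng.uniform(0.2, 0.8, (k, 3))
    modules = np.arange(n) % k
    rng.shuffle(modules)
    pos = centers[modules] + rng.normal(0.0, 0.12, (n, 3))
    return np.clip(pos, 0.0, 1.0), modules


def _backbone(profile: ConnectomeProfile):
    """Shared group-level expected connectivity: presence probabilities and
    lognormal weights, deterministic from the profile seed."""
    rng = np.random.default_rng((profile.seed, 0xC0FFEE))
    pos, modules = sample_roi_positions(profile)
    n = profile.n_rois
    d = pdist(pos)
    same = squareform(
        (modules[:, None] == modules[None, :]).astype(float), checks=False)
    decay = np.exp(-profile.distance_decay * d)
    decay /= decay.mean()  # keep the class densities interpretable
    base = np.where(same > 0, profile.intra_module_density,
                    profile.inter_module_density)
    p = np.minimum(base * decay, 1.0)
    present = rng.random(p.size) < p
    w = profile.weight_scale * rng.lognormal(0.0, 1.0, p.size)
    weights = np.where(present, np.maximum(np.rint(w), 1.0), 0.0)
    return weights, modules


def generate_connectome(profile: ConnectomeProfile,
                        subject_id: str = "S000",
                        group: str = "adult") -> ConnectivityMatrix:
    """One subject's fiber-count matrix drawn from the profile backbone."""
    weights, _ = _backbone(profile)
    counts = squareform(weights).astype(np.int64)
    return ConnectivityMatrix(counts, subject_id=subject_id, group=group)


def generate_group(profile: ConnectomeProfile, n_subjects: int,
                   group: str = "adult") -> list[ConnectivityMatrix]:
    """A cohort of subjects sharing the profile's structural backbone.

    Each subject perturbs the backbone weights with independent symmetric
    multiplicative lognormal noise (sd ``profile.noise_sd``); noise_sd = 0
    reproduces the backbone exactly for every subject.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    weights, _ = _backbone(profile)
    group_seed = zlib.crc32(group.encode())
    subjects = []
    for i in range(n_subjects):
        rng = np.random.default_rng((profile.seed, group_seed, i))
        noise = np.exp(profile.noise_sd * rng.normal(size=weights.size))
        counts = squareform(np.rint(weights * noise)).astype(np.int64)
        subjects.append(ConnectivityMatrix(
            counts, subject_id=f"{group}-{i:03d}", group=group))
    return subjects


def write_connectivity(C: ConnectivityMatrix, path,
                       format: str = "matrix") -> None:
    """Write as a whitespace-delimited square matrix or a weighted edge
    list ("i j count", 0-based, upper triangle only); both round-trip."""
    with open(path, "w") as fh:
        fh.write(f"# subject {C.subject_id} group {C.group}\n")
        if format == "matrix":
            for row in C.counts:
                fh.write(" ".join(str(int(x)) for x in row) + "\n")
        elif format == "edgelist":
            fh.write(f"# nodes {C.n_rois}\n")
            rows, cols = np.nonzero(np.triu(C.counts, k=1))
            for i, j in zip(rows, cols):
                fh.write(f"{i} {j} {int(C.counts[i, j])}\n")
        else:
            raise ValueError(f"unknown format: {format!r}")


def read_connectivity(path, format: str = "matrix") -> ConnectivityMatrix:
    """Inverse of :func:`write_connectivity`."""
    subject_id, group, n_declared = "S000", "adult", None
    rows = []
    triples = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split()
                if parts[:1] == ["subject"]:
                    subject_id = parts[1]
                    if len(parts) >= 4 and parts[2] == "group":
                        group = parts[3]
                elif parts[:1] == ["nodes"]:
                    n_declared = int(parts[1])
                continue
            vals = [int(x) for x in line.split()]
            if format == "matrix":
                rows.append(vals)
            else:
                triples.append(vals)
    if format == "matrix":
        counts = np.array(rows, dtype=np.int64)
    elif format == "edgelist":
        n = n_declared if n_declared is not None else (
            max((max(i, j) for i, j, _ in triples), default=-1) + 1)
        counts = np.zeros((n, n), dtype=np.int64)
        for i, j, c in triples:
            counts[i, j] = counts[j, i] = c
    else:
        raise ValueError(f"unknown format: {format!r}")
    return ConnectivityMatrix(counts, subject_id=subject_id, group=group)
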